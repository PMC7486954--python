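"""Codon-usage bias analytics: ENC, preferred codons, Fop and S.

ENC is Wright's effective number of codons: for an amino acid with k
synonymous codons observed n times with frequencies p_i, the codon
homozygosity estimate is

    F = (n * sum p_i^2 - 1) / (n - 1)

and ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, averaging F within each
degeneracy class (an absent 3-fold class is imputed as the mean of the
2- and 4-fold averages).  ENC runs from 20 (one codon per amino acid)
to 61 (uniform synonymous usage).

The strength of selected codon usage bias S = 4*Ne*s follows the
mutation-selection-drift equilibrium for a two-codon amino acid whose
preferred codon is GC-ending: with mutational bias b = u(GC->AT) /
u(AT->GC), the equilibrium frequency P of the preferred codon obeys
P/(1-P) = exp(S)/b, so S = ln[(P/(1-P)) * b].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")

SYNONYMS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    SYNONYMS.setdefault(GENETIC_CODE[_c], []).append(_c)

#: Degeneracy class of each amino acid (Leu/Ser/Arg are 6-fold).
DEGENERACY = {aa: len(cods) for aa, cods in SYNONYMS.items()}

#: The eight amino acids encoded by exactly two codons where one
#: synonym is GC-ending; the set over which S is estimated.
TWOFOLD_S_SET = ("F", "Y", "H", "Q", "N", "K", "D", "E")


@dataclass
class GeneCodonStats:
    gene: str
    counts: dict[str, int]
    n_codons: int
    gc3s: float
    enc: float | None
    low_confidence: bool = False
    internal_stop: bool = False


@dataclass
class CodonUsageTable:
    """Per-gene codon counts and summary statistics."""

    genes: list[GeneCodonStats]
    preferred: dict[str, str] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene": g.gene, "n_codons": g.n_codons, "gc3s": g.gc3s,
              "enc": g.enc, "low_confidence": g.low_confidence,
              "internal_stop": g.internal_stop} for g in self.genes])

    def pooled_counts(self, genes: set[str] | None = None) -> dict[str, int]:
        pooled = {c: 0 for c in SENSE_CODONS}
        for g in self.genes:
            if genes is not None and g.gene not in genes:
                continue
            for c, n in g.counts.items():
                pooled[c] += n
        return pooled


def codon_counts(cds: str, gene: str = "", min_codons: int = 100,
                 ) -> GeneCodonStats:
    """Count sense codons in a start-to-stop-frame CDS and compute GC3s.

    Stop codons are excluded from the counts; GC3s is the GC fraction
    at third positions of codons in synonymous families (Met, Trp and
    stops excluded).  A gene with an internal stop codon keeps its
    counts but is flagged and excluded from ENC.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"gene {gene or '?'}: CDS length {len(cds)} not divisible by 3")
    counts = {c: 0 for c in SENSE_CODONS}
    gc3 = syn3 = 0
    internal_stop = False
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for i, codon in enumerate(codons):
        aa = GENETIC_CODE.get(codon)
        if aa is None:
            continue  # ambiguous bases
        if aa == "*":
            if i < len(codons) - 1:
                internal_stop = True
            continue
        counts[codon] += 1
        if DEGENERACY[aa] > 1:
            syn3 += 1
            gc3 += codon[2] in "GC"
    n = sum(counts.values())
    gc3s = gc3 / syn3 if syn3 else float("nan")
    enc_value = None if internal_stop else enc(counts)
    return GeneCodonStats(gene=gene, counts=counts, n_codons=n, gc3s=gc3s,
                          enc=enc_value, low_confidence=n < min_codons,
                          internal_stop=internal_stop)


def _family_f(counts: dict[str, int], aa: str) -> tuple[float, int] | None:
    cods = SYNONYMS[aa]
    n = sum(counts[c] for c in cods)
    if n < 2:
        return None
    p2 = sum((counts[c] / n) ** 2 for c in cods)
    f = (n * p2 - 1) / (n - 1)
    return f, n


def enc(counts: dict[str, int]) -> float | None:
    """Wright's effective number of codons from one gene's codon counts.

    Returns None when a degeneracy-class average is undefined and
    cannot be imputed.  Capped at 61.
    """
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, k in DEGENERACY.items():
        if k == 1:
            continue
        fn = _family_f(counts, aa)
        if fn is not None and fn[0] > 0:
            by_class[k].append(fn[0])
    fbar = {k: (np.mean(v) if v else None) for k, v in by_class.items()}
    if fbar[3] is None and fbar[2] is not None and fbar[4] is not None:
        fbar[3] = (fbar[2] + fbar[4]) / 2  # Ile often absent in short genes
    if any(fbar[k] is None for k in (2, 3, 4, 6)):
        return None
    value = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return float(min(value, 61.0))


def usage_from_sequences(cds_seqs: dict[str, str],
                         min_codons: int = 100) -> CodonUsageTable:
    genes = [codon_counts(seq, gene=name, min_codons=min_codons)
             for name, seq in cds_seqs.items()]
    return CodonUsageTable(genes=genes)


def identify_preferred_codons(usage: CodonUsageTable, tail: float = 0.05,
                              alpha: float = 0.01) -> dict[str, str]:
    """Preferred codon per amino acid from ENC-ranked extreme gene sets.

    Genes are ranked by ENC (ascending = most biased); the top ``tail``
    fraction forms the high-bias set and the bottom fraction the
    low-bias set.  For each amino acid a two-way chi-square contingency
    test (codon x set) at ``alpha`` decides whether usage differs; if
    so, the codon most enriched in the high-bias set is preferred.
    """
    ranked = [g for g in usage.genes if g.enc is not None]
    if len(ranked) < 20:
        raise ValueError("need at least 20 genes with defined ENC")
    ranked.sort(key=lambda g: g.enc)
    k = max(int(round(len(ranked) * tail)), 1)
    high = {g.gene for g in ranked[:k]}
    low = {g.gene for g in ranked[-k:]}
    hi_counts = usage.pooled_counts(high)
    lo_counts = usage.pooled_counts(low)

    preferred: dict[str, str] = {}
    for aa, cods in SYNONYMS.items():
        if len(cods) < 2:
            continue
        table = np.array([[hi_counts[c] for c in cods],
                          [lo_counts[c] for c in cods]], dtype=float)
        used = table.sum(axis=0) > 0
        if used.sum() < 2 or table.sum(axis=1).min() == 0:
            continue
        sub = table[:, used]
        chi2, p, _, _ = stats.chi2_contingency(sub)
        if p >= alpha:
            continue
        hi_freq = table[0] / table[0].sum()
        lo_freq = table[1] / table[1].sum()
        enrich = hi_freq - lo_freq
        order = np.argsort(enrich)[::-1]
        if len(order) > 1 and np.isclose(enrich[order[0]], enrich[order[1]]):
            continue  # tie: no preferred codon
        preferred[aa] = cods[int(order[0])]
    usage.preferred = preferred
    return preferred


def fop(usage: CodonUsageTable, preferred: dict[str, str],
        gene_subset: set[str] | None = None,
        expression: pd.DataFrame | None = None, top_n: int = 500) -> float:
    """Frequency of optimal codons pooled over a gene subset.

    Fop = preferred codons / codons of amino acids that have a
    preferred codon.  When an expression table (gene, fpkm) is given
    the subset is the top_n most expressed genes.
    """
    if not preferred:
        raise ValueError("preferred-codon set is empty")
    if expression is not None:
        ranked = expression.sort_values("fpkm", ascending=False)
        gene_subset = set(ranked["gene"].head(top_n))
    pooled = usage.pooled_counts(gene_subset)
    if gene_subset is not None:
        present = {g.gene for g in usage.genes} & gene_subset
        if not present:
            raise ValueError("gene subset is empty")
    num = den = 0
    for aa, pref in preferred.items():
        for c in SYNONYMS[aa]:
            den += pooled[c]
        num += pooled[pref]
    if den == 0:
        raise ValueError("no codons in amino acids with a preferred codon")
    return num / den


def selection_strength(fop_value: float, bias_ratio: float,
                       preferred: dict[str, str] | None = None) -> float:
    """S = ln[(Fop/(1-Fop)) * b] with b = u(GC->AT)/u(AT->GC).

    Valid for two-codon amino acids whose preferred codon is GC-ending,
    so mutation towards the preferred codon runs at the AT->GC rate.
    """
    if not 0 < fop_value < 1:
        raise ValueError("Fop must be strictly between 0 and 1")
    if bias_ratio <= 0:
        raise ValueError("mutation-bias ratio must be positive")
    if preferred is not None:
        for aa in TWOFOLD_S_SET:
            if aa in preferred and preferred[aa][2] not in "GC":
                raise ValueError(
                    f"preferred codon for {aa} is not GC-ending; "
                    "equilibrium inversion does not apply")
    return float(np.log(fop_value / (1 - fop_value) * bias_ratio))


def ne_from_codon_bias(s_strength: float, s_coef: float) -> float:
    """Long-term Ne = S / (4 s) given the per-codon selective advantage."""
    if s_coef <= 0:
        raise ValueError("selection coefficient must be positive")
    return s_strength / (4.0 * s_coef)
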