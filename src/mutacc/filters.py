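"""Callable-site definition, de novo acceptance criteria and effect classes.

A site is *callable* for a line when the mapping quality and the
sequencing depth in both that line and the ancestor allow a confident
diploid genotype call: MQ >= 20 and both depths within [20, 150] (the
upper cap excludes collapsed repeats).  A candidate becomes an
accepted de novo mutation when, in order:

  1. mapping quality >= min_mq,
  2. depth >= min_depth in the line and the ancestor,
  3. depth <= max_depth in the line and the ancestor,
  4. the alt allele is supported by >= 1/3 of the total depth
     (inclusive: exactly one third passes),
  5. the site is > 5 bp from the nearest indel record,
  6. the alt allele is absent from the ancestor,
  7. the alt allele is absent from every other MA line.

The first failing criterion is recorded as the rejection reason.
Criteria 6-7 operationalise the cross-sample check: a variant shared
with the ancestor or another line cannot be an independent de novo
event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import GENETIC_CODE
from .genome import COMPLEMENT, GeneModel, Genome
from .io import CandidateTable

#: Rejection reasons, in evaluation order.
REASONS = ("low_mq", "low_depth", "high_depth", "low_alt_fraction",
           "near_indel", "ancestral", "shared_line", "not_callable")

EFFECT_CLASSES = ("intergenic", "UTR", "intron", "synonymous", "missense",
                  "stop_gained", "start_lost", "splice_region")

MUTATION_COLUMNS = ["line", "contig", "pos", "ref", "alt", "compartment",
                    "context", "cpg", "effect"]


@dataclass(frozen=True)
class FilterParams:
    min_mq: float = 20.0
    min_depth: int = 20
    max_depth: int = 150
    min_alt_fraction: float = 1.0 / 3.0
    indel_window: int = 5          # reject when distance <= this
    cross_line_unique: bool = True
    splice_window: int = 3         # bp either side of an exon-intron boundary

    def __post_init__(self) -> None:
        if not 0 < self.min_depth <= self.max_depth:
            raise ValueError("need 0 < min depth <= max depth")
        if not 0 < self.min_alt_fraction <= 1:
            raise ValueError("alt fraction threshold must be in (0, 1]")


@dataclass
class PileupStats:
    """Per-site mapping quality and per-sample depth over a shared
    coordinate space (one array per contig, index = 0-based position)."""

    mq: dict[str, np.ndarray]
    depth: dict[str, dict[str, np.ndarray]]  # sample -> contig -> depths

    def samples(self) -> list[str]:
        return list(self.depth)

    def check_coords(self) -> None:
        for sample, per_contig in self.depth.items():
            if set(per_contig) != set(self.mq):
                raise ValueError(f"sample {sample}: contig set mismatch")
            for contig, arr in per_contig.items():
                if len(arr) != len(self.mq[contig]):
                    raise ValueError(
                        f"sample {sample}, contig {contig}: length mismatch")


def compute_callable_sites(stats: PileupStats, line: str, ancestor: str,
                           params: FilterParams = FilterParams(),
                           ) -> tuple[dict[str, np.ndarray], int]:
    """Callable mask and count for one line against the ancestor."""
    stats.check_coords()
    masks: dict[str, np.ndarray] = {}
    total = 0
    for contig, mq in stats.mq.items():
        dl = stats.depth[line][contig]
        da = stats.depth[ancestor][contig]
        mask = ((mq >= params.min_mq)
                & (dl >= params.min_depth) & (da >= params.min_depth)
                & (dl <= params.max_depth) & (da <= params.max_depth))
        masks[contig] = mask
        total += int(mask.sum())
    return masks, total


def filter_candidates(candidates: CandidateTable,
                      params: FilterParams = FilterParams(),
                      genome: Genome | None = None,
                      callable_masks: dict[str, dict[str, np.ndarray]] | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the acceptance criteria per (candidate, line).

    A candidate is evaluated for every MA line carrying at least one
    alt-supporting read.  Returns (accepted, rejections); accepted rows
    are mutation records (with context/effect when a genome is given),
    rejections carry the first failing criterion.
    """
    df = candidates.table
    lines = candidates.lines
    anc = candidates.ancestor
    accepted: list[dict] = []
    rejected: list[dict] = []

    for row in df.itertuples():
        if genome is not None:
            seq = genome.sequences.get(row.contig)
            if seq is None or not (1 <= row.pos <= len(seq)):
                raise ValueError(
                    f"candidate at unknown position {row.contig}:{row.pos}")
        anc_ad = int(df.at[row.Index, f"AD:{anc}"])
        anc_dp = int(df.at[row.Index, f"DP:{anc}"])
        carriers = [ln for ln in lines if int(df.at[row.Index, f"AD:{ln}"]) > 0]
        for line in carriers:
            dp = int(df.at[row.Index, f"DP:{line}"])
            ad = int(df.at[row.Index, f"AD:{line}"])
            reason = _first_failure(row, dp, ad, anc_dp, anc_ad, line,
                                    carriers, params, callable_masks)
            base = {"line": line, "contig": row.contig, "pos": int(row.pos),
                    "ref": row.ref, "alt": row.alt}
            if reason is None:
                accepted.append(_mutation_record(base, genome, params))
            else:
                rejected.append({**base, "reason": reason})

    acc = pd.DataFrame(accepted, columns=MUTATION_COLUMNS)
    rej = pd.DataFrame(rejected, columns=["line", "contig", "pos", "ref",
                                          "alt", "reason"])
    return acc, rej


def _first_failure(row, dp, ad, anc_dp, anc_ad, line, carriers, params,
                   callable_masks):
    if row.mq < params.min_mq:
        return "low_mq"
    if dp < params.min_depth or anc_dp < params.min_depth:
        return "low_depth"
    if dp > params.max_depth or anc_dp > params.max_depth:
        return "high_depth"
    if callable_masks is not None:
        mask = callable_masks[line].get(row.contig)
        if mask is None or not mask[int(row.pos) - 1]:
            return "not_callable"
    if ad < dp * params.min_alt_fraction:
        return "low_alt_fraction"
    if row.dist_indel <= params.indel_window:
        return "near_indel"
    if anc_ad > 0:
        return "ancestral"
    if params.cross_line_unique and len(carriers) > 1:
        return "shared_line"
    return None


def _mutation_record(base: dict, genome: Genome | None,
                     params: FilterParams) -> dict:
    rec = dict(base)
    if genome is None:
        rec.update({"compartment": "nuclear", "context": "NNN", "cpg": False,
                    "effect": "intergenic"})
        return rec
    contig, pos0 = rec["contig"], rec["pos"] - 1
    ref_genome = genome.base_at(contig, pos0)
    if ref_genome != rec["ref"]:
        raise ValueError(
            f"{contig}:{rec['pos']}: candidate ref {rec['ref']} does not "
            f"match genome {ref_genome}")
    rec["compartment"] = genome.compartments[contig]
    rec["context"] = genome.context(contig, pos0)
    rec["cpg"] = genome.is_cpg(contig, pos0)
    rec["effect"] = classify_effect(contig, rec["pos"], rec["ref"],
                                    rec["alt"], genome,
                                    splice_window=params.splice_window)
    return rec


# ---------------------------------------------------------------------------
# Effect classification

def classify_effect(contig: str, pos: int, ref: str, alt: str,
                    genome: Genome, splice_window: int = 3) -> str:
    """Functional class of a substitution at a 1-based position.

    Precedence when several annotations apply:
    splice_region > start_lost > stop_gained > missense > synonymous >
    UTR > intron > intergenic.  Codon effects are computed by
    translating the annotated reading frame on the coding strand.
    """
    pos0 = pos - 1
    seq = genome.sequences.get(contig)
    if seq is None or not 0 <= pos0 < len(seq):
        raise ValueError(f"position {contig}:{pos} outside coordinate space")
    best_rank = len(EFFECT_CLASSES)
    best = "intergenic"
    rank = {c: i for i, c in enumerate(
        ("splice_region", "start_lost", "stop_gained", "missense",
         "synonymous", "UTR", "intron", "intergenic"))}
    for gene in genome.genes:
        if gene.contig != contig:
            continue
        s, e = gene.span
        if not s <= pos0 < e:
            continue
        eff = _effect_in_gene(gene, pos0, ref, alt, seq, splice_window)
        if eff is not None and rank[eff] < best_rank:
            best_rank, best = rank[eff], eff
    return best


def _effect_in_gene(gene: GeneModel, pos0: int, ref: str, alt: str,
                    seq: str, splice_window: int) -> str | None:
    for istart, iend in gene.introns:
        for junction in (istart, iend):
            if junction - splice_window <= pos0 < junction + splice_window:
                return "splice_region"
    for s, e in gene.cds:
        if s <= pos0 < e:
            return _codon_effect(gene, pos0, ref, alt, seq)
    for s, e in gene.utr5 + gene.utr3:
        if s <= pos0 < e:
            return "UTR"
    for s, e in gene.introns:
        if s <= pos0 < e:
            return "intron"
    return None


def _codon_effect(gene: GeneModel, pos0: int, ref: str, alt: str,
                  seq: str) -> str:
    if gene.cds_length() % 3 != 0:
        raise ValueError(f"gene {gene.gene_id}: CDS length not divisible by 3")
    offset = 0
    for s, e in sorted(gene.cds):
        if s <= pos0 < e:
            offset += pos0 - s
            break
        offset += e - s
    cds_seq = gene.cds_sequence(seq)
    if gene.strand == "-":
        offset = len(cds_seq) - 1 - offset
        ref_c, alt_c = ref.translate(COMPLEMENT), alt.translate(COMPLEMENT)
    else:
        ref_c, alt_c = ref, alt
    if cds_seq[offset] != ref_c:
        raise ValueError(
            f"gene {gene.gene_id}: reference base mismatch in CDS frame")
    ci, within = divmod(offset, 3)
    ref_codon = cds_seq[3 * ci:3 * ci + 3]
    alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1:]
    ref_aa = GENETIC_CODE[ref_codon]
    alt_aa = GENETIC_CODE[alt_codon]
    if ci == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gained"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


def spectrum_table(accepted: pd.DataFrame) -> pd.DataFrame:
    """Per-effect-class counts of the accepted mutations (conserving totals)."""
    counts = {c: 0 for c in EFFECT_CLASSES}
    for eff in accepted.get("effect", []):
        counts[eff] += 1
    table = pd.DataFrame({"effect": list(counts), "count": list(counts.values())})
    assert table["count"].sum() == len(accepted)
    return table


def score_calls(accepted: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity and false positives of accepted calls against a truth set.

    Keys on (line, contig, pos, alt).
    """
    key = ["line", "contig", "pos", "alt"]
    acc = set(map(tuple, accepted[key].itertuples(index=False))) if len(accepted) else set()
    tru = set(map(tuple, truth[key].itertuples(index=False))) if len(truth) else set()
    tp = len(acc & tru)
    return {
        "sensitivity": tp / len(tru) if tru else float("nan"),
        "false_positives": len(acc - tru),
        "true_positives": tp,
        "n_truth": len(tru),
    }
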