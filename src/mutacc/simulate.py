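"""Synthetic mutation-accumulation experiments.

Generates every input the analysis consumes - a diploid genome with
gene models, per-line de novo mutations, variant-call candidates with
labelled artifacts, codon usage under the mutation-selection-drift
equilibrium, expression values and bottleneck cell-count trajectories -
with the statistical structure the downstream estimators assume, so the
whole pipeline is testable without sequencing data.

Study-scale emulation: 15 diploid lines bottlenecked to a single cell
every 14 days, ~1.17 cell divisions per day, a GC-rich (65.7%) genome,
a GC-biased 6-class spectrum with transition/transversion ratio ~1.11,
and codon bias at selection strength S ~ 1.084 against mutational bias
b ~ 0.381.  The genome length and per-division rate default to a
desk-scale pairing (1 Mb at mu = 1e-7) that preserves the expected
per-line mutation counts of the study.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codon import SYNONYMS, TWOFOLD_S_SET
from .filters import FilterParams, PileupStats, compute_callable_sites
from .genome import GeneModel, Genome, revcomp
from .io import CandidateTable, CANDIDATE_CORE

#: Six-class spectrum weights consistent with the study's pooled totals
#: (207 AT->GC vs 151 GC->AT, 97 GC-conserving, ts/tv = 239/216 ~ 1.11).
DEFAULT_SPECTRUM = {
    "AT>GC": 155, "GC>AT": 84, "AT>TA": 48,
    "AT>CG": 52, "GC>TA": 67, "GC>CG": 49,
}

ARTIFACT_CLASSES = ("low_mq", "low_depth", "high_depth",
                    "low_alt_fraction", "near_indel", "ancestral")

_ALT_OF = {
    ("AT>GC", "A"): "G", ("AT>GC", "T"): "C",
    ("AT>TA", "A"): "T", ("AT>TA", "T"): "A",
    ("AT>CG", "A"): "C", ("AT>CG", "T"): "G",
    ("GC>AT", "G"): "A", ("GC>AT", "C"): "T",
    ("GC>TA", "G"): "T", ("GC>TA", "C"): "A",
    ("GC>CG", "G"): "C", ("GC>CG", "C"): "G",
}

_GC_ENDING = {aa: next(c for c in SYNONYMS[aa] if c[2] in "GC")
              for aa in TWOFOLD_S_SET}
_AT_ENDING = {aa: next(c for c in SYNONYMS[aa] if c[2] in "AT")
              for aa in TWOFOLD_S_SET}
_BODY_AAS = sorted(set(SYNONYMS) - {"M", "W"})
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic MA experiment; seed fixes every draw."""

    genome_length: int = 1_000_000
    gc_content: float = 0.657
    n_genes: int = 60
    mean_cds_length: int = 900           # nt, divisible by 3 after rounding
    n_lines: int = 15
    n_cycles: int = 14                   # 14-day bottleneck cycles
    cycle_days: int = 14
    divisions_per_day: float = 1.17
    generations: int | None = None       # overrides the cycle arithmetic
    mu_true: float = 1e-7                # per site per division
    ploidy: int = 2
    spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM))
    ts_tv: float | None = None           # derived from spectrum when None
    coverage_mean: float = 50.0
    artifact_means: dict[str, float] = field(
        default_factory=lambda: {c: 5.0 for c in ARTIFACT_CLASSES})
    s_true: float = 1.084
    bias_ratio: float = 0.38083          # b = u(GC->AT)/u(AT->GC)
    gc3_bias: float = 0.842              # P(G/C third base) outside the S set
    high_expression_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("GC fraction must be in (0, 1)")
        if self.mu_true < 0:
            raise ValueError("mu_true must be non-negative")
        w = np.array([self.spectrum.get(c, 0.0) for c in DEFAULT_SPECTRUM])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("spectrum weights must be >= 0 with positive sum")

    @property
    def generations_per_line(self) -> int:
        if self.generations is not None:
            return self.generations
        return int(round(self.n_cycles * self.cycle_days
                         * self.divisions_per_day))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TrueMutationSet:
    """Ground-truth mutations plus the growth bookkeeping of each line."""

    mutations: pd.DataFrame            # line, contig, pos, ref, alt
    generations: dict[str, int]
    cell_counts: pd.DataFrame          # line, cycle, day, cells

    def counts_per_line(self) -> pd.Series:
        base = pd.Series(0, index=list(self.generations))
        got = self.mutations.groupby("line").size()
        return base.add(got, fill_value=0).astype(int)

    def validate(self, genome: Genome) -> None:
        dup = self.mutations.duplicated(subset=["line", "contig", "pos"])
        if dup.any():
            raise ValueError("duplicate positions within a line")
        for row in self.mutations.itertuples():
            if genome.base_at(row.contig, row.pos - 1) != row.ref:
                raise ValueError(f"truth ref mismatch at {row.contig}:{row.pos}")


# ---------------------------------------------------------------------------
# Genome generation

def generate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> Genome:
    """A random genome with non-overlapping gene models at the target GC.

    Genes are implanted as valid ORFs (ATG ... stop, no internal stop)
    with UTRs and introns; the intergenic base composition is adjusted
    so the realized genome-wide GC matches the target within binomial
    noise despite the constrained coding sequence.
    """
    rng = rng or config.rng()
    L = config.genome_length
    contig = "chr1"
    genes: list[GeneModel] = []
    seq = np.frombuffer(_random_bases(L, config.gc_content, rng),
                        dtype="S1").copy()

    utr_len, intron_len = 60, 60
    footprint = config.mean_cds_length + 2 * utr_len + 2 * intron_len
    gap_mean = (L - config.n_genes * footprint) // max(config.n_genes + 1, 1)
    if config.n_genes > 0 and gap_mean < 20:
        raise ValueError("genes cannot be placed: genome too dense")
    gap_mean = max(gap_mean, 40)

    cursor = int(rng.integers(20, max(gap_mean, 21)))
    genic_intervals: list[tuple[int, int]] = []
    for gi in range(config.n_genes):
        n_codons = max(int(round(rng.normal(config.mean_cds_length / 3, 20))), 50)
        cds_seq = _random_cds(n_codons, rng, config.gc3_bias)
        n_exons = int(rng.integers(1, 4))
        pieces = _split_cds(len(cds_seq), n_exons)
        strand = "+" if rng.random() < 0.5 else "-"

        start = cursor
        utr5 = [(start, start + utr_len)]
        pos = start + utr_len
        cds_ivals = []
        for k, plen in enumerate(pieces):
            cds_ivals.append((pos, pos + plen))
            pos += plen
            if k < len(pieces) - 1:
                pos += intron_len
        utr3 = [(pos, pos + utr_len)]
        end = pos + utr_len
        if end >= L:
            if gi == 0:
                raise ValueError("genes cannot be placed: genome too short")
            break
        gene = GeneModel(gene_id=f"gene_{gi + 1:04d}", contig=contig,
                         strand=strand, cds=cds_ivals,
                         utr5=utr5 if strand == "+" else utr3,
                         utr3=utr3 if strand == "+" else utr5)
        _write_cds(seq, gene, cds_seq)
        genes.append(gene)
        genic_intervals.append((start, end))
        cursor = end + int(rng.integers(20, 2 * gap_mean + 21))
        if cursor >= L - utr_len:
            break

    _rebalance_intergenic(seq, genic_intervals, config.gc_content, L, rng)
    genome = Genome(sequences={contig: seq.tobytes().decode()},
                    compartments={contig: "nuclear"}, genes=genes)
    genome.validate()
    return genome


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> bytes:
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"GCAT", dtype="S1"), size=n, p=p).tobytes()


def _random_cds(n_codons: int, rng: np.random.Generator,
                gc3: float, p_pref: float | None = None) -> str:
    """ATG + body codons + stop; third-base GC bias, no internal stops.

    ``p_pref`` overrides the third-base draw for the eight two-codon
    amino acids used in selection-strength estimation: their GC-ending
    synonym is chosen with that probability (equilibrium frequency).
    """
    body = []
    for _ in range(n_codons - 2):
        aa = _BODY_AAS[rng.integers(len(_BODY_AAS))]
        if aa in TWOFOLD_S_SET and p_pref is not None:
            codon = _GC_ENDING[aa] if rng.random() < p_pref else _AT_ENDING[aa]
        else:
            cods = SYNONYMS[aa]
            want_gc = rng.random() < gc3
            pool = [c for c in cods if (c[2] in "GC") == want_gc] or cods
            codon = pool[rng.integers(len(pool))]
        body.append(codon)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(body) + stop


def _split_cds(total: int, n_exons: int) -> list[int]:
    per = total // (3 * n_exons) * 3
    pieces = [per] * (n_exons - 1)
    pieces.append(total - per * (n_exons - 1))
    return [p for p in pieces if p > 0]


def _write_cds(seq: np.ndarray, gene: GeneModel, cds_seq: str) -> None:
    s = cds_seq if gene.strand == "+" else revcomp(cds_seq)
    offset = 0
    for a, b in sorted(gene.cds):
        seq[a:b] = np.frombuffer(s[offset:offset + (b - a)].encode(), dtype="S1")
        offset += b - a


def _rebalance_intergenic(seq: np.ndarray, genic: list[tuple[int, int]],
                          target_gc: float, L: int,
                          rng: np.random.Generator) -> None:
    genic_mask = np.zeros(L, dtype=bool)
    for s, e in genic:
        genic_mask[s:e] = True
    inter_idx = np.flatnonzero(~genic_mask)
    if inter_idx.size == 0:
        return
    genic_gc = int(np.isin(seq[genic_mask], [b"G", b"C"]).sum())
    want = target_gc * L - genic_gc
    p = min(max(want / inter_idx.size, 0.0), 1.0)
    seq[inter_idx] = np.frombuffer(
        _random_bases(inter_idx.size, p, rng), dtype="S1")


def implant_cds(genome: Genome, cds_seqs: dict[str, str]) -> Genome:
    """Write per-gene CDS sequences into the genome (strand-aware)."""
    arrays = {c: np.frombuffer(s.encode(), dtype="S1").copy()
              for c, s in genome.sequences.items()}
    for gene in genome.genes:
        if gene.gene_id not in cds_seqs:
            continue
        cds_seq = cds_seqs[gene.gene_id]
        if len(cds_seq) != gene.cds_length():
            raise ValueError(f"{gene.gene_id}: CDS length mismatch")
        _write_cds(arrays[gene.contig], gene, cds_seq)
    return Genome(sequences={c: a.tobytes().decode() for c, a in arrays.items()},
                  compartments=dict(genome.compartments), genes=genome.genes)


# ---------------------------------------------------------------------------
# MA-line mutations

def simulate_ma_lines(genome: Genome, config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      ) -> TrueMutationSet:
    """Draw per-line de novo mutations and the bottleneck growth record.

    Counts are Poisson with mean ploidy * L * generations * mu_true;
    each mutation's class comes from the 6-class spectrum and its site
    is uniform among reference sites of the matching base class
    (infinite-sites: positions unique within a line, warning when the
    expected count approaches saturation).
    """
    rng = rng or config.rng()
    weights = np.array([config.spectrum.get(c, 0.0)
                        for c in DEFAULT_SPECTRUM], dtype=float)
    weights /= weights.sum()
    classes = list(DEFAULT_SPECTRUM)
    at_idx, gc_idx, contig_of, pos_of, base_of = _site_index(genome)

    rows = []
    generations: dict[str, int] = {}
    cells = []
    L = genome.size
    for li in range(config.n_lines):
        line = f"MA_{li + 1:02d}"
        gens = config.generations_per_line
        generations[line] = gens
        mean = config.ploidy * L * gens * config.mu_true
        if mean > L / 10:
            warnings.warn("expected mutation count approaches saturation; "
                          "infinite-sites approximation violated")
        n = int(rng.poisson(mean))
        per_class = rng.multinomial(n, weights)
        n_at = int(per_class[[0, 2, 3]].sum())   # AT>GC, AT>TA, AT>CG
        n_gc = int(per_class[[1, 4, 5]].sum())
        at_sites = rng.choice(at_idx, size=min(n_at, at_idx.size),
                              replace=False)
        gc_sites = rng.choice(gc_idx, size=min(n_gc, gc_idx.size),
                              replace=False)
        site_pools = {"AT": list(at_sites), "GC": list(gc_sites)}
        for cls, k in zip(classes, per_class):
            pool = site_pools[cls[:2]]
            for _ in range(int(k)):
                if not pool:
                    break
                gidx = pool.pop()
                ref = base_of[gidx]
                rows.append({"line": line, "contig": contig_of[gidx],
                             "pos": int(pos_of[gidx]) + 1, "ref": ref,
                             "alt": _ALT_OF[(cls, ref)], "klass": cls})
        for cyc in range(config.n_cycles):
            # day 0 is the founding single cell; the day-14 transfer
            # census coincides with the next cycle's founding dilution
            for day in range(config.cycle_days):
                cells.append({"line": line, "cycle": cyc + 1, "day": day,
                              "cells": 2.0 ** (config.divisions_per_day * day)})

    mutations = pd.DataFrame(
        rows, columns=["line", "contig", "pos", "ref", "alt", "klass"])
    truth = TrueMutationSet(mutations=mutations, generations=generations,
                            cell_counts=pd.DataFrame(cells))
    truth.validate(genome)
    return truth


def _site_index(genome: Genome):
    cached = getattr(genome, "_mutacc_site_index", None)
    if cached is not None:
        return cached
    contig_of, pos_of, base_arr = [], [], []
    for contig, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        contig_of.extend([contig] * len(arr))
        pos_of.append(np.arange(len(arr)))
        base_arr.append(arr)
    base = np.concatenate(base_arr)
    pos_of = np.concatenate(pos_of)
    contig_of = np.array(contig_of)
    at_idx = np.flatnonzero((base == b"A") | (base == b"T"))
    gc_idx = np.flatnonzero((base == b"G") | (base == b"C"))
    base_of = base.astype("U1")
    out = (at_idx, gc_idx, contig_of, pos_of, base_of)
    genome._mutacc_site_index = out
    return out


# ---------------------------------------------------------------------------
# Variant-call synthesis

@dataclass
class SyntheticCalls:
    candidates: CandidateTable
    pileup: PileupStats
    audit: pd.DataFrame                  # line, contig, pos, alt, klass
    indels: pd.DataFrame                 # contig, pos, ref, alt
    experiment: pd.DataFrame             # line, generations, callable, truth counts


def synthesize_variant_calls(truth: TrueMutationSet, genome: Genome,
                             config: SimulationConfig,
                             rng: np.random.Generator | None = None,
                             with_artifacts: bool = True,
                             params: FilterParams = FilterParams(),
                             ) -> SyntheticCalls:
    """Candidate table + pileup statistics embedding the truth set.

    Every true mutation appears as a heterozygous candidate at a
    callable site (depth and alt fraction drawn from the coverage
    model, truncated to the callable/heterozygous region so that
    sensitivity is measured on callable truth).  Artifact candidates of
    the six audited classes are injected at Poisson-distributed counts
    and labelled in the audit table.
    """
    rng = rng or config.rng()
    ancestor = "ancestor"
    lines = list(truth.generations)
    samples = lines + [ancestor]

    mq = {c: np.full(len(s), 60.0, dtype=np.float32)
          for c, s in genome.sequences.items()}
    depth = {smp: {c: rng.poisson(config.coverage_mean, len(s)).astype(np.int32)
                   for c, s in genome.sequences.items()}
             for smp in samples}
    pileup = PileupStats(mq=mq, depth=depth)

    used: set[tuple[str, int]] = set(
        (r.contig, int(r.pos)) for r in truth.mutations.itertuples())
    cand_rows: list[dict] = []
    audit_rows: list[dict] = []
    indel_rows: list[dict] = []

    def _blank_row(contig, pos, ref, alt, mq_val=60.0):
        row = {"contig": contig, "pos": pos, "ref": ref, "alt": alt,
               "mq": float(mq_val), "dist_indel": np.inf}
        for s in samples:
            row[f"DP:{s}"] = int(depth[s][contig][pos - 1])
            row[f"AD:{s}"] = 0
        return row

    # -- true mutations: callable heterozygous candidates
    for r in truth.mutations.itertuples():
        contig, pos = r.contig, int(r.pos)
        for smp in (r.line, ancestor):
            d = depth[smp][contig]
            d[pos - 1] = int(np.clip(d[pos - 1], params.min_depth,
                                     params.max_depth))
        row = _blank_row(contig, pos, r.ref, r.alt)
        dp = row[f"DP:{r.line}"]
        ad = int(rng.binomial(dp, 0.5))
        ad = int(np.clip(ad, math.ceil(dp * params.min_alt_fraction), dp))
        row[f"AD:{r.line}"] = ad
        cand_rows.append(row)

    if with_artifacts:
        for klass in ARTIFACT_CLASSES:
            n = int(rng.poisson(config.artifact_means.get(klass, 0.0)))
            for _ in range(n):
                contig, pos = _free_site(genome, used, rng)
                ref = genome.base_at(contig, pos - 1)
                alt = rng.choice([b for b in "ACGT" if b != ref])
                line = lines[int(rng.integers(len(lines)))]
                row = _inject_artifact(klass, contig, pos, ref, alt, line,
                                       lines, ancestor, depth, mq, rng,
                                       params, _blank_row, indel_rows, used,
                                       genome)
                cand_rows.append(row)
                audit_rows.append({"line": line, "contig": contig, "pos": pos,
                                   "alt": alt, "klass": klass})

    columns = CANDIDATE_CORE + [f"{k}:{s}" for s in samples
                                for k in ("DP", "AD")]
    table = pd.DataFrame(cand_rows, columns=columns).sort_values(
        ["contig", "pos"], kind="stable").reset_index(drop=True)
    indels = pd.DataFrame(indel_rows, columns=["contig", "pos", "ref", "alt"])
    _set_indel_distances(table, indels)
    candidates = CandidateTable(table=table, samples=samples,
                                ancestor=ancestor)

    exp_rows = []
    for line in lines:
        _, n_callable = compute_callable_sites(pileup, line, ancestor, params)
        exp_rows.append({"line": line,
                         "generations": truth.generations[line],
                         "callable_sites": n_callable,
                         "mutations": int((truth.mutations["line"] == line).sum())})
    experiment = pd.DataFrame(exp_rows)

    return SyntheticCalls(candidates=candidates, pileup=pileup,
                          audit=pd.DataFrame(
                              audit_rows,
                              columns=["line", "contig", "pos", "alt", "klass"]),
                          indels=indels, experiment=experiment)


def _free_site(genome: Genome, used: set, rng: np.random.Generator,
               margin: int = 12) -> tuple[str, int]:
    contigs = list(genome.sequences)
    while True:
        contig = contigs[int(rng.integers(len(contigs)))]
        L = len(genome.sequences[contig])
        pos = int(rng.integers(margin + 1, L - margin))
        if all((contig, p) not in used for p in range(pos - margin,
                                                      pos + margin + 1)):
            used.add((contig, pos))
            return contig, pos


def _inject_artifact(klass, contig, pos, ref, alt, line, lines, ancestor,
                     depth, mq, rng, params, blank_row, indel_rows, used,
                     genome):
    i = pos - 1
    if klass == "low_mq":
        mq[contig][i] = float(rng.uniform(5, params.min_mq - 0.5))
    elif klass == "low_depth":
        target = line if rng.random() < 0.5 else ancestor
        depth[target][contig][i] = int(rng.integers(5, params.min_depth))
    elif klass == "high_depth":
        target = line if rng.random() < 0.5 else ancestor
        depth[target][contig][i] = int(rng.integers(params.max_depth + 1,
                                                    params.max_depth + 150))
    else:
        for smp in (line, ancestor):
            d = depth[smp][contig]
            d[i] = int(np.clip(d[i], params.min_depth, params.max_depth))
    row = blank_row(contig, pos, ref, alt, mq_val=mq[contig][i])
    dp = row[f"DP:{line}"]
    if klass == "low_alt_fraction":
        hi = max(int(np.ceil(dp * params.min_alt_fraction)), 2)
        row[f"AD:{line}"] = int(rng.integers(1, hi))
    else:
        ad = int(rng.binomial(max(dp, 1), 0.5))
        row[f"AD:{line}"] = int(np.clip(ad, max(
            math.ceil(dp * params.min_alt_fraction), 1), max(dp, 1)))
    if klass == "near_indel":
        offset = int(rng.integers(1, params.indel_window + 1))
        ipos = pos + offset
        used.add((contig, ipos))
        iref = genome.base_at(contig, ipos - 1)
        indel_rows.append({"contig": contig, "pos": ipos, "ref": iref,
                           "alt": iref + "T"})
    if klass == "ancestral":
        for smp in lines + [ancestor]:
            d = int(depth[smp][contig][i])
            ad = int(np.clip(rng.binomial(max(d, 1), 0.5), 1, max(d, 1)))
            row[f"AD:{smp}"] = ad
    return row


def _set_indel_distances(table: pd.DataFrame, indels: pd.DataFrame) -> None:
    if indels.empty or table.empty:
        return
    for contig, sub in indels.groupby("contig"):
        arr = np.sort(sub["pos"].to_numpy())
        mask = table["contig"] == contig
        pos = table.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(arr, pos)
        left = np.abs(pos - arr[np.clip(idx - 1, 0, len(arr) - 1)])
        right = np.abs(arr[np.clip(idx, 0, len(arr) - 1)] - pos)
        table.loc[mask, "dist_indel"] = np.minimum(left, right).astype(float)


# ---------------------------------------------------------------------------
# Codon usage and expression

@dataclass
class CodonSimulation:
    cds: dict[str, str]
    expression: pd.DataFrame             # gene, fpkm, high
    high_genes: set[str]
    planted_preferred: dict[str, str]
    p_high: float
    p_low: float


def equilibrium_preferred_frequency(s_true: float, bias_ratio: float) -> float:
    """P with P/(1-P) = exp(S)/b for a GC-ending preferred codon."""
    odds = math.exp(s_true) / bias_ratio
    return odds / (1.0 + odds)


def simulate_codon_usage(genome: Genome, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         ) -> CodonSimulation:
    """CDS sequences whose two-codon families sit at the S equilibrium.

    Highly expressed genes (a configurable top stratum) use the
    preferred GC-ending codon with frequency P satisfying
    P/(1-P) = exp(S_true)/b; the rest of the genes are neutral (S = 0,
    P/(1-P) = 1/b).  Expression values are log-normal with the high
    stratum shifted upward.
    """
    rng = rng or config.rng()
    p_high = equilibrium_preferred_frequency(config.s_true, config.bias_ratio)
    p_low = equilibrium_preferred_frequency(0.0, config.bias_ratio)
    genes = genome.genes
    if not genes:
        raise ValueError("annotation has no genes")
    n_high = max(int(round(len(genes) * config.high_expression_fraction)), 1)
    order = rng.permutation(len(genes))
    high_genes = {genes[i].gene_id for i in order[:n_high]}

    cds: dict[str, str] = {}
    expr_rows = []
    for g in genes:
        n_codons = g.cds_length() // 3
        p = p_high if g.gene_id in high_genes else p_low
        cds[g.gene_id] = _random_cds(n_codons, rng, config.gc3_bias,
                                     p_pref=p)
        mu_log = 2.5 if g.gene_id in high_genes else 1.0
        expr_rows.append({"gene": g.gene_id,
                          "fpkm": float(10 ** rng.normal(mu_log, 0.4)),
                          "high": g.gene_id in high_genes})
    return CodonSimulation(cds=cds,
                           expression=pd.DataFrame(expr_rows),
                           high_genes=high_genes,
                           planted_preferred=dict(_GC_ENDING),
                           p_high=p_high, p_low=p_low)


def scaled_study_config(**overrides) -> SimulationConfig:
    """The desk-scale study emulation (1 Mb genome, 15 lines, mu 1e-7)."""
    return replace(SimulationConfig(), **overrides)
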