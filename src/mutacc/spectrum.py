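"""Mutation spectrum, GC bias and equilibrium GC content.

Single-nucleotide mutations are folded into six strand-symmetric
classes (a T>C on either strand is the same biochemical event as an
A>G, so both count as A:T->G:C).  Conditional rates normalise the two
GC-changing totals by the genomic abundance of each site class:

    R1 = n(GC->AT) / GCn        R2 = n(AT->GC) / ATn

and the equilibrium GC content - the GC fraction at which the two
fluxes balance - is GC_eq = R2 / (R1 + R2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome

#: Pooled strand-symmetric class labels, in canonical order.
SPECTRUM_CLASSES = ("AT>GC", "GC>AT", "AT>TA", "AT>CG", "GC>TA", "GC>CG")

#: Transition classes (purine<->purine / pyrimidine<->pyrimidine).
TRANSITIONS = ("AT>GC", "GC>AT")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def fold_mutation(ref: str, alt: str) -> str:
    """Map a ref>alt substitution to its pooled strand-symmetric class."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref in "TG":  # fold onto the A/C representative strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return {
        ("A", "G"): "AT>GC", ("A", "T"): "AT>TA", ("A", "C"): "AT>CG",
        ("C", "T"): "GC>AT", ("C", "A"): "GC>TA", ("C", "G"): "GC>CG",
    }[(ref, alt)]


@dataclass
class SpectrumSummary:
    """Pooled class counts with conditional rates and equilibrium GC."""

    counts: dict[str, int]
    gcn: int
    atn: int
    skipped: int = 0
    r1: float = field(init=False)
    r2: float = field(init=False)
    gc_eq: float = field(init=False)
    ts_tv: float | None = field(init=False)

    def __post_init__(self) -> None:
        # R1/R2 use only the GC-content-changing totals
        gc_to_at = self.counts["GC>AT"] + self.counts["GC>TA"]
        at_to_gc = self.counts["AT>GC"] + self.counts["AT>CG"]
        self.r1 = gc_to_at / self.gcn if self.gcn else float("nan")
        self.r2 = at_to_gc / self.atn if self.atn else float("nan")
        self.gc_eq = (self.r2 / (self.r1 + self.r2)
                      if (self.r1 + self.r2) > 0 else float("nan"))
        ts = sum(self.counts[c] for c in TRANSITIONS)
        tv = sum(v for c, v in self.counts.items() if c not in TRANSITIONS)
        self.ts_tv = ts / tv if tv > 0 else None  # undefined without transversions

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_gc_to_at(self) -> int:
        return self.counts["GC>AT"] + self.counts["GC>TA"]

    @property
    def n_at_to_gc(self) -> int:
        return self.counts["AT>GC"] + self.counts["AT>CG"]


def classify_spectrum(mutations: pd.DataFrame, genome: Genome | None = None,
                      gcn: int | None = None, atn: int | None = None,
                      callable_mask: dict[str, np.ndarray] | None = None,
                      ) -> SpectrumSummary:
    """Fold mutations (columns ref, alt) into the six pooled classes.

    GCn/ATn site counts come from the callable reference space when a
    mask is supplied, from the whole genome otherwise, or can be given
    directly.  Records with ambiguous bases are skipped and counted.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    skipped = 0
    for ref, alt in zip(mutations["ref"], mutations["alt"]):
        try:
            counts[fold_mutation(ref, alt)] += 1
        except ValueError:
            skipped += 1
    if gcn is None or atn is None:
        if genome is None:
            raise ValueError("need a genome or explicit GCn/ATn site counts")
        gcn, atn = count_site_classes(genome, callable_mask)
    return SpectrumSummary(counts=counts, gcn=gcn, atn=atn, skipped=skipped)


def count_site_classes(genome: Genome,
                       callable_mask: dict[str, np.ndarray] | None = None,
                       ) -> tuple[int, int]:
    """(GCn, ATn) over the whole genome or the callable subset."""
    gcn = atn = 0
    for contig, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        if callable_mask is not None:
            arr = arr[np.asarray(callable_mask[contig], dtype=bool)]
        gcn += int(np.sum((arr == b"G") | (arr == b"C")))
        atn += int(np.sum((arr == b"A") | (arr == b"T")))
    return gcn, atn


def gc_bias_test(n_at_to_gc: int, n_gc_to_at: int) -> float:
    """Two-sided exact binomial test of the two fluxes against 50:50."""
    if n_at_to_gc < 0 or n_gc_to_at < 0 or n_at_to_gc + n_gc_to_at == 0:
        raise ValueError("need non-negative counts, not both zero")
    return float(stats.binomtest(n_at_to_gc, n_at_to_gc + n_gc_to_at,
                                 0.5).pvalue)


def conditional_rates(n_gc_to_at: int, n_at_to_gc: int,
                      gc_fraction: float) -> tuple[float, float, float]:
    """(R1, R2, R1/R2) from flux counts and the genomic GC fraction.

    Proportionality constants cancel in the ratio and in GC_eq, so the
    site totals may be expressed as fractions.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("GC fraction must be in (0, 1)")
    r1 = n_gc_to_at / gc_fraction
    r2 = n_at_to_gc / (1.0 - gc_fraction)
    return r1, r2, r1 / r2


def equilibrium_gc(r1: float, r2: float) -> float:
    """GC_eq = R2 / (R1 + R2), the GC content where the fluxes balance."""
    if r1 < 0 or r2 < 0 or r1 + r2 == 0:
        raise ValueError("need non-negative rates with positive sum")
    return r2 / (r1 + r2)


def simulate_gc_equilibrium(r1: float, r2: float, n_sites: int = 20_000,
                            n_events: int = 1_000_000, gc_init: float = 0.5,
                            rng: np.random.Generator | None = None) -> float:
    """Forward-simulate per-site GC<->AT flips and return the realized GC.

    Each site is an independent two-state chain flipping GC->AT with
    per-step hazard proportional to R1 and AT->GC proportional to R2;
    after ~n_events total events the composition fluctuates around the
    analytic fixed point R2/(R1+R2).  Used as a simulation oracle for
    :func:`equilibrium_gc`.
    """
    rng = rng or np.random.default_rng()
    scale = max(r1, r2)
    p1, p2 = r1 / scale, r2 / scale
    # choose a step count so the expected number of events is ~n_events
    mean_p = (p1 + p2) / 2
    steps = max(int(n_events / (n_sites * mean_p * 0.25)), 50)
    is_gc = rng.random(n_sites) < gc_init
    # scale per-step probabilities down for chain stability
    step_scale = 0.25
    for _ in range(steps):
        u = rng.random(n_sites)
        flip_to_at = is_gc & (u < p1 * step_scale)
        flip_to_gc = ~is_gc & (u < p2 * step_scale)
        is_gc = is_gc & ~flip_to_at | flip_to_gc
    return float(is_gc.mean())


def cpg_analysis(genome: Genome, mutations: pd.DataFrame) -> dict:
    """CpG dinucleotide abundance and CpG-context mutation excess tests.

    The genomic null is base independence with equal C and G usage:
    expected CpG fraction (GC/2)^2.  The mutation-level null is that
    mutations at C:G sites hit CpG context in proportion to the
    fraction of C sites (either strand) that sit in a CG dinucleotide.
    """
    di_total = 0
    cpg = 0
    c_sites = 0
    c_in_cpg = 0
    for seq in genome.sequences.values():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        if len(arr) < 2:
            continue
        is_c, is_g = arr == b"C", arr == b"G"
        di_total += len(arr) - 1
        cg = is_c[:-1] & is_g[1:]
        cpg += int(cg.sum())
        # C of a CG on either strand: forward C followed by G, or G preceded by C
        c_sites += int(is_c.sum() + is_g.sum())
        c_in_cpg += int(cg.sum()) * 2
    gc = genome.gc_fraction()
    expected_cpg = (gc / 2.0) ** 2
    obs_frac = cpg / di_total if di_total else float("nan")
    chi2_genome = _one_proportion_chi2(cpg, di_total, expected_cpg)

    n_mut = len(mutations)
    n_cpg_mut = 0
    for row in mutations.itertuples():
        pos0 = int(row.pos) - 1
        if genome.is_cpg(row.contig, pos0):
            n_cpg_mut += 1
    exp_mut_frac = c_in_cpg / c_sites if c_sites else float("nan")
    chi2_mut = (_one_proportion_chi2(n_cpg_mut, n_mut, exp_mut_frac)
                if n_mut else {"chi2": float("nan"), "p_value": float("nan")})
    return {
        "cpg_fraction": obs_frac,
        "expected_cpg_fraction": expected_cpg,
        "genome_chi2": chi2_genome["chi2"],
        "genome_p": chi2_genome["p_value"],
        "cpg_mutation_fraction": n_cpg_mut / n_mut if n_mut else float("nan"),
        "expected_cpg_mutation_fraction": exp_mut_frac,
        "mutation_chi2": chi2_mut["chi2"],
        "mutation_p": chi2_mut["p_value"],
    }


def _one_proportion_chi2(observed: int, total: int, p0: float) -> dict:
    if not 0 < p0 < 1 or total == 0:  # degenerate null: test undefined
        return {"chi2": float("nan"), "p_value": float("nan")}
    exp = np.array([total * p0, total * (1 - p0)])
    obs = np.array([observed, total - observed])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return {"chi2": chi2, "p_value": float(stats.chi2.sf(chi2, 1))}


def coding_noncoding_test(n_coding: int, n_total: int,
                          callable_coding: float,
                          callable_noncoding: float) -> dict:
    """Exact binomial test of the coding-mutation count against the
    callable coding fraction."""
    if n_coding < 0 or n_total < n_coding:
        raise ValueError("bad counts")
    p0 = callable_coding / (callable_coding + callable_noncoding)
    res = stats.binomtest(n_coding, n_total, p0)
    return {"p_value": float(res.pvalue), "expected": n_total * p0,
            "observed": n_coding, "p0": p0}
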