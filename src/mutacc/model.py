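"""Model/results interface over the MA-experiment estimators.

`MutationAccumulationModel` is built from the per-line experiment
table (and optionally the accepted mutation records and genome
composition); `fit()` returns an `MAResults` carrying the per-site
rate with its exact Poisson CI, genome-wide rates, per-line
heterogeneity diagnostics, the folded mutation spectrum with its GC
equilibrium, and downstream syntheses (Ne, selection strength), with a
`summary()` table in the statsmodels idiom.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import codon, popgen, rates, spectrum
from .genome import Genome, experiment_table


class MutationAccumulationModel:
    """Per-site mutation-rate model for a set of bottlenecked MA lines.

    Parameters
    ----------
    experiment : DataFrame
        Per-line table with columns line, generations, callable_sites,
        mutations.
    mutations : DataFrame, optional
        Accepted mutation records (line, contig, pos, ref, alt, ...);
        when given, per-line counts are recomputed from it and the
        spectrum is fitted.
    genome : Genome, optional
        Provides GC composition for conditional rates; ``gc_fraction``
        can be given instead.
    ploidy : int
        Site copies per position (diploid lines accumulate on 2).
    """

    def __init__(self, experiment: pd.DataFrame,
                 mutations: pd.DataFrame | None = None,
                 genome: Genome | None = None, ploidy: int = 2,
                 genome_size: float | None = None,
                 cds_size: float | None = None,
                 gc_fraction: float | None = None):
        self.mutations = mutations
        if mutations is not None and len(mutations):
            counts = mutations.groupby("line").size()
            experiment = experiment.copy()
            experiment["mutations"] = (
                experiment["line"].map(counts).fillna(0).astype(int))
        self.experiment = experiment_table(experiment)
        self.genome = genome
        self.ploidy = ploidy
        self.genome_size = genome_size or (genome.size if genome else None)
        self.cds_size = cds_size or (genome.cds_size() if genome else None)
        if gc_fraction is None and genome is not None:
            gc_fraction = genome.gc_fraction()
        self.gc_fraction = gc_fraction

    @classmethod
    def from_tables(cls, experiment: pd.DataFrame,
                    mutations: pd.DataFrame | None = None,
                    **kwargs) -> "MutationAccumulationModel":
        return cls(experiment, mutations=mutations, **kwargs)

    @classmethod
    def from_study(cls) -> "MutationAccumulationModel":
        """The published E. huxleyi experiment (per-line exposures and counts)."""
        from . import datasets
        return cls(datasets.ehux_experiment(), ploidy=datasets.PLOIDY,
                   genome_size=datasets.GENOME_SIZE,
                   cds_size=datasets.CDS_SIZE,
                   gc_fraction=datasets.GENOMIC_GC)

    def fit(self, ci_level: float = 0.95, ci_method: str = "garwood",
            het_expectation: str = "exposure") -> "MAResults":
        total = int(self.experiment["mutations"].sum())
        rate = rates.estimate_rate(total, self.experiment, self.ploidy,
                                   level=ci_level, method=ci_method)
        genomic = (rates.genomic_rates(rate.rate, self.genome_size,
                                       self.cds_size)
                   if self.genome_size and self.cds_size else None)
        per_line = rates.per_line_rates(self.experiment, self.ploidy,
                                        expectation=het_expectation)
        spec = None
        if self.mutations is not None and len(self.mutations):
            if self.genome is not None:
                spec = spectrum.classify_spectrum(self.mutations, self.genome)
            elif self.gc_fraction is not None:
                n = 1_000_000  # proportionality constant cancels in GC_eq
                spec = spectrum.classify_spectrum(
                    self.mutations, gcn=int(n * self.gc_fraction),
                    atn=int(n * (1 - self.gc_fraction)))
        return MAResults(model=self, rate=rate, genomic=genomic,
                         per_line=per_line, spec=spec)


@dataclass
class MAResults:
    """Fitted estimates, uncertainties and diagnostics."""

    model: MutationAccumulationModel
    rate: rates.RateEstimate
    genomic: rates.GenomeWideRates | None
    per_line: dict
    spec: spectrum.SpectrumSummary | None

    @property
    def mu(self) -> float:
        return self.rate.rate

    def conf_int(self) -> tuple[float, float]:
        return self.rate.ci_low, self.rate.ci_high

    # -- syntheses -------------------------------------------------------
    def ne_from_diversity(self, pi_s: float) -> float:
        return popgen.ne_from_diversity(pi_s, self.mu)

    def bias_ratio(self, gc_fraction: float | None = None) -> float:
        """Unrounded b = R1/R2 from the fitted (or supplied) spectrum."""
        if self.spec is None:
            raise ValueError("no mutation records were fitted")
        gc = gc_fraction if gc_fraction is not None else (
            self.model.gc_fraction)
        _, _, ratio = spectrum.conditional_rates(
            self.spec.n_gc_to_at, self.spec.n_at_to_gc, gc)
        return ratio

    def selection_strength(self, fop_value: float,
                           bias_ratio: float | None = None) -> float:
        b = bias_ratio if bias_ratio is not None else self.bias_ratio()
        return codon.selection_strength(fop_value, b)

    def summary(self) -> str:
        lines = ["Mutation accumulation model", "=" * 60]
        r = self.rate
        lines += [
            f"lines: {len(self.model.experiment):>3d}    "
            f"mutations: {r.count}    ploidy: {self.model.ploidy}",
            f"exposure (site-divisions): {r.exposure:.4e}",
            f"mu per site per division:  {r.rate:.2e}   "
            f"[{r.ci_low:.2e}, {r.ci_high:.2e}] ({int(r.ci_level * 100)}% "
            f"{r.method} CI)",
        ]
        if self.genomic is not None:
            lines.append(f"U = {self.genomic.u:.3f} per haploid genome, "
                         f"U_cds = {self.genomic.u_cds:.3f} per coding genome")
        pl = self.per_line
        lines += [
            "-" * 60,
            f"per-line counts: mean {pl['mean_count']:.2f}, "
            f"SD {pl['sd_count']:.2f}",
            f"heterogeneity chi2 ({pl['expectation']}) = {pl['chi2']:.2f}, "
            f"df = {pl['dof']}, p = {pl['p_value']:.4g}",
        ]
        if self.spec is not None:
            s = self.spec
            lines += [
                "-" * 60,
                "spectrum (pooled classes): "
                + ", ".join(f"{k} {v}" for k, v in s.counts.items()),
                f"GC->AT {s.n_gc_to_at} vs AT->GC {s.n_at_to_gc}; "
                f"GC_eq = {100 * s.gc_eq:.2f}%"
                + (f"; ts/tv = {s.ts_tv:.2f}" if s.ts_tv is not None else ""),
            ]
        return "\n".join(lines)
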