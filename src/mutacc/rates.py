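"""Mutation-rate estimation with exact Poisson confidence intervals.

The per-site per-cell-division rate is estimated as a Poisson rate

    mu = N / E,   E = ploidy * sum_i callable_i * generations_i

where the exposure E counts site-divisions per haploid site copy: a
diploid MA line accumulates mutations on two copies of every callable
position.  Confidence intervals are exact (Garwood) intervals built
from chi-square quantiles,

    low  = chi2.ppf(alpha/2, 2N) / 2 / E      (0 when N = 0)
    high = chi2.ppf(1 - alpha/2, 2(N+1)) / 2 / E,

which guarantee at-least-nominal coverage for any true rate; a normal
approximation is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import experiment_table


@dataclass(frozen=True)
class RateEstimate:
    """A point rate with its exact Poisson CI and exposure denominator."""

    count: int
    exposure: float
    rate: float
    ci_level: float
    ci_low: float
    ci_high: float
    compartment: str = "nuclear"
    method: str = "garwood"

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("CI does not bracket the point estimate")


@dataclass(frozen=True)
class GenomeWideRates:
    """Per-haploid-genome and per-coding-genome rates, U = size * mu."""

    u: float
    u_cds: float
    genome_size: float
    cds_size: float


def poisson_ci(count: int, level: float = 0.95,
               method: str = "garwood") -> tuple[float, float]:
    """CI for a Poisson mean given an observed count (exposure 1)."""
    if count < 0:
        raise ValueError("count must be non-negative")
    alpha = 1.0 - level
    if method == "garwood":
        low = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2
        high = stats.chi2.ppf(1 - alpha / 2, 2 * (count + 1)) / 2
    elif method == "normal":
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(count)
        low, high = max(count - half, 0.0), count + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(low), float(high)


def total_exposure(experiment: pd.DataFrame, ploidy: int = 2) -> float:
    """Site-divisions: ploidy * sum over lines of callable * generations."""
    df = experiment_table(experiment)
    return float(ploidy) * float(
        (df["callable_sites"].astype(float) * df["generations"]).sum())


def estimate_rate(count: int, experiment: pd.DataFrame, ploidy: int = 2,
                  level: float = 0.95, method: str = "garwood",
                  compartment: str = "nuclear") -> RateEstimate:
    """Per-site rate from a pooled count and the per-line exposure table."""
    exposure = total_exposure(experiment, ploidy)
    return rate_from_exposure(count, exposure, level=level, method=method,
                              compartment=compartment)


def rate_from_exposure(count: int, exposure: float, level: float = 0.95,
                       method: str = "garwood",
                       compartment: str = "nuclear") -> RateEstimate:
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    low, high = poisson_ci(count, level=level, method=method)
    return RateEstimate(count=int(count), exposure=float(exposure),
                        rate=count / exposure, ci_level=level,
                        ci_low=low / exposure, ci_high=high / exposure,
                        compartment=compartment, method=method)


def genomic_rates(mu: float, genome_size: float,
                  cds_size: float) -> GenomeWideRates:
    """U and U_cds: expected mutations per haploid (coding) genome per division."""
    if genome_size <= 0 or cds_size <= 0:
        raise ValueError("sizes must be positive")
    return GenomeWideRates(u=genome_size * mu, u_cds=cds_size * mu,
                           genome_size=genome_size, cds_size=cds_size)


def per_line_rates(experiment: pd.DataFrame, ploidy: int = 2,
                   expectation: str = "exposure") -> dict:
    """Per-line rates plus an among-line heterogeneity chi-square test.

    ``expectation`` chooses the null expected counts: ``exposure``
    weights the total by each line's callable*generations share,
    ``equal`` splits it evenly across lines.
    """
    df = experiment_table(experiment)
    if len(df) < 2:
        raise ValueError("need at least two lines")
    cg = df["callable_sites"].astype(float) * df["generations"]
    if (cg <= 0).any():
        raise ValueError("line with zero exposure")
    counts = df["mutations"].astype(float)
    total = counts.sum()
    per_line = df.assign(rate=counts / (ploidy * cg))
    if expectation == "exposure":
        expected = total * cg / cg.sum()
    elif expectation == "equal":
        expected = pd.Series(np.full(len(df), total / len(df)), index=df.index)
    else:
        raise ValueError(f"unknown expectation mode {expectation!r}")
    if total == 0:  # no mutations: heterogeneity test is vacuous
        chi2 = 0.0
    else:
        chi2 = float(((counts - expected) ** 2 / expected).sum())
    dof = len(df) - 1
    return {
        "per_line": per_line,
        "mean_count": float(counts.mean()),
        "sd_count": float(counts.std(ddof=1)),
        "chi2": chi2,
        "dof": dof,
        "p_value": float(stats.chi2.sf(chi2, dof)),
        "expectation": expectation,
    }


def estimate_copy_number(organelle_coverage: float, nuclear_coverage: float,
                         nuclear_ploidy: int = 2) -> float:
    """Organelle genome copies per cell from relative read coverage."""
    if nuclear_coverage <= 0 or organelle_coverage <= 0:
        raise ValueError("coverages must be positive")
    return nuclear_ploidy * organelle_coverage / nuclear_coverage


def organelle_rate(count: int, organelle_length: float, copy_number: float,
                   experiment: pd.DataFrame, level: float = 0.95,
                   method: str = "garwood",
                   compartment: str = "mitochondrial") -> RateEstimate:
    """Per-site rate for an organelle genome of known per-cell copy number.

    Exposure is copy_number * organelle_length * total generations; the
    copy number is treated as fixed and known (no error propagation).
    """
    if copy_number is None or copy_number <= 0:
        raise ValueError("copy number required and must be positive")
    df = experiment_table(experiment)
    exposure = copy_number * organelle_length * float(df["generations"].sum())
    return rate_from_exposure(count, exposure, level=level, method=method,
                              compartment=compartment)


def compare_rates(a: RateEstimate, b: RateEstimate) -> dict:
    """2x2 contingency chi-square of counts against exposures.

    Tests whether two Poisson rates differ, comparing each count with
    its remaining exposure; Pearson chi-square without continuity
    correction, df = 1.
    """
    table = np.array([[a.count, a.exposure - a.count],
                      [b.count, b.exposure - b.count]], dtype=float)
    if (table < 0).any() or table.sum(axis=0).min() <= 0 or table.sum(axis=1).min() <= 0:
        raise ValueError("degenerate 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "p_value": float(p), "dof": 1}
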