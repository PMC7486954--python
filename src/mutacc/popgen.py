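"""Effective-population-size and molecular-clock syntheses.

Ties the MA-derived per-division mutation rate to population-scale
quantities: Ne from synonymous diversity (pi_s = 4*Ne*mu under neutral
equilibrium), a divergence-calibrated yearly clock rate (mu_year =
d_s / 2T), the implied generations per year in the wild, and the
bottleneck arithmetic of the MA design itself (generation counts from
cell censuses, harmonic-mean Ne of the 14-day cycles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class CladeCalibration:
    """Synonymous divergence and split time to a sister species."""

    ds: float                  # substitutions per synonymous site
    t_years: float             # divergence time, years
    max_generations_per_year: float = 300.0

    def __post_init__(self) -> None:
        if self.ds < 0 or self.t_years <= 0:
            raise ValueError("need ds >= 0 and T > 0")


def ne_from_diversity(pi_s: float, mu: float) -> float:
    """Ne = pi_s / (4 mu) for a diploid under neutral equilibrium."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if pi_s < 0:
        raise ValueError("pi_s must be non-negative")
    return pi_s / (4.0 * mu)


def clock_rate(calibration: CladeCalibration) -> float:
    """Per-year substitution rate mu_year = d_s / (2 T)."""
    return calibration.ds / (2.0 * calibration.t_years)


def generations_per_year(mu_year: float,
                         mu_per_generation: float) -> tuple[float, float]:
    """(generations/year, days/generation) from the two rate scales."""
    if mu_year <= 0 or mu_per_generation <= 0:
        raise ValueError("both rates must be positive")
    g = mu_year / mu_per_generation
    return g, DAYS_PER_YEAR / g


def min_per_generation_rate(mu_year: float,
                            max_generations_per_year: float) -> float:
    """Lower bound on the wild per-generation rate at the maximal division rate."""
    if max_generations_per_year <= 0:
        raise ValueError("max generations per year must be positive")
    return mu_year / max_generations_per_year


def estimate_generations(cell_count: float,
                         interval_days: float) -> tuple[float, float]:
    """(divisions, divisions/day) for a culture founded by one cell.

    Exponential doubling from a single cell gives divisions = log2(N).
    """
    if cell_count < 1:
        raise ValueError("cell count must be at least 1")
    if interval_days <= 0:
        raise ValueError("interval must be positive")
    divisions = float(np.log2(cell_count))
    return divisions, divisions / interval_days


def harmonic_mean_popsize(daily_counts) -> float:
    """Harmonic-mean Ne over sampled daily censuses of all cycles."""
    counts = np.asarray(list(daily_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty census")
    if (counts < 1).any():
        raise ValueError("all counts must be >= 1")
    return float(counts.size / np.sum(1.0 / counts))


def fitness_trend(divisions_per_day, interval_index=None) -> dict:
    """Spearman rank correlation of division rate against experiment time.

    A flat trend (p >> 0.05) indicates no fitness decline over the MA
    propagation.  Constant series have undefined correlation and are
    flagged rather than raising.
    """
    y = np.asarray(list(divisions_per_day), dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 intervals")
    x = (np.arange(y.size, dtype=float) if interval_index is None
         else np.asarray(list(interval_index), dtype=float))
    if np.allclose(y, y[0]):
        return {"rho": float("nan"), "p_value": float("nan"),
                "defined": False}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p), "defined": True}


def ne_mu_correlation(species: pd.DataFrame, log_scale: bool = True) -> dict:
    """Pearson correlation of mutation rate against Ne across species.

    Both axes are log10-transformed by default (the compilation spans
    many orders of magnitude); a raw-scale mode is available.
    """
    if len(species) < 4:
        raise ValueError("need at least 4 species")
    ne = species["ne"].to_numpy(dtype=float)
    mu = species["mu"].to_numpy(dtype=float)
    if (ne <= 0).any() or (mu <= 0).any():
        raise ValueError("Ne and mu must be positive")
    if log_scale:
        ne, mu = np.log10(ne), np.log10(mu)
    r, p = stats.pearsonr(ne, mu)
    return {"rho": float(r), "p_value": float(p), "n": len(species),
            "log_scale": log_scale}
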