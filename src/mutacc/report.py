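"""Final report writer: one TSV of key quantities + a text summary.

Column order is deterministic and rates are printed in scientific
notation with three significant digits, so reports diff cleanly
between runs.
"""

from __future__ import annotations

import os

import pandas as pd

from .model import MAResults


def format_rate(x: float) -> str:
    """Scientific notation with 3 significant digits (5.55e-10)."""
    return f"{x:.2e}"


def report_rows(results: MAResults, extras: dict | None = None) -> list[dict]:
    r = results.rate
    rows = [
        {"section": "rate", "quantity": "mutation_count", "value": str(r.count)},
        {"section": "rate", "quantity": "exposure_site_divisions",
         "value": format_rate(r.exposure)},
        {"section": "rate", "quantity": "mu_per_site_per_division",
         "value": format_rate(r.rate)},
        {"section": "rate", "quantity": "ci_low", "value": format_rate(r.ci_low)},
        {"section": "rate", "quantity": "ci_high", "value": format_rate(r.ci_high)},
    ]
    if results.genomic is not None:
        rows += [
            {"section": "rate", "quantity": "U_per_haploid_genome",
             "value": f"{results.genomic.u:.3g}"},
            {"section": "rate", "quantity": "U_cds",
             "value": f"{results.genomic.u_cds:.3g}"},
        ]
    pl = results.per_line
    rows += [
        {"section": "heterogeneity", "quantity": "mean_count",
         "value": f"{pl['mean_count']:.4g}"},
        {"section": "heterogeneity", "quantity": "sd_count",
         "value": f"{pl['sd_count']:.4g}"},
        {"section": "heterogeneity", "quantity": f"chi2_{pl['expectation']}",
         "value": f"{pl['chi2']:.4g}"},
        {"section": "heterogeneity", "quantity": "p_value",
         "value": f"{pl['p_value']:.4g}"},
    ]
    if results.spec is not None:
        s = results.spec
        for cls, n in s.counts.items():
            rows.append({"section": "spectrum", "quantity": cls,
                         "value": str(n)})
        rows += [
            {"section": "spectrum", "quantity": "GC_eq_percent",
             "value": f"{100 * s.gc_eq:.2f}"},
        ]
        if s.ts_tv is not None:
            rows.append({"section": "spectrum", "quantity": "ts_tv",
                         "value": f"{s.ts_tv:.3g}"})
    for key, value in (extras or {}).items():
        section, _, quantity = key.partition(".")
        rows.append({"section": section, "quantity": quantity or section,
                     "value": format_rate(value) if isinstance(value, float)
                     and 0 < abs(value) < 1e-3 else f"{value:.4g}"
                     if isinstance(value, float) else str(value)})
    return rows


def write_report(results: MAResults, path: str,
                 extras: dict | None = None) -> None:
    """Write the TSV report at ``path`` and a text summary alongside it.

    ``extras`` may carry additional (section.quantity -> value) pairs,
    e.g. selection strength or clock-rate syntheses.
    """
    rows = report_rows(results, extras)
    df = pd.DataFrame(rows, columns=["section", "quantity", "value"])
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    summary_path = os.path.splitext(path)[0] + ".txt"
    with open(summary_path, "w") as fh:
        fh.write(results.summary() + "\n")
        if extras:
            fh.write("-" * 60 + "\n")
            for key, value in extras.items():
                fh.write(f"{key}: {value}\n")
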