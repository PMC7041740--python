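"""Leave-one-out sensitivity analysis, forest-plot data and report tables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import HarmonizedInstrument, MREstimate, wald_interval, wald_ratio
from .estimators import EstimatorConfig, estimate

__all__ = [
    "LeaveOneOutRow",
    "ForestRow",
    "leave_one_out",
    "influence_ranking",
    "forest_table",
    "report_tables",
    "loo_table",
    "render_forest_plot",
]

# Default LOO estimator: the penalized-robust IVW, the variant whose stability
# the single-SNP influence question is usually asked about.
LOO_DEFAULT_CFG = EstimatorConfig(method="ivw", penalized=True, robust=True)


@dataclass(frozen=True)
class LeaveOneOutRow:
    excluded_snp: str
    estimate: MREstimate


@dataclass(frozen=True)
class ForestRow:
    """Per-SNP odds ratio and CI (the exponentiated Wald ratio)."""

    snp_id: str
    or_point: float
    or_low: float
    or_high: float


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    cfg: EstimatorConfig | None = None,
) -> list[LeaveOneOutRow]:
    """Re-estimate J times, each time excluding one instrument (input order).

    Requires J >= 2 for IVW variants and J >= 4 for MR-Egger variants so that
    every reduced set still supports the estimator.
    """
    cfg = cfg or LOO_DEFAULT_CFG
    J = len(instruments)
    j_min = 4 if cfg.method == "egger" else 2
    if J < j_min:
        raise ValueError(f"leave-one-out with {cfg.label} requires J >= {j_min}, got {J}")
    rows = []
    for k in range(J):
        reduced = [inst for i, inst in enumerate(instruments) if i != k]
        rows.append(LeaveOneOutRow(instruments[k].snp_id, estimate(reduced, cfg)))
    return rows


def influence_ranking(
    loo: Sequence[LeaveOneOutRow], full: MREstimate
) -> list[tuple[str, float]]:
    """Rank excluded SNPs by |beta change| from the full-sample estimate.

    Descending absolute change; exact ties broken lexicographically by rsID.
    """
    if not loo:
        raise ValueError("empty leave-one-out input")
    deltas = [(row.excluded_snp, abs(row.estimate.beta - full.beta)) for row in loo]
    return sorted(deltas, key=lambda t: (-t[1], t[0]))


def forest_table(
    instruments: Sequence[HarmonizedInstrument],
    z: float = 1.96,
    combined: MREstimate | None = None,
) -> list[ForestRow]:
    """Per-SNP ORs with Wald CIs on the exponentiated scale.

    A combined row (label ``"combined"``) is appended only when an overall
    estimate is explicitly supplied.
    """
    rows = []
    for inst in instruments:
        theta, se_theta = wald_ratio(inst)
        low, high = wald_interval(theta, se_theta, z)
        rows.append(ForestRow(inst.snp_id, np.exp(theta), np.exp(low), np.exp(high)))
    if combined is not None:
        rows.append(
            ForestRow(
                "combined",
                np.exp(combined.beta),
                np.exp(combined.ci_low),
                np.exp(combined.ci_high),
            )
        )
    return rows


def _round(x: float, precision: int) -> float:
    return float(np.round(x, precision))


def report_tables(
    results: Mapping[str, MREstimate], precision: int = 3
) -> pd.DataFrame:
    """Estimate table in the standard report layout.

    Columns: Method, Beta, Std error, CI low, CI high, P-value; each MR-Egger
    variant is followed by an ``(intercept)`` row.  CI bounds are recomputed
    from the unrounded beta/SE and rounded last, so the printed interval is
    always consistent with the printed point estimate at full precision.
    """
    rows = []
    for label, est in results.items():
        rows.append(
            {
                "Method": label,
                "Beta": _round(est.beta, precision),
                "Std error": _round(est.se, precision),
                "CI low": _round(est.ci_low, precision),
                "CI high": _round(est.ci_high, precision),
                "P-value": _round(est.pvalue, precision),
            }
        )
        if est.intercept_block is not None:
            ib = est.intercept_block
            rows.append(
                {
                    "Method": "(intercept)",
                    "Beta": _round(ib.beta, precision),
                    "Std error": _round(ib.se, precision),
                    "CI low": _round(ib.ci_low, precision),
                    "CI high": _round(ib.ci_high, precision),
                    "P-value": _round(ib.pvalue, precision),
                }
            )
    return pd.DataFrame(rows, columns=["Method", "Beta", "Std error", "CI low", "CI high", "P-value"])


def loo_table(loo: Sequence[LeaveOneOutRow], precision: int = 3) -> pd.DataFrame:
    """Leave-one-out table: SNP, Beta, SE, CI low, CI high, P value."""
    rows = []
    for row in loo:
        e = row.estimate
        rows.append(
            {
                "SNP": row.excluded_snp,
                "Beta": _round(e.beta, precision),
                "SE": _round(e.se, precision),
                "CI low": _round(e.ci_low, precision),
                "CI high": _round(e.ci_high, precision),
                "P value": _round(e.pvalue, precision),
            }
        )
    return pd.DataFrame(rows, columns=["SNP", "Beta", "SE", "CI low", "CI high", "P value"])


def render_forest_plot(rows: Sequence[ForestRow], path) -> None:
    """Basic forest plot of per-SNP ORs (log-scaled x axis) to SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.3 * len(rows) + 1.5))
    ys = np.arange(len(rows))[::-1]
    for y, row in zip(ys, rows):
        marker = "D" if row.snp_id == "combined" else "s"
        ax.plot([row.or_low, row.or_high], [y, y], color="black", lw=1)
        ax.plot([row.or_point], [y], marker, color="black", ms=4)
    ax.axvline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_yticks(ys)
    ax.set_yticklabels([r.snp_id for r in rows], fontsize=7)
    ax.set_xscale("log")
    ax.set_xlabel("OR (95% CI)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
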