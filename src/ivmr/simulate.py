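"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator emulates the product of a lipid-trait GWAS and a disease
meta-analysis at summary level.  For each instrument j a true exposure
effect betaX_j is drawn from the instrument-strength distribution (defaults
emulate per-allele LDL-C effects of 0.02-0.12 SD); the true outcome effect
is betaY_j = theta * betaX_j, plus a direct (pleiotropic) effect alpha_j for
the invalid fraction and an optional shared-confounder term in both traits.
Observed effects add independent Gaussian estimation noise on each side —
the two-sample design — with SEs drawn from ranges matching published
summary tables, and Wald p-values are attached.  Extra null SNPs (betaX = 0)
exercise the selection pipeline; optional exchangeable LD blocks exercise
the pruning stage.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AssociationRecord, harmonize_associations
from .estimators import EstimatorConfig, estimate
from .selection import LDMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_two_sample",
    "run_recovery_experiment",
    "make_paper_like_catalog",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for a two-sample summary-statistics dataset.

    ``theta`` is the true causal effect in log-odds per SD of exposure.
    Instrument strength |betaX| ~ Uniform(gamma_loc, gamma_loc + gamma_scale).
    SE ranges are uniform intervals per SNP.  ``invalid_fraction`` of the
    instruments receive a direct outcome effect drawn from
    N(pleiotropy_mean, pleiotropy_sd^2) — the exclusion-restriction
    violation; ``confounder_effect`` scales a shared N(0,1) term added to
    both true effects — the confounder-independence violation.  Defaults are
    a valid-instrument scenario sized like the 23-SNP LDL-C panel.
    """

    n_snps: int = 23
    theta: float = 0.25
    gamma_loc: float = 0.02
    gamma_scale: float = 0.10
    se_exposure_range: tuple[float, float] = (0.0036, 0.0121)
    se_outcome_range: tuple[float, float] = (0.00995, 0.0296)
    invalid_fraction: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    confounder_effect: float = 0.0
    null_snp_count: int = 0
    ld_block_size: int | None = None
    ld_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ValueError("invalid_fraction must be in [0, 1]")
        for name in ("se_exposure_range", "se_outcome_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval")
        if self.gamma_loc <= 0 or self.gamma_scale < 0:
            raise ValueError("instrument-strength distribution must be positive")
        if self.null_snp_count < 0:
            raise ValueError("null_snp_count must be >= 0")
        if not (0.0 <= self.ld_r2 <= 1.0):
            raise ValueError("ld_r2 must be in [0, 1]")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a simulated dataset, for recovery tests."""

    theta: float
    snp_ids: tuple[str, ...]
    is_instrument: tuple[bool, ...]
    is_valid: tuple[bool, ...]
    pleiotropy: tuple[float, ...]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "theta": self.theta,
                    "snp_ids": list(self.snp_ids),
                    "is_instrument": list(self.is_instrument),
                    "is_valid": list(self.is_valid),
                    "pleiotropy": list(self.pleiotropy),
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta) / se)


def simulate_two_sample(
    cfg: SyntheticConfig,
) -> tuple[list[AssociationRecord], list[AssociationRecord], LDMatrix, SyntheticTruth]:
    """Draw one two-sample summary-statistics dataset.

    Returns exposure records, outcome records, a pairwise-r2 matrix and the
    generating truth.  Instruments come first, then null SNPs.  Exposure and
    outcome noise are independent draws (non-overlapping samples).
    """
    rng = np.random.default_rng(cfg.seed)
    J, K = cfg.n_snps, cfg.null_snp_count
    total = J + K
    ids = tuple(f"rs{9000001 + i}" for i in range(total))

    bx_true = rng.uniform(cfg.gamma_loc, cfg.gamma_loc + cfg.gamma_scale, J)
    sx = rng.uniform(*cfg.se_exposure_range, total)
    sy = rng.uniform(*cfg.se_outcome_range, total)

    n_invalid = int(round(J * cfg.invalid_fraction))
    invalid_idx = rng.choice(J, size=n_invalid, replace=False)
    alpha = np.zeros(total)
    if n_invalid:
        alpha[invalid_idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n_invalid)

    u = rng.normal(0.0, 1.0, J) * cfg.confounder_effect
    bx_all = np.zeros(total)
    by_all = np.zeros(total)
    bx_all[:J] = bx_true + u
    by_all[:J] = cfg.theta * bx_true + u + alpha[:J]

    bx_hat = bx_all + rng.normal(0.0, sx)
    by_hat = by_all + rng.normal(0.0, sy)
    px = _wald_p(bx_hat, sx)
    py = _wald_p(by_hat, sy)

    exposure = [
        AssociationRecord(ids[i], float(bx_hat[i]), float(sx[i]), float(px[i]))
        for i in range(total)
    ]
    outcome = [
        AssociationRecord(ids[i], float(by_hat[i]), float(sy[i]), float(py[i]))
        for i in range(total)
    ]

    if cfg.ld_block_size and cfg.ld_block_size > 1 and cfg.ld_r2 > 0:
        r2 = np.zeros((total, total))
        for start in range(0, total, cfg.ld_block_size):
            stop = min(start + cfg.ld_block_size, total)
            r2[start:stop, start:stop] = cfg.ld_r2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(ids, r2)
    else:
        ld = LDMatrix.identity(ids)

    is_valid = np.ones(total, dtype=bool)
    is_valid[invalid_idx] = False
    truth = SyntheticTruth(
        theta=cfg.theta,
        snp_ids=ids,
        is_instrument=tuple([True] * J + [False] * K),
        is_valid=tuple(bool(v) for v in is_valid),
        pleiotropy=tuple(float(a) for a in alpha),
        seed=cfg.seed,
    )
    return exposure, outcome, ld, truth


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def run_recovery_experiment(
    cfg: SyntheticConfig,
    n_reps: int,
    estimator_cfgs: Sequence[EstimatorConfig] | None = None,
) -> pd.DataFrame:
    """Monte-Carlo recovery of theta: bias, RMSE, coverage, intercept type-I error.

    Each replicate simulates a fresh dataset from a child seed of
    ``cfg.seed``, harmonizes the instruments (null SNPs excluded — they have
    no exposure effect and would never pass selection) and runs every
    estimator configuration.  The summary has one row per estimator with
    Monte-Carlo standard errors; ``intercept_rejection_rate`` is the
    fraction of replicates where the MR-Egger intercept test rejects at
    alpha = 0.05 (NaN for IVW variants).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    estimator_cfgs = list(estimator_cfgs or [EstimatorConfig(method="ivw")])
    seeds = _child_seeds(cfg.seed, n_reps)
    betas: dict[str, list[float]] = {c.label: [] for c in estimator_cfgs}
    covered: dict[str, list[bool]] = {c.label: [] for c in estimator_cfgs}
    rejected: dict[str, list[bool]] = {c.label: [] for c in estimator_cfgs}
    for s in seeds:
        exposure, outcome, _, truth = simulate_two_sample(replace(cfg, seed=s))
        inst_ids = [i for i, flag in zip(truth.snp_ids, truth.is_instrument) if flag]
        instruments = harmonize_associations(exposure, outcome, inst_ids)
        for ecfg in estimator_cfgs:
            est = estimate(instruments, ecfg)
            betas[ecfg.label].append(est.beta)
            covered[ecfg.label].append(est.ci_low <= cfg.theta <= est.ci_high)
            if est.intercept_block is not None:
                rejected[ecfg.label].append(est.intercept_block.pvalue < 0.05)

    rows = []
    for ecfg in estimator_cfgs:
        b = np.asarray(betas[ecfg.label])
        cov = np.asarray(covered[ecfg.label], dtype=float)
        rej = np.asarray(rejected[ecfg.label], dtype=float)
        rows.append(
            {
                "method": ecfg.label,
                "n_reps": n_reps,
                "mean_estimate": b.mean(),
                "bias": b.mean() - cfg.theta,
                "mc_se": b.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else np.nan,
                "rmse": np.sqrt(np.mean((b - cfg.theta) ** 2)),
                "median_abs_error": np.median(np.abs(b - cfg.theta)),
                "coverage": cov.mean(),
                "coverage_mc_se": (
                    np.sqrt(cov.mean() * (1 - cov.mean()) / n_reps) if n_reps > 1 else np.nan
                ),
                "intercept_rejection_rate": rej.mean() if rej.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def make_paper_like_catalog(
    seed: int = 0,
) -> tuple[list[AssociationRecord], list[AssociationRecord], LDMatrix]:
    """A 35-SNP catalog whose selection outcome is fixed by construction.

    Exactly 29 SNPs reach genome-wide significance for the exposure
    (p <= 5e-8), exactly 6 of those are nominally associated with the
    outcome (p < 0.05) and get deleted, and the surviving 23 are mutually
    below the r^2 = 0.01 pruning threshold — so the selection pipeline
    returns set sizes (29, 23, 23) for every seed.  The seed only perturbs
    the effect sizes and p-values within their construction bands.  Betas
    and SEs are kept Wald-consistent with the assigned p-values.
    """
    rng = np.random.default_rng(seed)
    n_sig, n_deleted, n_nonsig = 29, 6, 6
    total = n_sig + n_nonsig  # 35
    ids = [f"rs{8000001 + i}" for i in range(total)]

    # exposure: 29 clearly genome-wide significant, 6 clearly not
    p_exp = np.concatenate(
        [
            10 ** rng.uniform(-15.0, -8.5, n_sig),
            10 ** rng.uniform(-6.0, -2.0, n_nonsig),
        ]
    )
    se_exp = rng.uniform(0.0036, 0.0121, total)
    z_exp = stats.norm.isf(p_exp / 2.0)
    beta_exp = se_exp * z_exp * rng.choice([-1.0, 1.0], total)

    # outcome: the first 6 significant SNPs are outcome-associated (p < 0.05)
    p_out = np.empty(total)
    p_out[:n_deleted] = rng.uniform(0.001, 0.045, n_deleted)
    p_out[n_deleted:] = rng.uniform(0.06, 0.95, total - n_deleted)
    se_out = rng.uniform(0.00995, 0.0296, total)
    z_out = stats.norm.isf(p_out / 2.0)
    beta_out = se_out * z_out * rng.choice([-1.0, 1.0], total)

    exposure = [
        AssociationRecord(ids[i], float(beta_exp[i]), float(se_exp[i]), float(p_exp[i]))
        for i in range(total)
    ]
    outcome = [
        AssociationRecord(ids[i], float(beta_out[i]), float(se_out[i]), float(p_out[i]))
        for i in range(total)
    ]

    # background LD strictly below the pruning threshold; one strongly
    # correlated pair among the outcome-deleted SNPs (removed before pruning)
    r2 = rng.uniform(0.0, 0.009, (total, total))
    r2 = (r2 + r2.T) / 2.0
    r2[0, 1] = r2[1, 0] = 0.8
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(tuple(ids), r2)
    return exposure, outcome, ld
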