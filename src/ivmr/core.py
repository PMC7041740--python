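"""Core domain types and per-variant arithmetic for summary-level MR.

Two-sample Mendelian randomization works entirely from GWAS summary
statistics: for each candidate instrument (a SNP) we hold its estimated
per-allele effect on the exposure (in SD units of the trait) and on the
outcome (log-odds), each with a standard error.  This module defines the
record types for those associations, the 2x2-table odds-ratio arithmetic
used when an outcome effect has to be reconstructed from allele counts,
Wald confidence intervals and p-values, and the per-SNP Wald-ratio causal
estimate that every downstream estimator combines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Literal, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "HarmonizedInstrument",
    "TwoByTwoTable",
    "MREstimate",
    "InterceptBlock",
    "DegenerateTableError",
    "odds_ratio_2x2",
    "beta_from_or",
    "or_from_beta",
    "wald_interval",
    "wald_pvalue",
    "wald_ratio",
    "apply_zero_se_policy",
    "read_association_tsv",
    "write_association_tsv",
    "read_instrument_tsv",
    "write_instrument_tsv",
    "harmonize_associations",
    "load_fixture",
]

Z_DEFAULT = 1.96  # reporting convention; Phi^-1(0.975)=1.959964 available by flag


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero cell; no continuity correction is applied."""


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's summary association with a single trait.

    ``beta`` is the per-effect-allele estimate: SD units for a quantitative
    exposure, log-odds for a binary outcome.  ``se`` must be finite and
    nonnegative; an exactly zero SE is tolerated only so that the explicit
    zero-SE policies downstream can deal with it.
    """

    snp_id: str
    beta: float
    se: float
    pvalue: float | None = None
    effect_allele: str | None = None
    other_allele: str | None = None
    sample_size: int | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: beta must be finite")
        if not math.isfinite(self.se) or self.se < 0:
            raise ValueError(f"{self.snp_id}: se must be finite and >= 0")
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"{self.snp_id}: pvalue {self.pvalue} outside [0, 1]")
        if self.sample_size is not None and self.sample_size <= 0:
            raise ValueError(f"{self.snp_id}: sample_size must be positive")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Paired exposure/outcome effects for one instrument.

    The effect alleles of the two studies are assumed already aligned, so
    ``beta_exposure`` and ``beta_outcome`` refer to the same allele.
    """

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    p_exposure: float | None = None
    p_outcome: float | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{self.snp_id}: {name} must be finite")
        if self.se_exposure <= 0:
            raise ValueError(f"{self.snp_id}: se_exposure must be > 0")
        if self.se_outcome < 0:
            raise ValueError(f"{self.snp_id}: se_outcome must be >= 0")


@dataclass(frozen=True)
class TwoByTwoTable:
    """Allele counts: effective/non-effective in cases (a, b) and controls (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"count {name}={v} must be a nonnegative integer")


@dataclass(frozen=True)
class InterceptBlock:
    """MR-Egger intercept: the average directional pleiotropy estimate."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float


@dataclass(frozen=True)
class MREstimate:
    """A combined causal-effect estimate on the log-odds-per-SD scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    intercept_block: InterceptBlock | None = None
    heterogeneity_q: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")


# ---------------------------------------------------------------------------
# arithmetic


def odds_ratio_2x2(table: TwoByTwoTable) -> tuple[float, float, float]:
    """Odds ratio, log-odds ratio and its SE from a 2x2 allele-count table.

    Returns ``(or, log_or, se_log_or)`` with OR = ad/bc and the standard
    large-sample SE of the log odds ratio, sqrt(1/a + 1/b + 1/c + 1/d).
    Any zero cell raises :class:`DegenerateTableError`; no continuity
    correction is applied.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        raise DegenerateTableError(
            f"2x2 table ({a}, {b}, {c}, {d}) has a zero cell; OR undefined"
        )
    oratio = (a * d) / (b * c)
    log_or = math.log(oratio)
    se_log_or = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return oratio, log_or, se_log_or


def beta_from_or(odds_ratio: float) -> float:
    """log-odds effect from an odds ratio: beta = ln(OR)."""
    if not (odds_ratio > 0):
        raise ValueError(f"odds ratio must be > 0, got {odds_ratio}")
    return math.log(odds_ratio)


def or_from_beta(beta: float) -> float:
    """Inverse of :func:`beta_from_or`."""
    return math.exp(beta)


def wald_interval(beta: float, se: float, z: float = Z_DEFAULT) -> tuple[float, float]:
    """Symmetric normal-approximation interval beta -/+ z*se (full precision)."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    if z <= 0:
        raise ValueError(f"z must be > 0, got {z}")
    return beta - z * se, beta + z * se

def wald_pvalue(beta: float, se: float) -> float:
    """Two-sided normal p-value, 2*(1 - Phi(|beta|/se))."""
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    return 2.0 * stats.norm.sf(abs(beta) / se)


def wald_ratio(inst: HarmonizedInstrument) -> tuple[float, float]:
    """Per-SNP causal estimate theta = betaY/betaX with first-order SE sigmaY/|betaX|.

    This is the single-instrument ratio estimate; its delta-method SE ignores
    the uncertainty in the exposure association (the usual summary-MR
    convention when instruments pass a genome-wide significance screen).
    """
    if inst.beta_exposure == 0:
        raise ValueError(f"{inst.snp_id}: beta_exposure is zero, Wald ratio undefined")
    if inst.se_outcome == 0:
        raise ValueError(
            f"{inst.snp_id}: se_outcome is zero; apply a zero-SE policy first"
        )
    theta = inst.beta_outcome / inst.beta_exposure
    se_theta = inst.se_outcome / abs(inst.beta_exposure)
    return theta, se_theta


# ---------------------------------------------------------------------------
# zero-SE policy

ZeroSePolicy = Literal["strict", "floor", "drop"]


def apply_zero_se_policy(
    instruments: Sequence[HarmonizedInstrument],
    policy: ZeroSePolicy = "strict",
    floor: float | None = None,
) -> list[HarmonizedInstrument]:
    """Resolve instruments whose outcome SE is exactly zero.

    A zero SE would give the SNP infinite inverse-variance weight, which is
    statistically meaningless, so it must be handled explicitly:

    - ``strict`` (default): raise, naming the offending SNPs;
    - ``floor``: substitute ``floor`` (default: the smallest positive outcome
      SE in the dataset), with a warning;
    - ``drop``: exclude the SNPs, with a warning.
    """
    zero = [inst.snp_id for inst in instruments if inst.se_outcome == 0]
    if not zero:
        return list(instruments)
    if policy == "strict":
        raise ValueError(
            "zero outcome SE for SNP(s) " + ", ".join(zero) +
            "; use the 'floor' or 'drop' policy to proceed"
        )
    if policy == "drop":
        logger.warning("dropping %d SNP(s) with zero outcome SE: %s", len(zero), zero)
        return [inst for inst in instruments if inst.se_outcome > 0]
    if policy == "floor":
        if floor is None:
            positive = [i.se_outcome for i in instruments if i.se_outcome > 0]
            if not positive:
                raise ValueError("all outcome SEs are zero; no floor available")
            floor = min(positive)
        if floor <= 0:
            raise ValueError("floor must be positive")
        logger.warning(
            "flooring zero outcome SE at %g for SNP(s): %s", floor, zero
        )
        return [
            replace(inst, se_outcome=floor) if inst.se_outcome == 0 else inst
            for inst in instruments
        ]
    raise ValueError(f"unknown zero-SE policy {policy!r}")


# ---------------------------------------------------------------------------
# TSV dialects

_ASSOC_COLS = ["snp", "beta", "se", "pvalue", "effect_allele", "other_allele", "n"]
_INST_COLS = ["SNP", "phenotype_Beta", "phenotype_SE", "disease_Beta", "disease_SE"]


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value in (".", ""):
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value in (".", ""):
        return None
    return str(value)


def read_association_tsv(path) -> list[AssociationRecord]:
    """Read a per-trait association table (columns snp, beta, se, pvalue[, ...])."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str}, na_values=["."], float_precision="round_trip")
    missing = {"snp", "beta", "se"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                AssociationRecord(
                    snp_id=row.snp,
                    beta=float(row.beta),
                    se=float(row.se),
                    pvalue=_opt(getattr(row, "pvalue", None)),
                    effect_allele=_opt_str(getattr(row, "effect_allele", None)),
                    other_allele=_opt_str(getattr(row, "other_allele", None)),
                    sample_size=(
                        int(n) if (n := _opt(getattr(row, "n", None))) is not None else None
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {idx}: {exc}") from exc
    return records


def write_association_tsv(records: Iterable[AssociationRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "snp": r.snp_id,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "n": r.sample_size,
            }
            for r in records
        ],
        columns=_ASSOC_COLS[:-1] + ["n"],
    )
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.17g")


def read_instrument_tsv(path) -> list[HarmonizedInstrument]:
    """Read a harmonized-instrument table (SNP, phenotype_Beta, phenotype_SE,
    disease_Beta, disease_SE[, phenotype_P, disease_P])."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str}, na_values=["."], float_precision="round_trip")
    missing = set(_INST_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                HarmonizedInstrument(
                    snp_id=row.SNP,
                    beta_exposure=float(row.phenotype_Beta),
                    se_exposure=float(row.phenotype_SE),
                    beta_outcome=float(row.disease_Beta),
                    se_outcome=float(row.disease_SE),
                    p_exposure=_opt(getattr(row, "phenotype_P", None)),
                    p_outcome=_opt(getattr(row, "disease_P", None)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {idx}: {exc}") from exc
    return out


def write_instrument_tsv(instruments: Iterable[HarmonizedInstrument], path) -> None:
    df = pd.DataFrame(
        [
            {
                "SNP": i.snp_id,
                "phenotype_Beta": i.beta_exposure,
                "phenotype_SE": i.se_exposure,
                "disease_Beta": i.beta_outcome,
                "disease_SE": i.se_outcome,
                "phenotype_P": i.p_exposure,
                "disease_P": i.p_outcome,
            }
            for i in instruments
        ],
        columns=_INST_COLS + ["phenotype_P", "disease_P"],
    )
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.17g")


def harmonize_associations(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    snp_ids: Sequence[str] | None = None,
) -> list[HarmonizedInstrument]:
    """Pair exposure and outcome records by rsID into instruments.

    ``snp_ids`` restricts and orders the output (e.g. a selection result);
    by default every SNP present in both tables is used, in exposure order.
    Allele-level harmonization (strand flips, palindromic SNPs) is out of
    scope: records are assumed to refer to the same effect allele already.
    """
    exp_map = {r.snp_id: r for r in exposure}
    out_map = {r.snp_id: r for r in outcome}
    if snp_ids is None:
        snp_ids = [r.snp_id for r in exposure if r.snp_id in out_map]
    instruments = []
    for snp in snp_ids:
        if snp not in exp_map:
            raise KeyError(f"{snp}: no exposure record")
        if snp not in out_map:
            raise KeyError(f"{snp}: no outcome record")
        e, o = exp_map[snp], out_map[snp]
        instruments.append(
            HarmonizedInstrument(
                snp_id=snp,
                beta_exposure=e.beta,
                se_exposure=e.se,
                beta_outcome=o.beta,
                se_outcome=o.se,
                p_exposure=e.pvalue,
                p_outcome=o.pvalue,
            )
        )
    return instruments


_FIXTURES = {"ldl_t2dm": "ldl_t2dm_instruments.tsv"}


def load_fixture(name: str = "ldl_t2dm") -> list[HarmonizedInstrument]:
    """Load a packaged harmonized-instrument table by name.

    ``ldl_t2dm``: the 23 LDL-C instruments with their T2DM outcome effects as
    published (values preserved verbatim, including four rows whose outcome SE
    is printed as exactly zero — see :func:`apply_zero_se_policy`).
    """
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    ref = resources.files("ivmr.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return read_instrument_tsv(path)
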