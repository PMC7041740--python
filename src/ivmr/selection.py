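"""Instrument selection: significance screen, outcome-association exclusion, LD pruning.

The pipeline mirrors the usual summary-MR instrument screen:

1. *Set1* — keep SNPs genome-wide significant for the exposure (p <= 5e-8);
2. *Set2* — delete SNPs nominally associated with the outcome (p < 0.05),
   a conservative guard against reverse-path effects;
3. *Set3* — greedily prune linkage disequilibrium so that every retained
   pair has r^2 < 0.01, visiting SNPs in ascending exposure p-value
   (lexicographic rsID tie-break) so the strongest signal of each
   correlated cluster is kept deterministically.

Every removal is recorded with its stage and triggering value.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AssociationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LDMatrix",
    "SelectionResult",
    "filter_exposure_significant",
    "exclude_outcome_associated",
    "ld_prune",
    "select_instruments",
    "read_ld_tsv",
    "write_ld_tsv",
]

P_EXPOSURE_DEFAULT = 5e-8
P_OUTCOME_DEFAULT = 0.05
R2_DEFAULT = 0.01


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise r-squared between SNPs; symmetric with unit diagonal."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        n = len(self.snp_ids)
        if r2.shape != (n, n):
            raise ValueError(f"r2 shape {r2.shape} does not match {n} SNP ids")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValueError("r2 matrix is not symmetric")
        if np.any(r2 < 0) or np.any(r2 > 1):
            raise ValueError("r2 values must lie in [0, 1]")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-12):
            raise ValueError("r2 diagonal must be 1")

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(tuple(snp_ids), np.eye(len(snp_ids)))

    def lookup(self, snp1: str, snp2: str) -> float | None:
        """r^2 for a pair, or None if either SNP is absent from the matrix."""
        try:
            i = self.snp_ids.index(snp1)
            j = self.snp_ids.index(snp2)
        except ValueError:
            return None
        return float(self.r2[i, j])


@dataclass
class SelectionResult:
    """The three nested SNP sets plus a per-removal provenance trail."""

    set1: list[str]
    set2: list[str]
    set3: list[str]
    provenance: list[dict] = field(default_factory=list)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.set1), len(self.set2), len(self.set3)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "set1": self.set1,
                    "set2": self.set2,
                    "set3": self.set3,
                    "sizes": self.sizes,
                    "provenance": self.provenance,
                },
                fh,
                indent=2,
            )


def filter_exposure_significant(
    exposure: Sequence[AssociationRecord],
    p_threshold: float = P_EXPOSURE_DEFAULT,
    provenance: list[dict] | None = None,
) -> list[str]:
    """Set1: SNPs whose exposure p-value is <= p_threshold (inclusive boundary)."""
    kept = []
    for rec in exposure:
        if rec.pvalue is None:
            raise ValueError(f"{rec.snp_id}: exposure p-value required for selection")
        if rec.pvalue <= p_threshold:
            kept.append(rec.snp_id)
        elif provenance is not None:
            provenance.append(
                {
                    "snp": rec.snp_id,
                    "stage": "exposure_significance",
                    "reason": f"exposure p {rec.pvalue:.3g} > {p_threshold:.3g}",
                    "value": rec.pvalue,
                }
            )
    return kept


def exclude_outcome_associated(
    set1: Sequence[str],
    outcome: Sequence[AssociationRecord],
    p_threshold: float = P_OUTCOME_DEFAULT,
    missing_policy: str = "keep",
    provenance: list[dict] | None = None,
) -> list[str]:
    """Set2: drop SNPs nominally associated with the outcome (strict p < threshold).

    A Set1 SNP with no outcome record is kept by default (absence of evidence
    of outcome association), logged; ``missing_policy='drop'`` removes it.
    """
    pmap = {rec.snp_id: rec.pvalue for rec in outcome}
    kept = []
    for snp in set1:
        if snp not in pmap or pmap[snp] is None:
            if missing_policy == "keep":
                logger.warning("%s: no outcome record; keeping (policy=keep)", snp)
                kept.append(snp)
            else:
                logger.warning("%s: no outcome record; dropping (policy=drop)", snp)
                if provenance is not None:
                    provenance.append(
                        {"snp": snp, "stage": "outcome_association",
                         "reason": "no outcome record (policy=drop)", "value": None}
                    )
            continue
        p = pmap[snp]
        if p < p_threshold:
            if provenance is not None:
                provenance.append(
                    {
                        "snp": snp,
                        "stage": "outcome_association",
                        "reason": f"outcome p {p:.3g} < {p_threshold:.3g}",
                        "value": p,
                    }
                )
        else:
            kept.append(snp)
    return kept


def ld_prune(
    set2: Sequence[str],
    ld: LDMatrix,
    exposure_p: Mapping[str, float],
    r2_threshold: float = R2_DEFAULT,
    provenance: list[dict] | None = None,
) -> list[str]:
    """Set3: greedy LD pruning at pairwise r^2 >= r2_threshold.

    SNPs are visited in ascending exposure p-value (ties broken by rsID); a
    SNP is kept iff its r^2 with every already-kept SNP is below the
    threshold.  The output preserves the input order of ``set2``.  A SNP
    absent from the LD matrix is treated as independent of everything, with
    a warning.
    """
    order = sorted(set2, key=lambda s: (exposure_p.get(s, 1.0), s))
    kept: list[str] = []
    for snp in order:
        partner = None
        for other in kept:
            r2 = ld.lookup(snp, other)
            if r2 is None:
                if snp not in ld.snp_ids:
                    logger.warning("%s: not in LD matrix; treated as independent", snp)
                continue
            if r2 >= r2_threshold:
                partner = (other, r2)
                break
        if partner is None:
            kept.append(snp)
        elif provenance is not None:
            provenance.append(
                {
                    "snp": snp,
                    "stage": "ld_pruning",
                    "reason": f"r2 {partner[1]:.3g} with kept SNP {partner[0]}"
                              f" >= {r2_threshold:.3g}",
                    "value": partner[1],
                }
            )
    kept_set = set(kept)
    return [s for s in set2 if s in kept_set]


def select_instruments(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    ld: LDMatrix | None = None,
    p_exposure: float = P_EXPOSURE_DEFAULT,
    p_outcome: float = P_OUTCOME_DEFAULT,
    r2_threshold: float = R2_DEFAULT,
    missing_policy: str = "keep",
) -> SelectionResult:
    """Run the three selection stages and return the nested sets with provenance."""
    provenance: list[dict] = []
    set1 = filter_exposure_significant(exposure, p_exposure, provenance)
    set2 = exclude_outcome_associated(set1, outcome, p_outcome, missing_policy, provenance)
    if ld is None:
        ld = LDMatrix.identity(set2)
    pmap = {rec.snp_id: rec.pvalue for rec in exposure}
    set3 = ld_prune(set2, ld, pmap, r2_threshold, provenance)
    if not set3:
        raise ValueError("no valid instruments remain after selection")
    return SelectionResult(set1=set1, set2=set2, set3=set3, provenance=provenance)


# ---------------------------------------------------------------------------
# LD matrix I/O: square TSV (header row+column of rsIDs) or long format


def read_ld_tsv(path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t")
    if set(df.columns[:3]) == {"snp1", "snp2", "r2"} or list(df.columns) == ["snp1", "snp2", "r2"]:
        ids = sorted(set(df["snp1"]).union(df["snp2"]))
        idx = {s: i for i, s in enumerate(ids)}
        mat = np.eye(len(ids))
        for row in df.itertuples(index=False):
            i, j = idx[row.snp1], idx[row.snp2]
            mat[i, j] = mat[j, i] = float(row.r2)
        return LDMatrix(tuple(ids), mat)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: square LD matrix must have matching row/column ids")
    return LDMatrix(tuple(df.index), df.to_numpy(dtype=float))


def write_ld_tsv(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r2, index=list(ld.snp_ids), columns=list(ld.snp_ids)).to_csv(
        path, sep="\t"
    )
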