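"""Acceptance-matrix statistics: robustness and competition between phenotypes.

Given an archive of m evaluated parameter vectors and n phenotypes, the
binary acceptance matrix A has A[i, l] = 1 iff vector i correctly captured
phenotype l.  From it:

* the acceptance ratio  Abar_l = (1/m) * sum_i A[i, l]  measures how robustly
  the model reproduces phenotype l under parameter variation;
* the pairwise correlation  R[k, l] = C[k, l] / sqrt(C[k, k] * C[l, l]),
  with C the sample covariance (1/(m-1) normalization), quantifies whether
  two phenotypes tend to be captured together (positive) or to exclude each
  other (negative);
* the competitiveness  Rhat_k = sum_{l != k} R[k, l]  summarizes the
  competition phenotype k faces from all others: strongly negative means
  hard to satisfy jointly with the rest.

Phenotypes with zero variance across the archive (captured by all vectors
or by none) carry no correlation information: their R entries are defined
as 0, they are excluded from the Rhat sums, and their own Rhat is undefined
(NaN) and flagged.

Dropping the least competitive phenotypes (largest Rhat) from the selection
objective reduces per-generation simulation load with little cost in final
full-panel performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcceptanceMatrix",
    "CompetitionProfile",
    "acceptance_from_archive",
    "acceptance_ratio",
    "correlation_matrix",
    "competitiveness",
    "competition_profile",
    "least_competitive_subset",
]

from .evolve import HIT_PREFIX


@dataclass
class AcceptanceMatrix:
    """m x n binary hit indicators with row and column provenance."""

    A: np.ndarray
    row_ids: list[str]
    strain_ids: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.ndim != 2:
            raise ValueError("A must be 2-dimensional")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A must be binary")
        if self.A.shape != (len(self.row_ids), len(self.strain_ids)):
            raise ValueError("A shape does not match row/column ids")

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]


def acceptance_from_archive(
    archive: pd.DataFrame, roles: Sequence[str] = ("offspring",)
) -> AcceptanceMatrix:
    """Extract the acceptance matrix from a DE archive (or any frame with
    ``hit:`` columns), filtered by row role.

    Which rows represent the "sample" is a provenance choice -- trial
    offspring by default; pass ``roles=("parent", "offspring")`` or
    ``("parent",)`` to analyze a different slice.
    """
    hit_cols = [c for c in archive.columns if c.startswith(HIT_PREFIX)]
    if not hit_cols:
        raise ValueError("frame has no hit: columns")
    if "role" in archive.columns:
        sub = archive[archive["role"].isin(roles)]
    else:
        sub = archive
    if "generation" in sub.columns and "lineage" in sub.columns:
        row_ids = [
            f"{r.role}:g{r.generation}:j{r.lineage}" for r in sub.itertuples()
        ]
    else:
        row_ids = [str(i) for i in sub.index]
    A = sub[hit_cols].to_numpy(dtype=np.int8)
    return AcceptanceMatrix(A, row_ids, [c[len(HIT_PREFIX):] for c in hit_cols])


def acceptance_ratio(acc: AcceptanceMatrix) -> pd.Series:
    """Per-phenotype fraction of vectors that captured it."""
    if acc.m < 1:
        raise ValueError("need at least one row")
    return pd.Series(acc.A.mean(axis=0), index=acc.strain_ids, name="acceptance_ratio")


def correlation_matrix(acc: AcceptanceMatrix) -> tuple[np.ndarray, set[str]]:
    """Pairwise phenotype correlations with degenerate-column handling.

    Uses the exact sample-covariance formula with 1/(m-1) normalization.
    Zero-variance columns are returned as a degenerate set; all their R
    entries (including the diagonal) are set to 0.
    """
    if acc.m < 2:
        raise ValueError("need at least two rows to form covariances")
    A = acc.A.astype(float)
    C = np.cov(A, rowvar=False, ddof=1)
    C = np.atleast_2d(C)
    var = np.diag(C).copy()
    degenerate_mask = var == 0.0
    denom = np.sqrt(np.where(degenerate_mask, 1.0, var))
    R = C / np.outer(denom, denom)
    R[degenerate_mask, :] = 0.0
    R[:, degenerate_mask] = 0.0
    np.fill_diagonal(R, np.where(degenerate_mask, 0.0, 1.0))
    degenerate = {sid for sid, d in zip(acc.strain_ids, degenerate_mask) if d}
    return R, degenerate


def competitiveness(
    R: np.ndarray, strain_ids: Sequence[str], degenerate: set[str]
) -> pd.Series:
    """Off-diagonal row sums Rhat; NaN for degenerate phenotypes."""
    R = np.asarray(R, dtype=float)
    rhat = R.sum(axis=1) - np.diag(R)
    out = pd.Series(rhat, index=list(strain_ids), name="competitiveness")
    out[list(degenerate)] = np.nan
    return out


@dataclass
class CompetitionProfile:
    """Bundled robustness/competition statistics of one archive slice."""

    abar: pd.Series
    R: np.ndarray
    rhat: pd.Series
    degenerate: set[str]
    provenance: str = ""

    def ranking(self) -> pd.Series:
        """Rhat sorted ascending: most competitive phenotypes first."""
        return self.rhat.sort_values(kind="stable")


def competition_profile(acc: AcceptanceMatrix, provenance: str = "") -> CompetitionProfile:
    abar = acceptance_ratio(acc)
    R, degenerate = correlation_matrix(acc)
    rhat = competitiveness(R, acc.strain_ids, degenerate)
    return CompetitionProfile(abar, R, rhat, degenerate, provenance)


def least_competitive_subset(
    rhat: pd.Series, k: int
) -> tuple[list[str], list[str]]:
    """Split phenotypes into (drop, keep): drop the k least competitive.

    The least competitive phenotypes are those with the LARGEST Rhat; ties
    are broken by strain id for determinism.  Degenerate (NaN) phenotypes
    are never dropped: competition says nothing about them.
    """
    if k >= len(rhat):
        raise ValueError("k must be smaller than the number of phenotypes")
    if k < 0:
        raise ValueError("k must be nonnegative")
    order = sorted(
        rhat.dropna().items(), key=lambda item: (-item[1], item[0])
    )
    drop = sorted(sid for sid, _ in order[:k])
    keep = sorted(set(rhat.index) - set(drop))
    return drop, keep
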