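"""Representational dissimilarity matrices from condition x voxel patterns.

A pattern matrix holds the voxel-wise response estimates (betas, in
percent-signal-change units) for each condition measured in one region of
interest.  Its RDM is the matrix of pairwise correlation distances
``1 - Pearson r`` between condition patterns: two conditions that evoke the
same spatial pattern (up to positive scaling) are at distance 0, perfectly
anti-correlated patterns at distance 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PatternMatrix",
    "RDM",
    "compute_rdm",
    "average_rdms",
    "upper_tri",
    "rdm_from_upper",
]


@dataclass
class PatternMatrix:
    """Condition x voxel response estimates for one ROI.

    Parameters
    ----------
    condition_ids : sequence of str
        Ordered condition labels (length ``n_cond >= 3``).
    betas : ndarray, shape (n_cond, n_voxels)
        Response estimate of every voxel to every condition.
    """

    condition_ids: list[str]
    betas: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.condition_ids = list(self.condition_ids)
        if self.betas.ndim != 2:
            raise ValueError("betas must be 2-D (conditions x voxels)")
        n_cond, n_vox = self.betas.shape
        if len(self.condition_ids) != n_cond:
            raise ValueError("condition_ids length does not match betas rows")
        if n_cond < 3:
            raise ValueError("need at least 3 conditions")
        if n_vox < 2:
            raise ValueError("need at least 2 voxels")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas must be finite")


@dataclass
class RDM:
    """Symmetric zero-diagonal dissimilarity matrix over labelled conditions."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.labels = list(self.labels)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("dissimilarity matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-8):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-8):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        # enforce exact symmetry / zero diagonal after tolerance check
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)


def compute_rdm(pattern: PatternMatrix) -> RDM:
    """Correlation-distance RDM of a pattern matrix.

    ``d(i, j) = 1 - Pearson r`` between the voxel patterns of conditions i
    and j.  Raises if any condition pattern has zero variance across voxels
    (a degenerate ROI/condition for which correlation is undefined).
    """
    betas = pattern.betas
    sd = betas.std(axis=1)
    if np.any(sd == 0):
        bad = [pattern.condition_ids[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance pattern for condition(s): {bad}")
    corr = np.corrcoef(betas)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return RDM(labels=pattern.condition_ids, d=d)


def average_rdms(rdms: Sequence[RDM]) -> RDM:
    """Element-wise mean of RDMs sharing identical condition labels."""
    if len(rdms) == 0:
        raise ValueError("cannot average an empty list of RDMs")
    labels = rdms[0].labels
    for r in rdms[1:]:
        if r.labels != labels:
            raise ValueError("all RDMs must share condition labels and order")
    mean_d = np.mean([r.d for r in rdms], axis=0)
    return RDM(labels=labels, d=mean_d)


def upper_tri(rdm: RDM | np.ndarray) -> np.ndarray:
    """Strict upper-triangle of an RDM as a vector.

    Ordering is row-major over pairs (i, j) with i < j — the fixed,
    project-wide convention — so the length is n(n-1)/2.
    """
    d = rdm.d if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    return d[iu].copy()


def rdm_from_upper(values: np.ndarray, labels: Sequence[str]) -> RDM:
    """Rebuild a symmetric zero-diagonal RDM from its upper-triangle vector."""
    n = len(labels)
    values = np.asarray(values, dtype=float)
    if values.size != n * (n - 1) // 2:
        raise ValueError("vector length inconsistent with number of labels")
    d = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    d[iu] = values
    d = d + d.T
    return RDM(labels=list(labels), d=d)
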