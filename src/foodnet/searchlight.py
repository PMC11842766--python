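"""Spherical-searchlight RSA mapping over beta volumes.

At every in-mask voxel a sphere of lattice offsets (radius in voxels) is
intersected with the mask; the local condition x voxel pattern matrix
yields a correlation-distance RDM whose Spearman correlation with a model
RDM is Fisher-z transformed and written to the center voxel.  Subject maps
are combined with a voxelwise one-sample t-test and thresholded by BH-FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rdm import RDM, upper_tri

__all__ = [
    "SearchlightMap",
    "sphere_offsets",
    "run_searchlight",
    "run_searchlight_naive",
    "group_searchlight",
]

ATANH_CLIP = 1.0 - 1e-7


@dataclass
class SearchlightMap:
    """Per-voxel Fisher-z map with its defined-center mask and QC counts."""

    data: np.ndarray  # float volume, NaN where undefined
    defined: np.ndarray  # bool volume
    radius: float
    min_voxels: int
    model_name: str = ""
    n_skipped_small: int = 0  # centers with too few in-mask sphere voxels
    n_skipped_degenerate: int = 0  # centers with a zero-variance pattern


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer lattice offsets within a ball: dx^2 + dy^2 + dz^2 <= r^2.

    Includes (0, 0, 0); deterministic lexicographic order.  Radius 3 gives
    123 offsets.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(np.floor(radius))
    out = []
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                if dx * dx + dy * dy + dz * dz <= radius * radius:
                    out.append((dx, dy, dz))
    return np.array(out, dtype=int)


def _as_beta_array(betas, model: RDM) -> np.ndarray:
    """Stack condition volumes into (n_cond, nx, ny, nz) in model-label order."""
    if isinstance(betas, dict):
        missing = [lab for lab in model.labels if lab not in betas]
        if missing:
            raise ValueError(f"model labels missing from betas: {missing}")
        return np.stack([np.asarray(betas[lab], float) for lab in model.labels])
    arr = np.asarray(betas, dtype=float)
    if arr.ndim != 4:
        raise ValueError("betas must be 4-D (conditions x volume)")
    if arr.shape[0] != model.n:
        raise ValueError("number of condition volumes does not match model labels")
    return arr


def run_searchlight(
    betas,
    mask: np.ndarray,
    model: RDM,
    radius: float = 3.0,
    min_voxels: int = 10,
    model_name: str = "",
) -> SearchlightMap:
    """Searchlight Spearman RSA of beta volumes against a model RDM.

    ``betas`` is either a dict mapping condition label -> 3-D volume or a
    4-D array ordered like ``model.labels``.  At each in-mask center the
    sphere is intersected with the mask and volume bounds; centers with
    fewer than ``min_voxels`` members, or whose local pattern is degenerate
    (some condition constant across the sphere), are left undefined (NaN)
    and counted in the QC fields.  Stored values are ``atanh(rho)`` with
    |rho| clipped to 1 - 1e-7.
    """
    mask = np.asarray(mask, dtype=bool)
    arr = _as_beta_array(betas, model)
    if arr.shape[1:] != mask.shape:
        raise ValueError("betas and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    nx, ny, nz = mask.shape

    offsets = sphere_offsets(radius)
    rank_model = stats.rankdata(upper_tri(model))
    rank_model_c = rank_model - rank_model.mean()
    denom_model = np.sqrt((rank_model_c**2).sum())
    iu = np.triu_indices(model.n, k=1)

    flat = arr.reshape(arr.shape[0], -1)
    lin_index = np.arange(nx * ny * nz).reshape(nx, ny, nz)

    data = np.full(mask.shape, np.nan)
    defined = np.zeros(mask.shape, dtype=bool)
    n_small = n_degen = 0
    centers = np.argwhere(mask)
    for cx, cy, cz in centers:
        pts = offsets + (cx, cy, cz)
        ok = (
            (pts[:, 0] >= 0) & (pts[:, 0] < nx)
            & (pts[:, 1] >= 0) & (pts[:, 1] < ny)
            & (pts[:, 2] >= 0) & (pts[:, 2] < nz)
        )
        pts = pts[ok]
        pts = pts[mask[pts[:, 0], pts[:, 1], pts[:, 2]]]
        if len(pts) < min_voxels:
            n_small += 1
            continue
        local = flat[:, lin_index[pts[:, 0], pts[:, 1], pts[:, 2]]]
        if np.any(local.std(axis=1) == 0):
            n_degen += 1
            continue
        neural = 1.0 - np.corrcoef(local)
        v = neural[iu]
        rank_v = stats.rankdata(v)
        rank_v = rank_v - rank_v.mean()
        dv = np.sqrt((rank_v**2).sum())
        if dv == 0:
            n_degen += 1
            continue
        rho = float((rank_v @ rank_model_c) / (dv * denom_model))
        rho = np.clip(rho, -ATANH_CLIP, ATANH_CLIP)
        data[cx, cy, cz] = np.arctanh(rho)
        defined[cx, cy, cz] = True
    return SearchlightMap(
        data=data,
        defined=defined,
        radius=radius,
        min_voxels=min_voxels,
        model_name=model_name,
        n_skipped_small=n_small,
        n_skipped_degenerate=n_degen,
    )


def run_searchlight_naive(
    betas,
    mask: np.ndarray,
    model: RDM,
    radius: float = 3.0,
    min_voxels: int = 10,
) -> SearchlightMap:
    """Reference engine: naive triple loop over voxel coordinates.

    Independent code path used to validate :func:`run_searchlight` — scans
    every (i, j, k), tests sphere membership per offset, and computes the
    local RDM and Spearman correlation through scipy calls.
    """
    mask = np.asarray(mask, dtype=bool)
    arr = _as_beta_array(betas, model)
    nx, ny, nz = mask.shape
    v_model = upper_tri(model)
    r2 = radius * radius
    data = np.full(mask.shape, np.nan)
    defined = np.zeros(mask.shape, dtype=bool)
    n_small = n_degen = 0
    ri = int(np.floor(radius))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                members = []
                for di in range(-ri, ri + 1):
                    for dj in range(-ri, ri + 1):
                        for dk in range(-ri, ri + 1):
                            if di * di + dj * dj + dk * dk > r2:
                                continue
                            x, y, z = i + di, j + dj, k + dk
                            if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz and mask[x, y, z]:
                                members.append((x, y, z))
                if len(members) < min_voxels:
                    n_small += 1
                    continue
                local = np.array([[vol[m] for m in members] for vol in arr])
                if np.any(local.std(axis=1) == 0):
                    n_degen += 1
                    continue
                neural = 1.0 - np.corrcoef(local)
                v = neural[np.triu_indices(model.n, k=1)]
                rho, _ = stats.spearmanr(v, v_model)
                rho = float(np.clip(rho, -ATANH_CLIP, ATANH_CLIP))
                data[i, j, k] = np.arctanh(rho)
                defined[i, j, k] = True
    return SearchlightMap(
        data=data,
        defined=defined,
        radius=radius,
        min_voxels=min_voxels,
        n_skipped_small=n_small,
        n_skipped_degenerate=n_degen,
    )


@dataclass
class GroupSearchlightResult:
    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray  # bool volume
    defined: np.ndarray  # centers defined in all subject maps
    q: float


def group_searchlight(maps: list[SearchlightMap], q: float = 0.05) -> GroupSearchlightResult:
    """Group-level one-sample t-test over subject Fisher-z maps with FDR.

    Only centers defined in every subject map enter the test; p-values are
    two-sided and BH-FDR corrected across those centers, and the
    significance mask thresholds the adjusted values at ``q``.
    """
    from .rsa import fdr_bh

    if len(maps) < 3:
        raise ValueError("need at least 3 subject maps")
    shape = maps[0].data.shape
    for m in maps[1:]:
        if m.data.shape != shape:
            raise ValueError("subject maps are not aligned")
    defined = np.logical_and.reduce([m.defined for m in maps])
    if not defined.any():
        raise ValueError("no commonly defined centers")
    stack = np.stack([m.data[defined] for m in maps])
    t, p = stats.ttest_1samp(stack, 0.0, axis=0)
    t_vol = np.full(shape, np.nan)
    p_vol = np.full(shape, np.nan)
    t_vol[defined] = t
    p_vol[defined] = p
    qvals = fdr_bh(p)
    sig = np.zeros(shape, dtype=bool)
    sig[defined] = qvals <= q
    return GroupSearchlightResult(t=t_vol, p=p_vol, significant=sig, defined=defined, q=q)
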