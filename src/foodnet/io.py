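"""File-format adapters: NIfTI volumes, RDM CSVs, pipeline configuration."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .rdm import RDM

__all__ = [
    "read_volume",
    "write_volume",
    "read_rdm_csv",
    "write_rdm_csv",
    "PipelineConfig",
]


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3-D NIfTI-1 volume (optionally gzipped) as (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    return data, np.asarray(img.affine)


def write_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a 3-D array as NIfTI-1; affine defaults to identity."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(path))


def read_rdm_csv(path) -> RDM:
    """Read a square, headered RDM CSV.

    Symmetry is enforced by averaging the two halves (raising beyond a
    1e-8 tolerance); a nonzero diagonal beyond tolerance is forced to zero
    with a warning.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError("RDM CSV must be square")
    labels = [str(c) for c in df.columns]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    if [str(i) for i in df.index] != labels:
        raise ValueError("row and column labels differ")
    d = df.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("RDM CSV is asymmetric beyond tolerance")
    d = (d + d.T) / 2.0
    if np.max(np.abs(np.diag(d))) > 1e-8:
        warnings.warn("nonzero diagonal in RDM CSV; forcing to 0")
    np.fill_diagonal(d, 0.0)
    return RDM(labels=labels, d=d)


def write_rdm_csv(rdm: RDM, path) -> None:
    pd.DataFrame(rdm.d, index=rdm.labels, columns=rdm.labels).to_csv(path)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration with stage toggles.

    Defaults follow the analysis parameters the pipeline is built around:
    10,000 permutations for the RSA null, searchlight radius 3 voxels,
    cubic polynomial detrending, and an outlier z-threshold of 2.0.
    """

    seed: int = 0
    out_dir: str = "foodnet_out"
    # stage toggles
    run_simulate: bool = True
    run_behavior: bool = True
    run_rdm: bool = True
    run_cluster: bool = True
    run_rsa: bool = True
    run_searchlight: bool = False
    run_glm: bool = True
    # stage parameters
    n_subjects: int = 43
    n_items: int = 36
    n_perm: int = 10_000
    radius: float = 3.0
    min_voxels: int = 10
    polort: int = 3
    z_threshold: float = 2.0
    cluster_method: str = "kmeans"
    k_min: int = 2
    k_max: int = 8
    behavior_k_min: int = 2
    behavior_k_max: int = 10
    n_searchlight_subjects: int = 8
    searchlight_q: float = 0.05

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError("configuration file must contain a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
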