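"""Amplitude-modulated GLM with a gamma-variate HRF.

The hemodynamic response kernel is the gamma-variate
``h(t) = (t / (p * q))**p * exp(p - t / q)`` (peak 1 at t = p*q); the
defaults p = 8.6, q = 0.547 s peak at ~4.70 s.  An amplitude-modulated
design carries, per condition, one unit-amplitude onset regressor and one
regressor whose event heights are the mean-centered behavioral ratings, so
the modulated beta isolates the rating-driven response while the onset
column absorbs the mean response.  Nuisance structure is Legendre
polynomial trends (up to cubic by default) plus optional extra event
regressors (instructions, missed trials, unpleasant-rated foods).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import stats

from .networks import NetworkPartition

__all__ = [
    "HRFKernel",
    "ModulatedDesign",
    "GLMFit",
    "gamma_hrf",
    "build_modulated_design",
    "fit_glm",
    "psc_network_anova",
]


@dataclass
class HRFKernel:
    """Sampled gamma-variate HRF, peak-normalized to 1."""

    dt: float
    shape_p: float
    scale_q: float
    samples: np.ndarray

    @property
    def peak_time(self) -> float:
        return self.shape_p * self.scale_q


def gamma_hrf(dt: float, p: float = 8.6, q_s: float = 0.547) -> HRFKernel:
    """Gamma-variate HRF sampled at spacing ``dt`` seconds.

    ``h(t) = (t/(p q))^p exp(p - t/q)`` for t >= 0, which peaks at exactly
    t = p*q with value 1; samples are renormalized so the discrete peak is
    1, and the kernel is truncated once it falls below 1e-4 of the peak
    after the peak.
    """
    if dt <= 0 or p <= 0 or q_s <= 0:
        raise ValueError("dt, p and q_s must all be > 0")
    t_peak = p * q_s
    # find truncation point: h decays monotonically after the peak
    t_end = t_peak
    while _gamma_variate(t_end, p, q_s) >= 1e-4:
        t_end += q_s
    t = np.arange(0.0, t_end + dt, dt)
    h = _gamma_variate(t, p, q_s)
    h = h / h.max()
    keep = np.nonzero(h >= 1e-4)[0]
    h = h[: keep[-1] + 1] if len(keep) else h
    return HRFKernel(dt=dt, shape_p=p, scale_q=q_s, samples=h)


def _gamma_variate(t, p: float, q_s: float):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(t > 0, (t / (p * q_s)) ** p * np.exp(p - t / q_s), 0.0)
    return h


@dataclass
class ModulatedDesign:
    """Design matrix with labelled columns and a record of dropped columns."""

    matrix: np.ndarray
    names: list[str]
    dropped: list[str] = field(default_factory=list)
    tr: float = 0.0

    @property
    def n_vols(self) -> int:
        return self.matrix.shape[0]


def _event_regressor(
    onsets: np.ndarray,
    amplitudes: np.ndarray,
    tr: float,
    n_vols: int,
    hrf: HRFKernel,
    oversample: int,
) -> np.ndarray:
    """Convolve an amplitude-weighted impulse train with the HRF at TR grid."""
    dt = tr / oversample
    n_fine = n_vols * oversample
    train = np.zeros(n_fine + len(hrf.samples))
    idx = np.round(np.asarray(onsets, float) / dt).astype(int)
    if np.any(idx < 0) or np.any(idx >= n_fine):
        raise ValueError("event onset outside the run")
    np.add.at(train, idx, amplitudes)
    conv = np.convolve(train, hrf.samples)[:n_fine]
    return conv[::oversample]


def build_modulated_design(
    onsets: dict[str, np.ndarray],
    modulators: dict[str, np.ndarray] | None,
    tr: float,
    n_vols: int,
    polort: int = 3,
    nuisance_onsets: dict[str, np.ndarray] | None = None,
    extra_columns: dict[str, np.ndarray] | None = None,
    hrf: HRFKernel | None = None,
    oversample: int = 16,
) -> ModulatedDesign:
    """Build an amplitude-modulated design matrix.

    Per condition in ``onsets``: a ``<cond>_onset`` column (unit-amplitude
    events convolved with the HRF, sampled at the TR) and — when a
    modulator vector is supplied — a ``<cond>_mod`` column whose event
    amplitudes are the modulator values minus their run mean.  Nuisance
    event regressors are convolved with unit amplitude; ``extra_columns``
    (e.g. motion estimates) are appended as-is; Legendre polynomial trends
    of order 0..``polort`` close the matrix.  Columns that are identically
    zero (a constant modulator, for instance) are dropped with a warning;
    a rank-deficient matrix after drops raises.
    """
    if tr <= 0:
        raise ValueError("tr must be > 0")
    if hrf is None:
        hrf = gamma_hrf(dt=tr / oversample)
    cols: list[np.ndarray] = []
    names: list[str] = []
    dropped: list[str] = []

    for cond, ons in onsets.items():
        ons = np.asarray(ons, dtype=float)
        cols.append(_event_regressor(ons, np.ones(len(ons)), tr, n_vols, hrf, oversample))
        names.append(f"{cond}_onset")
        if modulators and cond in modulators:
            amp = np.asarray(modulators[cond], dtype=float)
            if len(amp) != len(ons):
                raise ValueError(f"modulators misaligned with onsets for {cond!r}")
            amp = amp - amp.mean()
            cols.append(_event_regressor(ons, amp, tr, n_vols, hrf, oversample))
            names.append(f"{cond}_mod")

    for name, ons in (nuisance_onsets or {}).items():
        ons = np.asarray(ons, dtype=float)
        cols.append(_event_regressor(ons, np.ones(len(ons)), tr, n_vols, hrf, oversample))
        names.append(f"{name}_nuisance")

    for name, col in (extra_columns or {}).items():
        col = np.asarray(col, dtype=float)
        if col.shape != (n_vols,):
            raise ValueError(f"extra column {name!r} has wrong length")
        cols.append(col)
        names.append(name)

    if polort >= 0:
        x = np.linspace(-1.0, 1.0, n_vols)
        for deg in range(polort + 1):
            c = np.zeros(deg + 1)
            c[deg] = 1.0
            cols.append(legendre.legval(x, c))
            names.append(f"polort{deg}")

    keep_cols, keep_names = [], []
    for c, nm in zip(cols, names):
        if np.allclose(c, 0.0):
            warnings.warn(f"dropping identically-zero design column {nm!r}")
            dropped.append(nm)
        else:
            keep_cols.append(c)
            keep_names.append(nm)
    matrix = np.column_stack(keep_cols)
    if np.linalg.matrix_rank(matrix) < matrix.shape[1]:
        raise ValueError("design matrix is rank deficient after column drops")
    return ModulatedDesign(matrix=matrix, names=keep_names, dropped=dropped, tr=tr)


@dataclass
class GLMFit:
    """Ordinary least-squares fit of a modulated design."""

    beta: pd.Series
    residual_variance: float
    fitted: np.ndarray
    residuals: np.ndarray


def fit_glm(y: np.ndarray, design: ModulatedDesign | np.ndarray, names=None) -> GLMFit:
    """Fit a time series by OLS against a design matrix."""
    if isinstance(design, ModulatedDesign):
        x, names = design.matrix, design.names
    else:
        x = np.asarray(design, dtype=float)
        names = list(names) if names is not None else [f"x{i}" for i in range(x.shape[1])]
    y = np.asarray(y, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("time series length does not match design")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    resid = y - fitted
    dof = max(1, len(y) - x.shape[1])
    return GLMFit(
        beta=pd.Series(beta, index=names),
        residual_variance=float(resid @ resid / dof),
        fitted=fitted,
        residuals=resid,
    )


def psc_network_anova(
    betas: pd.DataFrame, partition: NetworkPartition | dict[str, int]
) -> dict:
    """Network x condition repeated-measures ANOVA on modulation betas.

    Stage 1 averages betas per subject x network x condition (outlier ROIs,
    network label 0, are dropped); stage 2 runs a 2 x 2 repeated-measures
    ANOVA across subjects plus post-hoc paired t-tests between conditions
    within each network, FDR-corrected over the post-hoc family.

    ``betas`` needs columns subject, roi, condition, beta.  Returns a dict
    with the ANOVA table and the post-hoc DataFrame.
    """
    from statsmodels.stats.anova import AnovaRM

    from .rsa import fdr_bh

    labels = partition.labels if isinstance(partition, NetworkPartition) else dict(partition)
    nets = {r: c for r, c in labels.items() if c != 0}
    df = betas[betas["roi"].isin(nets)].copy()
    df["network"] = df["roi"].map(nets)

    cells = df.groupby(["subject", "network", "condition"])["beta"].mean().reset_index()
    conditions = sorted(df["condition"].unique())
    networks = sorted(df["network"].unique())
    expected = len(networks) * len(conditions)
    counts = cells.groupby("subject").size()
    if (counts != expected).any():
        raise ValueError("missing subject x network x condition cells")

    aov = AnovaRM(
        cells, depvar="beta", subject="subject", within=["network", "condition"]
    ).fit()
    table = aov.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p"}
    )

    rows = []
    for net in networks:
        wide = cells[cells["network"] == net].pivot(
            index="subject", columns="condition", values="beta"
        )
        for c1, c2 in itertools.combinations(conditions, 2):
            t, p = stats.ttest_rel(wide[c1], wide[c2])
            rows.append((net, f"{c1}_vs_{c2}", float(t), len(wide) - 1, float(p)))
    posthoc = pd.DataFrame(rows, columns=["network", "contrast", "t", "df", "p"])
    posthoc["q"] = fdr_bh(posthoc["p"].to_numpy())
    return {"anova": table, "posthoc": posthoc, "cells": cells}
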