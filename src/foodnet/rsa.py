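"""Permutation-based representational similarity statistics.

Subject-level neural RDMs are compared to model RDMs by Spearman rank
correlation of their upper-triangle vectors.  Each observed correlation is
converted to a z-score against a permutation null built by randomly
relabelling the neural RDM's conditions (a joint row/column shuffle, the
standard RSA null that preserves the RDM's internal structure).  Network-
level inference uses a two-stage summary-statistic procedure: subject-wise
averaging of z within each network, then one-sample and paired t-tests
across subjects, with Benjamini-Hochberg FDR over the test family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .networks import NetworkPartition
from .rdm import RDM, upper_tri

__all__ = [
    "PermutationResult",
    "spearman_upper",
    "permutation_z",
    "rsa_table",
    "network_level_tests",
    "fdr_bh",
]


def spearman_upper(r1: RDM, r2: RDM) -> float:
    """Spearman rank correlation of two RDMs' upper-triangle vectors.

    Ties receive average ranks.  Raises if either vector is constant
    (rank correlation undefined).
    """
    if r1.labels != r2.labels:
        raise ValueError("RDMs must share condition labels")
    v1, v2 = upper_tri(r1), upper_tri(r2)
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("constant upper-triangle vector")
    rho, _ = stats.spearmanr(v1, v2)
    return float(rho)


@dataclass
class PermutationResult:
    rho: float
    z: float
    null_mean: float
    null_sd: float
    n_perm: int
    exhaustive: bool


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``a`` with the vector ``b``."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean()
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum())
    return (a @ b) / denom


def permutation_z(
    neural: RDM,
    model: RDM,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation z-score of the neural-model Spearman correlation.

    Null draws apply a random relabelling of the neural RDM's conditions
    jointly to its rows and columns and recompute the Spearman correlation
    with the model RDM; ``z = (rho_obs - mean_null) / sd_null`` using the
    raw null moments (no tail-based p conversion).  Exhaustive mode
    enumerates all n! relabelings (identity included) and is limited to
    n <= 7 conditions.
    """
    n = neural.n
    if n < 4:
        raise ValueError("need at least 4 conditions")
    rho_obs = spearman_upper(neural, model)

    iu = np.triu_indices(n, k=1)
    v_model = upper_tri(model)
    rank_model = stats.rankdata(v_model)

    if exhaustive:
        if n > 7:
            raise ValueError("exhaustive null limited to n <= 7 conditions")
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        if rng is None:
            rng = np.random.default_rng()
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    # Row p of the permuted RDM's upper triangle is d[p[i], p[j]] over the
    # fixed (i < j) pair list — a permutation of the original 630 values —
    # so its rank vector is the original rank matrix gathered at the same
    # positions (ties get identical average ranks).  One fancy gather per
    # null draw replaces per-permutation ranking.
    rank_mat = np.zeros_like(neural.d)
    rank_mat[iu] = stats.rankdata(neural.d[iu])
    rank_mat = rank_mat + rank_mat.T
    null_ranks = rank_mat[perms[:, iu[0]], perms[:, iu[1]]]
    null_rhos = _pearson_rows(null_ranks, rank_model)

    mean, sd = float(null_rhos.mean()), float(null_rhos.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate permutation null (zero sd)")
    return PermutationResult(
        rho=rho_obs,
        z=(rho_obs - mean) / sd,
        null_mean=mean,
        null_sd=sd,
        n_perm=len(perms),
        exhaustive=exhaustive,
    )


def rsa_table(
    neural_rdms: dict[str, dict[str, RDM]],
    models: dict[str, RDM],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Subject x ROI x model table of Spearman rho and permutation z.

    Permutation draws are reproducible given (seed, subject, roi, model):
    each cell gets its own child generator spawned deterministically.
    """
    rows = []
    base = np.random.SeedSequence(seed)
    for si, (subj, rois) in enumerate(sorted(neural_rdms.items())):
        for ri, (roi, rdm) in enumerate(sorted(rois.items())):
            for mi, (model_name, model) in enumerate(sorted(models.items())):
                child = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=base.entropy, spawn_key=(si, ri, mi)
                    )
                )
                res = permutation_z(rdm, model, n_perm=n_perm, rng=child)
                rows.append(
                    (subj, roi, model_name, res.rho, res.z, res.n_perm)
                )
    return pd.DataFrame(
        rows, columns=["subject", "roi", "model", "rho", "z", "n_perm"]
    )


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    Monotone in rank and capped at 1; never smaller than the raw p-value.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def network_level_tests(
    stats_table: pd.DataFrame, partition: NetworkPartition
) -> pd.DataFrame:
    """Two-stage network-level group tests on permutation z-scores.

    Stage 1 averages z across each network's ROIs within every subject;
    stage 2 runs, per model, a two-sided one-sample t-test of each
    network's subject means against zero and a two-sided paired t-test
    between networks.  All p-values are FDR-adjusted as one family.
    Outlier ROIs (network label 0) are ignored.
    """
    df = stats_table.copy()
    nets = {r: c for r, c in partition.labels.items() if c != 0}
    missing = set(df["roi"]) - set(partition.labels)
    if missing:
        raise ValueError(f"unlabelled ROIs: {sorted(missing)}")
    df = df[df["roi"].isin(nets)]
    df["network"] = df["roi"].map(nets)
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    communities = sorted(df["network"].unique())
    for c in communities:
        if (df["network"] == c).sum() == 0:
            raise ValueError(f"network {c} has zero ROIs")

    subj_means = (
        df.groupby(["model", "network", "subject"])["z"].mean().reset_index()
    )
    rows = []
    for model in sorted(df["model"].unique()):
        sub = subj_means[subj_means["model"] == model]
        by_net = {
            c: sub[sub["network"] == c].set_index("subject")["z"]
            for c in communities
        }
        for c in communities:
            vals = by_net[c]
            if vals.std(ddof=1) == 0:
                raise ValueError("zero variance across subjects")
            t, p = stats.ttest_1samp(vals, 0.0)
            rows.append((f"network{c}_vs_0", model, float(t), len(vals) - 1, float(p)))
        for c1, c2 in itertools.combinations(communities, 2):
            a = by_net[c1]
            b = by_net[c2].reindex(a.index)
            diff = a - b
            if diff.std(ddof=1) == 0 and np.allclose(diff, 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(a, b)
            rows.append(
                (f"network{c1}_vs_network{c2}", model, float(t), len(a) - 1, float(p))
            )
    out = pd.DataFrame(rows, columns=["contrast", "model", "t", "df", "p"])
    out["q"] = fdr_bh(out["p"].to_numpy())
    return out
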