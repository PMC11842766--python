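"""Synthetic data generator with planted ground truth.

Every input the analysis pipeline consumes can be simulated here: a latent
food-property space generating odd-one-out triplet choices, a cohort of
subjects x ROIs of voxel-pattern betas in which the ROIs split into two
representational sub-networks plus one outlier region, small 3-D beta
volumes with an embedded region encoding a target RDM (for searchlight
validation), and a two-condition rating-modulated BOLD design.

The planted parameters (latent coordinates, network membership, effect
sizes, noise levels) are returned alongside the data so every downstream
stage can be tested against known truth.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .rdm import RDM, PatternMatrix

__all__ = [
    "SyntheticConfig",
    "FoodSpace",
    "ROICohort",
    "SearchlightDataset",
    "PSCDataset",
    "gen_food_space",
    "gen_triplet_responses",
    "gen_roi_patterns",
    "gen_searchlight_dataset",
    "gen_psc_dataset",
    "gen_modulated_timeseries",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale configuration of the simulator.

    Defaults mirror the study conditions the pipeline is designed for:
    43 subjects viewing 36 foods, 17 food-responsive ROIs of which one is
    a representational outlier, five latent food categories in a
    two-dimensional property space, and a TR of 2.5 s.
    """

    seed: int = 0
    n_subjects: int = 43
    n_items: int = 36
    n_categories: int = 5
    latent_dims: int = 2
    n_rois_net1: int = 6
    n_rois_net2: int = 10
    n_outlier_rois: int = 1
    voxels_per_roi: int = 120
    pattern_noise_sd: float = 0.6
    choice_temperature: float = 0.15
    triplet_reps: int = 5
    volume_shape: tuple[int, int, int] = (16, 16, 10)
    tr_seconds: float = 2.5
    # within-category spread of item coordinates; centroid separation is
    # guaranteed to be at least 4x this (defaults give ~7x)
    category_spread: float = 0.12
    # between-subject variability of pattern signal amplitude (lognormal sd)
    subject_amp_sd: float = 0.4

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_items": self.n_items,
            "n_categories": self.n_categories,
            "latent_dims": self.latent_dims,
            "n_rois_net1": self.n_rois_net1,
            "n_rois_net2": self.n_rois_net2,
            "voxels_per_roi": self.voxels_per_roi,
            "triplet_reps": self.triplet_reps,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")
        if self.n_outlier_rois < 0:
            raise ValueError("n_outlier_rois must be >= 0")
        if self.n_items < 3:
            raise ValueError("n_items must be >= 3")
        if self.choice_temperature <= 0:
            raise ValueError("choice_temperature must be > 0")
        if self.pattern_noise_sd < 0:
            raise ValueError("pattern_noise_sd must be >= 0")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be > 0")
        if len(self.volume_shape) != 3 or any(int(s) != s or s < 1 for s in self.volume_shape):
            raise ValueError("volume_shape must be a triple of positive integers")
        if self.category_spread < 0:
            raise ValueError("category_spread must be >= 0")

    @property
    def n_rois(self) -> int:
        return self.n_rois_net1 + self.n_rois_net2 + self.n_outlier_rois

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FoodSpace:
    """Latent item coordinates with category labels and property scores.

    ``processing_score`` is the coordinate along latent dimension 1 (the
    processed/unprocessed axis that dominates behavioral food similarity);
    ``hedonic_score`` is an independent per-item hedonic value driving the
    second neural sub-network and the rating task.
    """

    coords: np.ndarray  # (n_items, latent_dims)
    category_label: np.ndarray  # ints in 1..n_categories
    processing_score: np.ndarray
    hedonic_score: np.ndarray

    @property
    def n_items(self) -> int:
        return self.coords.shape[0]

    def similarity(self) -> np.ndarray:
        """Ground-truth similarity kernel sim(i,j) = exp(-||c_i - c_j||).

        The exponential of negative Euclidean distance keeps similarity in
        (0, 1], matching the proportion-valued behavioral estimate.
        """
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        return np.exp(-dist)

    def item_labels(self) -> list[str]:
        return [f"food{i + 1:02d}" for i in range(self.n_items)]


def gen_food_space(cfg: SyntheticConfig, rng: np.random.Generator) -> FoodSpace:
    """Draw items around well-separated category centroids in latent space.

    Centroids follow a zigzag layout: evenly spaced along dimension 1 (step
    ~5.8x ``category_spread``) with alternating offsets (~4.2x spread) on
    dimension 2, so the nearest-centroid separation is ~7x the within-
    category spread (>= the 4x needed for recoverable categories), the
    maximum pairwise distance stays small enough that the exp(-distance)
    similarity kernel remains graded rather than saturating, and dimension
    1 dominates the layout's variance, making it the recoverable first
    principal axis of behavioral similarity.  Items are assigned to
    categories as evenly as possible and jittered isotropically.
    """
    cfg.validate()
    n, k, d = cfg.n_items, cfg.n_categories, cfg.latent_dims
    spread = cfg.category_spread

    x_step = (0.7 / 0.12) * spread
    y_off = (0.5 / 0.12) * spread
    centroids = np.zeros((k, d))
    centroids[:, 0] = x_step * (np.arange(k) - (k - 1) / 2.0)
    if d > 1 and k > 1:
        centroids[:, 1] = y_off * (np.arange(k) % 2 - 0.5)

    labels = np.array([i % k for i in range(n)], dtype=int)
    labels = labels[rng.permutation(n)]
    coords = centroids[labels] + rng.normal(0.0, spread, size=(n, d))
    hedonic = rng.normal(0.0, 1.0, size=n)
    return FoodSpace(
        coords=coords,
        category_label=labels + 1,
        processing_score=coords[:, 0].copy(),
        hedonic_score=hedonic,
    )


def gen_triplet_responses(
    space: FoodSpace,
    reps: int,
    temperature: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate odd-one-out choices for every unordered item triplet.

    All C(n, 3) triplets are enumerated and each repeated ``reps`` times.
    For a triplet {a, b, c} the odd item x is chosen with Luce/softmax
    probability proportional to ``exp(sim(y, z) / temperature)`` where
    {y, z} are the two remaining items — i.e. the surviving pair tends to
    be the most similar pair, with ``temperature`` controlling decision
    noise (-> 0 recovers the deterministic argmax choice).

    Returns a DataFrame with 1-based columns item_a, item_b, item_c, odd.
    """
    if space.n_items < 3:
        raise ValueError("need at least 3 items")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    sim = space.similarity()
    trips = np.array(list(itertools.combinations(range(space.n_items), 3)))
    a, b, c = trips[:, 0], trips[:, 1], trips[:, 2]
    # utility of choosing x as odd = similarity of the remaining pair
    util = np.stack([sim[b, c], sim[a, c], sim[a, b]], axis=1) / temperature
    util -= util.max(axis=1, keepdims=True)
    prob = np.exp(util)
    prob /= prob.sum(axis=1, keepdims=True)

    trips_rep = np.repeat(trips, reps, axis=0)
    prob_rep = np.repeat(prob, reps, axis=0)
    u = rng.random(len(trips_rep))
    choice = (u[:, None] > np.cumsum(prob_rep, axis=1)).sum(axis=1)
    odd = trips_rep[np.arange(len(trips_rep)), choice]
    return pd.DataFrame(
        {
            "item_a": trips_rep[:, 0] + 1,
            "item_b": trips_rep[:, 1] + 1,
            "item_c": trips_rep[:, 2] + 1,
            "odd": odd + 1,
        }
    )


def _exp_kernel_corr(dist: np.ndarray) -> np.ndarray:
    """Positive-definite target correlation matrix exp(-dist / median(dist)).

    The exponential kernel of a Euclidean distance is positive definite, so
    the target is a valid correlation matrix with unit diagonal; the median
    upper-triangle distance sets the length scale so target correlations
    span a wide range regardless of coordinate units.
    """
    iu = np.triu_indices(dist.shape[0], k=1)
    scale = np.median(dist[iu])
    if scale <= 0:
        scale = 1.0
    corr = np.exp(-dist / scale)
    np.fill_diagonal(corr, 1.0)
    return corr


def _mixing_root(corr: np.ndarray) -> np.ndarray:
    """Matrix square root (Cholesky factor) of a target correlation structure."""
    w = np.linalg.eigvalsh(corr)
    if w.min() < -1e-8:
        raise ValueError("target correlation structure is not positive semi-definite")
    jitter = 1e-10 * np.eye(corr.shape[0])
    return np.linalg.cholesky(corr + jitter)


def _white_noise_rows(rng: np.random.Generator, n: int, v: int) -> np.ndarray:
    """i.i.d. normal matrix whose rows are exactly zero-mean and white.

    Centering and empirically whitening the rows makes the mixed patterns'
    inter-condition correlation equal the target exactly in the noiseless
    limit (rather than only in expectation), so planted structure is
    recovered exactly as noise goes to zero.  Requires v > n.
    """
    if v <= n:
        raise ValueError("need more voxels than conditions to whiten patterns")
    z = rng.normal(size=(n, v))
    z -= z.mean(axis=1, keepdims=True)
    g = z @ z.T / v
    z = np.linalg.solve(np.linalg.cholesky(g), z)
    return z


@dataclass
class ROICohort:
    """Per-subject ROI pattern matrices with planted network structure.

    ``roi_network`` maps each ROI id to its planted label: 1 and 2 for the
    two sub-networks, 0 for outlier ROIs.  ``target_rdms`` holds the noise-
    free RDM (1 - target correlation) each group of ROIs encodes.
    """

    patterns: dict[str, dict[str, PatternMatrix]]  # subject -> roi -> patterns
    roi_network: dict[str, int]
    target_rdms: dict[int, RDM]
    condition_ids: list[str]

    @property
    def subjects(self) -> list[str]:
        return list(self.patterns.keys())

    @property
    def roi_ids(self) -> list[str]:
        return list(self.roi_network.keys())


def _roi_target_structures(
    cfg: SyntheticConfig, space: FoodSpace, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Target condition-correlation matrix for each planted group.

    Network 1 encodes the geometry of latent dimension 1 (the processing
    axis); network 2 encodes an independent hedonic geometry; outlier ROIs
    encode an unrelated random 1-D geometry with a 3x inflated distance
    scale, mimicking a region dominated by low-level stimulus features.
    """
    d1 = np.abs(space.processing_score[:, None] - space.processing_score[None, :])
    d2 = np.abs(space.hedonic_score[:, None] - space.hedonic_score[None, :])
    targets = {1: _exp_kernel_corr(d1), 2: _exp_kernel_corr(d2)}
    u = rng.normal(0.0, 1.0, size=cfg.n_items)
    du = np.abs(u[:, None] - u[None, :])
    iu = np.triu_indices(cfg.n_items, k=1)
    scale = np.median(du[iu])
    corr_out = np.exp(-3.0 * du / scale)
    np.fill_diagonal(corr_out, 1.0)
    targets[0] = corr_out
    return targets


def gen_roi_patterns(
    cfg: SyntheticConfig,
    space: FoodSpace,
    rng: np.random.Generator,
    pattern_noise_sd: float | None = None,
) -> ROICohort:
    """Simulate the subject x ROI cohort of condition-pattern betas.

    Each ROI's condition patterns are ``a_s * (L @ Z) + noise`` where Z is
    a (row-whitened) i.i.d. standard-normal conditions x voxels matrix, L
    the Cholesky square root of that ROI group's target correlation
    structure — so the inter-condition pattern correlation equals the
    target exactly in the noiseless limit, without iterative fitting —
    ``a_s`` a per-subject lognormal amplitude, and noise i.i.d. with sd
    ``pattern_noise_sd``.
    """
    cfg.validate()
    noise_sd = cfg.pattern_noise_sd if pattern_noise_sd is None else pattern_noise_sd
    targets = _roi_target_structures(cfg, space, rng)
    roots = {g: _mixing_root(c) for g, c in targets.items()}
    cond_ids = space.item_labels()

    roi_network: dict[str, int] = {}
    idx = 1
    for _ in range(cfg.n_rois_net1):
        roi_network[f"roi{idx:02d}"] = 1
        idx += 1
    for _ in range(cfg.n_rois_net2):
        roi_network[f"roi{idx:02d}"] = 2
        idx += 1
    for _ in range(cfg.n_outlier_rois):
        roi_network[f"roi{idx:02d}"] = 0
        idx += 1

    patterns: dict[str, dict[str, PatternMatrix]] = {}
    for s in range(cfg.n_subjects):
        amp = float(np.exp(rng.normal(0.0, cfg.subject_amp_sd)))
        subj = f"sub{s + 1:02d}"
        patterns[subj] = {}
        for roi, net in roi_network.items():
            z = _white_noise_rows(rng, cfg.n_items, cfg.voxels_per_roi)
            betas = amp * (roots[net] @ z)
            if noise_sd > 0:
                betas = betas + rng.normal(0.0, noise_sd, size=betas.shape)
            patterns[subj][roi] = PatternMatrix(condition_ids=cond_ids, betas=betas)

    target_rdms = {
        g: RDM(labels=cond_ids, d=_zero_diag(1.0 - c)) for g, c in targets.items()
    }
    return ROICohort(
        patterns=patterns,
        roi_network=roi_network,
        target_rdms=target_rdms,
        condition_ids=cond_ids,
    )


def _zero_diag(d: np.ndarray) -> np.ndarray:
    d = d.copy()
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class SearchlightDataset:
    """Condition beta volumes with a planted RDM-encoding cuboid region."""

    volumes: np.ndarray  # (n_cond, nx, ny, nz)
    mask: np.ndarray  # bool (nx, ny, nz)
    target_rdm: RDM
    truth: np.ndarray  # bool (nx, ny, nz)
    condition_ids: list[str]


def gen_searchlight_dataset(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    space: FoodSpace | None = None,
    truth_fraction: float = 0.3,
    min_truth_dim: int = 7,
    noise_sd: float | None = None,
) -> SearchlightDataset:
    """Simulate one subject's beta volumes for searchlight validation.

    An axis-aligned centered cuboid occupying ~``truth_fraction`` of the
    in-mask volume encodes the network-1 target RDM in its local patterns
    (same mixing construction as :func:`gen_roi_patterns`); all other
    voxels are i.i.d. noise of matched marginal variance.  The cuboid mask
    is returned as the planted truth region.

    Each cuboid dimension is floored at ``min_truth_dim`` (default 7, one
    sphere diameter at the standard radius of 3) so the planted region is
    resolvable by the searchlight: a searchlight map blurs any effect by
    roughly the sphere radius, and a region thinner than one sphere
    contains no center whose neighborhood lies wholly inside it.
    """
    cfg.validate()
    if any(s < 8 for s in cfg.volume_shape):
        raise ValueError("each volume dimension must be >= 8")
    if not 0.0 <= truth_fraction < 1.0:
        raise ValueError("truth_fraction must be in [0, 1)")
    noise = cfg.pattern_noise_sd if noise_sd is None else noise_sd
    if space is None:
        space = gen_food_space(cfg, rng)

    nx, ny, nz = cfg.volume_shape
    mask = np.ones((nx, ny, nz), dtype=bool)
    truth = np.zeros_like(mask)
    n_truth = int(round(truth_fraction * mask.sum()))
    if n_truth > 0:
        frac_side = truth_fraction ** (1.0 / 3.0)
        dims = [int(round(frac_side * s)) for s in (nx, ny, nz)]
        dims = [min(max(v, min_truth_dim), s) for v, s in zip(dims, (nx, ny, nz))]
        if np.prod(dims) < max(1, n_truth) and all(
            d == s for d, s in zip(dims, (nx, ny, nz))
        ):
            raise ValueError("planted cuboid does not fit inside the volume")
        starts = [(s - d) // 2 for s, d in zip((nx, ny, nz), dims)]
        sl = tuple(slice(st, st + d) for st, d in zip(starts, dims))
        truth[sl] = True

    d1 = np.abs(space.processing_score[:, None] - space.processing_score[None, :])
    corr = _exp_kernel_corr(d1)
    root = _mixing_root(corr)
    cond_ids = space.item_labels()
    n_cond = cfg.n_items

    amp = float(np.exp(rng.normal(0.0, cfg.subject_amp_sd)))
    vols = rng.normal(0.0, 1.0, size=(n_cond, nx, ny, nz))
    n_sig = int(truth.sum())
    if n_sig > 0:
        z = _white_noise_rows(rng, n_cond, n_sig)
        sig = amp * (root @ z)
        if noise > 0:
            sig = sig + rng.normal(0.0, noise, size=sig.shape)
        vols[:, truth] = sig
    return SearchlightDataset(
        volumes=vols,
        mask=mask,
        target_rdm=RDM(labels=cond_ids, d=_zero_diag(1.0 - corr)),
        truth=truth,
        condition_ids=cond_ids,
    )


@dataclass
class PSCDataset:
    """Rating-modulated two-condition dataset (pleasantness / self-control).

    ``ratings`` has one row per subject x item x condition; ``betas`` holds
    the planted rating-modulation coefficient per subject x ROI x condition
    plus measurement noise.  ``mod_truth`` maps (network, condition) to the
    planted modulation coefficient.
    """

    ratings: pd.DataFrame
    betas: pd.DataFrame
    roi_network: dict[str, int]
    mod_truth: dict[tuple[int, str], float]


CONDITIONS = ("pleasantness", "self_control")


def gen_psc_dataset(
    cfg: SyntheticConfig,
    space: FoodSpace,
    rng: np.random.Generator,
    rating_noise_sd: float = 0.2,
    mod_strength: float = 0.5,
    beta_noise_sd: float = 0.25,
) -> PSCDataset:
    """Simulate the rating task and per-ROI modulation betas.

    Item ratings in both conditions derive from the shared hedonic score
    plus subject-level noise, so within-subject inter-condition and
    between-subject rating correlations are high by construction (the
    defaults give ~0.95).  Planted modulation coefficients follow the
    opponent-network pattern: network-1 ROIs respond positively to
    self-control ratings and negatively to pleasantness ratings, network-2
    ROIs respond positively and equally in both conditions; outlier ROIs
    are unmodulated.
    """
    cfg.validate()
    if rating_noise_sd < 0 or beta_noise_sd < 0:
        raise ValueError("noise sds must be >= 0")

    n_items = cfg.n_items
    items = space.item_labels()
    rows = []
    for s in range(cfg.n_subjects):
        subj = f"sub{s + 1:02d}"
        for cond in CONDITIONS:
            r = space.hedonic_score + rng.normal(0.0, rating_noise_sd, size=n_items)
            for i in range(n_items):
                rows.append((subj, items[i], cond, r[i]))
    ratings = pd.DataFrame(rows, columns=["subject", "item", "condition", "rating"])

    mod_truth = {
        (1, "pleasantness"): -mod_strength,
        (1, "self_control"): mod_strength,
        (2, "pleasantness"): mod_strength,
        (2, "self_control"): mod_strength,
        (0, "pleasantness"): 0.0,
        (0, "self_control"): 0.0,
    }
    roi_network: dict[str, int] = {}
    idx = 1
    for _ in range(cfg.n_rois_net1):
        roi_network[f"roi{idx:02d}"] = 1
        idx += 1
    for _ in range(cfg.n_rois_net2):
        roi_network[f"roi{idx:02d}"] = 2
        idx += 1
    for _ in range(cfg.n_outlier_rois):
        roi_network[f"roi{idx:02d}"] = 0
        idx += 1

    brows = []
    for s in range(cfg.n_subjects):
        subj = f"sub{s + 1:02d}"
        for roi, net in roi_network.items():
            for cond in CONDITIONS:
                b = mod_truth[(net, cond)] + rng.normal(0.0, beta_noise_sd)
                brows.append((subj, roi, cond, b))
    betas = pd.DataFrame(brows, columns=["subject", "roi", "condition", "beta"])
    return PSCDataset(
        ratings=ratings, betas=betas, roi_network=roi_network, mod_truth=mod_truth
    )


def gen_modulated_timeseries(
    modulators: np.ndarray,
    mod_beta: float,
    onset_beta: float,
    tr: float,
    n_vols: int,
    rng: np.random.Generator,
    noise_sd: float = 0.1,
    isi: float = 12.5,
    first_onset: float = 10.0,
):
    """Simulate one run's ROI time series for an amplitude-modulated design.

    Events occur at a fixed ISI; the BOLD response is the sum of the
    unit-amplitude onset regressor scaled by ``onset_beta`` and the
    mean-centered modulated regressor scaled by ``mod_beta``, convolved
    with the gamma-variate HRF, plus white Gaussian noise.  Returns
    ``(y, onsets, modulators)`` for direct GLM fitting.
    """
    from .glm import build_modulated_design, gamma_hrf

    modulators = np.asarray(modulators, dtype=float)
    n_events = modulators.size
    onsets = first_onset + isi * np.arange(n_events)
    if onsets[-1] >= tr * n_vols:
        raise ValueError("events do not fit inside the run")
    design = build_modulated_design(
        onsets={"food": onsets},
        modulators={"food": modulators},
        tr=tr,
        n_vols=n_vols,
        polort=0,
    )
    x_on = design.matrix[:, design.names.index("food_onset")]
    x_mod = design.matrix[:, design.names.index("food_mod")]
    y = onset_beta * x_on + mod_beta * x_mod
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return y, onsets, modulators
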