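# Methods

This note documents the models, estimators, and numerical choices behind
`foodnet`, and what the synthetic ground truth does and does not show
about real data.

## Behavioral similarity from odd-one-out triplets

For a triplet {a, b, c} the participant removes the odd item; the
remaining pair is implicitly judged the most similar. Pairwise similarity
is estimated as the proportion of triplets containing both items in which
neither was removed. With full enumeration of all C(36,3) = 7140 triplets
each pair co-occurs with each of the 34 remaining items exactly once, so
every off-diagonal cell is an average over 34 × reps Bernoulli draws.
The diagonal is fixed at 1 (a self-pair can never contain its own odd
item) and participates in the PCA rows. Unobserved pairs are flagged and
are hard errors downstream; full enumeration makes them impossible in
intended use.

PCA treats rows of S as observations, centers columns (no scaling — the
entries are already on a common proportion scale), and takes components
from the SVD of the centered matrix. Component signs are fixed by making
each component's largest-magnitude loading positive. Category discovery
runs k-means (n_init = 50, seeded) for k = 2..10 on the first two
component scores and selects the k with the largest mean silhouette under
Euclidean distance.

## The choice model and the latent food space

The simulator's ground-truth similarity kernel is `sim(i,j) =
exp(−‖c_i − c_j‖)` over latent coordinates, which keeps similarity in
(0, 1] to match the proportion-valued estimator. Odd-one-out choices
follow a Luce/softmax rule: item x is removed with probability
proportional to `exp(sim(y,z)/T)` where {y, z} is the surviving pair;
the temperature T (default 0.15) controls decision noise, and T → 0
recovers the deterministic argmax.

Category centroids follow a **zigzag layout**: evenly spaced along latent
dimension 1 (step ≈ 5.8 × the within-category spread of 0.12) with
alternating offsets (≈ 4.2 × spread) on dimension 2. Three properties
motivated this over a symmetric circle:

- nearest-centroid separation ≈ 7 × spread, so planted categories are
  recoverable (silhouette of the true labels ≈ 0.75);
- the maximum pairwise distance stays below ~3, so the exponential kernel
  remains *graded* across all pairs instead of saturating to 0 — a
  saturated kernel degenerates into an exchangeable block structure whose
  PCA cannot concentrate variance in two components;
- dimension 1 dominates the layout variance, so the first principal
  component of the estimated similarity aligns with the planted
  processing axis (|Spearman| ≥ 0.9), and the first two components carry
  ≥ 80% of the variance, as in real food-similarity data.

With these defaults the silhouette-selected category count equals the
planted 5 in roughly nine of ten seeds; occasionally the selector prefers
a finer split of genuine within-category jitter clumps. This is a known
property of silhouette selection with 36 points, not an estimator bug,
and the corresponding stability test asserts modal-k stability rather
than unanimity.

## Neural patterns and RDMs

Pattern dissimilarity is plain correlation distance (1 − Pearson across
voxels); rank correlation enters only when *comparing* RDMs. No
cross-validated or noise-normalized distance variants are provided.
The upper-triangle vectorization is row-major over pairs (i < j),
project-wide.

The simulator builds each ROI's condition × voxel patterns as
`a_s · (L Z) + ε`, where L is the Cholesky square root of the target
condition-correlation structure, Z an i.i.d. normal voxel matrix whose
rows are centered and empirically whitened, `a_s` a per-subject lognormal
amplitude (sd 0.4 on the log scale, modelling between-subject
signal-strength differences), and ε i.i.d. noise (sd 0.6). Whitening
makes the noiseless empirical correlation *equal* the target, so the
noise → 0 round-trip through `compute_rdm` recovers the planted RDM
exactly rather than only in expectation. Target structures are
exponential-kernel correlation matrices (positive definite by
construction) built from: dimension-1 distances (network 1), independent
hedonic-score distances (network 2), and an unrelated random geometry
with a 3× inflated distance scale (the planted outlier ROI, mimicking a
region dominated by low-level stimulus features). How the second network's
geometry relates to behavior in real data is underdetermined; an
independent hedonic axis is one admissible reading.

## Outlier screening and network clustering

Outlier ROIs are screened on the mean distance of each ROI's RDM vector
to all others under three metrics — correlation, Euclidean, and
Mahalanobis — z-scored across ROIs (population sd, so z has mean 0, sd 1
by construction). Exclusion keys on the correlation metric at z ≥ 2.0,
with the other metrics reported for context. The Mahalanobis metric works
in a PCA-reduced space of at most m − 2 components because the 630-dim
covariance across ~17 ROIs is singular.

Two clustering paths are provided and surfaced explicitly rather than
merged: the default k-means path (rows of the ROI similarity matrix as
features, best of 50 seeded inits per k, mean silhouette under 1 − s
distance selecting k), and a graph path maximizing weighted modularity
with edge weights (s + 1)/2 (modularity needs nonnegative weights; the
affine map preserves order). The graph path is exact — an exhaustive
search over all set partitions via restricted-growth strings — up to 12
nodes, and greedy agglomeration plus single-node local refinement above
that. Whether the silhouette should be computed on 1 − s or on Euclidean
distances between similarity rows is underdetermined; 1 − s is the
implemented default.

## Permutation RSA

The null relabels the neural RDM's conditions jointly on rows and columns
and recomputes the Spearman correlation with the model RDM; `z =
(ρ_obs − mean_null)/sd_null` uses the raw null moments, no tail-based p
conversion. Each subject × ROI × model cell gets its own deterministic
child generator, so draws are reproducible given (seed, subject, roi,
model). Exhaustive mode enumerates all n! relabelings (identity included)
for n ≤ 7. A permuted upper triangle is a permutation of the same 630
values, so its rank vector is the pre-computed rank matrix gathered at
permuted positions — one fancy gather per draw, no per-permutation
ranking.

Network-level inference is a two-stage summary-statistic procedure:
per-subject averaging of z within each network, then two-sided one-sample
and paired t-tests across subjects, FDR-adjusted (Benjamini–Hochberg) as
one family. A crossed random-effects model over subjects and regions
would be the fuller treatment; the two-stage procedure is deterministic,
dependency-free, and consistent with the same contrasts.

## Searchlight

Sphere membership is all integer offsets with ‖δ‖² ≤ r² (123 voxels at
r = 3); spheres are intersected with the mask and volume bounds, and
centers keep a value only with ≥ 10 in-mask members (undefined centers
propagate as missing, never zero). Stored values are atanh(ρ) with |ρ|
clipped at 1 − 1e−7. Group inference is a voxelwise one-sample t-test
over subjects at commonly defined centers with BH-FDR thresholding;
cluster-extent correction based on spatial-autocorrelation simulation is
out of scope.

The planted-region generator embeds the network-1 structure in a centered
cuboid whose every dimension is at least one sphere diameter (7 voxels at
the default radius) and which occupies ~30% of the volume. A searchlight
map blurs any effect by roughly the sphere radius: centers outside a
signal region whose spheres reach into it genuinely carry diluted signal.
Consequently the recovery checks measure (a) Dice overlap between the
FDR-significant mask and the planted cuboid, and (b) the false-positive
rate only over centers whose spheres contain *no* signal voxel — flagging
a sphere that overlaps the region is detection, not a false positive. A
region much thinner or smaller than the sphere could not meet a Dice
criterion under this blur, which is a physical property of the method,
not of the implementation.

## Amplitude-modulated GLM

The HRF is the gamma variate `h(t) = (t/(p·q))^p · exp(p − t/q)` with
p = 8.6, q = 0.547 s (the conventional defaults of the standard fMRI
analysis software; peak at p·q ≈ 4.70 s, peak-normalized to 1, truncated
below 1e−4 of peak). Designs are built on a 16× oversampled grid and
sampled at the TR. Each condition contributes a unit-amplitude onset
regressor plus a modulated regressor whose event heights are the
mean-centered ratings — centering makes the onset column carry the mean
response and the modulated beta the rating-driven component. Nuisance
structure: Legendre polynomial trends to cubic order; optional extra
event regressors (instructions, missed responses, foods rated
unpleasant, which are excluded from modulation); optional motion columns
(accepted, not simulated). Identically zero columns (e.g., a constant
modulator) are dropped with a warning; rank deficiency after drops is an
error. Fits are ordinary least squares; no prewhitening.

The network analysis averages betas per subject × network × condition and
runs a 2 × 2 repeated-measures ANOVA across subjects (statsmodels
AnovaRM) with FDR-corrected paired post-hocs. The simulator plants the
opponent pattern: network 1 responds +m to self-control and −m to
pleasantness ratings (m = 0.5), network 2 responds +m to both; per-cell
noise sd 0.25. Ratings in both conditions derive from the shared hedonic
score plus subject noise (sd 0.2), giving within-subject and
between-subject rating correlations ≈ 0.95.

## Problem sizes and determinism

Defaults mirror the study scale: 43 subjects, 36 foods, 17 ROIs
(6 + 10 + 1 planted outlier, leaving 16 analysis ROIs after exclusion),
120 voxels per ROI, 16 × 16 × 10 searchlight volumes, 206-volume runs at
TR 2.5 s, 10,000 permutations. Validation simulations use smaller sizes
chosen for quick iteration — e.g., 8-subject searchlight cohorts, 100–1000
permutations in unit tests, 200 replicates for null calibration — and the
acceptance checks state their sizes explicitly. All randomness flows from
a single integer seed per run; the pipeline manifest (parameter echo plus
output hashes) makes a rerun's bit-reproducibility checkable.

## What the synthetic data do not show

The generator omits hemodynamic nonlinearity, physiological and motion
noise, spatial autocorrelation of voxel noise, surface geometry, and any
preprocessing artifacts. Passing recovery tests therefore demonstrates
the correctness of the estimators and inference machinery under the
stated noise model, not robustness to real fMRI confounds. Real-data
statistics that depend on the original cohort (specific t-values, ROI
tables) are outside what synthetic validation can or should reproduce.
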