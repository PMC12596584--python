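# Methods

This note documents the models, statistics, and design choices behind
`geoloci`, in the order data flows through the tool.

## Genotype encoding and preprocessing

Genotypes are alternate-allele doses (0/1/2) from biallelic SNPs;
multi-allelic and indel records are dropped (counted in the log) rather
than split, because every downstream operation — Mendelian crossing,
MAC filtering, binomial imputation — is defined on biallelic doses.
Phased and unphased separators are treated identically. Missing calls
carry a −9 sentinel until imputation.

Minor allele count is computed over non-missing calls only. Imputation
defaults to the per-locus mode (ties toward the smaller dose); a
mean-rounded and a stochastic binomial strategy (dose ~ Binomial(2, p̂)
with p̂ the observed alternate-allele frequency) are available, the
latter seed-reproducible. Imputation never alters observed entries.
Optional embedding (full-SVD PCA or classical Torgerson MDS) reduces
the dose matrix before modelling; signs are fixed so the
largest-magnitude loading of each component is positive, making both
embeddings deterministic. Feature standardization (per-column zero
mean, unit variance) happens inside training, from training-partition
statistics only, so the stored matrices keep integer dose semantics for
augmentation.

## Planar geometry

All local planar work — KDE bandwidths, k-means, jitter — uses an
equirectangular projection about the data centroid
(x = R·Δλ·cos φ₀, y = R·Δφ, R = 6371.0 km). At the regional scales the
tool targets (≤ ~1000 km) the distortion is far below the errors being
measured, and it avoids a projection-library dependency. Accuracy is
always *reported* on the sphere, via the Haversine formula with the
mean Earth radius R = 6371.0 km.

## Inverse sampling-density weights

Density is a Gaussian KDE on projected coordinates (Scott's rule by
default; Silverman or a fixed bandwidth in km are available — the
fixed-km option exists mainly for reproducible tests), scaled by n to
samples/km². Weights are 1/density, clipped at the (0.01, 0.99)
quantiles so one isolated sample cannot dominate a weighted loss, then
mean-normalized to 1. Clipping is logged whenever it changes a weight.
If the projected coordinates are collinear (singular covariance), an
isotropic fallback kernel with Scott's per-dimension factor is used.

Weighting is a bias–variance trade: with hotspot-biased designs the
clipped weights still cut the effective sample size (Σw)²/Σw² roughly
fourfold, so expect noisier fits whenever weighting is enabled; it is a
toggle, not a default.

## Geo-genetic outlier screen

Genetic space is the top 10 principal components of the column-
standardized dose matrix (configurable). For each sample, its location
is predicted as the inverse-distance-weighted mean of its K (default
20, capped at n−1) genetically nearest neighbors' projected
coordinates, self excluded, ties broken by sample order; reciprocally,
its PC vector is predicted from its K geographically nearest neighbors.
The reported errors are the Haversine distance (km) and the PC-space
Euclidean distance.

The test statistic is the squared error divided by (s² + median(s)²),
where s is the weighted RMS spread of the neighbor targets about the
prediction. The squaring makes an isotropic prediction error
gamma-family (a squared isotropic Gaussian error is exponential); the
spread normalization removes the dense-versus-sparse neighborhood scale
gradient; and the median regularization stops a sample whose neighbors
happen to coincide from dividing by ~0. A gamma is fit by maximum
likelihood (location fixed at 0, zeros replaced by half the smallest
positive value) and samples are flagged when the upper-tail p-value in
either direction falls below alpha (default 0.05, per tail, no
multiplicity correction — this is a screen, not inference).

A refit iteration (refit the null excluding decisively flagged samples,
p < alpha/(10n), then recompute) is available but **off by default**:
with the regularized statistic, planted translocations no longer mask
themselves, and any refit measurably inflates the null false-positive
rate above the 2·alpha design bound. On translocation-free simulations
the mean flagged fraction is ~0.09 at alpha = 0.05; on landscapes with
10 planted translocations (≥ 25% of the landscape diameter) recall is
0.9–1.0.

Pruning removes flagged samples from the training partition only —
never from validation, test, or the unknown set — and refuses to leave
fewer than 20 training samples.

## Clustering, oversampling, and splitting

Spatial clusters come from k-means on projected coordinates, k ∈ [2,
10] (10 restarts, fixed seed), selected by mean silhouette width with
ties to the smaller k. Oversampling fills each cluster's deficit to the
largest cluster's size (default) or to its density stratum's median
(strata = equal-count bins of cluster size, `n_bins` = 6): repeatedly
draw a seed sample uniformly from the cluster, a partner uniformly from
its min(20, cluster_size−1) geographically nearest within-cluster
neighbors, and emit a Mendelian-cross genotype at a location drawn at
fraction u ~ U(0.25, 0.75) along the parents' great-circle segment plus
1 km isotropic jitter. The interior fraction avoids synthetic
duplicates of real samples. Expected synthetic allele frequencies equal
the cluster's real frequencies (E[child] = mid-parent), which the tests
verify to < 0.05 mean absolute deviation over 300 loci. Size-1 clusters
are skipped (no self-crossing). Synthetic rows are tagged with their
parent IDs and enter training only — never validation, test, or
prediction — to prevent leakage.

The train/validation/test split (default 75/12.5/12.5) is stratified by
cluster with largest-remainder rounding (remainder ties train > val >
test); within each cluster, members are shuffled after sorting by
sample ID, so the split depends only on the ID set, the clustering, and
the seed — not input row order. Every cluster with ≥ 3 members gets at
least one training sample.

## The regressor and its training

Architecture: input batch normalization (momentum 0.1, ε = 1e-5) →
`n_hidden_layers` × (affine(width) → ELU → dropout) → affine(2). The
width is `resolve_width(initial, rows, cols)`: while width > rows·cols,
width ← ⌊0.8·width⌋, then used uniformly; widths below 2 raise. The
bound uses the training partition's dimensions (logged), since that is
the matrix the model actually fits.

Defaults: 2 hidden layers, initial width 256, dropout 0.2, learning
rate 1e-3, batch size 64, patience 50, LR factor 0.5, LR patience 20,
gradient-clip norm 1.0, max 5000 epochs, Huber δ = 1.0 (standardized
units). Targets are standardized per axis from training statistics;
losses operate in that space, evaluation in km. Implementation is plain
NumPy (forward, backward, Adam) and bit-reproducible under a fixed
seed; singleton minibatches are skipped because batch-norm statistics
degenerate there. Validation loss (same loss kind; optionally weighted
via `val_weights`) drives the plateau LR schedule and early stopping,
and the returned model is the best-validation snapshot. The RMSE/DRMS
gradients are guarded at loss → 0.

Checkpoints (npz: weights, running statistics, scalers, spec, config,
version header) reload to bit-identical predictions.

## Hyperparameter search

`tuning.minimize` is a univariate tree-structured-Parzen-estimator-
style optimizer: 10 uniform start-up trials, then candidates are drawn
from a Gaussian Parzen mixture over the best 25% of observed trials
(per dimension, log-transformed where declared) and scored by the
good/bad density ratio, categorical dimensions by Laplace-smoothed
frequency ratios. The contract — later trials concentrate near earlier
good regions, and a 1-D surrogate (log₁₀ lr + 3)² over [1e-5, 1e-1] is
minimized to within 3× of 1e-3 in 50 trials — is tested directly. The
model-level search tunes depth, width (log), learning rate (log),
dropout, loss kind, and weighting against validation mean Haversine
error; diverged trials score +∞ rather than aborting.

## Bootstrap uncertainty

Pseudoreplicates resample loci (feature columns) with replacement to
the original count, retrain from scratch with a replicate seed derived
as SeedSequence([seed, b]) (so results are independent of execution
order), and predict all unknowns. Resampling loci rather than samples
preserves the spatial sampling design while propagating marker-sampling
noise. Clouds are summarized by the arithmetic-mean centroid, per-axis
SDs, and the 50/90/95% quantiles of Haversine distance from the
centroid; coverage statements use the normal-theory ellipse
(Mahalanobis² ≤ χ²₂(level) under the cloud covariance). Defaults are
100 replicates; desk-scale runs and tests use 10–20.

## The synthetic landscape generator

`simulate_ibd` draws sampling locations from a mixture of Gaussian
hotspots (default two, at 4:1 relative effort, SD 30 km, holding 80% of
samples) and a uniform background over a ~520-km box, then gives each
locus a logistic allele-frequency surface p(s) = 1/(1+exp(−β(proj(s) −
c))) along a random axis, β ~ U(0.02, 0.08)/km for the steep-cline
default (cline widths of roughly 50–200 km). Genotypes are
Binomial(2, p); missingness is uniform; translocations swap the
recorded coordinates of n/2 disjoint pairs at least a stated distance
apart, flagging all n displaced samples in the truth table.

Pure logistic clines are globally smooth: a model fit mostly on hotspot
samples still recovers the entire surface, so sampling bias costs
almost nothing (an oracle experiment upweighting the sparse stratum
directly moved its holdout error by < 2%). Real landscape-genetic data
also carries local drift and kinship structure that only local samples
constrain. The generator therefore offers `local_sd` (logit units;
default 0) adding per-locus sums of random cosine waves with length
scale `local_scale_km` (default 60 km) — spatially autocorrelated
allele-frequency bumps. The sampling-bias study uses `local_sd` = 2,
chosen so the base model's relative error (~5–10% of the landscape
diameter) matches the regime reported for real reduced-representation
panels; it stays off elsewhere so the cline-only contracts (Mantel
correlations, outlier calibration) remain interpretable.

What passing tests on these fixtures do *not* show: performance under
linked loci, kin clusters, genotyping error, or range edges — none of
which the generator emulates.

## Study sizes and observed magnitudes

The default CI scale is 300 samples × 300 loci. At that scale the base
model's holdout error is ~12 km (8% of the centroid-null error); the
outlier screen attains recall ≥ 0.9 with a ~0.09 null flagged fraction;
bootstrap 90% ellipses cover ~84% of holdout truths at 20 replicates.
The sparse-stratum benefit of oversampling + weighting on the
local-heterogeneity fixture is real but modest and seed-noisy — wins in
most but not all seed blocks — consistent with the weights' effective-
sample-size cost discussed above.

## Known limitations

- The equirectangular projection degrades near the poles and for
  continental extents; a proper projected CRS would be needed there.
- The gamma null is an approximation; its regularized statistic is
  calibrated on the fixtures here (~0.09 null flagging at the 0.10
  design bound) but heavy kin structure could inflate it.
- Bootstrap clouds quantify marker-resampling variance, not model bias:
  a systematically displaced prediction can have a tight, wrong cloud.
- The TPE-style optimizer models dimensions independently; it will not
  exploit strong hyperparameter interactions.
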