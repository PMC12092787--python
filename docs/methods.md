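# Methods

This note documents the statistical model, the algorithmic and numerical
choices, and the synthetic designs used by the validation suite and
`scripts/acceptance.py`.

## Generative model and estimand

The measure matrix `X` (n subjects × V in-mask voxels, one vectorized
grey-matter image per row) is modelled as a noisy linear mixture of K
spatially independent sources, `X = A S + E`.  The scientific questions
are (i) which spatial patterns `S_k` covary across subjects, (ii) whether
their expression `A[:, k]` differs between patients and controls after
adjusting for age and total intracranial volume (TIV), and (iii) whether
grey matter in the significant patterns relates to clinical pain metrics.

## Preprocessing

* **Resampling** — trilinear interpolation onto an isotropic grid
  (default 3 mm), keeping the world bounding box; nearest-neighbour is
  available for label volumes.
* **Smoothing** — Gaussian kernel specified as FWHM in mm (default 8);
  `sigma = FWHM / (2 √(2 ln 2))` converted to voxel units per axis.
  Boundaries are zero-padded: grey-matter maps are zero outside the head,
  so no signal is invented at edges.
* **Mask** — a voxel enters the analysis if its across-subject mean
  exceeds 0.1 (a conventional liberal grey-matter threshold, exposed in
  config) and its across-subject variance is positive.  Voxels are
  enumerated in ascending flat index with x varying fastest; this order is
  fixed and shared by every flat voxel index in the package.

## Centering

Before PCA the measure matrix is double-centered: per-subject (row) means
and the across-subject mean image are both removed.  Removing the mean
image caps the subject-space rank at n − 1, which makes the PCA contracts
exact (reduction to k = n − 1 is lossless; the back-reconstruction
residual equals the discarded PCA variance to round-off) and gives every
estimated source row zero mean, so Z-scored maps and loadings remain a
consistent factorization.  The cost is that the "retained variance" of the
whitening refers to the differential (between-subject) structure only; the
common mean image is accounted separately.  The MDL eigen-spectrum, in
contrast, uses only row-centering, because the Wax–Kailath criterion needs
the full-rank noise tail of the covariance.

## Model-order selection (MDL)

In-mask voxels are treated as N observations of an n-dimensional signal.
With eigenvalues `l_1 ≥ … ≥ l_n` of the subject-space covariance,

    MDL(k) = −N (n−k) log( gm(l_{k+1..n}) / am(l_{k+1..n}) )
             + ½ k (2n−k) log N ,

minimized over k = 1..max_k (default n − 1).  Smoothing correlates
neighbouring voxels and inflates the effective sample count, so every 4th
voxel is used by default (`decimation`, exposed in config).  On the
synthetic designs below MDL recovers the true order essentially always;
on pure i.i.d. noise it selects k ≤ 2.

## Infomax ICA

Whitened data are unmixed by natural-gradient maximum likelihood with the
logistic nonlinearity `g(u) = 1/(1+e^{−u})`:

    W ← W + η ( I + (1 − 2 g(u)) uᵀ / B ) W

over shuffled voxel blocks of size `B = ⌊√(N/3)⌋` (the outer product is
averaged over the block, which is what keeps the stated learning rate
`η = 0.015/ln K` stable).  The rate anneals ×0.9 whenever the update
direction turns by more than 60° between sweeps; iteration stops when the
relative weight change falls below 1e−6 or after 512 sweeps.  Divergence
(|W| > 1e8) triggers a restart with halved rate, at most 3 times.  All
parameters are exposed in the config.

Two documented indeterminacies: (i) Gaussian sources are non-identifiable
— the run converges but the rotation is arbitrary, no error is raised;
(ii) plain logistic Infomax fixes scale only up to the stationarity
condition, so recovered unmixing rows are compared to references after
unit-norm normalization.

## ICASSO stability selection

`n_runs` (default 20) Infomax runs start from seeded random orthonormal
matrices on identically whitened data.  The pooled `K·n_runs` source
estimates are clustered by average-linkage agglomeration on the distance
`1 − |r|` (absolute Pearson correlation between source rows) into K
clusters.  Per cluster, the quality index

    Iq = mean intra-cluster |r|  −  mean |r| to estimates outside

is ≈1 for stable components; a cluster with fewer members than
`n_runs / 2` triggers an "unstable component" warning.  The cluster
centrotype (maximal total intra-cluster similarity) becomes the component.
Components are ordered by descending Iq.  Only random initialization is
used (no bootstrap resampling of voxels).

## Back-reconstruction, Z-scoring, sign rule

Loadings are the least-squares solution `A = X_c S⁺` on the centered
measure matrix.  Source rows are standardized to mean 0 / sd 1 over the
mask (the scale folds into the loadings), and any row with negative
skewness is flipped together with its mixing column.  Positive skewness
makes "predominantly positive spatial map" an operational, deterministic
convention: blob-like grey-matter sources are right-skewed, so recovered
maps almost never need flipping.

## Group inference

Each mixing column is tested by residualizing both the loadings and the
patient indicator on [1, age, TIV] (Frisch–Waugh), giving the partial t of
the group term with df = n₁ + n₂ − 2 − n_covariates (a config switch
restores the naive df = n₁ + n₂ − 2).  Sign convention: t > 0 iff the
adjusted patient mean exceeds the control mean.  Without covariates the
statistic reduces exactly to the pooled two-sample t.  Benjamini–Hochberg
FDR (q = 0.05) corrects across components; both raw and adjusted p are
reported.

Z maps of significant components are thresholded at |Z| > 3 and split by
sign into 26-connected clusters (6-connectivity available); each cluster
reports size, signed peak Z, and the peak's world-mm coordinates through
the affine.  The direction label applies the sign rule
`sign(t) · sign(Z) > 0 ⇒ greater-in-patients`.

## Clinical correlations

Per-subject mean grey matter over a cluster's voxels is residualized on
age, as is each clinical metric; the partial correlation is the Pearson r
of the residuals with `t = r √((n−2−n_cov)/(1−r²))`.  Rows with missing
metric values (scores undefined for controls, e.g. pain intensity) are
dropped pairwise and the effective n is recorded.  Both groups are pooled
by default (a `--group` switch restricts to one group); the grid of
ROI × metric correlations reports raw p by default, with optional BH
adjustment, reflecting the exploratory character of this stage.

## Synthetic designs

The generator produces what the model assumes: subject volumes
`baseline + Σ_k a_{ik} S_k + noise`, clipped at zero (a mild, documented
violation mimicking nonnegative grey-matter maps).  Sources are sums of
Gaussian blobs scaled to unit peak; blob centres of different sources are
rejection-sampled to lie ≥ 3σ apart (relaxed ×0.9 if a small grid cannot
satisfy it), keeping pairwise support overlap ≤ 0.2.  Ages are uniform
25–60 y; TIV ~ Normal(1400, 120) ml; clinical scores are drawn per group
from the published cohort means/SDs, and the linked score is constructed
as `r·z_loading + √(1−r²)·noise` plus a small age confounder so that the
age-partialled correlation targets the configured r and the
residualization step is genuinely exercised.

Defaults (the study-scale design): 20 patients + 20 controls, 24×28×24
grid at 3 mm (≈16k voxels), K = 4 sources of 3 blobs with σ = 8 mm,
baseline 0.25, loadings Normal(1.0, 0.25), patient shift 1.5 sd on source
4, noise sd 0.05, linked metric `magnification` at r = −0.6.  Blob width
and loading spread were chosen so that the K sources dominate the
centered variance (the mean image + rank-K model leaves only the injected
noise unexplained), the regime in which order selection and source
recovery are well posed; they also emulate spatially extended
grey-matter networks rather than point lesions.

What the generator does **not** emulate: cortical anatomy and folding,
nonlinear anatomical variability, registration error, spatially
correlated scanner noise, or non-Gaussian loading distributions.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to real-data
violations of them.

## Validation problem sizes

* Source/order recovery: 20 seeded replicates of the study-scale design,
  5 ICASSO runs each, scored by Hungarian-matched mean |correlation|
  between true and estimated maps (matching by maximum |r| handles the
  permutation/sign indeterminacy).  Decomposition runs on the raw
  generated volumes — the generator already produces smooth sources, and
  recovery is scored against the unsmoothed ground truth.
* Null calibration: 500 replicates on a 16³ grid (σ = 4.5 mm blobs so the
  separation constraint fits the 48 mm box), no group effect, k = 4 with
  a single Infomax run per replicate — stability selection permutes and
  re-picks source estimates but does not change the null distribution of
  the loading t-tests.  The family-wise rate of any BH-significant
  component stays at the nominal level.
* Oracle equivalences: partial correlation vs residualize-then-Pearson,
  BH vs the hand step-up, back-reconstruction residual vs the discarded
  PCA variance, Z-map standardization — all at machine precision.

## Numerical choices and edge cases

* Eigenvalues are floored at `1e−12 · l_max` (with a warning) when the
  covariance is rank-deficient; requesting k beyond the numerical rank is
  an error.
* Zero-variance source rows cannot be standardized → "degenerate
  component" error; zero-variance residuals in partial correlation (a
  covariate collinear with the series, detected at a relative 1e−10
  threshold) → "degenerate after residualization".
* Cluster ties are broken deterministically: size desc, then peak |Z|
  desc, then lexicographic voxel index.
* Two degenerate equal groups in the summary t-test return t = 0, p = 1
  rather than an error.
* All randomness flows from a single master seed: ICASSO run i uses
  `seed + i`; Infomax restarts reseed deterministically; generated data
  are bit-reproducible across runs on the same platform.

## Known limitations

* The MDL effective-sample correction (voxel decimation) is a heuristic;
  heavily smoothed data may still bias the selected order upward.
* Plain (non-extended) Infomax assumes super-Gaussian sources; sub-
  Gaussian structure would require the extended variant, which is not
  implemented.
* Anatomical labelling of clusters is supported only through a
  user-supplied integer label volume + lookup table; no atlas is bundled.
* Voxel-wise mass-univariate testing, permutation cluster inference and
  TFCE are out of scope.
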