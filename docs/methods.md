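# Methods

This note documents the models, the synthetic cohort generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Vertex-wise ridge with GCV

Each cortical vertex `j` gets its own ridge problem: design `Z_j`
(`n_train × f`, the subjects' feature values at that grayordinate,
standardized per column by training mean/SD), target `y_j` centred by
its training mean (the intercept). The penalty is selected per vertex
by generalized cross-validation,

    GCV(λ) = n · ‖(I − H_λ) y‖² / tr(I − H_λ)²,

evaluated for the whole grid from a single SVD of `Z_j`: with
`Z = U S Vᵀ`, the residual norm decomposes over shrinkage factors
`λ/(s_k²+λ)` plus the component of `y` orthogonal to the column space,
and `tr(I−H_λ) = n − Σ s_k²/(s_k²+λ)`. Fits for all vertices are
batched through numpy's stacked SVD, so a full-cortex fit is one
vectorized pass.

Numerical choices:

* **λ grid** — 30 log-spaced values spanning `[10⁻³, 10⁶]` times the
  design's mean squared singular value. A relative grid keeps the
  search scale-free across feature kinds.
* **Ties** — broken toward the *largest* tied λ. Under a flat GCV
  profile (e.g. an orthonormal design spanning the observation space,
  where GCV is exactly constant) the fit is then maximally
  conservative.
* **λ = 0** — permitted (it is how the OLS variants are expressed);
  singular values below `10⁻¹⁰ · s_max` are treated as zero
  (pseudo-inverse), so rank-deficient designs do not explode.
* **Degenerate targets** (zero training variance) — weights zero,
  λ at the grid maximum, vertex flagged.
* **Zero-variance feature columns** — dropped from the fit (weight 0)
  and recorded through the stored standardization constants.

The parcel-shared variant (`mmp-parcelrr`) selects one λ per region by
minimizing the *sum* of the region's per-vertex GCV scores on a common
absolute grid, then solves each vertex at that shared λ — isolating
exactly the vertex-wise-penalty delta from everything else. The
anatomical baseline is the same vertex-wise ridge over the 6 per-subject
anatomical maps; the group-Z baseline converts the per-vertex
one-sample t (df = n−1) to z by exact tail-probability matching rather
than a square-root approximation.

## Feature extractors

All covariance-based extractors share `G = Aᵀ X Xᵀ` on preprocessed
data (first 5 frames of each run discarded; each grayordinate row
demeaned and scaled to unit variance, zero-variance rows zero-filled
to preserve index alignment). Feature rows are demeaned and scaled to
unit Euclidean norm per subject ("unit norm" is read literally as the
L2 norm, not unit variance).

* **Parcel means** — `A` columns are `1/|region|` indicators, so `Aᵀx`
  is the vector of region means. Averaging (rather than 0/1 sums)
  keeps features on one scale; Pearson scoring is indifferent but the
  GCV ridge is not.
* **Gaussian random projection** — i.i.d. `N(0, 1/f)` entries; norms
  are preserved in expectation, making this the "no anatomical
  knowledge" control for the parcellation.
* **Group ICA** — per-subject PCA in time to the component count,
  concatenation, group PCA, FastICA rotation (log-cosh contrast, max
  500 iterations, seeded; concatenation+PCA stands in for the
  canonical-correlation group stage of the CanICA family, whose
  parameters are not fully specified in the literature we follow).
  Component signs are fixed so each map's peak is positive. The
  task-derived variant estimates components from the other contrasts'
  task series, excluding the to-be-predicted contrast to avoid
  circularity.
* **Dual regression** — group maps → per-frame least squares → subject
  time courses → per-vertex least squares → subject spatial maps.
* **Masked PCR (semi-partial connectome)** — per region: exclude the
  region plus all grayordinates within 10 mm of its cortical vertices
  (great-circle metric on the synthetic sphere, which is the exact
  geodesic there; Dijkstra shortest paths along mesh edges serve as
  the geodesic approximation for real meshes; Euclidean metric for
  subcortex), take the top principal components of the remaining data
  by randomized SVD (7 power iterations, oversampling 10, seeded; 512
  components at full scale, capped by the data rank at desk scale),
  regress the region's mean series on the component time courses, and
  back-project the coefficients through the loadings. Excluded
  grayordinates are exactly zero. The region's own vertices are
  excluded as well: regressing a mean onto its own members is
  degenerate.
* **Activity flow** — a single feature: the FC-weighted flow of the
  training-set mean activation template. Unfitted (`af`) it is scored
  as-is (scale-free under Pearson r, strongly negative in R² by
  construction); `af-mod` adds the two-parameter per-vertex OLS fit.

## The synthetic cohort

The generator plants exactly the structure the method needs to be
tested for, with known per-vertex ceilings.

* **Geometry** — cortical vertices on an 80 mm Fibonacci sphere (the
  great-circle metric is then exact), subcortical voxels in a 20 mm
  ball; parcellations by seeded nearest-centroid assignment, cortex
  and subcortex separately.
* **Latent structure** — `L = 8` group networks, smooth Gaussian
  fields (15 mm correlation length, unit per-vertex SD). Subject
  deviations are smooth fields with per-vertex SD
  `subject_dev_sd = 0.5` at a deliberately **finer** scale (4 mm):
  individual functional topography varies on finer scales than the
  group networks themselves. This choice is also what makes the
  planted signal recoverable from parcel-level covariance features —
  with equally smooth deviations, the nuisance term (parcel-mean
  deviation × vertex group map) has structurally the same magnitude
  as the informative term (parcel-mean group map × vertex deviation)
  and recovery collapses.
* **Rest series** — `X_i = M_iᵀ T_i + E_i` with AR(1) time courses
  (coefficient 0.5, a plausible BOLD autocorrelation; only spatial
  covariance matters downstream), unit-SD white noise, 2 runs × 200
  frames.
* **Task maps** — group component (amplitude 1, giving baseline
  correlations near the 0.55–0.65 seen in real cohorts) plus a
  subject component split into a rest-*shared* part and a rotated part
  invisible to rest data. The split is governed by the subject's
  alignment `a_i ~ U(0.5, 1)`: shared ∝ `a_i`, rotated ∝
  `√(1−a_i²)`, keeping total subject variance independent of `a_i`.
  Amplitudes are normalized so the shared part has SD `s_j·σ` and
  everything else (rotation residual + white noise) has SD `σ = 1`,
  making the oracle ceiling exactly `R²_j = s_j²/(s_j²+1)`. The
  default SNR profile is 1.0 on the "association" hemisphere and 0.1
  on the "sensory" hemisphere. Feasibility requires
  `s ≤ √(E[a²]/E[1−a²])` (≈1.18 at the default alignment range);
  infeasible profiles are rejected.
* **Behaviour** — `coupling · standardize(a) + √(1−coupling²) · noise`
  per task, default coupling 0.6. Because only the *fitted* model's
  scores depend on `a_i` (the baseline sees total variance only), the
  behavioural benchmark has a genuinely model-specific signal to
  detect.
* **Anatomical maps** — six smooth fields correlated 0.3 with the SNR
  profile plus subject-specific smooth noise: a non-trivial but
  uninformative-about-deviations baseline.

What the generator does **not** emulate: biophysical BOLD dynamics,
head motion and physiological artifacts, surface folding, distance-
dependent noise correlations, multi-session variability. Passing
tests therefore show the machinery is correct and the claims hold
under the planted model — not that any particular real cohort has
recoverable structure.

## Problem sizes

Desk-scale defaults (600 grayordinates / 500 cortical, t = 400, K = 20
parcels, 8 latents, 60–120 subjects) were chosen so a complete
benchmark runs in seconds and the full acceptance suite in a couple of
minutes while every planted property remains measurable. Comparative
experiments use 60 training subjects: per-vertex GCV needs roughly
that many observations before its selection noise stops masking the
benefit of vertex-level penalties (at 30 training subjects the
parcel-pooled selection is actually the more stable of the two — a
real small-sample effect, not an implementation artifact).

## Known limitations

* With 20 covariance features over 8 latent dimensions and 60 training
  subjects, the fitted model recovers roughly a third to a half of the
  planted predictable variance on high-SNR vertices — estimation loss
  (≈ f_eff/n), the alignment rotation, feature sampling noise, and the
  residual nuisance term each take a bite. An oracle design regressing
  directly on the true latent deviations tops out near a 0.10 gap to
  the ceiling at this n. Cross-checked against scikit-learn's
  `RidgeCV`: the loss is in the information content of the features,
  not the fitting path.
* The group-mean baseline's learning curve is flat only after its mean
  map has converged (≳30 subjects here); below that it climbs like any
  estimated predictor.
* GCV can under-penalize near the interpolation threshold `n ≈ f`;
  learning-curve evaluations sample training sizes away from that
  regime.
* The full-cortex vertex-wise *partial*-covariance model is out of
  scope, as is TFCE-corrected inference and any suprathreshold-overlap
  (Dice/Jaccard) scoring; intra- vs inter-subject identification is
  deliberately not offered as an evaluation metric.
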