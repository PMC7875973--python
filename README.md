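# restpred

Predicting individual task-fMRI activation maps from resting-state
functional connectivity — with baselines that keep the predictions
honest.

## The problem

Resting-state fMRI and task fMRI are measured from the same brain, and
much of the inter-subject variability seen in task activation maps is
already present in spontaneous activity. A long line of
"connectome-fingerprinting" work therefore fits models that map
resting-state functional-connectivity (FC) features to individual task
contrast maps. The catch: the *group mean* of training subjects' maps
is a deceptively strong predictor of any test subject's map, and many
published encodings never beat it over the whole cortex. `restpred`
implements the modeling strategy that does — vertex-wise regularized
regression — together with the full battery of feature extractors,
baselines, and evaluation/significance machinery needed to demonstrate
(or refute) an advantage, exercisable end-to-end on a synthetic
grayordinate cohort with planted ground truth.

## The model

Data live on "grayordinates": a single spatial axis of `v` entries
mixing cortical surface vertices with subcortical voxels (CIFTI-2
convention). For each subject `i`, a preprocessed rest matrix
`X_i ∈ R^{v×t}` is reduced to a *semi-dense connectome*

```
G_i = Aᵀ X_i X_iᵀ        (f × v)
```

where the projection `A ∈ R^{v×f}` comes from a parcellation (region
means), a Gaussian random projection, group ICA, or an activation
template; variants replace the plain covariance with dual-regression
subject maps or geodesically masked principal-component-regression
semi-partial covariances.

The predictor is fit **independently at every cortical vertex** `j`:

```
ŵ_j = argmin_w ‖y_j − G_j w‖² + λ_j ‖w‖²
```

with `y_j` the training subjects' activation values at vertex `j`,
`G_j` the `n×f` matrix of their features there, and — the crucial
part — a *per-vertex* penalty `λ_j` chosen by generalized
cross-validation (GCV), evaluated for a whole λ grid from one SVD of
the design. Evaluation uses per-subject whole-cortex Pearson `r` and
the per-vertex predictive

```
R²_j = 1 − ‖y_j − ŷ_j‖² / ‖y_j − ȳ_j‖²
```

with `ȳ_j` the **test**-cohort mean (negative values = the model loses
to a mean predictor), summarized over cortex by test-variance
weighting. Model-vs-baseline comparisons use one-sided paired
sign-flip permutation tests (Bonferroni across contrasts) and, over
repeated train/test splits, the corrected resampled t-test with
variance inflation `1/k + n_test/n_train`.

## Worked example

`examples/03_jump_the_baseline.py` simulates a 60-subject cohort with
planted subject-specific structure, fits on 30 subjects, and scores
the other 30:

```
group-mean   mean r = 0.682   weighted R^2 = -0.073
group-zstat  mean r = 0.654   weighted R^2 = -6.024
mmp-rr       mean r = 0.709   weighted R^2 = -0.014
mmp-ols      mean r = 0.479   weighted R^2 = -1.766

vertex-wise ridge vs group mean: paired t = 8.17, permutation p = 0.0002
```

Read this as: every prediction *looks* impressive in raw correlation
(even the unfitted baselines score r ≈ 0.65 because group structure
dominates any individual map), but only the vertex-wise ridge
(`mmp-rr`) is significantly above the group-mean bar; the same
features fit by unregularized OLS (`mmp-ols`) fall far below it, and
the group Z-statistic baseline underperforms the plain mean. The other
examples cover cohort simulation (`01`), feature extraction (`02`),
spatial R²/λ maps (`04` — penalty strength anticorrelates with
predictability), behavioural correlations of prediction scores (`05`),
and learning curves over 3–50 training subjects (`06`).

A thin CLI wraps the same library calls:

```sh
restpred simulate --seed 1 --subjects 60 --out cohort.h5
restpred evaluate --cohort cohort.h5 --models group-mean,mmp-rr --out scores.tsv
restpred benchmark --config bench.yaml --out artifacts/
```

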