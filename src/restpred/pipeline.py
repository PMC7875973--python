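"""End-to-end orchestration: cohort -> features -> fit -> predictions.

The model registry maps benchmark model names to (feature extractor,
fitting method) pairs:

==============  =====================  =======================
name            features               fitting
==============  =====================  =======================
mmp-rr          parcel means           vertex-wise GCV ridge
mmp-ols         parcel means           vertex-wise OLS
mmp-parcelrr    parcel means           parcel-shared-lambda ridge
mmp-rr-dr       dual regression        vertex-wise GCV ridge
mmp-rr-pcr      masked PCR             vertex-wise GCV ridge
grp-rr          random projection      vertex-wise GCV ridge
gica-rest-rr    group ICA (rest)       vertex-wise GCV ridge
gica-task-rr    group ICA (task)       vertex-wise GCV ridge
af              activation template    none (raw feature row)
af-mod          activation template    two-parameter OLS
anat-rr         anatomical maps        vertex-wise GCV ridge
group-mean      --                     training mean map
group-zstat     --                     one-sample t -> z map
==============  =====================  =======================

Feature extraction that does not depend on the train/test split
(parcel means, random projections, PCR, dual regression against the
fixed parcellation, anatomical maps) is cached per cohort so repeated
splits — learning curves, behavioural benchmarks — pay for it once.
Train-dependent extractors (group ICA, activity-flow templates) are
cached per training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ActivationMap, CohortSplit, RestScan, UsageError, preprocess_rest
from .distances import cortical_distance_matrix
from .evaluation import R2Map, pearson_score, predictive_r2, weighted_mean_r2
from .features import (
    Connectome,
    activity_flow_features,
    dual_regression_features,
    gaussian_random_projection,
    group_ica,
    normalize_features,
    parcel_projection,
    pcr_semipartial_connectome,
    semi_dense_connectome,
)
from .models import (
    BaselineModel,
    fit_anatomical_rr,
    fit_parcel_rr,
    fit_vertexwise,
    group_mean,
    group_zstat,
    predict,
)
from .synthetic import Cohort

__all__ = [
    "MODEL_REGISTRY",
    "PipelineCache",
    "make_split",
    "fit_and_predict",
    "evaluate_models",
    "EvaluationResult",
    "learning_curve",
]

MODEL_REGISTRY: dict[str, dict] = {
    "mmp-rr": {"features": "mmp", "fit": "rr"},
    "mmp-ols": {"features": "mmp", "fit": "ols"},
    "mmp-parcelrr": {"features": "mmp", "fit": "parcel_rr"},
    "mmp-rr-dr": {"features": "mmp-dr", "fit": "rr"},
    "mmp-rr-pcr": {"features": "mmp-pcr", "fit": "rr"},
    "grp-rr": {"features": "grp", "fit": "rr"},
    "gica-rest-rr": {"features": "gica-rest", "fit": "rr"},
    "gica-task-rr": {"features": "gica-task", "fit": "rr"},
    "af": {"features": "af", "fit": None},
    "af-mod": {"features": "af", "fit": "af_mod"},
    "anat-rr": {"features": "anat", "fit": "rr"},
    "group-mean": {"features": None, "fit": "baseline"},
    "group-zstat": {"features": None, "fit": "baseline"},
}


def make_split(
    subject_ids: list[str], n_train: int, n_test: int, seed: int = 0
) -> CohortSplit:
    """Seeded random disjoint train/test split of a subject pool."""
    if n_train + n_test > len(subject_ids):
        raise UsageError("split sizes exceed the subject pool")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subject_ids))
    ids = [subject_ids[i] for i in order]
    return CohortSplit(train_ids=ids[:n_train], test_ids=ids[n_train : n_train + n_test], seed=seed)


class PipelineCache:
    """Per-cohort cache of preprocessed scans, distances and features."""

    def __init__(self, cohort: Cohort, gica_components: int | None = None):
        self.cohort = cohort
        #: group-ICA dimensionality; defaults to the smaller of 80 and
        #: what the desk-scale scans can support
        self.gica_components = gica_components
        self._scans: dict[str, RestScan] = {}
        self._task_scans: dict[tuple[str, str], RestScan] = {}
        self._dist: np.ndarray | None = None
        self._features: dict[tuple, dict[str, Connectome]] = {}

    def scan(self, subject_id: str) -> RestScan:
        if subject_id not in self._scans:
            self._scans[subject_id] = preprocess_rest(self.cohort.rest_scans[subject_id])
        return self._scans[subject_id]

    def task_scan(self, contrast: str, subject_id: str) -> RestScan:
        key = (contrast, subject_id)
        if key not in self._task_scans:
            self._task_scans[key] = preprocess_rest(
                self.cohort.task_series[contrast][subject_id], n_discard=0
            )
        return self._task_scans[key]

    def distances(self) -> np.ndarray:
        if self._dist is None:
            self._dist = cortical_distance_matrix(self.cohort.geometry)
        return self._dist

    def features(
        self, method: str, contrast: str | None, train_ids: tuple[str, ...], seed: int
    ) -> dict[str, Connectome]:
        """Normalized connectomes for every cohort subject."""
        split_free = method in ("mmp", "grp", "mmp-dr", "mmp-pcr")
        key = (method,) if split_free else (method, contrast, train_ids, seed)
        if key not in self._features:
            self._features[key] = self._extract(method, contrast, train_ids, seed)
        return self._features[key]

    # ------------------------------------------------------------------
    def _extract(
        self, method: str, contrast: str | None, train_ids: tuple[str, ...], seed: int
    ) -> dict[str, Connectome]:
        cohort = self.cohort
        ids = cohort.subject_ids
        K = cohort.parcellation.K

        if method == "mmp":
            A = parcel_projection(cohort.parcellation)
            raw = {s: semi_dense_connectome(self.scan(s), A) for s in ids}
        elif method == "grp":
            A = gaussian_random_projection(cohort.geometry.n_total, f=K, seed=seed)
            raw = {s: semi_dense_connectome(self.scan(s), A) for s in ids}
        elif method == "mmp-dr":
            # group maps = parcel indicator maps of the fixed parcellation
            A = parcel_projection(cohort.parcellation)
            raw = {s: dual_regression_features(self.scan(s), A) for s in ids}
        elif method == "mmp-pcr":
            dist = self.distances()
            # 512 components at full scale; capped by the scan length at
            # desk scale, where the data rank is the limit anyway
            n_pcs = min(512, self.scan(ids[0]).t)
            raw = {
                s: pcr_semipartial_connectome(
                    self.scan(s),
                    cohort.parcellation,
                    cohort.geometry,
                    n_pcs=n_pcs,
                    seed=seed,
                    cortical_distances=dist,
                )
                for s in ids
            }
        elif method == "gica-rest":
            n_comp = self._gica_components()
            A = group_ica([self.scan(s) for s in train_ids], n_components=n_comp, seed=seed)
            raw = {s: semi_dense_connectome(self.scan(s), A) for s in ids}
        elif method == "gica-task":
            if not cohort.task_series:
                raise UsageError(
                    "cohort has no task series; simulate with task_series_frames > 0"
                )
            others = [c for c in cohort.task_series if c != contrast]
            if not others:
                raise UsageError("gica-task needs task series from other contrasts")
            # concatenate the other contrasts' task runs per training subject,
            # leaving out the to-be-predicted contrast to avoid circularity
            scans = []
            for s in train_ids:
                data = np.concatenate(
                    [self.task_scan(c, s).data for c in others], axis=1
                )
                t_runs = [self.task_scan(c, s).t for c in others]
                scans.append(
                    RestScan(
                        subject_id=s, data=data, run_boundaries=t_runs, preprocessed=True
                    )
                )
            n_comp = min(self._gica_components(), min(sc.t for sc in scans))
            A = group_ica(scans, n_components=n_comp, seed=seed)
            raw = {s: semi_dense_connectome(self.scan(s), A) for s in ids}
        elif method == "af":
            template = np.mean(
                [cohort.task_maps[contrast][s].values for s in train_ids], axis=0
            )
            raw = {
                s: activity_flow_features(self.scan(s), template, cohort.geometry)
                for s in ids
            }
        else:
            raise UsageError(f"unknown feature method: {method}")
        return {s: normalize_features(c) for s, c in raw.items()}

    def _gica_components(self) -> int:
        if self.gica_components is not None:
            return self.gica_components
        t_min = min(self.scan(s).t for s in self.cohort.subject_ids)
        return min(80, t_min // 4)


@dataclass
class EvaluationResult:
    """Everything a benchmark needs about one (model, contrast) cell."""

    model: str
    contrast: str
    scores: dict[str, float]  # test subject -> Pearson r
    r2map: R2Map
    weighted_r2: float
    lambdas: np.ndarray | None = None

    @property
    def mean_r(self) -> float:
        vals = [v for v in self.scores.values() if np.isfinite(v)]
        return float(np.mean(vals))


def fit_and_predict(
    cohort: Cohort,
    model_name: str,
    contrast: str,
    split: CohortSplit,
    seed: int = 0,
    cache: PipelineCache | None = None,
) -> tuple[np.ndarray, dict]:
    """Fit one registry model and predict all test subjects.

    Returns ``(preds, info)`` with ``preds`` of shape
    ``(n_test, n_cortex)`` (rows follow ``split.test_ids``) and
    ``info`` carrying the fitted object and, for ridge models, the
    per-vertex penalties.
    """
    if model_name not in MODEL_REGISTRY:
        raise UsageError(
            f"unknown model '{model_name}'; known: {sorted(MODEL_REGISTRY)}"
        )
    spec = MODEL_REGISTRY[model_name]
    cache = cache or PipelineCache(cohort)
    train_maps = [cohort.task_maps[contrast][s] for s in split.train_ids]
    info: dict = {"model_name": model_name}

    if spec["fit"] == "baseline":
        model = group_mean(train_maps) if model_name == "group-mean" else group_zstat(train_maps)
        preds = np.tile(predict(model), (split.n_test, 1))
        info["model"] = model
        return preds, info

    if spec["features"] == "anat":
        anat_train = [cohort.anatomical[s] for s in split.train_ids]
        model = fit_anatomical_rr(anat_train, train_maps)
        info["model"] = model
        info["lambdas"] = model.lambdas
        preds = np.empty((split.n_test, cohort.geometry.n_cortex))
        for i, s in enumerate(split.test_ids):
            conn = Connectome(
                subject_id=s,
                G=cohort.anatomical[s],
                feature_kind="anatomical",
                normalized=True,
            )
            preds[i] = predict(model, conn, cortex_index=np.arange(cohort.geometry.n_cortex))
        return preds, info

    feats = cache.features(spec["features"], contrast, tuple(split.train_ids), seed)
    ctx = cohort.geometry.cortex_index

    if spec["fit"] is None:  # unfitted activity flow
        preds = np.stack([feats[s].G[0, ctx] for s in split.test_ids])
        info["model"] = None
        return preds, info

    train_conn = [feats[s] for s in split.train_ids]
    if spec["fit"] == "parcel_rr":
        model = fit_parcel_rr(train_conn, train_maps, cohort.parcellation, cortex_index=ctx)
    else:
        model = fit_vertexwise(train_conn, train_maps, method=spec["fit"], cortex_index=ctx)
    info["model"] = model
    info["lambdas"] = model.lambdas
    preds = np.stack(
        [predict(model, feats[s], cortex_index=ctx) for s in split.test_ids]
    )
    return preds, info


def evaluate_models(
    cohort: Cohort,
    model_names: list[str],
    contrast: str,
    split: CohortSplit,
    seed: int = 0,
    cache: PipelineCache | None = None,
) -> dict[str, EvaluationResult]:
    """Fit and score several models on one contrast and one split."""
    cache = cache or PipelineCache(cohort)
    truths = cohort.task_matrix(contrast, split.test_ids)
    results = {}
    for name in model_names:
        preds, info = fit_and_predict(cohort, name, contrast, split, seed=seed, cache=cache)
        scores = {
            s: pearson_score(preds[i], truths[i]) for i, s in enumerate(split.test_ids)
        }
        r2map = predictive_r2(preds, truths)
        results[name] = EvaluationResult(
            model=name,
            contrast=contrast,
            scores=scores,
            r2map=r2map,
            weighted_r2=weighted_mean_r2(r2map),
            lambdas=info.get("lambdas"),
        )
    return results


def learning_curve(
    cohort: Cohort,
    model_name: str,
    contrast: str,
    train_sizes: list[int],
    test_ids: list[str],
    seed: int = 0,
    cache: PipelineCache | None = None,
) -> dict[int, tuple[float, float]]:
    """Mean Pearson r and weighted R^2 versus training-set size.

    Training subsets are *nested* (each smaller set is contained in
    every larger one), which removes subset-resampling variance from
    the curve shape; the test set is fixed throughout.
    """
    if min(train_sizes) < 3:
        raise UsageError("training sizes below 3 are not identifiable")
    pool = [s for s in cohort.subject_ids if s not in set(test_ids)]
    if max(train_sizes) > len(pool):
        raise UsageError("largest training size exceeds the available pool")
    rng = np.random.default_rng(seed)
    order = [pool[i] for i in rng.permutation(len(pool))]
    cache = cache or PipelineCache(cohort)
    truths = cohort.task_matrix(contrast, list(test_ids))

    curve: dict[int, tuple[float, float]] = {}
    for size in sorted(train_sizes):
        split = CohortSplit(train_ids=order[:size], test_ids=list(test_ids), seed=seed)
        preds, _ = fit_and_predict(cohort, model_name, contrast, split, seed=seed, cache=cache)
        rs = [pearson_score(preds[i], truths[i]) for i in range(len(test_ids))]
        r2 = weighted_mean_r2(predictive_r2(preds, truths))
        curve[size] = (float(np.nanmean(rs)), r2)
    return curve
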