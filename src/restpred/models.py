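"""Predictors: vertex-wise GCV ridge regression and all baselines.

The central model fits, for every cortical vertex ``j`` independently,

.. math::

   \\hat w_j = \\arg\\min_w \\|y_j - G_j w\\|_2^2 + \\lambda_j \\|w\\|_2^2

where ``y_j`` collects the training subjects' activation values at
vertex ``j`` and ``G_j`` is the ``n x f`` matrix of the subjects'
rest-derived features at that vertex.  Each vertex gets its *own*
penalty ``lambda_j``, selected by generalized cross-validation (GCV)
over the training set:

.. math::

   GCV(\\lambda) = n\\,\\|(I - H_\\lambda) y\\|^2 / \\mathrm{tr}(I - H_\\lambda)^2

with ``H`` the ridge hat matrix.  A single SVD of the design evaluates
the whole ``lambda`` grid; ties are broken toward the largest tied
``lambda`` (more shrinkage under flat GCV profiles).

Also provided: vertex-wise OLS (``lambda = 0``), the parcel-shared-
``lambda`` ridge (one penalty per region — the classical alternative
the vertex-wise selection is measured against), the two-parameter
activity-flow regression, an anatomical-features ridge, and the
unfitted group-mean / group-Z-statistic baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ActivationMap, Parcellation, UsageError
from .features import Connectome

__all__ = [
    "GCVRidgeResult",
    "VertexwiseModel",
    "BaselineModel",
    "default_lambda_grid",
    "gcv_ridge",
    "fit_vertexwise",
    "fit_parcel_rr",
    "fit_anatomical_rr",
    "group_mean",
    "group_zstat",
    "predict",
]

#: relative lambda grid: 30 log-spaced values, scaled per design
DEFAULT_GRID_REL = np.logspace(-3.0, 6.0, 30)

_SV_TOL = 1e-10  # relative singular-value cutoff for lambda = 0 solves
_DEGENERATE_VAR_TOL = 1e-24


def default_lambda_grid(design: np.ndarray) -> np.ndarray:
    """Default grid: ``DEFAULT_GRID_REL`` times the design's mean squared singular value."""
    s = np.linalg.svd(design, compute_uv=False)
    scale = float(np.mean(s**2)) if s.size else 1.0
    return DEFAULT_GRID_REL * max(scale, np.finfo(float).tiny)


@dataclass
class GCVRidgeResult:
    lambda_: float
    weights: np.ndarray
    intercept: float
    gcv_values: np.ndarray
    degenerate: bool = False


def _gcv_from_svd(
    s2: np.ndarray, uty2: np.ndarray, resid_perp: float, n: int, lam: np.ndarray
) -> np.ndarray:
    """GCV(lambda) for a lambda vector, given SVD pieces of one problem."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    shrink = lam[:, None] / (s2[None, :] + lam[:, None])  # (L, k); 0/0 -> handled below
    # lambda = 0 on zero singular values: component is annihilated anyway
    shrink = np.where(s2[None, :] + lam[:, None] == 0.0, 1.0, shrink)
    rss = (shrink**2 * uty2[None, :]).sum(axis=1) + resid_perp
    df_resid = n - (s2[None, :] / np.where(s2[None, :] + lam[:, None] == 0.0, 1.0, s2[None, :] + lam[:, None])).sum(axis=1)
    return n * rss / df_resid**2


def _argmin_prefer_large(values: np.ndarray) -> int:
    """Index of the minimum, preferring the *last* (largest-lambda) tie."""
    vmin = values.min()
    tol = abs(vmin) * 1e-10 + 1e-300
    return int(np.nonzero(values <= vmin + tol)[0][-1])


def gcv_ridge(
    design: np.ndarray,
    target: np.ndarray,
    lambda_grid: np.ndarray | None = None,
) -> GCVRidgeResult:
    """Ridge regression with GCV selection of the penalty.

    The target is centred (the intercept is its training mean); the
    design is used as given — standardize columns beforehand if the
    features live on different scales.  ``lambda = 0`` is permitted in
    the grid and reproduces (pseudo-inverse) OLS.

    An all-constant target is flagged degenerate: weights are zero and
    ``lambda`` is the grid maximum.
    """
    design = np.asarray(design, dtype=float)
    target = np.asarray(target, dtype=float).ravel()
    n = target.size
    if n < 2:
        raise UsageError("need at least 2 observations")
    if design.shape[0] != n:
        raise UsageError("design and target lengths differ")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(design)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float).ravel())
    if lambda_grid.size == 0:
        raise UsageError("lambda grid is empty")
    if np.any(lambda_grid < 0):
        raise UsageError("lambda values must be non-negative")

    intercept = float(target.mean())
    y = target - intercept
    if float(y @ y) <= _DEGENERATE_VAR_TOL * n:
        return GCVRidgeResult(
            lambda_=float(lambda_grid[-1]),
            weights=np.zeros(design.shape[1]),
            intercept=intercept,
            gcv_values=np.zeros(lambda_grid.size),
            degenerate=True,
        )

    u, s, vt = np.linalg.svd(design, full_matrices=False)
    s2 = s**2
    uty = u.T @ y
    resid_perp = float(y @ y - uty @ uty)
    gcv = _gcv_from_svd(s2, uty**2, max(resid_perp, 0.0), n, lambda_grid)
    best = _argmin_prefer_large(gcv)
    lam = float(lambda_grid[best])
    weights = _ridge_weights_from_svd(s, vt, uty, lam)
    return GCVRidgeResult(
        lambda_=lam, weights=weights, intercept=intercept, gcv_values=gcv
    )


def _ridge_weights_from_svd(
    s: np.ndarray, vt: np.ndarray, uty: np.ndarray, lam: float
) -> np.ndarray:
    """w = V diag(s/(s^2+lambda)) U^T y, with a pseudo-inverse at lambda=0."""
    if lam == 0.0:
        smax = s.max(initial=0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(s > _SV_TOL * smax, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    else:
        inv = s / (s**2 + lam)
    return vt.T @ (inv * uty)


@dataclass
class VertexwiseModel:
    """Per-vertex linear predictors sharing one feature space.

    ``weights`` act on *standardized* features; ``feature_means`` and
    ``feature_sds`` hold the training standardization constants applied
    at prediction time (zero-SD columns are frozen at weight 0).
    """

    weights: np.ndarray  # (n_vertex, f)
    intercepts: np.ndarray  # (n_vertex,)
    lambdas: np.ndarray  # (n_vertex,)
    feature_kind: str
    feature_means: np.ndarray  # (n_vertex, f)
    feature_sds: np.ndarray  # (n_vertex, f)
    method: str = "rr"
    degenerate_vertices: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.intp))

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.lambdas))):
            raise UsageError("model weights and lambdas must be finite")
        if np.any(self.lambdas < 0):
            raise UsageError("lambdas must be non-negative")

    @property
    def n_vertex(self) -> int:
        return self.weights.shape[0]

    @property
    def f(self) -> int:
        return self.weights.shape[1]


@dataclass
class BaselineModel:
    """Unfitted (or anatomy-fitted) reference predictors."""

    kind: str  # "group_mean" | "group_zstat"
    map: np.ndarray
    n_degenerate: int = 0


def _stack_designs(connectomes: list[Connectome], cortex_index: np.ndarray) -> np.ndarray:
    """(n_vertex, n_subject, f) design tensor from per-subject connectomes."""
    f = connectomes[0].f
    kind = connectomes[0].feature_kind
    for c in connectomes:
        if c.f != f:
            raise UsageError("connectomes disagree on the number of features f")
        if c.feature_kind != kind:
            raise UsageError("connectomes disagree on feature_kind")
    # G_i is (f, n_total); vertex j's design row for subject i is G_i[:, cortex_index[j]]
    arr = np.stack([c.G[:, cortex_index] for c in connectomes])  # (n, f, V)
    return np.ascontiguousarray(arr.transpose(2, 0, 1))  # (V, n, f)


def _standardize_designs(designs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = designs.mean(axis=1, keepdims=True)
    sds = designs.std(axis=1, keepdims=True)
    zero = sds <= 1e-12
    std = (designs - means) / np.where(zero, 1.0, sds)
    std = np.where(zero, 0.0, std)
    return std, means[:, 0, :], np.where(zero, 0.0, sds)[:, 0, :]


def _fit_designs(
    designs: np.ndarray,
    targets: np.ndarray,
    method: str,
    lambda_grid_rel: np.ndarray | None,
    parcel_groups: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched per-vertex ridge/OLS fits.

    Parameters
    ----------
    designs : (V, n, f) raw design tensor.
    targets : (n, V) activation values.
    method : "rr" (per-vertex GCV), "ols" (lambda = 0) or
        "parcel_rr" (one GCV-selected lambda per group of vertices,
        minimizing the *sum* of the group's per-vertex GCV scores).
    lambda_grid_rel : relative grid (scaled by each design's mean
        squared singular value); defaults to the module grid.
    parcel_groups : vertex-index arrays, required for "parcel_rr".
    """
    V, n, f = designs.shape
    if targets.shape != (n, V):
        raise UsageError("targets must have shape (n_subjects, n_vertex)")
    grid_rel = DEFAULT_GRID_REL if lambda_grid_rel is None else np.sort(np.asarray(lambda_grid_rel, float))

    std, means, sds = _standardize_designs(designs)
    intercepts = targets.mean(axis=0)
    y = targets - intercepts[None, :]
    yvar = (y**2).sum(axis=0)
    degenerate = yvar <= _DEGENERATE_VAR_TOL * n

    u, s, vt = np.linalg.svd(std, full_matrices=False)  # (V,n,k) (V,k) (V,k,f)
    s2 = s**2
    uty = np.einsum("vnk,nv->vk", u, y)
    resid_perp = np.clip(yvar - (uty**2).sum(axis=1), 0.0, None)

    k = s2.shape[1]
    if method == "ols":
        lambdas = np.zeros(V)
    elif method in ("rr", "af_mod"):
        scale = np.maximum(s2.mean(axis=1), np.finfo(float).tiny)  # (V,)
        if method == "af_mod":
            lambdas = np.zeros(V)
        else:
            grids = grid_rel[None, :] * scale[:, None]  # (V, L)
            gcv = _batched_gcv(s2, uty**2, resid_perp, n, grids)
            idx = _batched_argmin_prefer_large(gcv)
            lambdas = grids[np.arange(V), idx]
    elif method == "parcel_rr":
        if parcel_groups is None:
            raise UsageError("parcel_rr requires parcel_groups")
        lambdas = np.zeros(V)
        for members in parcel_groups:
            scale = np.maximum(s2[members].mean(), np.finfo(float).tiny)
            grid = grid_rel * scale
            gcv = _batched_gcv(s2[members], uty[members] ** 2, resid_perp[members], n, np.broadcast_to(grid, (members.size, grid.size)))
            total = gcv.sum(axis=0)
            lambdas[members] = grid[_argmin_prefer_large(total)]
    else:
        raise UsageError(f"unknown fitting method: {method}")

    lambdas = np.where(degenerate, (grid_rel[-1] * np.maximum(s2.mean(axis=1), np.finfo(float).tiny)), lambdas)
    smax = s.max(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(
            lambdas[:, None] > 0.0,
            s / (s2 + lambdas[:, None]),
            np.where(s > _SV_TOL * np.maximum(smax, np.finfo(float).tiny), 1.0 / np.where(s > 0, s, 1.0), 0.0),
        )
    weights = np.einsum("vkf,vk->vf", vt, inv * uty)
    weights[degenerate] = 0.0
    return weights, intercepts, lambdas, means, sds, np.nonzero(degenerate)[0]


def _batched_gcv(
    s2: np.ndarray, uty2: np.ndarray, resid_perp: np.ndarray, n: int, grids: np.ndarray
) -> np.ndarray:
    """GCV surface (V, L) from batched SVD pieces; grids is (V, L)."""
    lam = grids[:, :, None]  # (V, L, 1)
    denom = s2[:, None, :] + lam
    denom = np.where(denom == 0.0, 1.0, denom)
    shrink = lam / denom
    rss = (shrink**2 * uty2[:, None, :]).sum(axis=2) + resid_perp[:, None]
    df = n - (s2[:, None, :] / denom).sum(axis=2)
    return n * rss / df**2


def _batched_argmin_prefer_large(gcv: np.ndarray) -> np.ndarray:
    vmin = gcv.min(axis=1, keepdims=True)
    ok = gcv <= vmin + np.abs(vmin) * 1e-10 + 1e-300
    L = gcv.shape[1]
    return (ok * np.arange(L)[None, :]).max(axis=1)


def _maps_matrix(maps: list[ActivationMap]) -> np.ndarray:
    arr = np.array([m.values for m in maps])
    return arr


def fit_vertexwise(
    connectomes: list[Connectome],
    maps: list[ActivationMap],
    method: str = "rr",
    lambda_grid_rel: np.ndarray | None = None,
    cortex_index: np.ndarray | None = None,
) -> VertexwiseModel:
    """Fit one independent linear model per cortical vertex.

    ``connectomes`` and ``maps`` are aligned lists over training
    subjects.  ``method`` is ``"rr"`` (ridge with per-vertex GCV),
    ``"ols"`` (no penalty) or ``"af_mod"`` (single-feature
    slope+intercept OLS).  Feature columns are standardized per vertex
    by training mean/SD (stored on the model); zero-variance columns
    are dropped from the fit with weight 0.
    """
    if len(connectomes) < 3:
        raise UsageError("need at least 3 training subjects")
    if len(connectomes) != len(maps):
        raise UsageError("connectomes and maps must align")
    n_cortex = maps[0].values.size
    if cortex_index is None:
        cortex_index = np.arange(n_cortex)
    if method == "af_mod" and connectomes[0].f != 1:
        raise UsageError("af_mod requires single-feature connectomes (f = 1)")
    designs = _stack_designs(connectomes, np.asarray(cortex_index, dtype=np.intp))
    targets = _maps_matrix(maps)  # (n_subjects, V)
    weights, intercepts, lambdas, means, sds, degen = _fit_designs(
        designs, targets, method, lambda_grid_rel
    )
    return VertexwiseModel(
        weights=weights,
        intercepts=intercepts,
        lambdas=lambdas,
        feature_kind=connectomes[0].feature_kind,
        feature_means=means,
        feature_sds=sds,
        method=method,
        degenerate_vertices=degen,
    )


def fit_parcel_rr(
    connectomes: list[Connectome],
    maps: list[ActivationMap],
    parcellation: Parcellation,
    lambda_grid_rel: np.ndarray | None = None,
    cortex_index: np.ndarray | None = None,
) -> VertexwiseModel:
    """Ridge with one shared GCV-selected ``lambda`` per parcel.

    The shared penalty minimizes the sum of the parcel's per-vertex
    GCV scores; weights are then solved per vertex at that ``lambda``.
    This isolates exactly the delta between classical parcel-level
    penalty tuning and the vertex-wise selection.
    """
    if len(connectomes) < 3:
        raise UsageError("need at least 3 training subjects")
    n_cortex = maps[0].values.size
    if cortex_index is None:
        cortex_index = np.arange(n_cortex)
    cortex_index = np.asarray(cortex_index, dtype=np.intp)
    ctx_labels = parcellation.labels[cortex_index]
    groups = [np.nonzero(ctx_labels == k)[0] for k in range(1, parcellation.K + 1)]
    groups = [g for g in groups if g.size]
    designs = _stack_designs(connectomes, cortex_index)
    targets = _maps_matrix(maps)
    weights, intercepts, lambdas, means, sds, degen = _fit_designs(
        designs, targets, "parcel_rr", lambda_grid_rel, parcel_groups=groups
    )
    return VertexwiseModel(
        weights=weights,
        intercepts=intercepts,
        lambdas=lambdas,
        feature_kind=connectomes[0].feature_kind,
        feature_means=means,
        feature_sds=sds,
        method="parcel_rr",
        degenerate_vertices=degen,
    )


def fit_anatomical_rr(
    anatomical: list[np.ndarray],
    maps: list[ActivationMap],
    lambda_grid_rel: np.ndarray | None = None,
) -> VertexwiseModel:
    """Vertex-wise ridge on per-subject anatomical feature maps.

    ``anatomical[i]`` is the subject's ``(6, n_cortex)`` stack of
    anatomical maps; the design at vertex ``j`` is the subjects'
    6-vector of anatomical values there.
    """
    if len(anatomical) != len(maps):
        raise UsageError("anatomical maps and targets must align")
    arr = np.stack([np.asarray(a, dtype=float) for a in anatomical])  # (n, 6, V)
    if arr.shape[1] != 6:
        raise UsageError(f"expected 6 anatomical features, got {arr.shape[1]}")
    designs = np.ascontiguousarray(arr.transpose(2, 0, 1))  # (V, n, 6)
    targets = _maps_matrix(maps)
    weights, intercepts, lambdas, means, sds, degen = _fit_designs(
        designs, targets, "rr", lambda_grid_rel
    )
    return VertexwiseModel(
        weights=weights,
        intercepts=intercepts,
        lambdas=lambdas,
        feature_kind="anatomical",
        feature_means=means,
        feature_sds=sds,
        method="rr",
        degenerate_vertices=degen,
    )


def group_mean(train_maps: list[ActivationMap]) -> BaselineModel:
    """The bar every fitted model must jump over: the training mean map."""
    if len(train_maps) < 1:
        raise UsageError("need at least one training map")
    return BaselineModel(kind="group_mean", map=_maps_matrix(train_maps).mean(axis=0))


def group_zstat(train_maps: list[ActivationMap]) -> BaselineModel:
    """Per-vertex one-sample t statistic of the training maps, mapped to z.

    The t value (df = n - 1) is converted to a standard-normal quantile
    by matching upper-tail probabilities exactly (no sqrt
    approximation).  Degenerate vertices (zero SD, hence infinite t)
    are set to 0 and counted.
    """
    if len(train_maps) < 2:
        raise UsageError("need at least 2 training maps")
    arr = _maps_matrix(train_maps)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    ok = sd > 1e-12
    t = np.zeros_like(mean)
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    # exact tail matching; norm.isf(t.sf(.)) is stable in both tails
    z = np.zeros_like(t)
    z[ok] = stats.norm.isf(stats.t.sf(t[ok], df=n - 1))
    bad = ~np.isfinite(z)
    z[bad] = 0.0
    return BaselineModel(kind="group_zstat", map=z, n_degenerate=int((~ok).sum() + bad.sum()))


def predict(
    model: VertexwiseModel | BaselineModel,
    connectome: Connectome | None = None,
    cortex_index: np.ndarray | None = None,
) -> np.ndarray:
    """Predict one subject's cortical activation map.

    Baselines ignore the connectome.  For vertex-wise models the
    subject's features are standardized with the stored training
    constants before the per-vertex linear maps are applied.
    """
    if isinstance(model, BaselineModel):
        return model.map.copy()
    if connectome is None:
        raise UsageError("a connectome is required for fitted models")
    if connectome.feature_kind != model.feature_kind:
        raise UsageError(
            f"feature_kind mismatch: model was trained on '{model.feature_kind}', "
            f"got '{connectome.feature_kind}'"
        )
    V = model.n_vertex
    if cortex_index is None:
        cortex_index = np.arange(V)
    g = connectome.G[:, np.asarray(cortex_index, dtype=np.intp)].T  # (V, f)
    zero = model.feature_sds <= 0.0
    g_std = (g - model.feature_means) / np.where(zero, 1.0, model.feature_sds)
    g_std = np.where(zero, 0.0, g_std)
    return (g_std * model.weights).sum(axis=1) + model.intercepts
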