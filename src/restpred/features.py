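"""Resting-state feature extraction: semi-dense connectomes.

Every extractor maps a preprocessed rest scan ``X`` (grayordinate x
time) to a feature matrix ``G = A^T X X^T`` of shape ``(f, n_total)``
— the covariance between ``f`` projected time series and every
grayordinate's time series, known as a *semi-dense connectome*.  The
extractors differ only in how the projection ``A`` (``n_total x f``)
is built:

* ``parcel_projection`` — region means of a parcellation;
* ``gaussian_random_projection`` — i.i.d. N(0, 1/f) entries;
* ``group_ica`` — group-level independent spatial components estimated
  from a training set of scans;
* an activation template (activity flow) — a single feature row.

Two further extractors depart from the plain covariance form:
``dual_regression_features`` (two-stage least squares from group maps
to subject-specific spatial maps) and ``pcr_semipartial_connectome``
(principal-component regression per region with geodesic masking of
the region's spatial neighbourhood, yielding semi-partial rather than
marginal covariances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.extmath import randomized_svd

from .core import Geometry, Parcellation, RestScan, UsageError
from .distances import cortical_distance_matrix, exclusion_mask

__all__ = [
    "ProjectionMatrix",
    "Connectome",
    "parcel_projection",
    "gaussian_random_projection",
    "semi_dense_connectome",
    "normalize_features",
    "group_ica",
    "dual_regression_features",
    "pcr_semipartial_connectome",
    "activity_flow_features",
]


@dataclass
class ProjectionMatrix:
    """A projection ``A`` (``n_total x f``) with its provenance."""

    A: np.ndarray
    kind: str
    seed: int | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[1] < 1:
            raise UsageError("projection must be 2-D with f >= 1")
        col_norm = np.linalg.norm(self.A, axis=0)
        if np.any(col_norm == 0):
            raise UsageError("projection has an all-zero column")

    @property
    def f(self) -> int:
        return self.A.shape[1]


@dataclass
class Connectome:
    """One subject's feature-by-grayordinate matrix ``G``."""

    subject_id: str
    G: np.ndarray
    feature_kind: str
    normalized: bool = False
    degenerate_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise UsageError("Connectome.G must be 2-D (feature x grayordinate)")
        if not np.all(np.isfinite(self.G)):
            raise UsageError("Connectome.G must be finite")

    @property
    def f(self) -> int:
        return self.G.shape[0]


def parcel_projection(parcellation: Parcellation) -> ProjectionMatrix:
    """Averaging projection: column ``k`` is ``1/|region k|`` on region k.

    ``A^T x`` is then the vector of region means of ``x``; unlabeled
    grayordinates (label 0) contribute to no feature.
    """
    labels = parcellation.labels
    n, K = labels.size, parcellation.K
    A = np.zeros((n, K))
    for k in range(1, K + 1):
        idx = np.nonzero(labels == k)[0]
        if idx.size == 0:
            raise UsageError(f"region {k} is empty")
        A[idx, k - 1] = 1.0 / idx.size
    return ProjectionMatrix(A=A, kind="parcel_mean")


def gaussian_random_projection(n_total: int, f: int, seed: int = 0) -> ProjectionMatrix:
    """Random projection with i.i.d. N(0, 1/f) entries.

    With f large enough the projection approximately preserves norms
    and pairwise distances (Johnson-Lindenstrauss), which is why it is
    a serious competitor to anatomically informed parcellations.
    """
    if f < 1:
        raise UsageError("f must be >= 1")
    rng = np.random.default_rng(seed)
    A = rng.normal(0.0, 1.0 / np.sqrt(f), size=(n_total, f))
    return ProjectionMatrix(A=A, kind="gaussian_random", seed=seed)


def _require_preprocessed(scan: RestScan) -> None:
    if not scan.preprocessed:
        raise UsageError(
            "scan must be preprocessed before feature extraction "
            "(run preprocess_rest first)"
        )


def semi_dense_connectome(scan: RestScan, A: ProjectionMatrix) -> Connectome:
    """Compute ``G = A^T X X^T`` for one preprocessed scan."""
    _require_preprocessed(scan)
    if A.A.shape[0] != scan.n_total:
        raise UsageError(
            f"projection rows ({A.A.shape[0]}) do not match grayordinates ({scan.n_total})"
        )
    projected = A.A.T @ scan.data  # (f, t)
    return Connectome(
        subject_id=scan.subject_id,
        G=projected @ scan.data.T,
        feature_kind=A.kind,
        normalized=False,
    )


def normalize_features(connectome: Connectome) -> Connectome:
    """Demean each feature row and scale it to unit Euclidean norm.

    Degenerate rows (zero norm after demeaning) are zeroed and listed
    in ``degenerate_rows``.  Idempotent.
    """
    G = connectome.G
    centered = G - G.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms <= 1e-12 * max(1.0, float(np.abs(G).max(initial=0.0)))
    out = centered / np.where(degenerate, 1.0, norms)[:, None]
    out[degenerate, :] = 0.0
    return Connectome(
        subject_id=connectome.subject_id,
        G=out,
        feature_kind=connectome.feature_kind,
        normalized=True,
        degenerate_rows=np.nonzero(degenerate)[0],
    )


def group_ica(
    train_scans: list[RestScan],
    n_components: int = 80,
    seed: int = 0,
    max_iter: int = 500,
) -> ProjectionMatrix:
    """Group-level independent spatial components from training scans.

    Procedure: per-subject PCA in the time dimension down to
    ``n_components`` (separating subject-level noise), concatenation of
    the reduced subject matrices along the component axis, group-level
    PCA back to ``n_components``, and a FastICA rotation (log-cosh
    contrast) of the group subspace into independent spatial sources.
    Component signs are fixed so each map's maximum-magnitude entry is
    positive.

    A non-convergent ICA emits a warning and returns the best iterate
    with ``converged=False``.
    """
    if len(train_scans) < 2:
        raise UsageError("group_ica needs at least 2 scans")
    reduced = []
    for scan in train_scans:
        _require_preprocessed(scan)
        if n_components > scan.t:
            raise UsageError(
                f"n_components={n_components} exceeds scan length t={scan.t}"
            )
        # economy SVD: keep the n_components strongest temporal modes
        u, s, _ = np.linalg.svd(scan.data, full_matrices=False)
        reduced.append(u[:, :n_components] * s[:n_components])
    stacked = np.concatenate(reduced, axis=1)  # (v, n_subj * c)

    ica = FastICA(
        n_components=n_components,
        fun="logcosh",
        max_iter=max_iter,
        random_state=seed,
        whiten="unit-variance",
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(stacked)  # (v, c) independent spatial maps
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            warnings.warn(
                "group ICA did not converge; returning best iterate",
                RuntimeWarning,
                stacklevel=2,
            )
    # sign convention: strongest entry of each map is positive
    peaks = sources[np.abs(sources).argmax(axis=0), np.arange(sources.shape[1])]
    sources = sources * np.where(peaks < 0, -1.0, 1.0)
    return ProjectionMatrix(A=sources, kind="group_ica", seed=seed, converged=converged)


def dual_regression_features(scan: RestScan, group_maps: ProjectionMatrix) -> Connectome:
    """Two-stage dual regression against a set of group spatial maps.

    Stage 1 regresses the group maps onto each time frame, producing
    subject-specific time courses (``f x t``); stage 2 regresses those
    time courses onto every grayordinate's time series, producing
    subject-specific spatial maps (``f x n_total``) that serve as the
    connectome rows.
    """
    _require_preprocessed(scan)
    A = group_maps.A
    if A.shape[0] != scan.n_total:
        raise UsageError("group-map axis does not match scan grayordinates")
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise UsageError("group-map matrix is rank deficient")
    t_courses, *_ = np.linalg.lstsq(A, scan.data, rcond=None)  # (f, t)
    maps_t, *_ = np.linalg.lstsq(t_courses.T, scan.data.T, rcond=None)  # (f, v)
    return Connectome(
        subject_id=scan.subject_id,
        G=maps_t,
        feature_kind="dual_regression",
        normalized=False,
    )


def pcr_semipartial_connectome(
    scan: RestScan,
    parcellation: Parcellation,
    geometry: Geometry,
    n_pcs: int = 512,
    mask_radius_mm: float = 10.0,
    seed: int = 0,
    cortical_distances: np.ndarray | None = None,
) -> Connectome:
    """Semi-partial covariance features via masked principal-component regression.

    For each region ``k`` the region's own grayordinates plus every
    grayordinate within ``mask_radius_mm`` of its cortical vertices are
    excluded (spatial autocorrelation would otherwise dominate).  The
    top ``n_pcs`` principal components of the remaining data are
    computed by randomized SVD, the region's mean time series is
    regressed (OLS) on the component time courses, and the coefficients
    are back-projected through the component loadings onto the full
    grayordinate axis.  Excluded grayordinates receive exactly 0.

    ``n_pcs`` larger than the usable rank is truncated with a warning;
    at full rank the fit equals the OLS projection onto the masked
    data's row space.
    """
    _require_preprocessed(scan)
    if parcellation.labels.size != scan.n_total:
        raise UsageError("parcellation does not match scan grayordinates")
    if cortical_distances is None:
        cortical_distances = cortical_distance_matrix(geometry)

    G = np.zeros((parcellation.K, scan.n_total))
    warned = False
    for k in range(1, parcellation.K + 1):
        region = parcellation.region_indices(k)
        excluded = exclusion_mask(
            geometry, region, mask_radius_mm, cortical_distances=cortical_distances
        )
        keep = ~excluded
        if not keep.any():
            raise UsageError(f"exclusion set of region {k} covers all grayordinates")
        x_masked = scan.data[keep]
        rank_cap = min(x_masked.shape)
        p = min(n_pcs, rank_cap)
        if p < n_pcs and not warned:
            warnings.warn(
                f"n_pcs={n_pcs} exceeds usable rank {rank_cap}; truncating",
                RuntimeWarning,
                stacklevel=2,
            )
            warned = True
        u, s, vt = randomized_svd(
            x_masked, n_components=p, n_iter=7, n_oversamples=10, random_state=seed
        )
        nonzero = s > s[0] * 1e-12 if s.size else s.astype(bool)
        u, s, vt = u[:, nonzero], s[nonzero], vt[nonzero]
        y = scan.data[region].mean(axis=0)  # region mean time series
        beta = vt @ y  # OLS on orthonormal component time courses
        G[k - 1, keep] = u @ (beta / s)
    return Connectome(
        subject_id=scan.subject_id,
        G=G,
        feature_kind="pcr_semipartial",
        normalized=False,
    )


def activity_flow_features(scan: RestScan, template: np.ndarray, geometry: Geometry) -> Connectome:
    """Single-feature connectome from a group-mean activation template.

    The template (cortical values, typically the training-set mean
    contrast map) is placed on the cortical positions of the
    grayordinate axis, zero elsewhere, and used as a one-column
    projection; the resulting feature row is the FC-weighted flow of
    mean activation into every grayordinate.
    """
    _require_preprocessed(scan)
    template = np.asarray(template, dtype=float).ravel()
    if template.size != geometry.n_cortex:
        raise UsageError(
            f"template length {template.size} does not match n_cortex {geometry.n_cortex}"
        )
    col = np.zeros(scan.n_total)
    col[geometry.cortex_index] = template
    projected = col @ scan.data  # (t,)
    return Connectome(
        subject_id=scan.subject_id,
        G=(scan.data @ projected)[None, :],
        feature_kind="activity_flow",
        normalized=False,
    )
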