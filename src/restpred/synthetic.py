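"""Self-contained synthetic cohorts with planted ground truth.

The generator emulates the structure that makes rest-to-task prediction
possible in real cohorts: every subject shares a set of latent spatial
networks, expresses subject-specific deviations of those networks in
*both* the resting series and the task contrast maps, and carries a
behaviour score coupled to how consistently the two modalities express
the same deviations.  Signal-to-noise is spatially heterogeneous:
"primary-sensory" vertices are stereotyped across subjects (nothing to
predict) while "association" vertices carry predictable inter-subject
variance — the pattern that makes spatial maps of predictive
performance informative.

Generative model
----------------
For subject :math:`i` with latent maps
:math:`M_i = M_{group} + D_i` (``n_latent x n_total``; deviations
:math:`D_i` are smooth fields with per-vertex SD ``subject_dev_sd``):

* rest runs: :math:`X_i = M_i^T T_i + \\sigma_{rest} E_i`, with AR(1)
  latent time courses :math:`T_i` and i.i.d. noise;
* task map for contrast :math:`c` with unit loading vector
  :math:`\\ell_c`, at cortical vertex :math:`j`:

  .. math::

     y_{ij} = (\\ell_c^T M_{group})_j
              + \\alpha_j\\,[a_i (\\ell_c^T D_i)_j
                 + \\sqrt{1-a_i^2}\\,(\\ell_c^T \\tilde D_i)_j]
              + w_j \\varepsilon_{ij}

  where :math:`a_i \\in (0, 1]` is the subject's rest–task *alignment*
  (the rotated share :math:`\\tilde D_i` is an independent deviation
  field invisible to rest data), and :math:`\\alpha_j, w_j` are chosen
  so that the rest-*shared* component has variance
  :math:`s_j^2 \\sigma^2` and everything else (rotation residual plus
  white noise) has variance :math:`\\sigma^2`, with :math:`s_j` the
  per-vertex ``snr_profile`` entry and :math:`\\sigma` the task noise
  SD.  The oracle per-vertex ceiling of predictive :math:`R^2` is then
  exactly :math:`s_j^2/(s_j^2+1)`.

* behaviour: ``coupling * standardize(a) + sqrt(1-coupling^2) * eta``.

Two calls with the same :class:`SimConfig` produce bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    ActivationMap,
    Geometry,
    Parcellation,
    RestScan,
    UsageError,
)
from .distances import great_circle_distances

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Cohort",
    "make_geometry",
    "make_parcellation",
    "simulate_cohort",
    "default_snr_profile",
]

CORTEX_RADIUS_MM = 80.0
SUBCORTEX_RADIUS_MM = 20.0


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    The defaults are desk-scale: small enough that a full benchmark
    runs in minutes, large enough that every planted property is
    measurable.
    """

    n_subjects: int = 60
    n_total: int = 600
    n_cortex: int = 500
    t_per_run: int = 200
    n_runs: int = 2
    n_latent: int = 8
    #: per-vertex SD of subject-specific deviations of the latent maps
    subject_dev_sd: float = 0.5
    #: per-vertex ratio of predictable-signal SD to noise SD (length
    #: n_cortex); ``None`` selects the built-in sensory/association split
    snr_profile: np.ndarray | None = None
    #: correlation strength between rest-task alignment and behaviour
    behavior_coupling: float = 0.6
    seed: int = 0
    # --- secondary knobs -------------------------------------------------
    contrasts: tuple[str, ...] = ("2BK-0BK", "MATH-STORY", "MATCH-REL")
    #: AR(1) coefficient of the latent time courses (BOLD-like smoothness)
    ar_coef: float = 0.5
    rest_noise_sd: float = 1.0
    #: total unpredictable task-map SD per vertex (sigma above)
    task_noise_sd: float = 1.0
    #: amplitude of the group-level task component (shared by everyone)
    group_task_amp: float = 1.0
    #: spatial correlation length (mm) of the group latent maps
    smooth_scale_mm: float = 15.0
    #: spatial correlation length (mm) of subject-specific deviations;
    #: individual topography varies on a finer scale than the group
    #: networks themselves, so this defaults well below smooth_scale_mm
    dev_smooth_scale_mm: float = 4.0
    #: range of the per-subject rest-task alignment scalar
    alignment_range: tuple[float, float] = (0.5, 1.0)
    n_anatomical: int = 6
    #: spatial correlation between anatomical maps and the SNR profile
    anat_coupling: float = 0.3
    #: frames of per-contrast task series (0 disables task-series output)
    task_series_frames: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_total", "n_cortex", "t_per_run", "n_runs", "n_latent"):
            if getattr(self, name) <= 0:
                raise UsageError(f"{name} must be positive")
        if self.n_cortex > self.n_total:
            raise UsageError("n_cortex cannot exceed n_total")
        if not 0.0 <= self.behavior_coupling <= 1.0:
            raise UsageError("behavior_coupling must lie in [0, 1]")
        lo, hi = self.alignment_range
        if not (0.0 < lo <= hi <= 1.0):
            raise UsageError("alignment_range must satisfy 0 < lo <= hi <= 1")
        if self.snr_profile is not None:
            self.snr_profile = np.asarray(self.snr_profile, dtype=float)
            if self.snr_profile.shape != (self.n_cortex,):
                raise UsageError("snr_profile must have length n_cortex")
            if np.any(self.snr_profile < 0):
                raise UsageError("snr_profile must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream oracles."""

    group_maps: np.ndarray  # (n_latent, n_total)
    subject_deviations: np.ndarray  # (n_subjects, n_latent, n_total)
    task_loadings: dict[str, np.ndarray]  # contrast -> (n_latent,)
    noise_sd_map: np.ndarray  # (n_cortex,) total unpredictable SD
    snr_profile: np.ndarray  # (n_cortex,)
    alignment: np.ndarray  # (n_subjects,) rest-task alignment scalars
    subject_ids: list[str]

    def r2_ceiling(self) -> np.ndarray:
        """Oracle per-vertex predictive-R^2 ceiling s^2 / (s^2 + sigma^2)."""
        s2 = self.snr_profile**2 * self.noise_sd_map**2
        return s2 / (s2 + self.noise_sd_map**2)


@dataclass
class Cohort:
    """A complete synthetic cohort (the in-memory form of one study)."""

    config: SimConfig
    geometry: Geometry
    parcellation: Parcellation
    subject_ids: list[str]
    rest_scans: dict[str, RestScan]
    task_maps: dict[str, dict[str, ActivationMap]]  # contrast -> subject -> map
    anatomical: dict[str, np.ndarray]  # subject -> (n_anatomical, n_cortex)
    behavior: pd.DataFrame  # index subject_id, one column per contrast
    ground_truth: GroundTruth
    task_series: dict[str, dict[str, RestScan]] = field(default_factory=dict)

    @property
    def contrasts(self) -> tuple[str, ...]:
        return tuple(self.task_maps.keys())

    def task_matrix(self, contrast: str, subject_ids: list[str]) -> np.ndarray:
        """Stack task maps as an ``(n_subjects, n_cortex)`` array."""
        return np.array([self.task_maps[contrast][s].values for s in subject_ids])


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic low-discrepancy layout of n points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.c_[r * np.cos(theta), r * np.sin(theta), z]


def make_geometry(config: SimConfig) -> Geometry:
    """Cortical vertices on an 80 mm sphere, subcortical voxels in a ball.

    The layout is a deterministic low-discrepancy (Fibonacci) spiral,
    so identical configurations yield identical coordinates.  The
    cortex occupies the first ``n_cortex`` positions of the
    grayordinate axis.
    """
    if config.n_cortex < 3:
        raise UsageError("n_cortex must be at least 3")
    n_sub = config.n_total - config.n_cortex
    ctx = CORTEX_RADIUS_MM * _fibonacci_sphere(config.n_cortex)
    coords = ctx
    if n_sub:
        dirs = _fibonacci_sphere(n_sub)
        radii = SUBCORTEX_RADIUS_MM * ((np.arange(n_sub) + 0.5) / n_sub) ** (1.0 / 3.0)
        coords = np.vstack([ctx, radii[:, None] * dirs])
    return Geometry(
        n_total=config.n_total,
        n_cortex=config.n_cortex,
        cortex_index=np.arange(config.n_cortex),
        coordinates=coords,
    )


def make_parcellation(geometry: Geometry, K: int = 20, seed: int = 0) -> Parcellation:
    """Spatially contiguous regions via seeded nearest-centroid assignment.

    Centroid vertices are drawn separately for cortex and subcortex
    (proportionally to their sizes) so regions never straddle the two
    compartments; every vertex is assigned to its nearest centroid,
    which by construction yields nonempty, contiguous regions.
    """
    if K > geometry.n_total:
        raise UsageError("K cannot exceed the number of grayordinates")
    coords = geometry.require_coordinates()
    rng = np.random.default_rng(seed)
    sub_idx = geometry.subcortex_index
    if sub_idx.size and K >= 2:
        k_sub = int(round(K * sub_idx.size / geometry.n_total))
        k_sub = min(max(k_sub, 1), min(K - 1, sub_idx.size))
    else:
        k_sub = 0
    k_ctx = K - k_sub

    labels = np.zeros(geometry.n_total, dtype=int)
    ctx_idx = geometry.cortex_index
    ctx_centroids = rng.choice(ctx_idx, size=k_ctx, replace=False)
    d = np.linalg.norm(coords[ctx_idx][:, None, :] - coords[ctx_centroids][None], axis=2)
    labels[ctx_idx] = 1 + np.argmin(d, axis=1)
    if k_sub:
        sub_centroids = rng.choice(sub_idx, size=k_sub, replace=False)
        d = np.linalg.norm(coords[sub_idx][:, None, :] - coords[sub_centroids][None], axis=2)
        labels[sub_idx] = 1 + k_ctx + np.argmin(d, axis=1)
    return Parcellation(labels=labels, K=K)


def default_snr_profile(geometry: Geometry) -> np.ndarray:
    """Built-in heterogeneous SNR map.

    Vertices on the "upper" hemisphere (z >= 0) stand in for
    association cortex (predictable inter-subject variance, SNR ratio
    1.0); the lower hemisphere stands in for primary-sensory cortex,
    stereotyped across subjects (SNR ratio 0.1).
    """
    z = geometry.require_coordinates()[geometry.cortex_index, 2]
    return np.where(z >= 0, 1.0, 0.1)


def _smoothing_operator(coords: np.ndarray, scale_mm: float, spherical: bool) -> np.ndarray:
    """Row-normalized Gaussian smoothing weights.

    Rows have unit L2 norm, so smoothing an i.i.d. N(0, s^2) field
    preserves the per-vertex SD exactly while introducing spatial
    correlation with length ~``scale_mm``.
    """
    if spherical:
        d = great_circle_distances(coords)
    else:
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    w = np.exp(-0.5 * (d / scale_mm) ** 2)
    return w / np.linalg.norm(w, axis=1, keepdims=True)


def _alignment_moments(lo: float, hi: float) -> tuple[float, float]:
    """E[a^2] and E[1-a^2] for a ~ Uniform(lo, hi)."""
    ea2 = (lo * lo + lo * hi + hi * hi) / 3.0
    return ea2, 1.0 - ea2


def _ar1_series(rng: np.random.Generator, n_series: int, n_frames: int, phi: float) -> np.ndarray:
    """AR(1) rows with unit marginal variance."""
    x = np.empty((n_series, n_frames))
    x[:, 0] = rng.standard_normal(n_series)
    innov = rng.standard_normal((n_series, n_frames - 1)) * np.sqrt(1.0 - phi * phi)
    for t in range(1, n_frames):
        x[:, t] = phi * x[:, t - 1] + innov[:, t - 1]
    return x


def simulate_cohort(config: SimConfig, K: int = 20) -> Cohort:
    """Generate a full cohort from one configuration.

    Returns rest scans (raw, with ``preprocessed=False`` — callers run
    the standard preprocessing), per-contrast task maps, per-subject
    anatomical feature maps, behaviour scores and the planted
    :class:`GroundTruth`.

    Raises
    ------
    UsageError
        If the SNR profile is degenerate (all zero) or infeasible given
        the alignment distribution (the rotation residual alone would
        exceed the total noise budget).
    """
    rng = np.random.default_rng(config.seed)
    geometry = make_geometry(config)
    parcellation = make_parcellation(geometry, K=K, seed=config.seed)
    coords = geometry.require_coordinates()
    n_sub = geometry.subcortex_index.size
    n_subj, n_lat, n_tot, n_ctx = (
        config.n_subjects,
        config.n_latent,
        config.n_total,
        config.n_cortex,
    )
    subject_ids = [f"sub-{i:03d}" for i in range(n_subj)]

    snr = config.snr_profile
    if snr is None:
        snr = default_snr_profile(geometry)
    if np.all(snr == 0):
        raise UsageError("degenerate snr_profile: all zero")

    lo, hi = config.alignment_range
    ea2, eb2 = _alignment_moments(lo, hi)
    sigma = config.task_noise_sd
    delta = config.subject_dev_sd
    # rotation residual variance per vertex; must fit inside sigma^2
    rot_var = (snr * sigma) ** 2 * (eb2 / ea2) if delta > 0 else np.zeros(n_ctx)
    white_var = sigma**2 - rot_var
    if np.any(white_var < 0):
        raise UsageError(
            "snr_profile infeasible for the alignment distribution: "
            f"max allowed SNR ratio is {np.sqrt(ea2 / eb2):.3f}"
        )

    # --- planted spatial structure --------------------------------------
    w_ctx = _smoothing_operator(coords[: n_ctx], config.smooth_scale_mm, spherical=True)
    smooth = np.zeros((n_tot, n_tot))
    smooth[:n_ctx, :n_ctx] = w_ctx
    if n_sub:
        smooth[n_ctx:, n_ctx:] = _smoothing_operator(
            coords[n_ctx:], config.smooth_scale_mm, spherical=False
        )

    dev_w_ctx = _smoothing_operator(
        coords[:n_ctx], config.dev_smooth_scale_mm, spherical=True
    )
    dev_smooth = np.zeros((n_tot, n_tot))
    dev_smooth[:n_ctx, :n_ctx] = dev_w_ctx
    if n_sub:
        dev_smooth[n_ctx:, n_ctx:] = _smoothing_operator(
            coords[n_ctx:], config.dev_smooth_scale_mm, spherical=False
        )

    group_maps = rng.standard_normal((n_lat, n_tot)) @ smooth.T
    deviations = np.einsum(
        "ilv,wv->ilw", rng.standard_normal((n_subj, n_lat, n_tot)) * delta, dev_smooth
    )
    rotated = np.einsum(
        "ilv,wv->ilw", rng.standard_normal((n_subj, n_lat, n_tot)) * delta, dev_smooth
    )

    task_loadings: dict[str, np.ndarray] = {}
    for contrast in config.contrasts:
        active = rng.choice(n_lat, size=min(3, n_lat), replace=False)
        ell = np.zeros(n_lat)
        ell[active] = rng.standard_normal(active.size)
        task_loadings[contrast] = ell / np.linalg.norm(ell)

    alignment = rng.uniform(lo, hi, size=n_subj)
    # scale factor turning unit-variance latent deviations into the
    # planted shared-signal SD  s_j * sigma
    alpha = (snr * sigma) / (delta * np.sqrt(ea2)) if delta > 0 else np.zeros(n_ctx)

    # --- task maps -------------------------------------------------------
    task_maps: dict[str, dict[str, ActivationMap]] = {}
    for contrast, ell in task_loadings.items():
        group_part = config.group_task_amp * (ell @ group_maps[:, :n_ctx])
        maps: dict[str, ActivationMap] = {}
        for i, sid in enumerate(subject_ids):
            shared = alignment[i] * (ell @ deviations[i, :, :n_ctx])
            rot = np.sqrt(1.0 - alignment[i] ** 2) * (ell @ rotated[i, :, :n_ctx])
            noise = rng.standard_normal(n_ctx) * np.sqrt(white_var)
            values = group_part + alpha * (shared + rot) + noise
            maps[sid] = ActivationMap(subject_id=sid, contrast_id=contrast, values=values)
        task_maps[contrast] = maps

    # --- rest series ------------------------------------------------------
    rest_scans: dict[str, RestScan] = {}
    for i, sid in enumerate(subject_ids):
        m_i = group_maps + deviations[i]
        runs = []
        for _ in range(config.n_runs):
            t_courses = _ar1_series(rng, n_lat, config.t_per_run, config.ar_coef)
            noise = rng.standard_normal((n_tot, config.t_per_run)) * config.rest_noise_sd
            runs.append(m_i.T @ t_courses + noise)
        rest_scans[sid] = RestScan(
            subject_id=sid,
            data=np.concatenate(runs, axis=1),
            run_boundaries=[config.t_per_run] * config.n_runs,
            preprocessed=False,
        )

    # --- anatomical stand-ins --------------------------------------------
    snr_std = (snr - snr.mean()) / (snr.std() + 1e-12)
    anat_base = np.empty((config.n_anatomical, n_ctx))
    c = config.anat_coupling
    for m in range(config.n_anatomical):
        field_m = rng.standard_normal(n_ctx) @ w_ctx.T
        anat_base[m] = c * snr_std + np.sqrt(1.0 - c * c) * field_m
    anatomical = {}
    for sid in subject_ids:
        subj_noise = rng.standard_normal((config.n_anatomical, n_ctx)) @ w_ctx.T
        anatomical[sid] = anat_base + 0.5 * subj_noise

    # --- behaviour --------------------------------------------------------
    a_std = (alignment - alignment.mean()) / (alignment.std() + 1e-12)
    bc = config.behavior_coupling
    behavior = pd.DataFrame(index=pd.Index(subject_ids, name="subject_id"))
    for contrast in config.contrasts:
        eta = rng.standard_normal(n_subj)
        behavior[contrast] = bc * a_std + np.sqrt(1.0 - bc * bc) * eta

    # --- optional per-contrast task series (for task-derived group ICA) --
    task_series: dict[str, dict[str, RestScan]] = {}
    if config.task_series_frames > 0:
        for contrast, ell in task_loadings.items():
            boost = 1.0 + 2.0 * np.abs(ell)
            series: dict[str, RestScan] = {}
            for i, sid in enumerate(subject_ids):
                m_i = group_maps + deviations[i]
                t_courses = _ar1_series(rng, n_lat, config.task_series_frames, config.ar_coef)
                noise = (
                    rng.standard_normal((n_tot, config.task_series_frames))
                    * config.rest_noise_sd
                )
                series[sid] = RestScan(
                    subject_id=sid,
                    data=(m_i * boost[:, None]).T @ t_courses + noise,
                    run_boundaries=[config.task_series_frames],
                    preprocessed=False,
                )
            task_series[contrast] = series

    ground_truth = GroundTruth(
        group_maps=group_maps,
        subject_deviations=deviations,
        task_loadings=task_loadings,
        noise_sd_map=np.full(n_ctx, sigma),
        snr_profile=snr.copy(),
        alignment=alignment,
        subject_ids=subject_ids,
    )
    return Cohort(
        config=config,
        geometry=geometry,
        parcellation=parcellation,
        subject_ids=subject_ids,
        rest_scans=rest_scans,
        task_maps=task_maps,
        anatomical=anatomical,
        behavior=behavior,
        ground_truth=ground_truth,
        task_series=task_series,
    )
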