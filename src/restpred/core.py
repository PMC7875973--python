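"""Domain containers for grayordinate-space fMRI data.

The package operates on "grayordinates": a single spatial axis mixing
cortical surface vertices with subcortical/cerebellar voxels (the HCP
CIFTI-2 convention; 91,282 total of which 59,412 are cortical at full
scale).  All downstream machinery — feature extraction, vertex-wise
regression, evaluation — is written against the small set of containers
defined here so that real CIFTI data and synthetic cohorts are
interchangeable.

Conventions
-----------
* Rest data matrices are ``(n_total, t)``: grayordinates on the rows,
  time on the columns.
* Task contrast maps live on the cortex only and have length
  ``n_cortex``; the mapping from cortical vertex ``j`` to its position
  on the grayordinate axis is ``Geometry.cortex_index[j]``.
* Parcellation labels are integers ``0..K`` over the full grayordinate
  axis; 0 means "unassigned" (never produced by the synthetic
  generator, tolerated on input).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RestpredError",
    "UsageError",
    "FormatError",
    "Geometry",
    "RestScan",
    "ActivationMap",
    "Parcellation",
    "CohortSplit",
    "preprocess_rest",
]

#: absolute tolerance below which a row standard deviation is treated as zero
DEGENERATE_SD_TOL = 1e-12


class RestpredError(Exception):
    """Base class for errors raised by this package."""


class UsageError(RestpredError, ValueError):
    """The caller violated a documented precondition."""


class FormatError(RestpredError, IOError):
    """An input file does not match the expected on-disk format."""


@dataclass
class Geometry:
    """Spatial layout of one grayordinate axis.

    Parameters
    ----------
    n_total :
        Number of grayordinates (cortical vertices plus subcortical
        voxels).
    n_cortex :
        Number of cortical surface vertices.
    cortex_index :
        Ordered integer index (length ``n_cortex``) of the cortical
        vertices within the grayordinate axis.
    coordinates :
        Optional ``(n_total, 3)`` array of positions in millimetres.
        Required by any distance-based operation (geodesic masking,
        spatially contiguous parcellations).
    """

    n_total: int
    n_cortex: int
    cortex_index: np.ndarray
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cortex_index = np.asarray(self.cortex_index, dtype=np.intp)
        if self.n_cortex > self.n_total:
            raise UsageError("n_cortex cannot exceed n_total")
        if self.cortex_index.shape != (self.n_cortex,):
            raise UsageError("cortex_index must have length n_cortex")
        if np.unique(self.cortex_index).size != self.n_cortex:
            raise UsageError("cortex_index contains duplicates")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (self.n_total, 3):
                raise UsageError("coordinates must have shape (n_total, 3)")

    @property
    def subcortex_index(self) -> np.ndarray:
        """Grayordinate indices that are not cortical vertices."""
        mask = np.ones(self.n_total, dtype=bool)
        mask[self.cortex_index] = False
        return np.nonzero(mask)[0]

    def require_coordinates(self) -> np.ndarray:
        if self.coordinates is None:
            raise UsageError("this operation requires Geometry.coordinates")
        return self.coordinates


@dataclass
class RestScan:
    """One subject's (possibly multi-run) resting-state series.

    ``data`` has shape ``(n_total, t)`` with ``t`` equal to the sum of
    ``run_boundaries``.  After :func:`preprocess_rest` each row has mean
    zero and unit variance (or is all-zero and listed in
    ``degenerate_rows``).
    """

    subject_id: str
    data: np.ndarray
    run_boundaries: list[int]
    preprocessed: bool = False
    degenerate_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.run_boundaries = [int(b) for b in self.run_boundaries]
        if self.data.ndim != 2:
            raise UsageError("RestScan.data must be 2-D (grayordinate x time)")
        if sum(self.run_boundaries) != self.data.shape[1]:
            raise UsageError(
                "run_boundaries must sum to the number of time frames "
                f"({sum(self.run_boundaries)} != {self.data.shape[1]})"
            )

    @property
    def n_total(self) -> int:
        return self.data.shape[0]

    @property
    def t(self) -> int:
        return self.data.shape[1]


@dataclass
class ActivationMap:
    """A single subject's task contrast map on the cortical surface."""

    subject_id: str
    contrast_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise UsageError("ActivationMap values must be finite")


@dataclass
class Parcellation:
    """Integer region labels (1..K) over the grayordinate axis."""

    labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise UsageError("labels must be a 1-D integer array")
        nz = self.labels[self.labels != 0]
        if nz.size and (nz.min() < 1 or nz.max() > self.K):
            raise UsageError("nonzero labels must lie in 1..K")
        present = np.unique(nz)
        if present.size != self.K:
            missing = sorted(set(range(1, self.K + 1)) - set(present.tolist()))
            raise UsageError(f"empty regions in parcellation: {missing}")

    def region_indices(self, k: int) -> np.ndarray:
        """Grayordinate indices belonging to region ``k`` (1-based)."""
        return np.nonzero(self.labels == k)[0]


@dataclass
class CohortSplit:
    """Disjoint train/test subject-id lists with the seed that made them."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise UsageError(f"train/test overlap: {sorted(overlap)[:5]}")

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    @property
    def n_test(self) -> int:
        return len(self.test_ids)


def preprocess_rest(scan: RestScan, n_discard: int = 5) -> RestScan:
    """Apply the standard rest preprocessing contract.

    Discards the first ``n_discard`` frames of every run, then demeans
    and variance-normalizes each grayordinate row over the concatenated
    remaining frames.  Rows with (numerically) zero variance are set to
    all zeros and recorded in ``degenerate_rows`` on the returned scan.

    Applying the function to an already preprocessed scan skips the
    frame discarding and renormalizes, which makes the operation
    idempotent on its own output.

    Parameters
    ----------
    scan :
        Raw (or already preprocessed) rest scan.
    n_discard :
        Leading frames dropped from each run; the default of 5 discards
        pre-steady-state volumes.

    Returns
    -------
    RestScan
        A new scan with ``preprocessed=True``; the input is not
        modified.
    """
    if scan.preprocessed:
        kept = scan.data
        boundaries = list(scan.run_boundaries)
    else:
        short = [b for b in scan.run_boundaries if b <= n_discard]
        if short:
            raise UsageError(
                f"every run must be longer than n_discard={n_discard}; "
                f"got run lengths {scan.run_boundaries}"
            )
        pieces = []
        start = 0
        for b in scan.run_boundaries:
            pieces.append(scan.data[:, start + n_discard : start + b])
            start += b
        kept = np.concatenate(pieces, axis=1)
        boundaries = [b - n_discard for b in scan.run_boundaries]

    mean = kept.mean(axis=1, keepdims=True)
    centered = kept - mean
    sd = centered.std(axis=1, keepdims=True)
    degenerate = sd.ravel() <= DEGENERATE_SD_TOL
    sd_safe = np.where(degenerate[:, None], 1.0, sd)
    out = centered / sd_safe
    out[degenerate, :] = 0.0

    return RestScan(
        subject_id=scan.subject_id,
        data=out,
        run_boundaries=boundaries,
        preprocessed=True,
        degenerate_rows=np.nonzero(degenerate)[0],
    )


def _replace(scan: RestScan, **kw) -> RestScan:
    return replace(scan, **kw)
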