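"""File I/O for grayordinate data and derived artifacts.

Real data arrives as CIFTI-2 (``.dtseries.nii`` rest series,
``.dscalar.nii`` maps, ``.dlabel.nii`` parcellations), read through
nibabel.  Synthetic and derived arrays use a portable HDF5 container:

* rest scan — datasets ``/data`` (grayordinate x time) and
  ``/run_boundaries``, attributes ``subject_id`` and ``preprocessed``;
* connectome store — one group per subject under ``/connectomes``,
  dataset ``G`` plus ``feature_kind`` / ``normalized`` attributes;
* cohort — the full synthetic cohort including a ``/ground_truth``
  group.

Parcellations are also accepted as single-column integer TSV; cohort
splits are JSON ``{"train": [...], "test": [...], "seed": N}``.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import h5py
import numpy as np
import pandas as pd

from .core import (
    ActivationMap,
    CohortSplit,
    FormatError,
    Geometry,
    Parcellation,
    RestScan,
    UsageError,
)
from .features import Connectome
from .synthetic import Cohort, GroundTruth, SimConfig

__all__ = [
    "save_rest_scan",
    "load_rest_scan",
    "load_rest_series",
    "write_connectome",
    "read_connectome",
    "list_connectomes",
    "save_split",
    "load_split",
    "save_parcellation_tsv",
    "load_parcellation_tsv",
    "save_cohort",
    "load_cohort",
]


# ---------------------------------------------------------------------------
# rest scans
# ---------------------------------------------------------------------------

def save_rest_scan(path: str | os.PathLike, scan: RestScan) -> None:
    """Write one scan to the portable HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=scan.data)
        f.create_dataset("run_boundaries", data=np.asarray(scan.run_boundaries))
        f.attrs["subject_id"] = scan.subject_id
        f.attrs["preprocessed"] = bool(scan.preprocessed)


def load_rest_scan(path: str | os.PathLike) -> RestScan:
    try:
        with h5py.File(path, "r") as f:
            return RestScan(
                subject_id=str(f.attrs["subject_id"]),
                data=f["data"][()],
                run_boundaries=list(f["run_boundaries"][()]),
                preprocessed=bool(f.attrs["preprocessed"]),
            )
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read rest container {path}: {exc}") from exc


def _load_one_run(path: str) -> np.ndarray:
    """A single run as (grayordinate, time), from HDF5 or CIFTI-2."""
    name = str(path)
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(name)
        data = np.asarray(img.get_fdata())
        # CIFTI-2 dtseries convention: time on the rows
        return data.T
    try:
        with h5py.File(name, "r") as f:
            return f["data"][()]
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read rest container {name}: {exc}") from exc


def load_rest_series(
    paths: list[str | os.PathLike], geometry: Geometry, subject_id: str | None = None
) -> RestScan:
    """Read and concatenate one subject's rest runs.

    All files must share the grayordinate axis of ``geometry``; run
    boundaries record the per-file frame counts.  The result is raw
    (``preprocessed=False``).
    """
    if not paths:
        raise UsageError("load_rest_series needs at least one file")
    runs = []
    for p in paths:
        data = _load_one_run(str(p))
        if data.shape[0] != geometry.n_total:
            raise FormatError(
                f"{p}: grayordinate axis has length {data.shape[0]}, "
                f"expected {geometry.n_total}"
            )
        runs.append(data)
    if subject_id is None:
        subject_id = os.path.basename(str(paths[0])).split(".")[0]
    return RestScan(
        subject_id=subject_id,
        data=np.concatenate(runs, axis=1),
        run_boundaries=[r.shape[1] for r in runs],
        preprocessed=False,
    )


# ---------------------------------------------------------------------------
# connectome store
# ---------------------------------------------------------------------------

def write_connectome(store: str | os.PathLike, connectome: Connectome) -> None:
    """Add (or replace) one subject's connectome in an HDF5 store."""
    with h5py.File(store, "a") as f:
        grp = f.require_group("connectomes")
        if connectome.subject_id in grp:
            del grp[connectome.subject_id]
        sub = grp.create_group(connectome.subject_id)
        sub.create_dataset("G", data=connectome.G)
        sub.attrs["feature_kind"] = connectome.feature_kind
        sub.attrs["normalized"] = bool(connectome.normalized)


def read_connectome(store: str | os.PathLike, subject_id: str) -> Connectome:
    try:
        with h5py.File(store, "r") as f:
            sub = f["connectomes"][subject_id]
            return Connectome(
                subject_id=subject_id,
                G=sub["G"][()],
                feature_kind=str(sub.attrs["feature_kind"]),
                normalized=bool(sub.attrs["normalized"]),
            )
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read connectome for {subject_id}: {exc}") from exc


def list_connectomes(store: str | os.PathLike) -> list[str]:
    with h5py.File(store, "r") as f:
        return sorted(f["connectomes"].keys()) if "connectomes" in f else []


# ---------------------------------------------------------------------------
# splits and parcellations
# ---------------------------------------------------------------------------

def save_split(path: str | os.PathLike, split: CohortSplit) -> None:
    with open(path, "w") as f:
        json.dump(
            {"train": split.train_ids, "test": split.test_ids, "seed": split.seed}, f
        )


def load_split(path: str | os.PathLike) -> CohortSplit:
    with open(path) as f:
        d = json.load(f)
    try:
        return CohortSplit(train_ids=d["train"], test_ids=d["test"], seed=d.get("seed", 0))
    except KeyError as exc:
        raise FormatError(f"split file {path} lacks key {exc}") from exc


def load_parcellation(path: str | os.PathLike) -> Parcellation:
    """Parcellation from a CIFTI-2 ``.dlabel.nii`` or an integer TSV."""
    name = str(path)
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(name)
        labels = np.rint(np.asarray(img.get_fdata()).ravel()).astype(int)
        return Parcellation(labels=labels, K=int(labels.max()))
    return load_parcellation_tsv(path)


def save_parcellation_tsv(path: str | os.PathLike, parcellation: Parcellation) -> None:
    pd.DataFrame({"label": parcellation.labels}).to_csv(path, sep="\t", index=False)


def load_parcellation_tsv(path: str | os.PathLike) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise FormatError(f"{path}: expected a 'label' column")
    labels = df["label"].to_numpy(dtype=int)
    return Parcellation(labels=labels, K=int(labels.max()))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def save_cohort(path: str | os.PathLike, cohort: Cohort) -> None:
    """Persist a synthetic cohort (including ground truth) to HDF5."""
    cfg = cohort.config
    with h5py.File(path, "w") as f:
        c = f.create_group("config")
        for key, val in asdict(cfg).items():
            if val is None:
                continue
            if key == "snr_profile":
                c.create_dataset("snr_profile", data=np.asarray(val))
            elif key in ("contrasts", "alignment_range"):
                c.attrs[key] = json.dumps(list(val))
            else:
                c.attrs[key] = val

        g = f.create_group("geometry")
        g.create_dataset("cortex_index", data=cohort.geometry.cortex_index)
        g.create_dataset("coordinates", data=cohort.geometry.coordinates)
        g.attrs["n_total"] = cohort.geometry.n_total
        g.attrs["n_cortex"] = cohort.geometry.n_cortex

        f.create_dataset("parcellation/labels", data=cohort.parcellation.labels)
        f["parcellation"].attrs["K"] = cohort.parcellation.K

        rest = f.create_group("rest")
        for sid, scan in cohort.rest_scans.items():
            sub = rest.create_group(sid)
            sub.create_dataset("data", data=scan.data)
            sub.create_dataset("run_boundaries", data=np.asarray(scan.run_boundaries))
            sub.attrs["preprocessed"] = bool(scan.preprocessed)

        task = f.create_group("task")
        for contrast, maps in cohort.task_maps.items():
            tg = task.create_group(contrast)
            for sid, amap in maps.items():
                tg.create_dataset(sid, data=amap.values)

        anat = f.create_group("anatomical")
        for sid, arr in cohort.anatomical.items():
            anat.create_dataset(sid, data=arr)

        beh = f.create_group("behavior")
        beh.attrs["columns"] = json.dumps(list(cohort.behavior.columns))
        beh.attrs["subjects"] = json.dumps(list(cohort.behavior.index))
        beh.create_dataset("values", data=cohort.behavior.to_numpy())

        gt = cohort.ground_truth
        gg = f.create_group("ground_truth")
        gg.create_dataset("group_maps", data=gt.group_maps)
        gg.create_dataset("subject_deviations", data=gt.subject_deviations)
        gg.create_dataset("noise_sd_map", data=gt.noise_sd_map)
        gg.create_dataset("snr_profile", data=gt.snr_profile)
        gg.create_dataset("alignment", data=gt.alignment)
        gg.attrs["subject_ids"] = json.dumps(gt.subject_ids)
        tl = gg.create_group("task_loadings")
        for contrast, ell in gt.task_loadings.items():
            tl.create_dataset(contrast, data=ell)

        if cohort.task_series:
            ts = f.create_group("task_series")
            for contrast, series in cohort.task_series.items():
                tg = ts.create_group(contrast)
                for sid, scan in series.items():
                    tg.create_dataset(sid, data=scan.data)


def load_cohort(path: str | os.PathLike) -> Cohort:
    with h5py.File(path, "r") as f:
        c = f["config"]
        kwargs = {}
        for key, val in c.attrs.items():
            if key in ("contrasts", "alignment_range"):
                kwargs[key] = tuple(json.loads(val))
            else:
                kwargs[key] = val.item() if hasattr(val, "item") else val
        if "snr_profile" in c:
            kwargs["snr_profile"] = c["snr_profile"][()]
        cfg = SimConfig(**kwargs)

        g = f["geometry"]
        geometry = Geometry(
            n_total=int(g.attrs["n_total"]),
            n_cortex=int(g.attrs["n_cortex"]),
            cortex_index=g["cortex_index"][()],
            coordinates=g["coordinates"][()],
        )
        parcellation = Parcellation(
            labels=f["parcellation/labels"][()], K=int(f["parcellation"].attrs["K"])
        )

        rest_scans = {}
        for sid in f["rest"]:
            sub = f["rest"][sid]
            rest_scans[sid] = RestScan(
                subject_id=sid,
                data=sub["data"][()],
                run_boundaries=list(sub["run_boundaries"][()]),
                preprocessed=bool(sub.attrs["preprocessed"]),
            )

        task_maps = {}
        # preserve the configured contrast order (h5 iterates alphabetically)
        contrast_order = [c for c in cfg.contrasts if c in f["task"]]
        contrast_order += [c for c in f["task"] if c not in contrast_order]
        for contrast in contrast_order:
            task_maps[contrast] = {
                sid: ActivationMap(
                    subject_id=sid, contrast_id=contrast, values=f["task"][contrast][sid][()]
                )
                for sid in f["task"][contrast]
            }

        anatomical = {sid: f["anatomical"][sid][()] for sid in f["anatomical"]}

        beh = f["behavior"]
        behavior = pd.DataFrame(
            beh["values"][()],
            index=pd.Index(json.loads(beh.attrs["subjects"]), name="subject_id"),
            columns=json.loads(beh.attrs["columns"]),
        )

        gg = f["ground_truth"]
        ground_truth = GroundTruth(
            group_maps=gg["group_maps"][()],
            subject_deviations=gg["subject_deviations"][()],
            task_loadings={c: gg["task_loadings"][c][()] for c in gg["task_loadings"]},
            noise_sd_map=gg["noise_sd_map"][()],
            snr_profile=gg["snr_profile"][()],
            alignment=gg["alignment"][()],
            subject_ids=json.loads(gg.attrs["subject_ids"]),
        )

        task_series: dict = {}
        if "task_series" in f:
            for contrast in f["task_series"]:
                task_series[contrast] = {
                    sid: RestScan(
                        subject_id=sid,
                        data=f["task_series"][contrast][sid][()],
                        run_boundaries=[f["task_series"][contrast][sid].shape[1]],
                        preprocessed=False,
                    )
                    for sid in f["task_series"][contrast]
                }

        subject_ids = ground_truth.subject_ids
    return Cohort(
        config=cfg,
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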