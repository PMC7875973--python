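"""One-command benchmark orchestration.

A :class:`BenchConfig` (YAML-serializable, schema-validated, unknown
keys rejected) describes a full study: cohort source, model battery,
split, evaluation options.  :func:`run_benchmark` executes it
deterministically and writes a provenance-stamped artifact directory:

* ``scores.tsv`` — long-format per-subject Pearson scores;
* ``significance.tsv`` — paired permutation tests of every model
  against the group-mean baseline, Bonferroni-corrected across
  contrasts;
* ``r2_summary.tsv`` — variance-weighted cortical mean R^2 per cell;
* ``r2maps.h5`` — full per-vertex R^2 maps;
* ``curves.tsv`` — optional learning curves;
* ``resolved-config.yaml`` — the fully resolved configuration and its
  hash (also stamped into every TSV header);
* ``benchmark.log`` — per-stage timings and seeds.

A single global seed fans out to stage-specific seeds by stable
hashing of ``(seed, stage name)``, so reordering stages cannot
silently change any stream of randomness.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core import UsageError
from .evaluation import paired_permutation_test
from .pipeline import MODEL_REGISTRY, PipelineCache, evaluate_models, learning_curve, make_split
from .synthetic import SimConfig, simulate_cohort

__all__ = ["BenchConfig", "SimSettings", "run_benchmark", "stage_seed"]

logger = logging.getLogger("restpred.bench")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


class SimSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_subjects: int = 120
    n_total: int = 600
    n_cortex: int = 500
    t_per_run: int = 200
    n_runs: int = 2
    n_latent: int = 8
    subject_dev_sd: float = 0.5
    behavior_coupling: float = 0.6
    n_parcels: int = 20
    task_series_frames: int = 0


class SplitSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_train: int = 60
    n_test: int = 60


class EvalSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_perm: int = 5000
    #: Bonferroni family size; defaults to the number of contrasts run
    n_comparisons: int | None = None


class CurveSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    enabled: bool = False
    model: str = "mmp-rr"
    train_sizes: list[int] = Field(default_factory=lambda: [3, 10, 30, 50])


class BenchConfig(BaseModel):
    """Schema-validated benchmark configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    sim: SimSettings = Field(default_factory=SimSettings)
    cohort_path: str | None = None  # load instead of simulate when set
    models: list[str] = Field(
        default_factory=lambda: ["group-mean", "group-zstat", "mmp-rr", "mmp-ols"]
    )
    contrasts: list[str] | None = None  # None = all cohort contrasts
    split: SplitSettings = Field(default_factory=SplitSettings)
    evaluation: EvalSettings = Field(default_factory=EvalSettings)
    curves: CurveSettings = Field(default_factory=CurveSettings)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "BenchConfig":
        with open(path) as f:
            return cls.model_validate(yaml.safe_load(f) or {})

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:12]


def _validate_models(names: list[str]) -> None:
    unknown = [m for m in names if m not in MODEL_REGISTRY]
    if unknown:
        raise UsageError(f"unknown model names: {unknown}; known: {sorted(MODEL_REGISTRY)}")


def run_benchmark(config: BenchConfig, out_dir: str | Path) -> Path:
    """Run the configured benchmark; returns the artifact directory."""
    _validate_models(config.models)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    header = f"# restpred benchmark, config hash {cfg_hash}\n"

    handler = logging.FileHandler(out / "benchmark.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        (out / "resolved-config.yaml").write_text(
            f"# config hash: {cfg_hash}\n" + config.resolved_yaml()
        )

        t0 = time.time()
        if config.cohort_path:
            from .io import load_cohort

            cohort = load_cohort(config.cohort_path)
            logger.info("stage=load_cohort path=%s", config.cohort_path)
        else:
            sim_seed = stage_seed(config.seed, "simulate")
            s = config.sim
            sim_cfg = SimConfig(
                n_subjects=s.n_subjects,
                n_total=s.n_total,
                n_cortex=s.n_cortex,
                t_per_run=s.t_per_run,
                n_runs=s.n_runs,
                n_latent=s.n_latent,
                subject_dev_sd=s.subject_dev_sd,
                behavior_coupling=s.behavior_coupling,
                task_series_frames=s.task_series_frames,
                seed=sim_seed,
            )
            cohort = simulate_cohort(sim_cfg, K=s.n_parcels)
            logger.info("stage=simulate seed=%d dt=%.1fs", sim_seed, time.time() - t0)

        contrasts = config.contrasts or list(cohort.contrasts)
        n_cmp = config.evaluation.n_comparisons or len(contrasts)
        split = make_split(
            cohort.subject_ids,
            config.split.n_train,
            config.split.n_test,
            seed=stage_seed(config.seed, "split"),
        )
        cache = PipelineCache(cohort)

        score_rows, sig_rows, r2_rows = [], [], []
        with h5py.File(out / "r2maps.h5", "w") as r2f:
            r2f.attrs["config_hash"] = cfg_hash
            for contrast in contrasts:
                t1 = time.time()
                results = evaluate_models(
                    cohort,
                    config.models,
                    contrast,
                    split,
                    seed=stage_seed(config.seed, f"fit:{contrast}"),
                    cache=cache,
                )
                logger.info(
                    "stage=evaluate contrast=%s models=%d dt=%.1fs",
                    contrast,
                    len(config.models),
                    time.time() - t1,
                )
                for name, res in results.items():
                    for sid, r in res.scores.items():
                        score_rows.append(
                            {"model": name, "contrast": contrast, "subject": sid, "r": r}
                        )
                    r2_rows.append(
                        {
                            "model": name,
                            "contrast": contrast,
                            "weighted_mean_r2": res.weighted_r2,
                            "mean_r": res.mean_r,
                        }
                    )
                    grp = r2f.require_group(contrast).create_group(name)
                    grp.create_dataset("r2", data=res.r2map.r2)
                    grp.create_dataset("weights", data=res.r2map.weights)
                    if res.lambdas is not None:
                        grp.create_dataset("lambdas", data=res.lambdas)
                        positive = res.lambdas[res.lambdas > 0]
                        if positive.size:  # OLS variants have all-zero lambdas
                            deciles = np.percentile(np.log10(positive), np.arange(0, 101, 10))
                            logger.debug(
                                "lambda log10 deciles %s/%s: %s",
                                name,
                                contrast,
                                np.round(deciles, 2),
                            )
                if "group-mean" in results:
                    base = results["group-mean"]
                    order = split.test_ids
                    b = np.array([base.scores[s] for s in order])
                    for name, res in results.items():
                        if name == "group-mean":
                            continue
                        m = np.array([res.scores[s] for s in order])
                        perm = paired_permutation_test(
                            m,
                            b,
                            n_perm=config.evaluation.n_perm,
                            n_comparisons=n_cmp,
                            seed=stage_seed(config.seed, f"perm:{contrast}:{name}"),
                        )
                        sig_rows.append(
                            {
                                "model": name,
                                "contrast": contrast,
                                "t": perm.t_observed,
                                "p_raw": perm.p_raw,
                                "p_bonferroni": perm.p_bonferroni,
                                "significant": perm.p_bonferroni < 0.05,
                            }
                        )

        # row order: models ranked by their subject-wise mean score
        # across contrasts (best first)
        summary = pd.DataFrame(r2_rows)
        rank = summary.groupby("model")["mean_r"].mean().sort_values(ascending=False)
        order = {m: i for i, m in enumerate(rank.index)}
        summary = summary.sort_values(
            ["model", "contrast"], key=lambda s: s.map(order) if s.name == "model" else s
        )
        sig = pd.DataFrame(sig_rows)
        if len(sig):
            sig = sig.sort_values(
                ["model", "contrast"],
                key=lambda s: s.map(order) if s.name == "model" else s,
            )
        _write_tsv(out / "scores.tsv", pd.DataFrame(score_rows), header)
        _write_tsv(out / "r2_summary.tsv", summary, header)
        _write_tsv(out / "significance.tsv", sig, header)

        if config.curves.enabled:
            t1 = time.time()
            curve_rows = []
            for contrast in contrasts:
                curve = learning_curve(
                    cohort,
                    config.curves.model,
                    contrast,
                    config.curves.train_sizes,
                    split.test_ids,
                    seed=stage_seed(config.seed, f"curve:{contrast}"),
                    cache=cache,
                )
                for size, (mean_r, w_r2) in curve.items():
                    curve_rows.append(
                        {
                            "model": config.curves.model,
                            "contrast": contrast,
                            "n_train": size,
                            "mean_r": mean_r,
                            "weighted_mean_r2": w_r2,
                        }
                    )
            _write_tsv(out / "curves.tsv", pd.DataFrame(curve_rows), header)
            logger.info("stage=curves dt=%.1fs", time.time() - t1)

        logger.info("stage=done total=%.1fs hash=%s", time.time() - t0, cfg_hash)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _write_tsv(path: Path, df: pd.DataFrame, header: str) -> None:
    with open(path, "w") as f:
        f.write(header)
        df.to_csv(f, sep="\t", index=False)
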