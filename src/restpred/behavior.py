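"""Relating prediction scores to behavioural task accuracy.

A subject whose resting-state features predict their task activation
well has, by construction of the score, a tight rest-task
correspondence.  This module asks whether that correspondence carries
behavioural information: per-subject Pearson prediction scores are
variance-stabilized (Fisher z) and correlated with task accuracy, and
models are compared against the group-mean baseline's behavioural
correlation across repeated train/test splits with the corrected
resampled t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import UsageError
from .evaluation import CorrectedTTestResult, corrected_resampled_ttest, pearson_score

__all__ = [
    "fisher_z",
    "behavior_correlation",
    "multi_split_behavior_benchmark",
    "BehaviorBenchmarkResult",
]


def fisher_z(r):
    """Fisher z transform ``atanh(r)``, variance-stabilizing for correlations.

    Values with ``|r| >= 1`` are clipped to ``1 - 1e-7`` in magnitude
    with a warning (a perfect correlation has infinite z).
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    clip = 1.0 - 1e-7
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| >= 1 clipped before Fisher z", RuntimeWarning, stacklevel=2)
        r = np.clip(r, -clip, clip)
    z = np.arctanh(r)
    return float(z[0]) if scalar else z


def behavior_correlation(scores: pd.Series, behavior: pd.Series) -> float:
    """Pearson r between Fisher-z prediction scores and task accuracy.

    Both series are indexed by subject id; only matched subjects enter.
    """
    joined = pd.concat([scores.rename("score"), behavior.rename("acc")], axis=1).dropna()
    if len(joined) < 3:
        raise UsageError(f"need at least 3 matched subjects, got {len(joined)}")
    z = fisher_z(joined["score"].to_numpy())
    return float(np.corrcoef(z, joined["acc"].to_numpy())[0, 1])


@dataclass
class BehaviorBenchmarkResult:
    """Per-model behavioural correlations over repeated splits."""

    contrast: str
    n_splits: int
    correlations: dict[str, np.ndarray]  # model -> (n_splits,) r values
    comparisons: dict[str, CorrectedTTestResult] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for model, r in self.correlations.items():
            row = {
                "contrast": self.contrast,
                "model": model,
                "mean_r": float(np.mean(r)),
                "sd_r": float(np.std(r, ddof=1)),
            }
            if model in self.comparisons:
                row["t_vs_group_mean"] = self.comparisons[model].t
                row["p_vs_group_mean"] = self.comparisons[model].p
            rows.append(row)
        return pd.DataFrame(rows)


def multi_split_behavior_benchmark(
    cohort,
    model_names: list[str],
    contrast: str,
    n_splits: int = 20,
    n_train: int | None = None,
    seed: int = 0,
) -> BehaviorBenchmarkResult:
    """Behavioural-correlation benchmark over repeated train/test splits.

    For each of ``n_splits`` seeded random partitions of the cohort,
    every model (plus the group-mean baseline) is fitted on the
    training half and scored on the test half; test-subject Fisher-z
    prediction scores are correlated with the task's behaviour
    measure.  All models share identical partitions, which is what
    makes the paired corrected-resampled comparison against the
    group-mean baseline valid.
    """
    from .pipeline import PipelineCache, fit_and_predict, make_split

    if n_train is None:
        n_train = len(cohort.subject_ids) // 2
    n_test = len(cohort.subject_ids) - n_train
    names = list(dict.fromkeys(list(model_names) + ["group-mean"]))
    cache = PipelineCache(cohort)
    behavior = cohort.behavior[contrast]

    correlations: dict[str, list[float]] = {m: [] for m in names}
    rng = np.random.default_rng(seed)
    for _ in range(n_splits):
        split_seed = int(rng.integers(0, 2**31 - 1))
        split = make_split(cohort.subject_ids, n_train, n_test, seed=split_seed)
        truths = {s: cohort.task_maps[contrast][s].values for s in split.test_ids}
        for model in names:
            preds, _ = fit_and_predict(
                cohort, model, contrast, split, seed=split_seed, cache=cache
            )
            r_scores = pd.Series(
                {
                    s: pearson_score(preds[i], truths[s])
                    for i, s in enumerate(split.test_ids)
                }
            )
            correlations[model].append(behavior_correlation(r_scores, behavior))

    arrays = {m: np.asarray(v) for m, v in correlations.items()}
    comparisons = {}
    for model in names:
        if model == "group-mean":
            continue
        diffs = fisher_z(arrays[model]) - fisher_z(arrays["group-mean"])
        comparisons[model] = corrected_resampled_ttest(diffs, n_train=n_train, n_test=n_test)
    return BehaviorBenchmarkResult(
        contrast=contrast,
        n_splits=n_splits,
        correlations=arrays,
        comparisons=comparisons,
    )
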