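"""Scoring and inference.

Two complementary scores are used throughout:

* the per-subject Pearson correlation ``r_i`` between a predicted and
  a true whole-cortex map (shape similarity, scale-free); and
* the per-vertex predictive ``R^2``,

  .. math:: R^2_j = 1 - \\|y_j - \\hat y_j\\|^2 / \\|y_j - \\bar y_j\\|^2

  with :math:`\\bar y_j` the *test*-cohort mean — negative values mean
  the fitted model loses to a plain mean predictor at that vertex.
  The cortical one-number summary weights each vertex by its
  test-target variance.

Significance machinery: a paired sign-flip permutation test (one-sided,
model minus baseline) with Bonferroni correction across contrasts, and
the corrected resampled t-test for quantities measured over repeated
overlapping train/test splits (variance inflated by
``1/k + n_test/n_train``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ActivationMap, UsageError

__all__ = [
    "R2Map",
    "pearson_score",
    "score_table",
    "predictive_r2",
    "weighted_mean_r2",
    "paired_permutation_test",
    "PermutationResult",
    "corrected_resampled_ttest",
    "CorrectedTTestResult",
    "learning_curve",
]


def pearson_score(pred: ActivationMap | np.ndarray, truth: ActivationMap | np.ndarray) -> float:
    """Pearson r between a predicted and a true cortical map.

    Returns ``nan`` (the score is recorded as missing) when either map
    has zero variance.
    """
    p = pred.values if isinstance(pred, ActivationMap) else np.asarray(pred, float).ravel()
    t = truth.values if isinstance(truth, ActivationMap) else np.asarray(truth, float).ravel()
    if p.size != t.size:
        raise UsageError("prediction and truth lengths differ")
    if p.std() <= 1e-15 or t.std() <= 1e-15:
        return float("nan")
    return float(np.corrcoef(p, t)[0, 1])


def score_table(
    scores: dict[tuple[str, str], dict[str, float]]
) -> pd.DataFrame:
    """Long-format score table from ``(model, contrast) -> {subject: r}``."""
    rows = [
        {"model": m, "contrast": c, "subject": s, "r": r}
        for (m, c), per_subject in scores.items()
        for s, r in per_subject.items()
    ]
    return pd.DataFrame(rows, columns=["model", "contrast", "subject", "r"])


@dataclass
class R2Map:
    """Per-vertex predictive R^2 over a test cohort.

    ``weights`` are the per-vertex test-target variances used by the
    cortical summary; ``mask`` marks vertices where the score is
    defined (nonzero test variance).
    """

    r2: np.ndarray
    weights: np.ndarray
    n_test: int
    mask: np.ndarray

    @property
    def n_masked(self) -> int:
        return int((~self.mask).sum())


def predictive_r2(preds: np.ndarray, truths: np.ndarray) -> R2Map:
    """Vertex-wise predictive R^2 of test predictions.

    Parameters
    ----------
    preds, truths :
        ``(n_test, n_cortex)`` arrays, rows aligned on subjects.
    """
    preds = np.asarray(preds, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if preds.shape != truths.shape:
        raise UsageError("preds and truths must have identical shapes")
    n = preds.shape[0]
    if n < 2:
        raise UsageError("need at least 2 test subjects")
    mean = truths.mean(axis=0)
    sse = ((truths - preds) ** 2).sum(axis=0)
    sst = ((truths - mean[None, :]) ** 2).sum(axis=0)
    ok = sst > 1e-24
    r2 = np.full(mean.size, np.nan)
    r2[ok] = 1.0 - sse[ok] / sst[ok]
    return R2Map(r2=r2, weights=truths.var(axis=0, ddof=1), n_test=n, mask=ok)


def weighted_mean_r2(r2map: R2Map, vertices: np.ndarray | None = None) -> float:
    """Variance-weighted cortical mean of an R^2 map.

    ``vertices`` optionally restricts the summary to a subset (e.g.,
    high-SNR vertices).  Masked (zero-variance) vertices are ignored;
    an entirely masked selection is an error.
    """
    sel = np.ones(r2map.r2.size, dtype=bool)
    if vertices is not None:
        sel = np.zeros(r2map.r2.size, dtype=bool)
        sel[np.asarray(vertices, dtype=np.intp)] = True
    sel &= r2map.mask
    if not sel.any():
        raise UsageError("all selected vertices are masked")
    w = r2map.weights[sel]
    return float(np.sum(w * r2map.r2[sel]) / np.sum(w))


@dataclass
class PermutationResult:
    p_raw: float
    p_bonferroni: float
    t_observed: float
    n_perm: int


def paired_permutation_test(
    model_scores: np.ndarray,
    baseline_scores: np.ndarray,
    n_perm: int = 5000,
    n_comparisons: int = 47,
    seed: int = 0,
) -> PermutationResult:
    """One-sided paired test of model > baseline via sign flips.

    The observed statistic is the paired t of the score differences;
    the null distribution is built by randomly sign-flipping each
    subject's difference.  ``p_raw = (1 + #{t_perm >= t_obs}) /
    (1 + n_perm)``; the Bonferroni-corrected value multiplies by
    ``n_comparisons`` (the number of contrasts compared, 47 in the
    full battery).
    """
    d = np.asarray(model_scores, float) - np.asarray(baseline_scores, float)
    n = d.size
    if n < 3:
        raise UsageError("need at least 3 paired scores")
    if np.allclose(d, 0.0):
        return PermutationResult(p_raw=1.0, p_bonferroni=1.0, t_observed=0.0, n_perm=n_perm)

    def paired_t(diffs: np.ndarray) -> np.ndarray:
        m = diffs.mean(axis=-1)
        sd = diffs.std(axis=-1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return m / (sd / np.sqrt(n))

    t_obs = float(paired_t(d))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = paired_t(signs * d[None, :])
    t_null = np.nan_to_num(t_null, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p_raw = (1.0 + float(np.sum(t_null >= t_obs))) / (1.0 + n_perm)
    return PermutationResult(
        p_raw=p_raw,
        p_bonferroni=min(1.0, n_comparisons * p_raw),
        t_observed=t_obs,
        n_perm=n_perm,
    )


@dataclass
class CorrectedTTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def corrected_resampled_ttest(
    per_split_diffs: np.ndarray, n_train: int, n_test: int
) -> CorrectedTTestResult:
    """Corrected resampled t-test over k overlapping train/test splits.

    .. math:: t = \\bar d / \\sqrt{(1/k + n_{test}/n_{train})\\, s_d^2}

    with ``s_d^2`` the sample variance of the k split differences; the
    correction term accounts for the dependence between splits drawn
    from one pool.  One-sided p from the t distribution with k-1
    degrees of freedom.
    """
    d = np.asarray(per_split_diffs, dtype=float).ravel()
    k = d.size
    if k < 2:
        raise UsageError("need at least 2 splits")
    var = float(d.var(ddof=1))
    mean = float(d.mean())
    df = k - 1
    if var == 0.0:
        if mean == 0.0:
            return CorrectedTTestResult(t=0.0, p=0.5, df=df, degenerate=True)
        t = np.inf if mean > 0 else -np.inf
        return CorrectedTTestResult(t=t, p=0.0 if mean > 0 else 1.0, df=df, degenerate=True)
    t = mean / np.sqrt((1.0 / k + n_test / n_train) * var)
    return CorrectedTTestResult(t=float(t), p=float(stats.t.sf(t, df)), df=df)


def learning_curve(
    cohort,
    model_name: str,
    contrast: str,
    train_sizes: list[int],
    test_ids: list[str],
    seed: int = 0,
):
    """Generalization curve over nested training subsets.

    Thin wrapper around :func:`restpred.pipeline.learning_curve`
    (imported lazily to keep this module free of pipeline
    dependencies); see there for details.
    """
    from .pipeline import learning_curve as _lc

    return _lc(cohort, model_name, contrast, train_sizes, test_ids, seed=seed)
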