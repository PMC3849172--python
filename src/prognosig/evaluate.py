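"""Classifier and cohort evaluation: ROC/AUC, survival curves, exact tests.

The positive class is *good prognosis* throughout (the classifier's
false-negative rate is the fraction of good-prognosis patients called poor);
reversing the convention reflects the AUC about 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import DataError
from .simulate import GOOD, POOR

__all__ = [
    "EvaluationReport",
    "roc_auc",
    "auc_ci",
    "sens_spec",
    "km_logrank",
    "fisher_exact",
    "concordance",
    "plot_roc",
    "plot_km",
]


def _binary_labels(labels) -> np.ndarray:
    """Coerce good/poor, boolean or 0/1 labels to int {0, 1}; good/True = 1."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        ok = np.isin(arr, [GOOD, POOR])
        if not ok.all():
            raise DataError(f"labels must be good/poor; got {sorted(set(arr[~ok]))}")
        return (arr == GOOD).astype(int)
    return arr.astype(int)


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    if scores.shape != y.shape:
        raise DataError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise DataError("scores must be finite")
    if y.min() == y.max():
        raise DataError("both classes must be present")
    return scores, y


def roc_auc(scores, labels):
    """ROC points and trapezoidal AUC with good prognosis as positive class.

    Thresholds sweep all distinct score values; tied scores produce diagonal
    segments, so the AUC equals the Mann–Whitney statistic with the usual
    tie convention. Returns ``(points, auc)`` with ``points`` an (n, 2)
    array of (FPR, TPR) from (0, 0) to (1, 1).
    """
    scores, y = _check_scores_labels(scores, labels)
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(np.trapezoid(tpr, fpr))


def _auc_rank(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via midranks (Mann–Whitney with ties counted 1/2)."""
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    return (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_ci(scores, labels, level: float = 0.95, n_boot: int = 2000, seed=None):
    """Stratified bootstrap percentile confidence interval for the AUC.

    Resamples within each class (so every replicate keeps both classes),
    reproducible under a fixed seed.
    """
    scores, y = _check_scores_labels(scores, labels)
    if not 0 < level < 1:
        raise DataError(f"level must be in (0, 1) (got {level})")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; interval will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    pos = scores[y == 1]
    neg = scores[y == 0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        p = pos[rng.integers(0, len(pos), len(pos))]
        n = neg[rng.integers(0, len(neg), len(neg))]
        boots[b] = _auc_rank(p, n)
    alpha = 1.0 - level
    low, high = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)


def sens_spec(scores, labels, threshold: float):
    """Sensitivity and specificity at a CI threshold.

    A score strictly above the threshold is a positive (good) call; a score
    equal to the threshold is a negative call, matching the threshold
    calibration rule.
    """
    scores, y = _check_scores_labels(scores, labels)
    calls = scores > threshold
    sensitivity = float(calls[y == 1].mean())
    specificity = float((~calls[y == 0]).mean())
    return sensitivity, specificity


def km_logrank(annotation: pd.DataFrame, groups: pd.Series):
    """Kaplan–Meier curves per group and the two-sample log-rank test.

    ``annotation`` needs one row per subject with ``survival_months`` and
    ``event`` (1 observed, 0 censored); ``groups`` maps the same index to a
    binary group label. Returns ``(curves, statistic, p)`` where ``curves``
    maps each group to ``{"time": [...], "survival": [...]}``. With no
    observed event the curves are still estimated but the log-rank test is
    undefined and ``(nan, nan)`` is returned.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    groups = groups.reindex(annotation.index)
    if groups.isna().any():
        raise DataError("every subject needs a group label")
    names = sorted(groups.unique(), key=str)
    if len(names) != 2:
        raise DataError(f"exactly two groups required (got {list(names)})")
    time = annotation["survival_months"].astype(float)
    event = annotation["event"].astype(int)
    if (time < 0).any():
        raise DataError("survival_months must be nonnegative")
    curves = {}
    for name in names:
        mask = (groups == name).values
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask])
        sf = km.survival_function_
        curves[str(name)] = {
            "time": [float(t) for t in sf.index],
            "survival": [float(s) for s in sf.iloc[:, 0]],
        }
    if event.sum() == 0:
        return curves, float("nan"), float("nan")
    mask = (groups == names[0]).values
    res = logrank_test(time[mask], time[~mask], event[mask], event[~mask])
    return curves, float(res.test_statistic), float(res.p_value)


def fisher_exact(table):
    """Two-sided Fisher's exact test on a 2×2 table.

    Returns ``(odds_ratio, p)`` with the conditional maximum-likelihood odds
    ratio; the p-value sums hypergeometric probabilities no larger than the
    observed table's. A zero margin gives ``(nan, 1.0)``.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise DataError(f"expected a 2x2 table (got shape {arr.shape})")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
            raise DataError("table entries must be nonnegative integers")
        arr = np.round(arr).astype(int)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return float("nan"), 1.0
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    odds = float(stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    return odds, p


def concordance(vector_a, vector_b):
    """Pearson correlation between two platforms' measurements, with p-value."""
    a = np.asarray(vector_a, dtype=float)
    b = np.asarray(vector_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("vectors must be one-dimensional and of equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise DataError(f"need >= 3 complete pairs (got {len(a)})")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DataError("concordance undefined for a constant vector")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvaluationReport:
    """Everything the evaluation stage computes, JSON-serializable."""

    roc_points: list = field(default_factory=list)  # [[fpr, tpr], ...]
    auc: float = float("nan")
    auc_ci: tuple = (float("nan"), float("nan"))
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    threshold: float = float("nan")
    km_curves: dict = field(default_factory=dict)
    logrank_stat: float = float("nan")
    logrank_p: float = float("nan")
    logrank_defined: bool = True
    fisher_tables: list = field(default_factory=list)  # [{"table", "odds_ratio", "p"}]
    extras: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        def default(obj):
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            raise TypeError(f"not JSON-serializable: {type(obj)}")

        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=default)


def plot_roc(points, auc_value, path) -> None:
    """Write a basic ROC plot (optional artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    points = np.asarray(points)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(points[:, 0], points[:, 1], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"AUC = {auc_value:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_km(curves: dict, path) -> None:
    """Write a basic Kaplan–Meier plot (optional artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, curve in curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=str(name))
    ax.set_xlabel("months")
    ax.set_ylabel("survival fraction")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
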