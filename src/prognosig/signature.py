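"""Minimal prognostic reporter-gene selection and the CI classifier.

The derivation follows the classic mini-array signature recipe:

1. correlate each differential gene's tumor expression with the binary
   outcome (good = 1, poor = 0) and keep genes with |r| above ``r_min``;
2. rank the retained genes by |r| (ties broken by probe ID);
3. grow the signature by batches of 5 genes from the top of the ranking,
   scoring each candidate size by leave-one-out cross-validation of a
   two-centroid correlation classifier (a held-out tumor is assigned to the
   outcome class whose mean profile it correlates with best; ties go to
   poor, the conservative call);
4. the signature size is the smallest size attaining the maximal LOOCV
   accuracy;
5. for deployment, a single good-prognosis centroid is kept and a decision
   threshold on the correlation index CI = r(sample, good centroid) is
   calibrated so that at most a target fraction (default 13%) of
   good-prognosis training tumors fall below it; CI > threshold calls good.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .io import LESION_MALIGNANT
from .simulate import GOOD, POOR

logger = logging.getLogger(__name__)


@dataclass
class GeneOutcomeCorrelation:
    """Per-gene outcome correlations and the |r|-filtered ranking.

    ``table`` holds r and |r| for every computable probe; ``ranked`` is the
    subset with |r| > ``r_min`` ordered by descending |r| (ties by probe ID).
    """

    table: pd.DataFrame
    ranked: pd.DataFrame
    r_min: float

    @property
    def ranked_probes(self) -> pd.Index:
        return self.ranked.index


@dataclass
class Signature:
    """An ordered reporter-gene list with centroid and decision threshold."""

    probe_ids: list[str]
    good_centroid: pd.Series
    threshold: float
    achieved_fnr: float
    target_fnr: float
    accuracy_curve: list[tuple[int, float]] = field(default_factory=list)
    r_values: pd.Series | None = None

    @property
    def size(self) -> int:
        return len(self.probe_ids)

    @property
    def loocv_accuracy(self) -> float:
        """LOOCV accuracy at the selected size."""
        return dict(self.accuracy_curve)[self.size]

    def to_table(self) -> pd.DataFrame:
        table = pd.DataFrame(
            {
                "rank": np.arange(1, self.size + 1),
                "r": self.r_values.reindex(self.probe_ids).values
                if self.r_values is not None
                else np.nan,
                "centroid_value": self.good_centroid.reindex(self.probe_ids).values,
            },
            index=pd.Index(self.probe_ids, name="probe_id"),
        )
        return table

    def to_json(self) -> str:
        payload = {
            "size": self.size,
            "probe_ids": list(self.probe_ids),
            "threshold": self.threshold,
            "achieved_fnr": self.achieved_fnr,
            "target_fnr": self.target_fnr,
            "accuracy_curve": [[int(s), float(a)] for s, a in self.accuracy_curve],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, tsv_path, json_path) -> None:
        self.to_table().to_csv(tsv_path, sep="\t", float_format="%.6g")
        with open(json_path, "w") as fh:
            fh.write(self.to_json() + "\n")


def _binary_outcome(outcome: pd.Series) -> pd.Series:
    """Map good/poor (or 1/0) labels to float 1/0."""
    if outcome.dtype == object:
        bad = ~outcome.isin([GOOD, POOR])
        if bad.any():
            raise DataError(f"outcome labels must be good/poor; got {sorted(outcome[bad].unique())}")
        return (outcome == GOOD).astype(float)
    return outcome.astype(float)


def outcome_correlations(
    expr: pd.DataFrame, outcome: pd.Series, r_min: float = 0.3
) -> GeneOutcomeCorrelation:
    """Pearson correlation of each probe with the binary outcome, |r|-filtered.

    Parameters
    ----------
    expr
        Probes × samples log2 expression over the tumor training samples.
    outcome
        Per-sample labels (``good``/``poor`` or 1/0); good is coded 1.
    r_min
        Retain probes with r < −r_min or r > r_min (default 0.3).
    """
    y = _binary_outcome(outcome.reindex(expr.columns))
    if y.isna().any():
        raise DataError("outcome labels missing for some samples")
    if expr.shape[1] < 3:
        raise DataError(f"need >= 3 samples (got {expr.shape[1]})")
    if y.nunique() < 2:
        raise DataError("outcome is constant; correlation undefined")

    X = expr.values.astype(float)
    yv = y.values
    yc = yv - yv.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    constant = ~(sx > 0)
    if constant.any():
        logger.warning(
            "excluding %d constant probes from outcome correlation (r undefined)",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    table = pd.DataFrame({"r": r}, index=expr.index)[~constant]
    table["abs_r"] = table["r"].abs()
    kept = table[table["abs_r"] > r_min]
    # deterministic tie-break: |r| descending, then probe ID ascending
    ranked = (
        kept.assign(_pid=kept.index)
        .sort_values(["abs_r", "_pid"], ascending=[False, True], kind="mergesort")
        .drop(columns="_pid")
    )
    return GeneOutcomeCorrelation(table=table, ranked=ranked, r_min=r_min)


def ci_score(profile: pd.Series, centroid: pd.Series) -> float:
    """Correlation index: Pearson r between a sample profile and a centroid.

    Missing values are excluded pairwise; at least 3 complete pairs are
    required and both vectors must be non-constant over them.
    """
    common = profile.index.intersection(centroid.index)
    a = profile.reindex(common).values.astype(float)
    b = centroid.reindex(common).values.astype(float)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise DataError(f"CI needs >= 3 complete probe pairs (got {len(a)})")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DataError("CI undefined for a constant profile or centroid")
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def _centroid(expr: pd.DataFrame, samples) -> pd.Series:
    return expr[list(samples)].mean(axis=1)


def loocv_accuracy(
    expr: pd.DataFrame, outcome: pd.Series, probe_subset
) -> float:
    """Leave-one-out accuracy of the two-centroid correlation classifier.

    For each held-out tumor, good and poor centroids are recomputed from the
    remaining samples and the sample is assigned to the class whose centroid
    it correlates with best (CI ties assign poor).
    """
    probes = list(probe_subset)
    if len(probes) < 3:
        raise DataError(f"need >= 3 probes for centroid classification (got {len(probes)})")
    sub = expr.loc[probes]
    outcome = outcome.reindex(sub.columns)
    counts = outcome.value_counts()
    if len(counts) != 2 or (counts < 2).any():
        raise DataError(
            f"LOOCV requires both classes with >= 2 members (got {counts.to_dict()})"
        )
    good_samples = outcome.index[outcome == GOOD]
    poor_samples = outcome.index[outcome == POOR]
    correct = 0
    for sample in sub.columns:
        good_rest = [s for s in good_samples if s != sample]
        poor_rest = [s for s in poor_samples if s != sample]
        profile = sub[sample]
        ci_good = ci_score(profile, _centroid(sub, good_rest))
        ci_poor = ci_score(profile, _centroid(sub, poor_rest))
        pred = GOOD if ci_good > ci_poor else POOR
        correct += pred == outcome[sample]
    return correct / len(sub.columns)


def choose_threshold(
    scores: pd.Series, outcome: pd.Series, target_fnr: float = 0.13
) -> tuple[float, float]:
    """Calibrate the CI decision threshold to a target false-negative rate.

    Returns the largest threshold t such that the fraction of good-prognosis
    (positive-class) training scores with CI ≤ t is at most ``target_fnr``
    (samples with CI > t are called good), together with the achieved FNR.
    Concretely t is placed midway between the critical good score and the
    largest score strictly below it.
    """
    if not 0.0 <= target_fnr < 1.0:
        raise DataError(f"target_fnr must be in [0, 1) (got {target_fnr})")
    outcome = outcome.reindex(scores.index)
    y = _binary_outcome(outcome)
    if not np.isfinite(scores.values).all():
        raise DataError("scores must be finite")
    good_scores = np.sort(scores.values[y.values == 1.0])
    if len(good_scores) == 0 or (y.values == 0.0).sum() == 0:
        raise DataError("both outcome classes must be present to calibrate the threshold")
    k = int(np.floor(target_fnr * len(good_scores)))  # max good samples allowed at or below t
    critical = good_scores[k]
    below = scores.values[scores.values < critical]
    threshold = float((below.max() + critical) / 2.0) if len(below) else float(critical - 1.0)
    achieved = float((good_scores <= threshold).sum() / len(good_scores))
    return threshold, achieved


def forward_select(
    expr: pd.DataFrame,
    outcome: pd.Series,
    ranked: GeneOutcomeCorrelation,
    batch: int = 5,
    target_fnr: float = 0.13,
) -> Signature:
    """Grow the reporter set in batches from the |r| ranking, scored by LOOCV.

    Candidate sizes are ``batch, 2·batch, …`` up to the filtered pool size
    (the pool size itself is always evaluated); the selected size is the
    smallest attaining the maximal LOOCV accuracy. The returned signature
    carries the full accuracy curve, the good-prognosis centroid recomputed
    on all training tumors, and the FNR-calibrated threshold.
    """
    pool = list(ranked.ranked_probes)
    if not pool:
        raise DataError("ranked gene pool is empty; nothing to select")
    if batch < 1:
        raise DataError(f"batch must be >= 1 (got {batch})")
    sizes = list(range(batch, len(pool) + 1, batch))
    if not sizes or sizes[-1] != len(pool):
        sizes.append(len(pool))
    curve = []
    for size in sizes:
        acc = loocv_accuracy(expr, outcome, pool[:size])
        curve.append((size, acc))
    best_acc = max(acc for _, acc in curve)
    best_size = min(size for size, acc in curve if acc == best_acc)
    probes = pool[:best_size]

    outcome = outcome.reindex(expr.columns)
    good_samples = outcome.index[outcome == GOOD]
    centroid = _centroid(expr.loc[probes], good_samples)
    scores = pd.Series(
        {sample: ci_score(expr.loc[probes, sample], centroid) for sample in expr.columns}
    )
    threshold, achieved = choose_threshold(scores, outcome, target_fnr)
    return Signature(
        probe_ids=probes,
        good_centroid=centroid,
        threshold=threshold,
        achieved_fnr=achieved,
        target_fnr=target_fnr,
        accuracy_curve=curve,
        r_values=ranked.ranked["r"],
    )


def classify(
    expr: pd.DataFrame, signature: Signature
) -> tuple[pd.Series, pd.Series]:
    """Apply a deployed signature: CI against the good centroid, thresholded.

    Returns ``(scores, calls)`` with calls ``good`` when CI > threshold and
    ``poor`` otherwise (scores equal to the threshold are called poor).
    """
    scores = pd.Series(
        {
            sample: ci_score(expr.loc[signature.probe_ids, sample], signature.good_centroid)
            for sample in expr.columns
        },
        dtype=float,
    )
    calls = pd.Series(np.where(scores > signature.threshold, GOOD, POOR), index=scores.index)
    return scores, calls


def derive_outcome_labels(
    assignment, annotation: pd.DataFrame, coding: str = "cluster"
) -> pd.Series:
    """Label tumor samples good/poor for the correlation-ranking step.

    ``coding="cluster"`` (default) uses the two-cluster split of the tumor
    dendrogram and names the cluster with the longer mean observed survival
    "good" (ties: the cluster containing the first sample). ``"metastasis"``
    labels samples directly from the 5-year metastasis flag (``no`` → good);
    samples with an unknown flag are dropped.
    """
    ann = annotation.set_index("sample_id")
    if coding == "cluster":
        labels = assignment.labels
        surv = ann["survival_months"].reindex(labels.index).astype(float)
        mean1 = surv[labels == 1].mean()
        mean2 = surv[labels == 2].mean()
        good_cluster = 1 if mean1 >= mean2 else 2
        return pd.Series(
            np.where(labels == good_cluster, GOOD, POOR), index=labels.index
        )
    if coding == "metastasis":
        tumors = ann[ann["lesion"] == LESION_MALIGNANT]
        known = tumors[tumors["metastasis_5yr"].isin(["yes", "no"])]
        if len(known) < len(tumors):
            logger.warning(
                "dropping %d tumors with unknown metastasis status", len(tumors) - len(known)
            )
        return pd.Series(
            np.where(known["metastasis_5yr"] == "no", GOOD, POOR), index=known.index
        )
    raise DataError(f"unknown outcome coding {coding!r}; expected 'cluster' or 'metastasis'")


__all__ = [
    "GeneOutcomeCorrelation",
    "Signature",
    "outcome_correlations",
    "ci_score",
    "loocv_accuracy",
    "choose_threshold",
    "forward_select",
    "classify",
    "derive_outcome_labels",
]
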