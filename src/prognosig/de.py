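"""Differential expression between malignant and premalignant lesions.

Selection applies a linear fold-change threshold and a t-test p-value
threshold conjunctively, the screening rule used to build reduced diagnostic
arrays: fold change > ``fc_min`` (i.e. |mean log2 FC| ≥ log2(fc_min)) and
p ≤ ``p_max``. The test is a paired t-test on per-patient log2 differences by
default (the study design is paired); a Welch t-test is available for
unpaired designs. Normalization-role probes are never candidates.

No multiple-testing correction is applied by default; a Benjamini–Hochberg
option (``adjust="bh"``) is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import (
    LESION_MALIGNANT,
    LESION_PREMALIGNANT,
    ROLE_NORMALIZATION,
    ExpressionMatrix,
    paired_log_ratios,
)

logger = logging.getLogger(__name__)

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"


@dataclass
class DEResult:
    """Per-probe differential-expression statistics and the selected subset.

    ``table`` is indexed by probe ID with columns ``mean_log2_fc``,
    ``p_value``, ``direction`` and ``selected`` (plus ``p_adjusted`` when a
    correction was requested). Thresholds are recorded as given
    (``fc_min`` in linear fold units).
    """

    table: pd.DataFrame
    fc_min: float
    p_max: float
    paired: bool
    adjust: str | None = None

    @property
    def selected_probes(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


class DESummary(NamedTuple):
    n_selected: int
    n_up: int
    n_down: int


def select_de_genes(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    paired: bool = True,
    adjust: str | None = None,
) -> DEResult:
    """Select probes differentially expressed between lesion types.

    Parameters
    ----------
    fc_min
        Minimal linear fold change (default 2, i.e. |log2 FC| ≥ 1).
    p_max
        Maximal p-value (default 0.05).
    paired
        Paired t-test on per-patient log2 differences (default) or Welch
        t-test on the two lesion groups.
    adjust
        ``None`` (default) or ``"bh"`` for Benjamini–Hochberg; when set,
        selection thresholds the adjusted p-values.
    """
    if fc_min < 1:
        raise DataError(f"fc_min must be >= 1 linear fold (got {fc_min})")
    candidates = matrix.probe_ids[matrix.probe_roles != ROLE_NORMALIZATION]
    sub = matrix.restrict(probes=candidates)

    if paired:
        diffs = paired_log_ratios(sub, annotation)  # patients x probes
        if diffs.shape[0] < 2:
            raise DataError(f"paired test requires >= 2 complete pairs (got {diffs.shape[0]})")
        mean_fc = diffs.mean(axis=0)
        sd = diffs.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore"):
            res = stats.ttest_1samp(diffs.values, 0.0, axis=0, nan_policy="omit")
        p = pd.Series(np.asarray(res.pvalue), index=diffs.columns)
    else:
        ann = annotation.set_index("sample_id")
        mal = [s for s in sub.sample_ids if ann.loc[s, "lesion"] == LESION_MALIGNANT]
        pre = [s for s in sub.sample_ids if ann.loc[s, "lesion"] == LESION_PREMALIGNANT]
        if not mal or not pre:
            raise DataError("both lesion groups must be nonempty")
        mean_fc = sub.values[mal].mean(axis=1) - sub.values[pre].mean(axis=1)
        with np.errstate(invalid="ignore"):
            res = stats.ttest_ind(
                sub.values[mal].values, sub.values[pre].values,
                axis=1, equal_var=False, nan_policy="omit",
            )
        p = pd.Series(np.asarray(res.pvalue), index=sub.probe_ids)

    # degenerate zero-variance probes: p = 1 for a zero mean difference, else 0
    degenerate = p.isna()
    if degenerate.any():
        logger.warning("%d zero-variance probes; assigning degenerate p-values",
                       int(degenerate.sum()))
        p[degenerate] = np.where(np.isclose(mean_fc[degenerate], 0.0), 1.0, 0.0)

    table = pd.DataFrame({"mean_log2_fc": mean_fc, "p_value": p})
    table["direction"] = np.where(table["mean_log2_fc"] > 0, DIRECTION_UP, DIRECTION_DOWN)
    p_select = table["p_value"]
    if adjust is not None:
        if adjust != "bh":
            raise DataError(f"unknown adjustment {adjust!r}; expected None or 'bh'")
        from statsmodels.stats.multitest import multipletests

        table["p_adjusted"] = multipletests(table["p_value"].values, method="fdr_bh")[1]
        p_select = table["p_adjusted"]
    table["selected"] = (table["mean_log2_fc"].abs() >= np.log2(fc_min)) & (p_select <= p_max)
    return DEResult(table=table, fc_min=fc_min, p_max=p_max, paired=paired, adjust=adjust)


def de_summary(result: DEResult) -> DESummary:
    """Counts of selected, up-regulated and down-regulated probes."""
    sel = result.table[result.table["selected"]]
    n_up = int((sel["direction"] == DIRECTION_UP).sum())
    return DESummary(n_selected=len(sel), n_up=n_up, n_down=len(sel) - n_up)


def write_de_table(result: DEResult, path) -> None:
    out = result.table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


__all__ = ["DEResult", "DESummary", "select_de_genes", "de_summary", "write_de_table",
           "DIRECTION_UP", "DIRECTION_DOWN"]
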