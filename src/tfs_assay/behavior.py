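"""Per-subject behavioral aggregation, the nonsensory score, and lapse-adjusted thresholds.

Thresholds live on dB axes (dB re 1 Hz for FM depth, dB re 1 μs for ITD) and
are aggregated on that scale — across ears and blocks the dB mean equals a
geometric mean in linear units, matching the staircase reversal rules.  The
nonsensory score is the fraction of incorrect responses on easy catch
trials, pooled over a task's blocks; an ordinary least-squares fit of
threshold on that score yields residual ("clean") thresholds with the
nonsensory contribution removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from tfs_assay.staircase import StaircaseRun

__all__ = [
    "SubjectBehavior",
    "linear_to_db",
    "db_to_linear",
    "compute_lapse_rate",
    "aggregate_blocks",
    "worst_block_threshold",
    "adjust_thresholds",
    "AdjustmentReport",
]


def linear_to_db(value, reference: float = 1.0):
    """20·log10(value / reference); exact inverse of :func:`db_to_linear`."""
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0) or reference <= 0:
        raise ValueError("linear values and reference must be positive")
    out = 20.0 * np.log10(value / reference)
    return float(out) if out.ndim == 0 else out


def db_to_linear(db, reference: float = 1.0):
    """reference · 10^(dB/20)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    out = reference * 10.0 ** (np.asarray(db, dtype=float) / 20.0)
    return float(out) if out.ndim == 0 else out


def compute_lapse_rate(runs: list[StaircaseRun]) -> float:
    """Pooled catch-trial error rate over a subject's blocks for one task.

    Counts are pooled (total incorrect / total catch trials), not averaged
    across blocks, because the adaptive procedure yields unequal catch
    counts per block.  Raises if no catch trials exist.
    """
    n_catch = sum(r.n_catch for r in runs)
    n_bad = sum(r.n_catch_incorrect for r in runs)
    if n_catch == 0:
        raise ValueError("no catch trials pooled across blocks; lapse rate undefined")
    return n_bad / n_catch


def aggregate_blocks(thresholds_db) -> float:
    """Across-block (or across-ear) mean on the dB scale."""
    t = np.asarray(list(thresholds_db), dtype=float)
    if t.size == 0:
        raise ValueError("no block thresholds to aggregate")
    return float(np.mean(t))


def worst_block_threshold(thresholds_db) -> float:
    """Largest (worst) block threshold for a subject/task."""
    t = np.asarray(list(thresholds_db), dtype=float)
    if t.size == 0:
        raise ValueError("no block thresholds")
    return float(np.max(t))


@dataclass
class SubjectBehavior:
    """One subject's behavioral summary across tasks."""

    subject: str
    fm_threshold_db: float = np.nan   # dB re 1 Hz, averaged over ears/blocks
    itd_threshold_db: float = np.nan  # dB re 1 μs, averaged over blocks
    am_threshold_db: float = np.nan
    lapse_rate: dict = field(default_factory=dict)       # per task
    worst_block_db: dict = field(default_factory=dict)   # per task
    adjusted: dict = field(default_factory=dict)         # per task residual threshold


@dataclass
class AdjustmentReport:
    """OLS fit of threshold on the nonsensory score, per task."""

    task: str
    slope: float
    intercept: float
    r_squared: float
    predicted: pd.Series   # indexed by subject; subjects without a lapse rate are absent
    residuals: pd.Series


def adjust_thresholds(cohort: pd.DataFrame, task: str,
                      threshold_col: str | None = None,
                      lapse_col: str | None = None) -> AdjustmentReport:
    """Regress thresholds on the nonsensory score and return the residuals.

    The residuals are the lapse-adjusted ("clean") thresholds; slope,
    intercept and predicted values support measured-vs-predicted plots.
    Fit separately per task.  With zero variance in the lapse rates the
    model is unidentifiable and the residuals fall back to centered
    thresholds (with a warning).
    """
    threshold_col = threshold_col or f"{task}_threshold_db"
    lapse_col = lapse_col or f"{task}_lapse_rate"
    sub = cohort[[threshold_col, lapse_col]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 subjects with defined lapse rates")
    y = sub[threshold_col].to_numpy(dtype=float)
    x = sub[lapse_col].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        warnings.warn("zero variance in lapse rates; residuals are centered thresholds",
                      stacklevel=2)
        return AdjustmentReport(task, 0.0, float(y.mean()), 0.0,
                                pd.Series(y.mean(), index=sub.index),
                                pd.Series(y - y.mean(), index=sub.index))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return AdjustmentReport(
        task=task,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        predicted=pd.Series(np.asarray(model.fittedvalues), index=sub.index),
        residuals=pd.Series(np.asarray(model.resid), index=sub.index),
    )


def behavior_table(subjects: list[SubjectBehavior]) -> pd.DataFrame:
    """Cohort table: one row per subject with thresholds, lapse rates, worst blocks."""
    rows = []
    for s in subjects:
        row = {"subject": s.subject,
               "fm_threshold_db": s.fm_threshold_db,
               "itd_threshold_db": s.itd_threshold_db,
               "am_threshold_db": s.am_threshold_db}
        for task, v in s.lapse_rate.items():
            row[f"{task}_lapse_rate"] = v
        for task, v in s.worst_block_db.items():
            row[f"{task}_worst_block_db"] = v
        for task, v in s.adjusted.items():
            row[f"{task}_threshold_adj_db"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")
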