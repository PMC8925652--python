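"""Correlations, sequential variance partitioning, and FDR control.

The variance partition is a hierarchical (fixed-entry-order) linear
regression: predictors enter one at a time and each is credited with the
increase in R² it brings over the preceding model (sequential / Type-I sums
of squares).  Only this convention makes the per-predictor percentages add
up to the full-model explained variance, which is how the battery's
nonsensory-score → EEG-latency → EEG-slope partition is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegressionReport",
    "pearson_r",
    "stepwise_incremental_r2",
    "bh_fdr",
]

COLLINEARITY_EPS = 1e-10


def pearson_r(x, y) -> tuple[float, float, int]:
    """Sample Pearson correlation with a two-sided p-value.

    NaN pairs are dropped (pairwise-complete); needs at least 3 complete
    pairs and nonzero variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(x.size)


@dataclass
class RegressionReport:
    """Sequential variance partition of one response on ordered predictors."""

    response: str
    predictors: list[str]
    incremental_r2_pct: list[float]
    total_explained_pct: float
    unexplained_pct: float
    coefficients: dict
    fitted: np.ndarray
    residuals: np.ndarray
    flagged_collinear: list[str] = field(default_factory=list)
    n: int = 0

    def to_markdown(self) -> str:
        """Markdown table in the explained/unexplained layout."""
        lines = ["| Predictor | Variance explained |", "| --- | --- |"]
        for name, inc in zip(self.predictors, self.incremental_r2_pct):
            lines.append(f"| {name} | {inc:.2f}% |")
        lines.append(f"| Explained | {self.total_explained_pct:.2f}% |")
        lines.append(f"| Unexplained | {self.unexplained_pct:.2f}% |")
        return "\n".join(lines)


def stepwise_incremental_r2(y, predictors: dict | pd.DataFrame,
                            order: list[str] | None = None,
                            response_name: str = "y") -> RegressionReport:
    """Hierarchical regression: credit each predictor with its R² increment.

    Predictors enter in ``order`` (default: mapping/column order); the k-th
    increment is R²(first k) − R²(first k−1), reported in percent.  The
    increments sum to the full-model R² by construction.  A predictor whose
    increment is numerically zero (e.g. a duplicate) is flagged as
    collinear.
    """
    if isinstance(predictors, pd.DataFrame):
        pred = {c: predictors[c].to_numpy(dtype=float) for c in predictors.columns}
    else:
        pred = {k: np.asarray(v, dtype=float) for k, v in predictors.items()}
    order = list(order) if order is not None else list(pred)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y)
    for name in order:
        keep &= np.isfinite(pred[name])
    y = y[keep]
    n = y.size
    if n <= len(order) + 1:
        raise ValueError("need more observations than predictors + 1")
    X = np.column_stack([pred[name][keep] for name in order])

    r2_prev = 0.0
    incs, flagged = [], []
    model = None
    for k in range(1, len(order) + 1):
        model = sm.OLS(y, sm.add_constant(X[:, :k])).fit()
        inc = model.rsquared - r2_prev
        if inc < COLLINEARITY_EPS:
            flagged.append(order[k - 1])
            inc = max(inc, 0.0)
        incs.append(100.0 * inc)
        r2_prev = model.rsquared
    total = 100.0 * r2_prev
    coeffs = {"intercept": float(model.params[0]),
              **{name: float(b) for name, b in zip(order, model.params[1:])}}
    return RegressionReport(
        response=response_name,
        predictors=order,
        incremental_r2_pct=incs,
        total_explained_pct=total,
        unexplained_pct=100.0 - total,
        coefficients=coeffs,
        fitted=np.asarray(model.fittedvalues),
        residuals=np.asarray(model.resid),
        flagged_collinear=flagged,
        n=n,
    )


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up: reject all p ≤ p₍k*₎ with
    k* = max{k : p₍k₎ ≤ k·q/m}.  Returns a boolean rejection array."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
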