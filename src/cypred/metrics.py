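"""Regression metrics for percent-inhibition prediction.

The composite score balances absolute accuracy against preservation of the
inhibition ranking:

    custom_metric = w_err * (1 - RMSE / R) + w_corr * PCC

with equal weights by default and label range R = 100 (labels are clipped
percentages); the empirical range max(y) - min(y) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

DEFAULT_LABEL_RANGE = 100.0


@dataclass(frozen=True)
class EvalReport:
    n: int
    rmse: float
    nrmse: float
    r2: float
    pcc: float
    custom_metric: float
    label_range: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.ndim != 1 or yhat.ndim != 1:
        raise ValueError("y and yhat must be 1-D")
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root-mean-square error, in percentage points."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pcc(y, yhat) -> float:
    """Sample Pearson correlation; raises on constant input (undefined)."""
    y, yhat = _check_pair(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(stats.pearsonr(y, yhat).statistic)


def r2(y, yhat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y, yhat = _check_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant truth: R^2 undefined")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def nrmse(y, yhat, label_range: float = DEFAULT_LABEL_RANGE) -> float:
    if label_range <= 0:
        raise ValueError("label_range must be > 0")
    return rmse(y, yhat) / label_range


def custom_metric_from_components(
    rmse_value: float,
    pcc_value: float,
    label_range: float = DEFAULT_LABEL_RANGE,
    w_err: float = 0.5,
    w_corr: float = 0.5,
) -> float:
    """Composite score from precomputed RMSE and PCC."""
    if rmse_value < 0:
        raise ValueError("rmse must be >= 0")
    if label_range <= 0:
        raise ValueError("label_range must be > 0")
    return w_err * (1.0 - rmse_value / label_range) + w_corr * pcc_value


def custom_metric(y, yhat, label_range: float = DEFAULT_LABEL_RANGE) -> float:
    """Composite score computed from predictions."""
    return custom_metric_from_components(rmse(y, yhat), pcc(y, yhat), label_range)


def empirical_range(y) -> float:
    """max(y) - min(y); the optional alternative to the fixed range of 100."""
    y = np.asarray(y, dtype=float)
    r = float(np.ptp(y))
    if r == 0:
        raise ValueError("constant labels have zero range")
    return r


def evaluate(y, yhat, label_range: float = DEFAULT_LABEL_RANGE) -> EvalReport:
    """Full evaluation report for one prediction set."""
    y, yhat = _check_pair(y, yhat)
    r = rmse(y, yhat)
    p = pcc(y, yhat)
    return EvalReport(
        n=int(y.size),
        rmse=r,
        nrmse=r / label_range,
        r2=r2(y, yhat),
        pcc=p,
        custom_metric=custom_metric_from_components(r, p, label_range),
        label_range=float(label_range),
    )
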