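"""Brain-age calibration, performance and reliability.

Raw brain-predicted ages are subject to regression dilution: predictions
regress toward the training mean, so the slope of predicted age on
chronological age in healthy controls is below one and the brain-age gap
(BAG = predicted - chronological) acquires a spurious age trend. The
standard remedy fits predicted ~ alpha + beta * age in non-carrier controls
and rescales predictions as (raw - alpha) / beta, after which controls
centre at BAG 0 with no age trend.

Performance metrics are, by contract, computed on *uncorrected*
predictions (correcting first would inflate apparent accuracy), with the
coefficient of determination measured against the identity line rather
than as a squared correlation; this is why a correlation of 0.82 can
coexist with an R^2 of 0.50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationModel",
    "PerformanceReport",
    "ReliabilityReport",
    "aggregate_slices",
    "fit_calibration",
    "apply_calibration",
    "compute_bag",
    "performance_metrics",
    "icc_a1",
    "read_slice_csv",
]


@dataclass(frozen=True)
class CalibrationModel:
    """NC-fit linear recalibration: corrected = (raw - intercept) / slope."""
    intercept: float
    slope: float
    n_fit: int
    fit_group: str = "NC"


@dataclass(frozen=True)
class PerformanceReport:
    r: float
    r2: float
    mae: float
    rmse: float
    n: int


@dataclass(frozen=True)
class ReliabilityReport:
    icc: float
    ci_low: float
    ci_high: float
    n_pairs: int


def aggregate_slices(slice_predictions) -> float:
    """Median of per-slice age predictions (mean of the middle two for
    even-length inputs)."""
    arr = np.asarray(slice_predictions, dtype=float)
    if arr.size == 0:
        raise ValueError("slice_predictions must be non-empty")
    return float(np.median(arr))


def fit_calibration(nc_rows: pd.DataFrame,
                    raw_col: str = "raw_predicted_age",
                    age_col: str = "age") -> CalibrationModel:
    """OLS of raw predicted age on chronological age over NC rows only."""
    if "group" in nc_rows.columns and not (nc_rows["group"] == "NC").all():
        raise ValueError("calibration must be fit on NC rows only")
    age = nc_rows[age_col].to_numpy(dtype=float)
    raw = nc_rows[raw_col].to_numpy(dtype=float)
    if len(age) < 3:
        raise ValueError("need at least 3 NC rows to fit calibration")
    if np.ptp(age) == 0:
        raise ValueError("degenerate design: chronological age is constant")
    slope, intercept = np.polyfit(age, raw, 1)
    if slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    return CalibrationModel(intercept=float(intercept), slope=float(slope),
                            n_fit=len(age))


def apply_calibration(model: CalibrationModel, raw_predicted_age):
    """Corrected predicted age = (raw - intercept) / slope."""
    if model.slope == 0:
        raise ValueError("calibration slope must be nonzero")
    raw = np.asarray(raw_predicted_age, dtype=float)
    out = (raw - model.intercept) / model.slope
    return out if out.ndim else float(out)


def compute_bag(corrected_age, chronological_age):
    """Brain-age gap: corrected minus chronological (positive = older)."""
    c = np.asarray(corrected_age, dtype=float)
    a = np.asarray(chronological_age, dtype=float)
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(a))):
        raise ValueError("ages must be finite")
    out = c - a
    return out if out.ndim else float(out)


def performance_metrics(raw_predictions, true_ages) -> PerformanceReport:
    """Accuracy of *uncorrected* predictions against chronological age.

    r is the Pearson correlation; r2 is the identity-line coefficient of
    determination 1 - SS(pred - true) / SS(true - mean(true)), which can be
    negative and is generally below r**2.
    """
    pred = np.asarray(raw_predictions, dtype=float)
    true = np.asarray(true_ages, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction and age vectors must have equal length")
    n = len(pred)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    err = pred - true
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((true - true.mean())**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = float(np.corrcoef(pred, true)[0, 1])   # nan for constant input
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PerformanceReport(r=r, r2=r2,
                             mae=float(np.mean(np.abs(err))),
                             rmse=float(np.sqrt(np.mean(err**2))), n=n)


def _two_way_mean_squares(x: np.ndarray):
    """Mean squares of the two-way (subject x visit) ANOVA for an n-by-k
    table of repeated measurements."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1(visit1, visit2, alpha: float = 0.05) -> ReliabilityReport:
    """ICC(A,1): two-way model, single measurement, absolute agreement.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) with k = 2;
    the confidence interval uses the F-distribution bounds of McGraw &
    Wong (1996).
    """
    v1 = np.asarray(visit1, dtype=float)
    v2 = np.asarray(visit2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("visit vectors must be paired (equal length)")
    n = len(v1)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    x = np.column_stack([v1, v2])
    k = 2
    msr, msc, mse = _two_way_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        # zero variance everywhere: perfect (degenerate) agreement
        return ReliabilityReport(icc=1.0, ci_low=1.0, ci_high=1.0, n_pairs=n)
    icc = (msr - mse) / denom

    if mse == 0 and msc == 0:
        return ReliabilityReport(icc=float(icc), ci_low=1.0, ci_high=1.0,
                                 n_pairs=n)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
        fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - fl * mse) / (
            fl * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (fu * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * fu * msr)
    else:
        lo, hi = 1.0, 1.0
    return ReliabilityReport(icc=float(icc), ci_low=float(lo),
                             ci_high=float(hi), n_pairs=n)


def read_slice_csv(path, id_col: str = "participant_id") -> pd.DataFrame:
    """Read per-slice predictions (wide: participant x slice columns, or
    long: participant_id, slice, prediction) and return one aggregated
    prediction per participant."""
    df = pd.read_csv(path)
    if {"slice", "prediction"}.issubset(df.columns):
        agg = df.groupby(id_col)["prediction"].apply(
            lambda s: aggregate_slices(s.to_numpy()))
    else:
        slice_cols = [c for c in df.columns if c != id_col]
        agg = df.set_index(id_col)[slice_cols].apply(
            lambda row: aggregate_slices(row.to_numpy()), axis=1)
    out = agg.rename("raw_predicted_age").reset_index()
    return out
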