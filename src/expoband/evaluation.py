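"""Lack-of-agreement and correlation statistics for model evaluation.

Model estimates are compared with measured exposures on the natural-log
scale.  With d_i = ln(estimate_i) - ln(measurement_i):

* bias            = mean(d_i)
* relative bias   = (e^bias - 1) * 100 %
* precision       = sqrt( sum (d_i - bias)^2 / (n0 - 1) )
* accuracy (MAE)  = mean |d_i|
* residuals       = the d_i themselves, with Bland-Altman 95% limits of
                    agreement mean +/- 1.96 * SD

When only per-situation summaries (n, GM, GSD) are available instead of
individual measurements, bias and precision are recovered exactly through
grouped identities: the situation estimate is constant within its group,
so the group's residual mean is a_c - ln(gm_c) and its residual
sum-of-squares splits into a between part n_c (a_c - m_c - bias)^2 plus
the within part (n_c - 1) ln(gsd_c)^2.  Accuracy has no such identity;
a normal-theory (folded-normal) approximation is provided and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import GroupedLogMoments, MeasurementSet, MeasurementSummary, grouped_log_moments

__all__ = [
    "bias",
    "relative_bias",
    "precision",
    "accuracy_mae",
    "residual_analysis",
    "ResidualAnalysis",
    "grouped_bias",
    "grouped_precision",
    "grouped_accuracy_normal",
    "pearson_log",
    "CorrelationResult",
    "EvaluationReport",
    "evaluate",
    "reports_to_frame",
]

LOA_Z = 1.96  # Bland-Altman 95% limits-of-agreement multiplier


def _paired(est_ln, meas_ln) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(est_ln, dtype=float)
    b = np.asarray(meas_ln, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(
            f"estimate and measurement vectors must be 1-d and equal length, "
            f"got shapes {a.shape} and {b.shape}"
        )
    if a.size < 1:
        raise ValueError("need at least one pair")
    return a, b


def bias(est_ln: Sequence[float], meas_ln: Sequence[float]) -> float:
    """Mean log residual, mean(ln est - ln meas)."""
    a, b = _paired(est_ln, meas_ln)
    return float((a - b).mean())


def relative_bias(b: float) -> float:
    """Bias back-transformed to a percentage: (e^b - 1) * 100."""
    return (math.exp(b) - 1.0) * 100.0


def precision(
    est_ln: Sequence[float], meas_ln: Sequence[float], b: float | None = None
) -> float:
    """SD of log residuals about the bias (n0 - 1 denominator)."""
    a, y = _paired(est_ln, meas_ln)
    if a.size < 2:
        raise ValueError("precision needs n0 >= 2")
    d = a - y
    if b is None:
        b = float(d.mean())
    return float(np.sqrt(((d - b) ** 2).sum() / (a.size - 1)))


def accuracy_mae(est_ln: Sequence[float], meas_ln: Sequence[float]) -> float:
    """Mean absolute log residual."""
    a, y = _paired(est_ln, meas_ln)
    return float(np.abs(a - y).mean())


@dataclass(frozen=True)
class ResidualAnalysis:
    residuals: tuple[float, ...]
    mean: float
    sd: float
    loa_lower: float
    loa_upper: float


def residual_analysis(
    est_ln: Sequence[float], meas_ln: Sequence[float]
) -> ResidualAnalysis:
    """Residuals with Bland-Altman 95% limits of agreement."""
    a, y = _paired(est_ln, meas_ln)
    if a.size < 2:
        raise ValueError("limits of agreement need n0 >= 2")
    d = a - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return ResidualAnalysis(
        residuals=tuple(float(x) for x in d),
        mean=mean,
        sd=sd,
        loa_lower=mean - LOA_Z * sd,
        loa_upper=mean + LOA_Z * sd,
    )


# ---------------------------------------------------------------------------
# grouped (summary-level) reconstructions


def _align(
    estimates_ln: Mapping[str, float], moments: GroupedLogMoments
) -> np.ndarray:
    missing = [sid for sid in moments.situation_ids if sid not in estimates_ln]
    if missing:
        raise KeyError(f"no estimate for situations: {missing}")
    return np.array([estimates_ln[sid] for sid in moments.situation_ids])


def grouped_bias(
    estimates_ln: Mapping[str, float],
    summaries: Sequence[MeasurementSummary] | GroupedLogMoments,
) -> float:
    """Individual-level bias recovered from group summaries.

    Exact: within group c the estimate a_c is constant, so
    mean_i (a_c - ln y_i) = a_c - ln(gm_c).
    """
    mom = summaries if isinstance(summaries, GroupedLogMoments) else grouped_log_moments(summaries)
    a = _align(estimates_ln, mom)
    n = np.asarray(mom.ns, dtype=float)
    m = np.asarray(mom.log_means)
    return float((n * (a - m)).sum() / n.sum())


def grouped_precision(
    estimates_ln: Mapping[str, float],
    summaries: Sequence[MeasurementSummary] | GroupedLogMoments,
    b: float | None = None,
) -> float:
    """Individual-level precision recovered from group summaries.

    Exact under the sample-SD GSD convention:
    sum_i (d_i - b)^2 = n_c (a_c - m_c - b)^2 + (n_c - 1) ln(gsd_c)^2.
    """
    mom = summaries if isinstance(summaries, GroupedLogMoments) else grouped_log_moments(summaries)
    a = _align(estimates_ln, mom)
    n = np.asarray(mom.ns, dtype=float)
    m = np.asarray(mom.log_means)
    w = np.asarray(mom.within_ss)
    if mom.total_n < 2:
        raise ValueError("precision needs n0 >= 2")
    if b is None:
        b = float((n * (a - m)).sum() / n.sum())
    ss = (n * (a - m - b) ** 2).sum() + w.sum()
    return float(np.sqrt(ss / (mom.total_n - 1)))


def grouped_accuracy_normal(
    estimates_ln: Mapping[str, float],
    summaries: Sequence[MeasurementSummary] | GroupedLogMoments,
) -> float:
    """Approximate MAE from group summaries (folded-normal within groups).

    Assumes log measurements within group c are Normal(m_c, s_c^2) with
    s_c = ln(gsd_c); then E|a_c - ln Y| follows the folded normal mean.
    Unlike grouped bias/precision this is an approximation, not an
    identity: the exact MAE depends on the individual values.
    """
    mom = summaries if isinstance(summaries, GroupedLogMoments) else grouped_log_moments(summaries)
    a = _align(estimates_ln, mom)
    n = np.asarray(mom.ns, dtype=float)
    mu = a - np.asarray(mom.log_means)
    s = np.sqrt(np.asarray(mom.within_ss) / np.maximum(n - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        folded = s * np.sqrt(2 / np.pi) * np.exp(-(mu**2) / (2 * s**2)) + mu * (
            1 - 2 * sps.norm.cdf(-mu / s)
        )
    e_abs = np.where(s > 0, folded, np.abs(mu))
    return float((n * e_abs).sum() / n.sum())


# ---------------------------------------------------------------------------
# correlation


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float


def pearson_log(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value.

    Callers pass values already on the scale to be correlated (model
    outcomes are conventionally log-transformed first; the exposure score
    is already a log-scale quantity).
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("correlation needs two equal-length vectors, n >= 3")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("correlation inputs must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(a, b)
    return CorrelationResult(r=float(res.statistic), n=a.size, p_value=float(res.pvalue))


# ---------------------------------------------------------------------------
# full evaluation driver


@dataclass(frozen=True)
class EvaluationReport:
    """Agreement statistics for one model-vs-measurement comparison."""

    model_label: str
    group_label: str
    n0: int
    bias: float
    relative_bias_pct: float
    precision: float
    accuracy: float
    accuracy_is_approximate: bool
    residuals: tuple[float, ...] | None = None
    loa_mean: float | None = None
    loa_lower: float | None = None
    loa_upper: float | None = None


def _estimates_map(
    estimates: pd.DataFrame, column: str
) -> Mapping[str, float]:
    col = column if column in estimates.columns else f"{column}_ppm"
    if col not in estimates.columns:
        raise KeyError(
            f"estimate column {column!r} not found; available: "
            f"{sorted(estimates.columns)}"
        )
    vals = estimates.set_index("situation_id")[col]
    if (vals <= 0).any():
        raise ValueError(f"estimate column {col!r} must be positive (ppm)")
    return np.log(vals).to_dict()


def evaluate(
    estimates: pd.DataFrame,
    measurements: Sequence[MeasurementSummary] | Sequence[MeasurementSet],
    column: str = "p90",
    model_label: str = "model",
    group_by: str | None = "task",
) -> list[EvaluationReport]:
    """Overall and per-group agreement statistics for one estimate column.

    ``estimates`` needs columns ``situation_id`` and the estimate column
    (ppm); ``measurements`` are either raw per-situation MeasurementSets
    (exact individual-level statistics, residuals included) or
    MeasurementSummary objects (grouped identities; accuracy approximate).
    Situations present on only one side raise an error listing them.
    """
    if not len(measurements):
        raise ValueError("no measurements supplied")
    raw = isinstance(measurements[0], MeasurementSet)
    est_ln = _estimates_map(estimates, column)
    meas_ids = [m.situation_id for m in measurements]
    unmatched = sorted(set(meas_ids) - set(est_ln)) + sorted(
        set(est_ln) - set(meas_ids)
    )
    if unmatched:
        raise ValueError(f"situation_ids not present on both sides: {unmatched}")

    group_of: dict[str, str] = {}
    if group_by is not None and group_by in estimates.columns:
        group_of = estimates.set_index("situation_id")[group_by].astype(str).to_dict()
    groups = ["Overall"] + sorted(set(group_of.values()))

    reports = []
    for g in groups:
        sel = [
            m
            for m in measurements
            if g == "Overall" or group_of.get(m.situation_id) == g
        ]
        if not sel:
            continue
        if raw:
            est_vec = np.concatenate(
                [np.full(m.n, est_ln[m.situation_id]) for m in sel]
            )
            meas_vec = np.concatenate([np.log(m.values) for m in sel])
            b = bias(est_vec, meas_vec)
            prec = precision(est_vec, meas_vec, b) if meas_vec.size >= 2 else float("nan")
            acc = accuracy_mae(est_vec, meas_vec)
            ra = residual_analysis(est_vec, meas_vec) if meas_vec.size >= 2 else None
            reports.append(
                EvaluationReport(
                    model_label=model_label,
                    group_label=g,
                    n0=int(meas_vec.size),
                    bias=b,
                    relative_bias_pct=relative_bias(b),
                    precision=prec,
                    accuracy=acc,
                    accuracy_is_approximate=False,
                    residuals=ra.residuals if ra else None,
                    loa_mean=ra.mean if ra else None,
                    loa_lower=ra.loa_lower if ra else None,
                    loa_upper=ra.loa_upper if ra else None,
                )
            )
        else:
            mom = grouped_log_moments(sel)
            b = grouped_bias(est_ln, mom)
            prec = grouped_precision(est_ln, mom, b) if mom.total_n >= 2 else float("nan")
            acc = grouped_accuracy_normal(est_ln, mom)
            reports.append(
                EvaluationReport(
                    model_label=model_label,
                    group_label=g,
                    n0=mom.total_n,
                    bias=b,
                    relative_bias_pct=relative_bias(b),
                    precision=prec,
                    accuracy=acc,
                    accuracy_is_approximate=True,
                )
            )
    return reports


def reports_to_frame(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of evaluation reports."""
    return pd.DataFrame(
        {
            "model": [r.model_label for r in reports],
            "group": [r.group_label for r in reports],
            "n0": [r.n0 for r in reports],
            "bias": [r.bias for r in reports],
            "relative_bias_pct": [r.relative_bias_pct for r in reports],
            "precision": [r.precision for r in reports],
            "accuracy": [r.accuracy for r in reports],
            "accuracy_is_approximate": [r.accuracy_is_approximate for r in reports],
            "loa_mean": [r.loa_mean for r in reports],
            "loa_lower": [r.loa_lower for r in reports],
            "loa_upper": [r.loa_upper for r in reports],
        }
    )
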