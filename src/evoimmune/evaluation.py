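"""Goodness-of-fit and treatment-effect metrics.

Concordance (CCC), Pearson correlation (PCC), mean absolute percent
error with a measurement floor, and the between-arm tumor-burden
reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tumor_model import Trajectory

__all__ = ["FitMetrics", "ccc", "pcc", "mape", "burden_reduction", "fit_metrics"]


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value for the given input."""


@dataclass(frozen=True)
class FitMetrics:
    """Agreement metrics between an observed and a predicted series."""

    ccc: float
    pcc: float
    mape: float
    n_excluded: int = 0

    def __post_init__(self):
        if not (-1 - 1e-12 <= self.ccc <= 1 + 1e-12):
            raise ValueError(f"ccc out of range: {self.ccc}")
        if not (-1 - 1e-12 <= self.pcc <= 1 + 1e-12):
            raise ValueError(f"pcc out of range: {self.pcc}")

    def to_dict(self) -> dict:
        return {"ccc": self.ccc, "pcc": self.pcc, "mape": self.mape,
                "n_excluded": self.n_excluded}


def _check_pair(observed, predicted, min_len=2):
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    if o.size < min_len:
        raise ValueError(f"need at least {min_len} points, got {o.size}")
    return o, p


def ccc(observed, predicted) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    ``2*cov(o,p) / (var(o) + var(p) + (mean(o) - mean(p))^2)``.  Two equal
    constant series concord perfectly (1 by convention); a constant series
    against a varying one has zero covariance, hence CCC = 0.
    """
    o, p = _check_pair(observed, predicted)
    vo, vp = np.var(o), np.var(p)
    dm = np.mean(o) - np.mean(p)
    denom = vo + vp + dm * dm
    if denom == 0.0:
        # zero variance and zero location shift (to fp precision)
        return 1.0 if np.array_equal(o, p) else 0.0
    return float(2.0 * np.mean((o - o.mean()) * (p - p.mean())) / denom)


def pcc(observed, predicted) -> float:
    """Pearson correlation; 0 when either series is constant."""
    o, p = _check_pair(observed, predicted)
    so, sp = np.std(o), np.std(p)
    if so == 0.0 or sp == 0.0:
        return 0.0
    return float(np.mean((o - o.mean()) * (p - p.mean())) / (so * sp))


def mape(observed, predicted, floor: float = 1.0):
    """Mean absolute percent error, excluding observations at or below ``floor``.

    Measured zeros (a caliper floor, not a true volume) would make the
    percent error blow up; points with ``|observed| <= floor`` are excluded
    from the mean and counted.

    Returns
    -------
    (value_percent, n_excluded)
    """
    o, p = _check_pair(observed, predicted, min_len=1)
    keep = np.abs(o) > floor
    n_excluded = int(np.sum(~keep))
    if not np.any(keep):
        raise UndefinedMetricError("all observations at or below the floor")
    value = float(100.0 * np.mean(np.abs(o[keep] - p[keep]) / np.abs(o[keep])))
    return value, n_excluded


def burden_reduction(reference: Trajectory, treated: Trajectory, at: float) -> float:
    """Percent reduction of tumor volume in ``treated`` relative to ``reference``
    at day ``at``: ``100 * (T_ref - T_treated) / T_ref``."""
    t_ref = float(reference.at(at, "T")[0])
    t_trt = float(treated.at(at, "T")[0])
    if t_ref <= 0:
        raise UndefinedMetricError(f"reference volume at day {at} is {t_ref} <= 0")
    return 100.0 * (t_ref - t_trt) / t_ref


def fit_metrics(observed, predicted, floor: float = 1.0) -> FitMetrics:
    """CCC, PCC and MAPE for one observed/predicted pair."""
    value, n_excluded = mape(observed, predicted, floor=floor)
    return FitMetrics(
        ccc=ccc(observed, predicted),
        pcc=pcc(observed, predicted),
        mape=value,
        n_excluded=n_excluded,
    )
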