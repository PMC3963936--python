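"""Thyroid time–activity curves and cumulated activity.

The biokinetic model is deliberately minimal, matching what 3-point
small-animal SPECT designs can support: activity rises linearly from zero at
injection to a peak (reached at the first scan, ~1 h for pertechnetate) and
washes out mono-exponentially with an *effective* rate λ_eff that combines
physical decay and biological clearance — activities are handled without
decay correction throughout, so λ_eff is the directly observed slope.  The
cumulated activity Ã over [0, t_end] then has a closed form, and the
absorbed dose is Ã·S downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .emissions import TC99M_HALF_LIFE_H

__all__ = [
    "TACSample",
    "TACFit",
    "CumulatedActivity",
    "FitError",
    "decay",
    "decay_correct",
    "fit_tac",
    "tac_model",
    "cumulated_activity",
    "percent_id",
]

MBQ_H_TO_BQ_S = 1e6 * 3600.0


class FitError(ValueError):
    """Raised for unusable time–activity data."""


@dataclass(frozen=True)
class TACSample:
    """One measured point: time post-injection (h), thyroid activity (MBq,
    not decay-corrected) and the injected activity (MBq)."""

    time: float
    activity: float
    injected_activity: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise FitError("sample time must be >= 0")
        if self.activity < 0:
            raise FitError("activity must be >= 0")
        if self.activity > self.injected_activity:
            raise FitError("thyroid activity cannot exceed injected activity")


@dataclass(frozen=True)
class TACFit:
    """Fitted piecewise TAC: linear uptake through the origin to
    ``(peak_time, peak_activity)``, then mono-exponential washout at rate
    ``lambda_eff`` (1/h).  ``rss`` is the residual sum of squares of the
    model against the samples on the activity scale."""

    peak_time: float
    peak_activity: float
    lambda_eff: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if not self.peak_time > 0:
            raise FitError("peak_time must be > 0")
        if not self.peak_activity > 0:
            raise FitError("peak_activity must be > 0")
        if not self.lambda_eff > 0:
            raise FitError("lambda_eff must be > 0")

    @property
    def uptake_slope(self) -> float:
        """Uptake-phase slope in MBq/h."""
        return self.peak_activity / self.peak_time


@dataclass(frozen=True)
class CumulatedActivity:
    """Time-integrated activity Ã over [0, t_end] in Bq·s."""

    value: float
    t_end: float = 24.0

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("cumulated activity must be >= 0")


def decay(activity: float, elapsed: float, half_life: float = TC99M_HALF_LIFE_H) -> float:
    """Physical decay: activity · 2^(−elapsed/half_life)."""
    if activity < 0:
        raise ValueError("activity must be >= 0")
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0 (use decay_correct to go back in time)")
    return activity * 2.0 ** (-elapsed / half_life)


def decay_correct(
    activity: float, elapsed: float, half_life: float = TC99M_HALF_LIFE_H
) -> float:
    """Inverse of :func:`decay`: multiply by 2^(+elapsed/half_life).

    ``elapsed`` may be negative (correcting to a later reference time).
    """
    if activity < 0:
        raise ValueError("activity must be >= 0")
    if half_life <= 0:
        raise ValueError("half_life must be > 0")
    return activity * 2.0 ** (elapsed / half_life)


def _as_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    if len(samples) and isinstance(samples[0], TACSample):
        t = np.array([s.time for s in samples], dtype=float)
        a = np.array([s.activity for s in samples], dtype=float)
    else:
        arr = np.asarray(samples, dtype=float)
        t, a = arr[:, 0], arr[:, 1]
    return t, a


def fit_tac(samples, peak_time_mode: str = "fixed") -> TACFit:
    """Fit the piecewise uptake/washout model to one animal's samples.

    Parameters
    ----------
    samples:
        Sequence of :class:`TACSample` or of ``(time_h, activity_MBq)``
        pairs, with strictly increasing times.
    peak_time_mode:
        ``"fixed"`` places the peak at the first measured time point (the
        pertechnetate peak is reached within the first hour, i.e. by the
        first scan); ``"free"`` places it at the sample with maximal
        activity.

    Notes
    -----
    The washout amplitude and rate are the least-squares fit of
    ``log A = log A_peak − λ_eff (t − t_peak)`` over the strictly post-peak
    samples; with exactly two post-peak samples this is the exact two-point
    solution.  The uptake line joins (0, 0) to the fitted
    ``(peak_time, peak_activity)``.  A warning is emitted when the fitted
    washout is slower than physical decay alone (possible with noise, but
    kinetically implausible).
    """
    if peak_time_mode not in ("fixed", "free"):
        raise FitError(f"unknown peak_time_mode {peak_time_mode!r}")
    t, a = _as_arrays(samples)
    if len(t) == 0:
        raise FitError("no samples")
    if np.any(np.diff(t) <= 0):
        raise FitError("sample times must be strictly increasing")

    t_peak = float(t[0]) if peak_time_mode == "fixed" else float(t[int(np.argmax(a))])
    if t_peak <= 0:
        raise FitError("peak time must be > 0 (no activity is assumed at t = 0)")

    post = t > t_peak
    n_post = int(post.sum())
    if n_post < 2:
        raise FitError(
            f"need >= 2 samples after the peak for the washout fit, got {n_post}"
        )
    if np.any(a[post] <= 0):
        raise FitError("post-peak activities must be > 0 (log-linear washout fit)")

    slope, intercept = np.polyfit(t[post] - t_peak, np.log(a[post]), 1)
    lam = -float(slope)
    if lam <= 0:
        raise FitError("fitted washout rate is non-positive (activity not declining)")
    a_peak = float(np.exp(intercept))
    if lam < np.log(2.0) / TC99M_HALF_LIFE_H:
        warnings.warn(
            "fitted lambda_eff is slower than physical decay alone "
            f"({lam:.4f} < ln2/{TC99M_HALF_LIFE_H} 1/h)",
            stacklevel=2,
        )
    fit = TACFit(peak_time=t_peak, peak_activity=a_peak, lambda_eff=lam)
    rss = float(np.sum((tac_model(fit, t) - a) ** 2))
    return TACFit(peak_time=t_peak, peak_activity=a_peak, lambda_eff=lam, rss=rss)


def tac_model(fit: TACFit, t) -> np.ndarray:
    """Evaluate the fitted piecewise TAC (MBq) at times ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    up = fit.uptake_slope * t
    down = fit.peak_activity * np.exp(-fit.lambda_eff * (t - fit.peak_time))
    return np.where(t <= fit.peak_time, up, down)


def cumulated_activity(fit: TACFit, t_end: float = 24.0) -> CumulatedActivity:
    """Closed-form Ã = ½·A_peak·t_peak + (A_peak/λ)(1 − e^(−λ(t_end−t_peak))).

    Input units are MBq and hours; the result is converted to Bq·s.
    """
    if t_end <= fit.peak_time:
        raise ValueError(
            f"t_end ({t_end} h) must exceed the peak time ({fit.peak_time} h)"
        )
    lam = fit.lambda_eff
    a_mbq_h = 0.5 * fit.peak_activity * fit.peak_time + (fit.peak_activity / lam) * (
        1.0 - np.exp(-lam * (t_end - fit.peak_time))
    )
    return CumulatedActivity(value=float(a_mbq_h) * MBQ_H_TO_BQ_S, t_end=t_end)


def percent_id(
    activity: float,
    injected: float,
    elapsed: float = 0.0,
    half_life: float = TC99M_HALF_LIFE_H,
    decay_correct_flag: bool = False,
) -> float:
    """Thyroid uptake as percent of injected activity.

    With ``decay_correct_flag`` the measured activity is corrected back to
    injection time (multiplied by 2^(elapsed/half_life)) before the ratio.
    """
    if injected <= 0:
        raise ValueError("injected activity must be > 0")
    corrected = (
        decay_correct(activity, elapsed, half_life) if decay_correct_flag else activity
    )
    return 100.0 * corrected / injected
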