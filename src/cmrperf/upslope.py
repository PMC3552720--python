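"""Baseline, contrast-arrival foot and maximum up-slope of a curve.

The maximum up-slope of a first-pass time-intensity curve is the standard
semi-quantitative surrogate for myocardial blood flow: a sliding linear fit
over the rising limb, keeping the steepest window.  Myocardial up-slopes
are normalized to the LV-cavity (blood pool) up-slope, which cancels the
injection profile, contrast dose and receiver gain, and are conventionally
reported x100 so typical resting values land near 8-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import (
    InsufficientRiseError,
    NoEnhancementError,
    NormalizationError,
    ParameterError,
)
from .segmentation import TimeIntensityCurve

MIN_WINDOW = 2  # two points define a slope; default window adds residual df


@dataclass(frozen=True)
class BaselineFoot:
    """Pre-contrast baseline statistics and the contrast-arrival frame."""

    baseline_mean: float
    baseline_sd: float
    foot_frame: int


@dataclass(frozen=True)
class UpslopeEstimate:
    """Maximum up-slope of one curve with its fit diagnostics.

    ``slope`` is in signal units per heartbeat; the fit window
    ``[window_start, window_end]`` is inclusive in 0-based frame indices;
    ``intercept`` is the OLS intercept in absolute frame coordinates;
    ``r_squared`` the coefficient of determination of the window fit.
    """

    slope: float
    window_start: int
    window_end: int
    intercept: float
    r_squared: float
    baseline_mean: float
    foot_frame: int
    region: str = ""
    state: str | None = None


def moving_average_3(values: np.ndarray) -> np.ndarray:
    """Optional 3-point moving average (edges keep the original samples)."""
    out = np.asarray(values, dtype=float).copy()
    if len(out) >= 3:
        out[1:-1] = (out[:-2] + out[1:-1] + out[2:]) / 3.0
    return out


def estimate_baseline_foot(
    curve: TimeIntensityCurve, k_baseline: int = 5, threshold_sd: float = 2.0
) -> BaselineFoot:
    """Locate the pre-contrast baseline and the contrast-arrival foot.

    Baseline mean and sd come from the first ``k_baseline`` frames.  The
    foot is the frame before the first frame whose value exceeds
    ``baseline + threshold_sd * sd`` (clamped to 0).  With noise-free data
    the sd is 0 and any strict rise above baseline triggers arrival.

    Raises
    ------
    NoEnhancementError
        If no frame ever exceeds the threshold (flat curve).
    """
    if k_baseline < 3:
        raise ParameterError("k_baseline must be >= 3")
    if len(curve) <= k_baseline:
        raise ParameterError("curve must be longer than k_baseline")
    if threshold_sd < 0:
        raise ParameterError("threshold_sd must be >= 0")
    base = curve.values[:k_baseline]
    mean = float(np.mean(base))
    sd = float(np.std(base, ddof=1))
    above = np.nonzero(curve.values > mean + threshold_sd * sd)[0]
    if above.size == 0:
        raise NoEnhancementError(
            f"curve {curve.region!r} never rises above baseline "
            f"{mean:.3g} + {threshold_sd:g} sd"
        )
    foot = max(int(above[0]) - 1, 0)
    return BaselineFoot(baseline_mean=mean, baseline_sd=sd, foot_frame=foot)


def _window_slopes(values: np.ndarray, starts: np.ndarray, length: int):
    """OLS slope/intercept/r^2 of value-vs-frame for each candidate window."""
    x = np.arange(length, dtype=float)
    x_mean = x.mean()
    x_var = np.sum((x - x_mean) ** 2)
    windows = np.lib.stride_tricks.sliding_window_view(values, length)[starts]
    y_mean = windows.mean(axis=1)
    cov = np.sum((x - x_mean) * (windows - y_mean[:, None]), axis=1)
    slopes = cov / x_var
    # intercept relative to window start; r^2 of the fit
    resid = windows - (y_mean[:, None] + slopes[:, None] * (x - x_mean))
    ss_res = np.sum(resid**2, axis=1)
    ss_tot = np.sum((windows - y_mean[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    intercept_local = y_mean - slopes * x_mean
    return slopes, intercept_local, r2


def max_upslope(
    curve: TimeIntensityCurve,
    window_len: int = 3,
    k_baseline: int = 5,
    threshold_sd: float = 2.0,
    smooth: bool = False,
) -> UpslopeEstimate:
    """Steepest linear up-slope between contrast arrival and first-pass peak.

    Every contiguous window of ``window_len`` frames starting at or after
    the foot and ending at or before the curve's global maximum is fit by
    ordinary least squares (value vs frame); the window with the maximal
    slope wins, ties broken by the earliest window.  Restricting the search
    to [foot, peak] excludes the recirculation phase.

    Raises
    ------
    InsufficientRiseError
        If fewer than ``window_len`` frames lie between foot and peak.
    NoEnhancementError
        If the curve is flat (propagated from foot detection).
    """
    if window_len < MIN_WINDOW:
        raise ParameterError(f"window_len must be >= {MIN_WINDOW}")
    bf = estimate_baseline_foot(curve, k_baseline=k_baseline, threshold_sd=threshold_sd)
    values = moving_average_3(curve.values) if smooth else np.asarray(curve.values, float)
    peak = int(np.argmax(values))
    last_start = peak - window_len + 1
    if last_start < bf.foot_frame:
        raise InsufficientRiseError(
            f"curve {curve.region!r}: rise from foot {bf.foot_frame} to peak "
            f"{peak} is shorter than window_len={window_len}"
        )
    starts = np.arange(bf.foot_frame, last_start + 1)
    slopes, intercept_local, r2 = _window_slopes(values, starts, window_len)
    best = int(np.argmax(slopes))  # first occurrence wins ties
    s0 = int(starts[best])
    return UpslopeEstimate(
        slope=float(slopes[best]),
        window_start=s0,
        window_end=s0 + window_len - 1,
        # convert the local intercept to absolute frame coordinates
        intercept=float(intercept_local[best] - slopes[best] * s0),
        r_squared=float(r2[best]),
        baseline_mean=bf.baseline_mean,
        foot_frame=bf.foot_frame,
        region=curve.region,
        state=curve.state,
    )


@dataclass(frozen=True)
class NormalizedUpslopeSet:
    """Per-sector myocardial up-slopes normalized to the blood pool.

    Values are ``100 * sector_slope / blood_slope`` when ``times100`` (the
    reporting convention), else the pure ratio; ``mean`` is the arithmetic
    mean over sectors.  Because all sectors share the blood-pool
    denominator, normalizing then averaging equals averaging then
    normalizing.
    """

    per_sector: dict[str, float]
    mean: float
    blood_slope: float
    state: str | None = None
    times100: bool = True


def normalize_upslopes(
    sector_estimates: dict[str, UpslopeEstimate] | list[UpslopeEstimate],
    blood: UpslopeEstimate,
    times100: bool = True,
) -> NormalizedUpslopeSet:
    """Normalize myocardial up-slopes to the LV-cavity up-slope."""
    if blood.slope <= 0:
        raise NormalizationError(
            f"blood-pool up-slope must be positive, got {blood.slope:.3g}"
        )
    if isinstance(sector_estimates, dict):
        items = list(sector_estimates.items())
    else:
        items = []
        seen: set[str] = set()
        for i, e in enumerate(sector_estimates):
            name = e.region or f"sector_{i}"
            if name in seen:  # keep duplicates distinct rather than overwrite
                name = f"{name}_{i}"
            seen.add(name)
            items.append((name, e))
    if not items:
        raise ParameterError("need at least one sector estimate")
    scale = 100.0 if times100 else 1.0
    per_sector = {name: scale * e.slope / blood.slope for name, e in items}
    mean = float(np.mean(list(per_sector.values())))
    state = items[0][1].state if items else None
    return NormalizedUpslopeSet(
        per_sector=per_sector, mean=mean, blood_slope=blood.slope,
        state=state, times100=times100,
    )
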