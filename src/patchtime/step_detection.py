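"""Detection of discrete firing-rate state transitions via bounded sigmoid fits.

Units that time the post-reward interval switch between a high and a low
firing-rate state at a characteristic delay after each reward. The detector:

1. computes each unit's instantaneous rate as one over the interspike
   interval on a 10 ms grid;
2. pools all post-reward responses and fits a single "session" sigmoid to the
   unsmoothed rates, establishing the unit's low/high states and polarity;
3. refits every reward-to-reward and reward-to-exit interval with the offset
   and height bounded near the session values, a minimum absolute center
   slope of 11 (spikes/s)/s so shallow ramps cannot pass as steps, and the
   center confined to the interval ±10%. A fit succeeds when the center
   lands at least 100 ms inside the interval; flat or ramping intervals push
   the center to a bound and fail;
4. classifies a unit as step-like when steps are found on at least half of
   the intervals longer than the unit's mean step time plus one SD.

The sigmoid is a 4-parameter logistic reported as (y_offset, height, slope,
center) where slope is the derivative at the center in (spikes/s)/s, so the
slope bound is applied in those units regardless of parameterization.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

log = logging.getLogger(__name__)

__all__ = [
    "RateSeries",
    "SigmoidParams",
    "IntervalStepFit",
    "UnitStepProfile",
    "StepDetectionConfig",
    "instantaneous_rate",
    "fit_session_sigmoid",
    "fit_interval_sigmoid",
    "classify_unit",
    "analyze_unit",
]


@dataclass(frozen=True)
class StepDetectionConfig:
    """Tunables of the step detector."""

    rate_bin: float = 0.01
    slope_min: float = 11.0  # (spikes/s)/s at the sigmoid center
    center_margin: float = 0.1  # s inside the interval required for success
    center_slack: float = 0.1  # center bound: interval duration +/- 10%
    state_band: float = 0.2  # y_offset/height bound: +/- 20% of session values
    min_interval_duration: float = 0.3  # shorter intervals cannot hold a valid center
    min_intervals: int = 10
    min_eligible: int = 5
    min_height: float = 3.0  # Hz; smaller session contrast means no detectable step
    min_height_z: float = 3.0  # pre/post contrast in autocorrelation-corrected SEs
    refine_step: bool = True  # ML changepoint refinement of successful centers
    refine_window: float = 0.3  # s around the sigmoid center searched by the MLE
    n_center_starts: int = 1  # deterministic evenly-spaced center initializations


@dataclass
class RateSeries:
    """Instantaneous firing rate on a fixed bin grid within one interval."""

    bin_starts: np.ndarray
    rate: np.ndarray
    unit_id: int | str = 0
    interval_id: tuple | int | None = None


@dataclass(frozen=True)
class SigmoidParams:
    """4-parameter logistic: y_offset + height / (1 + exp(-k (t - center)))
    with the slope reported as the derivative at the center, k*height/4."""

    y_offset: float
    height: float
    slope: float
    center: float


@dataclass
class IntervalStepFit:
    """Sigmoid fit of one interval; ``step_time`` is the center when successful."""

    interval_id: tuple | int
    params: SigmoidParams | None
    success: bool
    step_time: float
    interval_duration: float
    interval_kind: str = "reward_reward"
    reason: str = ""


@dataclass
class UnitStepProfile:
    """Unit-level classification from its interval fits."""

    unit_id: int | str
    is_step_like: bool
    polarity: str
    mean_step_time: float
    step_time_sd: float
    fits: list = field(default_factory=list)
    n_eligible: int = 0
    n_success_on_eligible: int = 0
    session_params: SigmoidParams | None = None


def instantaneous_rate(
    spikes: np.ndarray, window: tuple[float, float], bin: float = 0.01,
    unit_id=0, interval_id=None,
) -> RateSeries:
    """Rate = 1 / (interspike interval covering each bin center).

    The enclosing interspike interval is taken from the full spike train, so
    intervals spanning the window edges use the true neighboring spikes; only
    when no spike exists beyond an edge (start or end of the recording) is
    the gap to the window edge used instead. A window with no spikes at all
    gets rate 0.
    """
    spikes = np.asarray(spikes, float)
    if np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted ascending")
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive duration")
    starts = np.arange(t0, t1 - bin / 2, bin)
    centers = starts + bin / 2
    if len(spikes) == 0:
        return RateSeries(starts - t0, np.zeros(len(starts)), unit_id, interval_id)
    # pad with the window edges only where the train itself has no spike beyond
    bounds = spikes
    if spikes[0] > t0:
        bounds = np.concatenate([[min(t0, spikes[0] - 1e-9)], bounds])
    if spikes[-1] < t1:
        bounds = np.concatenate([bounds, [max(t1, spikes[-1] + 1e-9)]])
    idx = np.searchsorted(bounds, centers, side="right")
    idx = np.clip(idx, 1, len(bounds) - 1)
    isi = bounds[idx] - bounds[idx - 1]
    rate = np.where(isi > 0, 1.0 / np.where(isi > 0, isi, 1.0), 0.0)
    return RateSeries(starts - t0, rate, unit_id, interval_id)


def _logistic(t, y0, h, k, c):
    z = np.clip(-k * (t - c), -500, 500)
    return y0 + h / (1.0 + np.exp(z))


def _sig(t, k, c):
    z = np.clip(-k * (t - c), -500, 500)
    return 1.0 / (1.0 + np.exp(z))


def _logistic_jac(t, y0, h, k, c):
    s = _sig(t, k, c)
    sp = s * (1.0 - s)
    return np.column_stack([
        np.ones_like(t),        # d/dy0
        s,                      # d/dh
        h * sp * (t - c),       # d/dk
        -h * sp * k,            # d/dc
    ])


def fit_session_sigmoid(
    t: np.ndarray, rate: np.ndarray, maxfev: int = 5000
) -> SigmoidParams | None:
    """Fit one sigmoid to a unit's pooled post-reward rates.

    ``t`` is time from interval start pooled across all intervals (no
    truncation or alignment beyond the interval start). Returns None on
    non-convergence; callers skip the unit with a log entry.
    """
    t = np.asarray(t, float)
    rate = np.asarray(rate, float)
    if len(t) < 8:
        return None
    # lexicographic order makes the fit invariant to interval ordering even
    # with tied time points pooled from different intervals
    order = np.lexsort((rate, t))
    t, rate = t[order], rate[order]
    lo = rate[: max(1, len(t) // 5)].mean()
    hi = rate[-max(1, len(t) // 5):].mean()
    h0 = hi - lo
    if h0 == 0:
        h0 = 1e-3
    p0 = [lo, h0, 5.0, float(np.median(t))]
    span = float(t[-1] - t[0]) or 1.0
    rmax = float(rate.max()) or 1.0
    bounds = (
        [-2 * rmax, -4 * rmax, 1e-3, float(t[0]) - span],
        [2 * rmax, 4 * rmax, 1e4, float(t[-1]) + span],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(_logistic, t, rate, p0=p0, bounds=bounds,
                                   jac=_logistic_jac, maxfev=maxfev)
    except (RuntimeError, ValueError) as err:
        log.info("session sigmoid did not converge: %s", err)
        return None
    y0, h, k, c = popt
    return SigmoidParams(float(y0), float(h), float(k * h / 4.0), float(c))


def contrast_zscore(
    t: np.ndarray, rate: np.ndarray, center: float, rate_bin: float = 0.01
) -> float:
    """Significance of a unit's pre/post contrast around the session center.

    Welch-style z between pooled rates before and after the session sigmoid's
    center. Consecutive rate bins within one interspike interval carry no
    independent information, so each side's effective sample size is its
    approximate spike count (mean rate x total binned time) rather than its
    bin count. Units with no two-state structure score near zero.
    """
    t = np.asarray(t, float)
    rate = np.asarray(rate, float)
    c = float(np.clip(center, np.quantile(t, 0.05), np.quantile(t, 0.95)))
    pre, post = rate[t < c], rate[t >= c]
    if len(pre) < 2 or len(post) < 2:
        return 0.0
    n1 = max(pre.mean() * len(pre) * rate_bin, 1.0)
    n2 = max(post.mean() * len(post) * rate_bin, 1.0)
    denom = math.sqrt(pre.var() / n1 + post.var() / n2)
    return abs(post.mean() - pre.mean()) / denom if denom > 0 else math.inf


def ml_changepoint(
    spikes_rel: np.ndarray, duration: float, center: float,
    window: float = 0.5, margin: float = 0.1, grid: float = 1e-3,
) -> float:
    """Maximum-likelihood transition time for a two-state Poisson interval.

    Profiles the piecewise-constant Poisson likelihood over candidate split
    times near the sigmoid ``center`` (which gates that a step exists and
    roughly where); the MLE localizes the transition to spike resolution
    instead of the rate-bin straddle. Returns ``center`` unchanged when the
    search window is empty.
    """
    lo = max(margin, center - window)
    hi = min(duration - margin, center + window)
    if hi <= lo:
        return center
    cand = np.arange(lo, hi, grid)
    n1 = np.searchsorted(spikes_rel, cand).astype(float)
    n_tot = float(len(spikes_rel))
    n2 = n_tot - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(n1 > 0, n1 * np.log(n1 / cand), 0.0) + np.where(
            n2 > 0, n2 * np.log(n2 / (duration - cand)), 0.0
        )
    return float(cand[int(np.argmax(ll))])


def _band(value: float, frac: float, floor: float = 0.5) -> tuple[float, float]:
    """Symmetric bound around ``value`` with a minimum half-width ``floor`` Hz."""
    half = max(frac * abs(value), floor * frac)
    return value - half, value + half


def fit_interval_sigmoid(
    series: RateSeries,
    seed_params: SigmoidParams,
    duration: float,
    config: StepDetectionConfig = StepDetectionConfig(),
    kind: str = "reward_reward",
    maxfev: int = 200,
) -> IntervalStepFit:
    """Bounded sigmoid fit of one interval, seeded from the session fit.

    y_offset and height are confined to ±20% of the session values (forcing
    the fit to match the unit's identified low/high states), |slope| at the
    center must exceed the minimum (rejecting shallow ramps), and the center
    may roam the interval ±10%. Success requires the fitted center at least
    ``center_margin`` inside the interval; otherwise the optimizer saturates
    the center at a bound, fitting the interval as all-low or all-high.
    """
    iid = series.interval_id if series.interval_id is not None else 0
    if duration < config.min_interval_duration:
        return IntervalStepFit(iid, None, False, np.nan, duration, kind, "too_short")
    h_s = seed_params.height
    if h_s == 0:
        return IntervalStepFit(iid, None, False, np.nan, duration, kind, "flat_session")
    sgn = 1.0 if h_s > 0 else -1.0

    def model(t, y0, h, m, c):
        k = 4.0 * m / h
        return _logistic(t, y0, h, k, c)

    def model_jac(t, y0, h, m, c):
        k = 4.0 * m / h
        s = _sig(t, k, c)
        sp = s * (1.0 - s)
        return np.column_stack([
            np.ones_like(t),                       # d/dy0
            s - 4.0 * m * (t - c) * sp / h,        # d/dh (k depends on h)
            4.0 * (t - c) * sp,                    # d/dm
            -4.0 * m * sp,                         # d/dc
        ])

    y_lo, y_hi = _band(seed_params.y_offset, config.state_band)
    y_lo = max(y_lo, -1e-9) if seed_params.y_offset >= 0 else y_lo
    h_lo, h_hi = sorted(_band(h_s, config.state_band))
    # slopes above ~100x the minimum are indistinguishable from instantaneous
    # steps on a 10 ms rate grid; the cap keeps the problem well-scaled
    m_cap = max(100.0 * config.slope_min, 10.0 * abs(h_s) / config.rate_bin)
    m_lo, m_hi = (config.slope_min, m_cap) if sgn > 0 else (-m_cap, -config.slope_min)
    c_lo, c_hi = -config.center_slack * duration, (1.0 + config.center_slack) * duration

    m0 = sgn * max(config.slope_min * 1.5, abs(seed_params.slope))
    t, r = series.bin_starts + (series.bin_starts[1] - series.bin_starts[0]) / 2, series.rate
    n_starts = max(1, config.n_center_starts)
    c_inits = (np.arange(n_starts) + 1.0) / (n_starts + 1.0) * duration
    best, best_sse = None, np.inf
    err = None
    for c0 in c_inits:
        p0 = [
            float(np.clip(seed_params.y_offset, y_lo, y_hi)),
            float(np.clip(h_s, h_lo, h_hi)),
            float(np.clip(m0, m_lo, m_hi)),
            float(np.clip(c0, c_lo, c_hi)),
        ]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, t, r, p0=p0,
                    bounds=([y_lo, h_lo, m_lo, c_lo], [y_hi, h_hi, m_hi, c_hi]),
                    jac=model_jac, maxfev=maxfev,
                    x_scale=[max(abs(seed_params.y_offset), 1.0), max(abs(h_s), 1.0),
                             10.0 * config.slope_min, max(duration / 10.0, 0.1)],
                    ftol=1e-4, xtol=1e-4, gtol=1e-4,
                )
        except (RuntimeError, ValueError) as e:
            err = e
            continue
        sse = float(((r - model(t, *popt)) ** 2).sum())
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        return IntervalStepFit(iid, None, False, np.nan, duration, kind,
                               f"no_convergence: {err}")
    y0, h, m, c = (float(v) for v in best)
    params = SigmoidParams(y0, h, m, c)
    ok = config.center_margin <= c <= duration - config.center_margin
    return IntervalStepFit(
        iid, params, bool(ok), c if ok else np.nan, duration, kind,
        "" if ok else "center_at_bound",
    )


def classify_unit(
    fits: list[IntervalStepFit],
    session_params: SigmoidParams | None,
    unit_id=0,
    config: StepDetectionConfig = StepDetectionConfig(),
    session_height_z: float = math.inf,
) -> UnitStepProfile:
    """Step-like classification from a unit's interval fits.

    Mean and SD of step time come from all successful fits; eligible
    intervals are those longer than mean + SD, and the unit is step-like when
    at least half the eligible intervals (with a minimum count) yielded a
    successful fit and the session contrast is both large enough
    (``min_height``) and statistically distinguishable from zero
    (``min_height_z``, guarding against rate-noise fits on units with no
    two-state structure). Polarity follows the sign of the session height.
    """
    succ = [f for f in fits if f.success]
    if session_params is None:
        return UnitStepProfile(unit_id, False, "unknown", np.nan, np.nan, fits)
    polarity = "off_on" if session_params.height > 0 else "on_off"
    if not succ:
        return UnitStepProfile(unit_id, False, polarity, np.nan, np.nan, fits,
                               session_params=session_params)
    times = np.array([f.step_time for f in succ])
    mean = float(times.mean())
    sd = float(times.std(ddof=1)) if len(times) > 1 else 0.0
    eligible = [f for f in fits if f.interval_duration > mean + sd]
    n_ok = sum(f.success for f in eligible)
    is_step = (
        len(fits) >= config.min_intervals
        and len(eligible) >= config.min_eligible
        and n_ok / len(eligible) >= 0.5
        and abs(session_params.height) >= config.min_height
        and session_height_z >= config.min_height_z
    )
    return UnitStepProfile(
        unit_id, bool(is_step), polarity, mean, sd, fits,
        n_eligible=len(eligible), n_success_on_eligible=int(n_ok),
        session_params=session_params,
    )


def analyze_unit(
    spikes: np.ndarray,
    intervals,
    unit_id=0,
    config: StepDetectionConfig = StepDetectionConfig(),
) -> UnitStepProfile:
    """Full per-unit pipeline: rates, session sigmoid, interval fits, class.

    ``intervals`` is a DataFrame with columns (visit, epoch, start, end,
    kind), e.g. from :func:`patchtime.behavior_analysis.reward_intervals`.
    Interval fit results are order-invariant: each interval is fit
    independently from the same session seed.
    """
    spikes = np.asarray(spikes, float)
    series_list = []
    for row in intervals.itertuples(index=False):
        s = instantaneous_rate(
            spikes, (row.start, row.end), bin=config.rate_bin,
            unit_id=unit_id, interval_id=(row.visit, row.epoch),
        )
        series_list.append((s, row))
    pooled_t = np.concatenate([s.bin_starts + config.rate_bin / 2 for s, _ in series_list])
    pooled_r = np.concatenate([s.rate for s, _ in series_list])
    session = fit_session_sigmoid(pooled_t, pooled_r)
    if session is None:
        log.info("unit %s skipped: session sigmoid did not converge", unit_id)
        return UnitStepProfile(unit_id, False, "unknown", np.nan, np.nan, [])
    height_z = contrast_zscore(pooled_t, pooled_r, session.center, config.rate_bin)
    fits = []
    for s, row in series_list:
        duration = float(row.end - row.start)
        f = fit_interval_sigmoid(s, session, duration, config, row.kind)
        if f.success and config.refine_step:
            rel = spikes[(spikes >= row.start) & (spikes < row.end)] - row.start
            f.step_time = ml_changepoint(
                rel, duration, f.step_time,
                window=config.refine_window, margin=config.center_margin,
            )
        fits.append(f)
    return classify_unit(fits, session, unit_id, config, session_height_z=height_z)
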