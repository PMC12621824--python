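"""Population accumulation-to-threshold model of patch exit.

After each reward, step-like units switch to their post-transition state at
staggered delays, so the running count of transitioned units grows roughly
linearly over the waiting epoch. A line is fit to the count in every
reward-to-reward and reward-to-exit interval; the mean count at true exits
defines a threshold, and the time where each interval's line crosses the
threshold is the neurally predicted exit time. The model's signatures are a
negative correlation between accumulation slope and exit time (the count
ramps faster when the animal will leave sooner) and an intercept that does
not track exit time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .step_detection import UnitStepProfile

log = logging.getLogger(__name__)

__all__ = [
    "AccumulationCurve",
    "ThresholdModel",
    "SessionSkipped",
    "build_accumulation",
    "fit_threshold_model",
]


class SessionSkipped(RuntimeError):
    """Raised when a session lacks enough step-like units for the model."""


@dataclass
class AccumulationCurve:
    """Cumulative transitioned-unit count in one interval plus its line fit.

    The count is a nondecreasing integer step function starting at 0 at the
    interval start. The line is ordinary least squares on the step function's
    support points: (0, 0), each transition's post-jump value, and the final
    value at the interval end.
    """

    interval_id: tuple
    interval_kind: str
    times: np.ndarray  # transition times, seconds from interval start
    duration: float
    slope: float
    intercept: float
    r_squared: float

    @property
    def final_count(self) -> int:
        return len(self.times)

    def count_at(self, t: float) -> int:
        return int(np.searchsorted(self.times, t, side="right"))


@dataclass
class ThresholdModel:
    """Accumulate-to-threshold exit prediction for one session."""

    session_id: str
    n_step_units: int
    threshold: float
    predictions: pd.DataFrame  # per reward-exit interval: true & predicted exit
    slope_exit_r: float
    slope_exit_p: float
    intercept_exit_r: float
    intercept_exit_p: float
    predicted_true_r: float
    predicted_true_p: float
    n_unavailable: int = 0
    reward_reward: dict = field(default_factory=dict)


def _fit_line(times: np.ndarray, duration: float) -> tuple[float, float, float]:
    """OLS on the accumulation step function's support points."""
    k = len(times)
    x = np.concatenate([[0.0], times, [duration]])
    y = np.concatenate([[0.0], np.arange(1, k + 1, dtype=float), [float(k)]])
    if len(np.unique(x)) < 2:
        return np.nan, np.nan, np.nan
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def build_accumulation(
    profiles: list[UnitStepProfile],
    intervals: pd.DataFrame,
    min_step_units: int = 6,
) -> list[AccumulationCurve]:
    """Per-interval cumulative transition counts over the step-like units.

    A unit counts as transitioned from its detected step time onward (both
    polarities count on reaching their post-step state); a unit with no
    successful fit in an interval never counts there. Sessions with fewer
    than ``min_step_units`` step-like units are skipped.
    """
    step_units = [p for p in profiles if p.is_step_like]
    if len(step_units) < min_step_units:
        raise SessionSkipped(
            f"skipped: {len(step_units)} step-like units < {min_step_units}"
        )
    by_interval: dict[tuple, list[float]] = {}
    for p in step_units:
        for f in p.fits:
            if f.success:
                by_interval.setdefault(tuple(f.interval_id), []).append(f.step_time)
    curves = []
    for row in intervals.itertuples(index=False):
        iid = (row.visit, row.epoch)
        times = np.sort(np.asarray(by_interval.get(iid, []), float))
        dur = float(row.end - row.start)
        slope, intercept, r2 = _fit_line(times, dur) if len(times) else (0.0, 0.0, np.nan)
        curves.append(
            AccumulationCurve(iid, row.kind, times, dur, slope, intercept, r2)
        )
    return curves


def _pearson(x, y) -> tuple[float, float]:
    x, y = np.asarray(x, float), np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def fit_threshold_model(
    curves: list[AccumulationCurve],
    projected: pd.DataFrame | None = None,
    session_id: str = "session",
    n_step_units: int | None = None,
    min_exit_intervals: int = 5,
) -> ThresholdModel:
    """Threshold, exit predictions, and slope/intercept-exit correlations.

    The threshold is the mean transitioned count at true exits (final counts
    of reward-exit intervals). A prediction exists for an interval when its
    fitted line reaches the threshold with positive slope; non-crossing lines
    are counted as unavailable. ``projected`` (from
    :func:`patchtime.behavior_analysis.project_exit_times`) supplies the
    behaviorally projected exit for reward-to-reward intervals, keyed by
    (visit, epoch).
    """
    exits = [c for c in curves if c.interval_kind == "reward_exit"]
    if len(exits) < min_exit_intervals:
        raise SessionSkipped(
            f"skipped: {len(exits)} reward-exit intervals < {min_exit_intervals}"
        )
    threshold = float(np.mean([c.final_count for c in exits]))

    def predict(c: AccumulationCurve) -> float:
        if not np.isfinite(c.slope) or c.slope <= 0:
            return np.nan
        t = (threshold - c.intercept) / c.slope
        return t if t >= 0 else np.nan

    rows = []
    for c in exits:
        rows.append(
            dict(visit=c.interval_id[0], epoch=c.interval_id[1],
                 true_exit=c.duration, predicted_exit=predict(c),
                 slope=c.slope, intercept=c.intercept, final_count=c.final_count)
        )
    pred = pd.DataFrame(
        rows, columns=["visit", "epoch", "true_exit", "predicted_exit",
                       "slope", "intercept", "final_count"],
    )
    n_unavail = int(pred["predicted_exit"].isna().sum())
    sr, sp = _pearson(pred["slope"], pred["true_exit"])
    ir, ip = _pearson(pred["intercept"], pred["true_exit"])
    pr, pp = _pearson(pred["predicted_exit"], pred["true_exit"])

    rr_stats: dict = {}
    if projected is not None and len(projected):
        key = projected.set_index(["visit", "epoch"])["projected_exit_from_reward"]
        rr = [c for c in curves if c.interval_kind == "reward_reward"]
        proj, slopes, inters, preds = [], [], [], []
        for c in rr:
            v = key.get(tuple(c.interval_id), np.nan)
            proj.append(v)
            slopes.append(c.slope)
            inters.append(c.intercept)
            preds.append(predict(c))
        rr_stats = dict(
            slope_projected_r=_pearson(slopes, proj)[0],
            intercept_projected_r=_pearson(inters, proj)[0],
            predicted_projected_r=_pearson(preds, proj)[0],
            n=len(rr),
        )
    return ThresholdModel(
        session_id=session_id,
        n_step_units=n_step_units if n_step_units is not None else -1,
        threshold=threshold,
        predictions=pred,
        slope_exit_r=sr, slope_exit_p=sp,
        intercept_exit_r=ir, intercept_exit_p=ip,
        predicted_true_r=pr, predicted_true_p=pp,
        n_unavailable=n_unavail,
        reward_reward=rr_stats,
    )
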