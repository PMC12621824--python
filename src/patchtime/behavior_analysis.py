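"""Behavioral characterization: trial table, leaving hazard, stay/leave SVM,
and projected exit times.

The central behavioral quantity is the hazard of leaving the patch — the
probability of exiting in a time bin given the animal is still in the patch
at the bin's start — aligned either to patch entry or to the most recent
reward. A linear SVM over 10 ms time bins ranks the contribution of time
since reward, time since entry, and reward-rate context to the stay/leave
decision, and a per-context linear regression of exit-from-last-reward on
last-reward time projects, for every reward, how long the animal would have
waited had no further reward arrived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import SessionEvents

__all__ = [
    "HazardCurve",
    "StayLeaveWeights",
    "ProjectedExits",
    "build_trial_table",
    "leaving_hazard",
    "fit_stay_leave_svm",
    "project_exit_times",
    "reward_intervals",
]


@dataclass
class HazardCurve:
    """Discrete leaving hazard for one group of trials or epochs."""

    bin_edges: np.ndarray
    hazard: np.ndarray
    n_at_risk: np.ndarray
    grouping: str

    def survival(self) -> np.ndarray:
        """Empirical survival implied by the hazard: cumprod of (1 - hazard)."""
        return np.cumprod(1.0 - self.hazard)


@dataclass(frozen=True)
class StayLeaveWeights:
    """Normalized-feature coefficients of the linear stay/leave classifier."""

    coef_time_from_reward: float
    coef_time_from_entry: float
    coef_context: float
    n_stay: int
    n_leave: int


@dataclass
class ProjectedExits:
    """Per-reward projected exit times and the per-context regressions.

    ``regressions`` maps context -> dict(slope, intercept, n) or None when a
    context has too few rewarded trials. ``projections`` has one row per
    patch reward with its projected exit-from-reward (NaN if the context's
    regression is unavailable).
    """

    regressions: dict
    projections: pd.DataFrame


def build_trial_table(events: SessionEvents) -> pd.DataFrame:
    """One row per completed patch visit; a truncated final visit is dropped.

    Columns: visit, entry_time, exit_time, context, reward_times (array,
    relative to entry), n_rewards, occupancy, last_reward_time,
    exit_from_last_reward (NaN for visits with no reward).
    """
    rows = []
    entry = None
    ctx = None
    rewards: list[float] = []
    visit = 0
    for rec in events.records.itertuples(index=False):
        if rec.event == "patch_entry":
            if entry is not None:
                raise ValueError(f"patch_entry at t={rec.time} without prior exit")
            entry, ctx, rewards = rec.time, rec.context, []
        elif rec.event == "patch_reward":
            if entry is None:
                raise ValueError(f"patch_reward at t={rec.time} outside a patch visit")
            rewards.append(rec.time - entry)
        elif rec.event == "patch_exit":
            if entry is None:
                raise ValueError(f"patch_exit at t={rec.time} without prior entry")
            occ = rec.time - entry
            last = rewards[-1] if rewards else np.nan
            rows.append(
                dict(visit=visit, entry_time=entry, exit_time=rec.time, context=ctx,
                     reward_times=np.asarray(rewards), n_rewards=len(rewards),
                     occupancy=occ, last_reward_time=last,
                     exit_from_last_reward=occ - last if rewards else np.nan)
            )
            visit += 1
            entry = None
    return pd.DataFrame(
        rows,
        columns=["visit", "entry_time", "exit_time", "context", "reward_times",
                 "n_rewards", "occupancy", "last_reward_time", "exit_from_last_reward"],
    )


def reward_intervals(table: pd.DataFrame) -> pd.DataFrame:
    """Waiting epochs starting at each patch reward.

    One row per reward with the epoch end (next reward or exit), its kind
    (reward_reward | reward_exit), and its duration. Keys (visit, epoch)
    match the generator's epoch indexing (epoch 0 is the entry epoch, so the
    k-th reward starts epoch k).
    """
    rows = []
    for tr in table.itertuples(index=False):
        r = tr.reward_times
        for k in range(len(r)):
            start = tr.entry_time + r[k]
            if k + 1 < len(r):
                end, kind = tr.entry_time + r[k + 1], "reward_reward"
            else:
                end, kind = tr.exit_time, "reward_exit"
            rows.append(
                dict(visit=tr.visit, epoch=k + 1, start=start, end=end, kind=kind,
                     duration=end - start, context=tr.context,
                     reward_time_from_entry=r[k])
            )
    return pd.DataFrame(
        rows,
        columns=["visit", "epoch", "start", "end", "kind", "duration", "context",
                 "reward_time_from_entry"],
    )


def _hazard_from_durations(durations, observed, edges) -> tuple[np.ndarray, np.ndarray]:
    """Discrete hazard from (possibly right-censored) waiting times.

    ``observed`` marks epochs ending in an exit; censored epochs count as
    at-risk up to their censoring time with no event.
    """
    durations = np.asarray(durations, float)
    observed = np.asarray(observed, bool)
    hazard = np.zeros(len(edges) - 1)
    at_risk = np.zeros(len(edges) - 1, dtype=int)
    for b in range(len(edges) - 1):
        risk = durations >= edges[b]
        at_risk[b] = int(risk.sum())
        ev = risk & observed & (durations < edges[b + 1])
        hazard[b] = ev.sum() / at_risk[b] if at_risk[b] > 0 else 0.0
    return hazard, at_risk


def leaving_hazard(
    table: pd.DataFrame,
    align: str = "entry",
    bin: float = 0.25,
    group_by: str = "context",
    max_time: float | None = None,
    strata_edges=(0.0, 2.0, 4.0, 7.0, np.inf),
) -> list[HazardCurve]:
    """Leaving hazard curves aligned to patch entry or to the last reward.

    With ``align='entry'`` each visit contributes its occupancy. With
    ``align='last_reward'`` every reward-to-(next reward | exit) epoch
    contributes; epochs ending in a new reward are censored at that reward.
    ``group_by`` is "context", "reward_time" (strata of the epoch's reward
    time from entry, edges in ``strata_edges``), or "none". Empty groups
    yield empty curves.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    if align == "entry":
        df = table[["occupancy", "context"]].copy()
        df["duration"] = df.pop("occupancy")
        df["observed"] = True
        df["reward_time_from_entry"] = np.nan
    elif align == "last_reward":
        ep = reward_intervals(table)
        df = ep[["duration", "context", "reward_time_from_entry"]].copy()
        df["observed"] = (ep["kind"] == "reward_exit").to_numpy()
    else:
        raise ValueError("align must be 'entry' or 'last_reward'")

    if group_by == "context":
        groups = [(c, df[df["context"] == c]) for c in ("high", "low")]
    elif group_by == "reward_time":
        if align != "last_reward":
            raise ValueError("reward_time grouping requires align='last_reward'")
        edges = np.asarray(strata_edges, float)
        groups = []
        for i in range(len(edges) - 1):
            m = (df["reward_time_from_entry"] >= edges[i]) & (
                df["reward_time_from_entry"] < edges[i + 1]
            )
            groups.append((f"reward_time[{edges[i]:g},{edges[i+1]:g})", df[m]))
    elif group_by == "none":
        groups = [("all", df)]
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    curves = []
    for label, g in groups:
        if len(g) == 0:
            curves.append(HazardCurve(np.array([0.0]), np.empty(0), np.empty(0, int), label))
            continue
        tmax = max_time if max_time is not None else float(g["duration"].max())
        # one spare bin so events landing exactly on the last edge are counted
        edges = np.arange(0.0, tmax + 2 * bin, bin)
        hz, risk = _hazard_from_durations(g["duration"], g["observed"], edges)
        curves.append(HazardCurve(edges, hz, risk, label))
    return curves


def _stay_leave_features(
    table: pd.DataFrame, bin: float, leave_window: float
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (time_from_reward, time_from_entry, context_low) and labels."""
    X, y = [], []
    for tr in table.itertuples(index=False):
        ctx = 1.0 if tr.context == "low" else 0.0
        n_stay = int(tr.occupancy / bin)
        if n_stay > 0:
            tc = (np.arange(n_stay) + 0.5) * bin  # bin centers from entry
            anchors = np.concatenate([[0.0], tr.reward_times])
            idx = np.searchsorted(anchors, tc, side="right") - 1
            tfr = tc - anchors[idx]
            X.append(np.column_stack([tfr, tc, np.full(n_stay, ctx)]))
            y.append(np.zeros(n_stay, dtype=int))
        n_leave = int(leave_window / bin)
        u = (np.arange(n_leave) + 0.5) * bin
        last = tr.last_reward_time if tr.n_rewards > 0 else 0.0
        X.append(
            np.column_stack([tr.occupancy - last + u, tr.occupancy + u,
                             np.full(n_leave, ctx)])
        )
        y.append(np.ones(n_leave, dtype=int))
    return np.concatenate(X), np.concatenate(y)


def fit_stay_leave_svm(
    table: pd.DataFrame, bin: float = 0.01, leave_window: float = 5.0, C: float = 1.0
) -> StayLeaveWeights:
    """Linear maximum-margin classification of stay vs leave time bins.

    Each visit's occupancy is divided into ``bin`` time bins ("stay"); the
    ``leave_window`` after each exit is binned the same way ("leave"). Bin
    features are the time since the most recent reward (time since entry
    before the first reward), the time since entry, and the low-context
    indicator, z-scored before fitting. Class weights are balanced because
    leave bins are rarer.
    """
    from sklearn.svm import LinearSVC

    if len(table) == 0 or table["occupancy"].isna().all():
        raise ValueError("need at least one completed visit")
    X, y = _stay_leave_features(table, bin, leave_window)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class input")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    clf = LinearSVC(C=C, class_weight="balanced", dual=False)
    clf.fit(Xz, y)
    w = clf.coef_[0]
    return StayLeaveWeights(
        coef_time_from_reward=float(w[0]),
        coef_time_from_entry=float(w[1]),
        coef_context=float(w[2]),
        n_stay=int((y == 0).sum()),
        n_leave=int((y == 1).sum()),
    )


def project_exit_times(table: pd.DataFrame, min_trials: int = 3) -> ProjectedExits:
    """Per-context regression of exit-from-last-reward on last-reward time.

    Fit on final rewards only (visits with >= 1 reward), then applied to
    every reward to produce the exit time the animal was projected to accept
    had that reward been the last. Contexts with fewer than ``min_trials``
    rewarded visits get no regression and NaN projections.
    """
    regressions: dict[str, dict | None] = {}
    for ctx in ("high", "low"):
        sub = table[(table["context"] == ctx) & (table["n_rewards"] > 0)]
        if len(sub) < min_trials:
            regressions[ctx] = None
            continue
        fit = stats.linregress(
            sub["last_reward_time"].to_numpy(), sub["exit_from_last_reward"].to_numpy()
        )
        regressions[ctx] = dict(slope=float(fit.slope), intercept=float(fit.intercept),
                                n=int(len(sub)))

    rows = []
    for tr in table.itertuples(index=False):
        reg = regressions.get(tr.context)
        for k, rt in enumerate(tr.reward_times):
            proj = reg["intercept"] + reg["slope"] * rt if reg else np.nan
            rows.append(
                dict(visit=tr.visit, epoch=k + 1, reward_time_from_entry=float(rt),
                     context=tr.context, projected_exit_from_reward=proj)
            )
    projections = pd.DataFrame(
        rows,
        columns=["visit", "epoch", "reward_time_from_entry", "context",
                 "projected_exit_from_reward"],
    )
    return ProjectedExits(regressions=regressions, projections=projections)
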