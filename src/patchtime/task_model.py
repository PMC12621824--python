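"""Generative structure of the patch-foraging task and the MVT-optimal exit policy.

The task alternates between two nose-poke ports. The *context port* delivers a
fixed number of evenly spaced water rewards over a block-dependent duration
(5 s in "high" reward-rate blocks, 10 s in "low" blocks), setting the
environmental reward rate. The *time-investment port* (the patch) delivers
reward opportunities on a discrete time grid with per-bin Bernoulli
probability that decays exponentially from patch entry,

    p(t) = p0 * exp(-t / tau),

calibrated so that the infinite sum of per-bin probabilities equals a fixed
expected total (8 rewards for an agent that never leaves).

Given this structure, the reward-rate-maximizing exit time follows from the
Marginal Value Theorem (MVT): leave the patch when its instantaneous reward
rate falls to the best achievable overall reward rate of the environment.
Because reward opportunities live on a discrete grid, the overall-rate curve
is piecewise and the optimum is found by exhaustive search over bin starts,
which is exact for this task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field

import numpy as np

__all__ = [
    "TaskConfig",
    "OptimalPolicy",
    "calibrate_hazard_p0",
    "is_calibrated",
    "context_duration",
    "patch_reward_probability",
    "expected_cumulative_rewards",
    "overall_reward_rate",
    "mvt_optimal_exit",
]

CONTEXTS = ("high", "low")


def calibrate_hazard_p0(
    hazard_tau: float, hazard_bin: float, expected_total_rewards: float
) -> float:
    """Solve for the initial per-bin reward probability.

    The per-bin probabilities form a geometric series with ratio
    r = exp(-bin/tau); setting its sum p0 / (1 - r) equal to the expected
    total reward count gives p0 = total * (1 - r).

    Raises ``ValueError`` if the resulting p0 falls outside (0, 1].
    """
    if hazard_tau <= 0 or hazard_bin <= 0:
        raise ValueError("hazard_tau and hazard_bin must be positive")
    p0 = expected_total_rewards * (1.0 - math.exp(-hazard_bin / hazard_tau))
    if not 0.0 < p0 <= 1.0:
        raise ValueError(
            f"calibration gives p0={p0:.4g} outside (0, 1]; "
            "decrease hazard_bin or increase hazard_tau"
        )
    return p0


@dataclass(frozen=True)
class TaskConfig:
    """All task constants: context schedule, patch hazard, session layout.

    ``hazard_p0`` defaults to the value calibrated from ``hazard_tau``,
    ``hazard_bin`` and ``expected_total_rewards`` so that a default-constructed
    config is always calibrated.
    """

    n_context_rewards: int = 4
    context_duration_high: float = 5.0
    context_duration_low: float = 10.0
    travel_time: float = 0.3
    session_duration: float = 1080.0
    block_duration: float = 180.0
    n_blocks: int = 6
    hazard_bin: float = 0.1
    hazard_tau: float = 8.0
    hazard_p0: float = field(default=float("nan"))
    expected_total_rewards: float = 8.0

    def __post_init__(self):
        if math.isnan(self.hazard_p0):
            object.__setattr__(
                self,
                "hazard_p0",
                calibrate_hazard_p0(
                    self.hazard_tau, self.hazard_bin, self.expected_total_rewards
                ),
            )
        if not (0.0 < self.hazard_p0 <= 1.0):
            raise ValueError("hazard_p0 must be in (0, 1]")
        if self.hazard_tau <= 0 or self.hazard_bin <= 0:
            raise ValueError("hazard_tau and hazard_bin must be positive")
        if self.context_duration_low <= self.context_duration_high:
            raise ValueError("context_duration_low must exceed context_duration_high")
        if abs(self.n_blocks * self.block_duration - self.session_duration) > 1e-9:
            raise ValueError("n_blocks * block_duration must equal session_duration")

    def recalibrated(self, **changes) -> "TaskConfig":
        """Return a copy with ``changes`` applied and p0 re-solved."""
        changes.setdefault("hazard_p0", float("nan"))
        return replace(self, **changes)


@dataclass(frozen=True)
class OptimalPolicy:
    """MVT-optimal exit for one context.

    ``bounded`` is False when the overall-rate curve has no interior maximum
    (a non-depleting patch), in which case ``optimal_exit_time`` is +inf.
    ``stationarity_gap`` is the relative difference between the instantaneous
    patch reward rate at the optimum and the achieved overall rate — the MVT
    stationarity condition, which holds only approximately on a discrete
    reward grid.
    """

    context: str
    optimal_exit_time: float
    achieved_overall_rate: float
    bounded: bool = True
    stationarity_gap: float = float("nan")


def is_calibrated(config: TaskConfig, tol: float = 1e-6) -> bool:
    """Whether the per-bin probability series sums to the expected total."""
    r = math.exp(-config.hazard_bin / config.hazard_tau)
    total = config.hazard_p0 / (1.0 - r)
    return abs(total - config.expected_total_rewards) <= tol


def context_duration(config: TaskConfig, context: str) -> float:
    if context == "high":
        return config.context_duration_high
    if context == "low":
        return config.context_duration_low
    raise ValueError(f"unknown context {context!r}")


def patch_reward_probability(config: TaskConfig, t):
    """Per-bin reward probability at time ``t`` since patch entry.

    Accepts scalars or arrays; strictly decreasing in t, in (0, p0].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = config.hazard_p0 * np.exp(-t / config.hazard_tau)
    return float(out) if out.ndim == 0 else out


def expected_cumulative_rewards(config: TaskConfig, t):
    """Expected rewards from bins fully contained in [0, t).

    Bin k covers [k*bin, (k+1)*bin) and contributes p0 * exp(-k*bin/tau); the
    partial sum has the closed form p0 * (1 - r**n) / (1 - r) with
    r = exp(-bin/tau) and n = floor(t / bin). Nondecreasing in t with limit
    ``expected_total_rewards``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    # tolerance absorbs float error of grid points sitting an ulp below an edge
    n = np.floor(t / config.hazard_bin + 1e-9)
    r = math.exp(-config.hazard_bin / config.hazard_tau)
    out = config.hazard_p0 * (1.0 - r**n) / (1.0 - r)
    return float(out) if out.ndim == 0 else out


def overall_reward_rate(config: TaskConfig, exit_time, context: str):
    """Overall reward rate of the full context-patch cycle.

    (expected patch rewards by ``exit_time`` + context rewards) divided by the
    cycle duration (patch occupancy + context duration + two travels).
    """
    exit_time = np.asarray(exit_time, dtype=float)
    if np.any(exit_time <= 0):
        raise ValueError("exit_time must be positive")
    cycle = exit_time + context_duration(config, context) + 2.0 * config.travel_time
    out = (expected_cumulative_rewards(config, exit_time) + config.n_context_rewards) / cycle
    return float(out) if out.ndim == 0 else out


def mvt_optimal_exit(
    config: TaskConfig,
    context: str,
    t_max: float | None = None,
    require_calibrated: bool = True,
) -> OptimalPolicy:
    """Reward-rate-maximizing exit time for one context.

    The expected-reward curve steps only at bin boundaries, and within each
    bin the overall rate declines (fixed numerator, growing denominator), so
    the maximizer lies exactly on a bin start; evaluating every bin start up
    to ``t_max`` (default 10 * tau) is therefore an exact search at the
    task's native resolution. If the maximum lands on the final grid point
    the patch does not deplete fast enough to favor leaving and the policy is
    flagged unbounded.
    """
    if require_calibrated and not is_calibrated(config):
        raise ValueError("TaskConfig is not calibrated; use recalibrated()")
    if t_max is None:
        t_max = max(10.0 * min(config.hazard_tau, 1e4), 60.0)
    candidates = np.arange(config.hazard_bin, t_max, config.hazard_bin)
    rates = overall_reward_rate(config, candidates, context)
    k = int(np.argmax(rates))
    if k == len(candidates) - 1:
        return OptimalPolicy(context, float("inf"), float(rates[k]), bounded=False)
    t_opt = float(candidates[k])
    rate = float(rates[k])
    inst = patch_reward_probability(config, t_opt) / config.hazard_bin
    gap = abs(inst - rate) / rate
    return OptimalPolicy(context, t_opt, rate, bounded=True, stationarity_gap=gap)
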