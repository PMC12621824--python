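"""Seeded generators for behavioral event logs, spike trains, and photometry.

These generators produce the three input classes of the pipeline with known
ground truth so every downstream stage is testable by parameter recovery:

* ``simulate_session`` — an agent playing the patch-foraging task with a
  *reward-reset* exit policy: each patch reward re-arms an intended wait that
  declines linearly with patch occupancy time and is longer in the low
  reward-rate context. Exits happen when the intended wait elapses without a
  further reward.
* ``simulate_spike_trains`` — two-state Poisson units that switch firing
  rate once per waiting epoch, at a characteristic fraction of the agent's
  current intended wait (so transition delays compress and stretch with the
  intended exit time).
* ``simulate_photometry`` — a two-channel fluorescence trace (signal +
  isosbestic) with slow drift, a shared motion artifact, and per-reward
  transients whose amplitude grows with log time-from-entry, is larger in the
  low context, and is suppressed when rewards arrive < 1 s apart.

All randomness is drawn from a per-call seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_model import TaskConfig, context_duration, is_calibrated

__all__ = [
    "ExitPolicy",
    "SyntheticNeuron",
    "PhotometryGenParams",
    "SessionEvents",
    "SpikeTrainSet",
    "simulate_session",
    "simulate_spike_trains",
    "simulate_photometry",
    "make_population",
]

EVENT_TYPES = (
    "context_entry",
    "context_reward",
    "context_exit",
    "patch_entry",
    "patch_reward",
    "patch_exit",
    "block_switch",
)


@dataclass(frozen=True)
class ExitPolicy:
    """Reward-reset exit policy of the simulated agent.

    After a reward delivered ``s`` seconds into the patch, the agent intends
    to wait ``intercept(context) + slope * s`` more seconds (plus Gaussian
    noise, truncated at ``min_wait``). ``baseline_wait`` is the intended wait
    timed from patch entry before any reward arrives.
    """

    slope: float = -0.1
    intercept_high: float = 3.0
    intercept_low: float = 4.5
    baseline_wait: float = 4.0
    noise_sd: float = 0.3
    min_wait: float = 0.2

    def __post_init__(self):
        if self.slope > 0:
            raise ValueError("slope must be <= 0 (willingness to wait declines)")
        if self.intercept_low < self.intercept_high:
            raise ValueError("intercept_low must be >= intercept_high")

    def intercept(self, context: str) -> float:
        return self.intercept_high if context == "high" else self.intercept_low


@dataclass(frozen=True)
class SyntheticNeuron:
    """Two-state Poisson unit with one reward-triggered rate transition.

    ``delay_fraction`` is the fraction of the agent's current intended wait at
    which the unit switches from ``rate_pre`` to ``rate_post``; the switch is
    realized on a given epoch with probability ``participation``.
    """

    rate_pre: float = 5.0
    rate_post: float = 20.0
    delay_fraction: float = 0.5
    delay_jitter_sd: float = 0.05
    participation: float = 0.9

    def __post_init__(self):
        if self.rate_pre < 0 or self.rate_post < 0:
            raise ValueError("rates must be >= 0")
        if self.rate_pre == self.rate_post:
            raise ValueError("rate_pre must differ from rate_post")
        if not 0.0 < self.delay_fraction < 1.0:
            raise ValueError("delay_fraction must be in (0, 1)")

    @property
    def polarity(self) -> str:
        return "off_on" if self.rate_post > self.rate_pre else "on_off"


@dataclass(frozen=True)
class PhotometryGenParams:
    """Generative parameters of the two-channel fluorescence trace.

    Amplitudes are in ΔF/F0 units relative to ``baseline_470``; the transient
    kernel is a double exponential whose peak lands ``peak_latency`` after the
    reward. The ground-truth amplitude of the transient for a reward with
    entry-to-reward interval NRI and inter-reward interval IRI is

        A = amp_base + amp_nri_gain * log(NRI) + amp_context_low_gain * 1[low]

    multiplied by ``amp_iri_suppression`` when IRI < 1 s.
    """

    sampling_rate: float = 40.0
    kernel_rise: float = 0.07
    kernel_decay: float = 1.0
    peak_latency: float = 0.3
    amp_base: float = 0.05
    amp_nri_gain: float = 0.02
    amp_context_low_gain: float = 0.01
    amp_iri_suppression: float = 0.5
    iri_suppression_threshold: float = 1.0
    drift_amplitude: float = 5.0
    artifact_amplitude: float = 2.0
    noise_sd: float = 0.2
    baseline_470: float = 100.0
    baseline_405: float = 60.0
    drift_scale_405: float = 0.7
    amp_session_sd: float = 0.005


@dataclass
class SessionEvents:
    """Ordered, timestamped event records for one session.

    ``records`` has columns (time, event, context). ``epochs`` carries the
    generator's ground truth — one row per waiting epoch in the patch with
    the agent's intended wait — and is absent for logs read from disk.
    """

    records: pd.DataFrame
    session_id: str = "session"
    config: TaskConfig | None = None
    epochs: pd.DataFrame | None = None

    def validate(self) -> None:
        t = self.records["time"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be nondecreasing")
        bad = set(self.records["event"]) - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event types: {sorted(bad)}")


@dataclass
class SpikeTrainSet:
    """Per-unit spike times plus (for synthetic data) ground-truth transitions."""

    spikes: dict
    transitions: pd.DataFrame
    neurons: list | None = None


def _block_context(t: float, config: TaskConfig, start_context: str) -> str:
    k = min(int(t // config.block_duration), config.n_blocks - 1)
    other = "low" if start_context == "high" else "high"
    return start_context if k % 2 == 0 else other


def simulate_session(
    config: TaskConfig,
    policy: ExitPolicy,
    seed: int,
    start_context: str | None = None,
    exit_disabled: bool = False,
    max_visit_duration: float = 120.0,
) -> SessionEvents:
    """Simulate one behavioral session of the patch-foraging task.

    The agent alternates context and patch visits. Patch rewards are per-bin
    Bernoulli draws from the exponentially decaying hazard; the patch exit
    occurs when the current intended wait elapses without a new reward. With
    ``exit_disabled`` the agent sits in the patch until ``max_visit_duration``
    (used to audit the reward-schedule calibration).
    """
    if not is_calibrated(config):
        raise ValueError("TaskConfig is not calibrated")
    rng = np.random.default_rng(seed)
    if start_context is None:
        start_context = str(rng.choice(CONTEXT_CHOICES))
    rows: list[tuple[float, str, str]] = []
    epochs: list[dict] = []
    t = 0.0
    visit = 0
    end = config.session_duration

    while t < end:
        ctx = _block_context(t, config, start_context)
        dur = context_duration(config, ctx)
        if t + dur + config.travel_time >= end:
            break
        rows.append((t, "context_entry", ctx))
        for i in range(1, config.n_context_rewards + 1):
            rows.append((t + i * dur / config.n_context_rewards, "context_reward", ctx))
        t += dur
        rows.append((t, "context_exit", ctx))
        t += config.travel_time

        if t >= end:
            break
        ctx = _block_context(t, config, start_context)
        entry = t
        rows.append((entry, "patch_entry", ctx))
        horizon = min(max_visit_duration, end - entry)
        nbins = int(math.floor(horizon / config.hazard_bin))
        k = np.arange(nbins)
        p = config.hazard_p0 * np.exp(-k * config.hazard_bin / config.hazard_tau)
        hits = rng.random(nbins) < p
        # reward for bin k is delivered at the end of the bin
        candidates = entry + (k[hits] + 1) * config.hazard_bin

        wait = max(policy.min_wait, policy.baseline_wait + rng.normal(0.0, policy.noise_sd))
        intended_exit = math.inf if exit_disabled else entry + wait
        epoch_start, epoch_idx = entry, 0
        n_rewards = 0
        for c in candidates:
            c = float(c)
            if c >= intended_exit:
                break
            rows.append((c, "patch_reward", ctx))
            n_rewards += 1
            epochs.append(
                dict(visit=visit, epoch=epoch_idx, start=epoch_start, end=c,
                     kind=("entry_reward" if epoch_idx == 0 else "reward_reward"),
                     intended_wait=wait, context=ctx)
            )
            wait = max(
                policy.min_wait,
                policy.intercept(ctx) + policy.slope * (c - entry)
                + rng.normal(0.0, policy.noise_sd),
            )
            intended_exit = math.inf if exit_disabled else c + wait
            epoch_start, epoch_idx = c, epoch_idx + 1
        if exit_disabled:
            exit_t = entry + horizon
        else:
            exit_t = intended_exit
        if exit_t >= end:
            # truncated final visit: keep events up to the session end, no exit
            epochs = [e for e in epochs if e["visit"] != visit]
            rows = [r for r in rows if r[0] < end]
            break
        rows.append((exit_t, "patch_exit", ctx))
        epochs.append(
            dict(visit=visit, epoch=epoch_idx, start=epoch_start, end=exit_t,
                 kind=("entry_exit" if epoch_idx == 0 else "reward_exit"),
                 intended_wait=wait, context=ctx)
        )
        visit += 1
        t = exit_t + config.travel_time

    for b in range(1, config.n_blocks):
        tb = b * config.block_duration
        rows.append((tb, "block_switch", _block_context(tb, config, start_context)))

    records = pd.DataFrame(rows, columns=["time", "event", "context"])
    records = records.sort_values("time", kind="stable").reset_index(drop=True)
    epochs_df = pd.DataFrame(
        epochs, columns=["visit", "epoch", "start", "end", "kind", "intended_wait", "context"]
    )
    return SessionEvents(records, session_id=f"sim-{seed}", config=config, epochs=epochs_df)


CONTEXT_CHOICES = ("high", "low")


def _poisson_segment(rng: np.random.Generator, t0: float, t1: float, rate: float) -> np.ndarray:
    if t1 <= t0 or rate <= 0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def simulate_spike_trains(
    events: SessionEvents, neurons: list[SyntheticNeuron], seed: int
) -> SpikeTrainSet:
    """Emit two-state Poisson spike trains tied to the agent's waiting epochs.

    Each unit fires at ``rate_pre`` by default and, on each waiting epoch
    (patch entry or reward to the next reward/exit), switches to
    ``rate_post`` at ``delay_fraction`` of the epoch's intended wait (plus
    jitter, clipped into the epoch), with probability ``participation``. At
    the next reward the unit resets to its pre state. Ground-truth transition
    times are returned alongside the spikes.
    """
    if events.epochs is None or len(events.epochs) == 0:
        raise ValueError("events carry no ground-truth epochs (need >= 1 patch visit)")
    duration = float(events.config.session_duration) if events.config else float(
        events.records["time"].max()
    )
    spikes: dict[int, np.ndarray] = {}
    gt_rows = []
    ep = events.epochs
    for i, nrn in enumerate(neurons):
        rng = np.random.default_rng([seed, i])
        # segment boundaries: (time, rate) changepoints over the whole session
        changes: list[tuple[float, float, dict | None]] = []
        for row in ep.itertuples(index=False):
            if rng.random() >= nrn.participation:
                continue
            tt = row.start + nrn.delay_fraction * row.intended_wait
            if nrn.delay_jitter_sd > 0:
                tt += rng.normal(0.0, nrn.delay_jitter_sd)
            tt = float(np.clip(tt, row.start + 1e-3, row.end - 1e-3))
            changes.append((tt, row.end, row._asdict() | {"time": tt}))
        changes.sort(key=lambda c: c[0])
        train = []
        cursor = 0.0
        for tt, ep_end, meta in changes:
            train.append(_poisson_segment(rng, cursor, tt, nrn.rate_pre))
            train.append(_poisson_segment(rng, tt, min(ep_end, duration), nrn.rate_post))
            cursor = min(ep_end, duration)
            gt_rows.append(
                dict(unit=i, visit=meta["visit"], epoch=meta["epoch"],
                     time=tt, kind=meta["kind"])
            )
        train.append(_poisson_segment(rng, cursor, duration, nrn.rate_pre))
        spikes[i] = np.sort(np.concatenate(train)) if train else np.empty(0)
    transitions = pd.DataFrame(gt_rows, columns=["unit", "visit", "epoch", "time", "kind"])
    return SpikeTrainSet(spikes=spikes, transitions=transitions, neurons=list(neurons))


def make_population(
    n_units: int,
    seed: int,
    fraction_on_off: float = 0.25,
    rate_low: float = 5.0,
    rate_high: float = 20.0,
    delay_range: tuple[float, float] = (0.05, 0.95),
    delay_jitter_sd: float = 0.05,
    participation: float = 0.9,
) -> list[SyntheticNeuron]:
    """Population of step units with transition delays spread over the wait.

    Delay fractions are evenly spaced over ``delay_range`` (shuffled), so the
    cumulative count of transitioned units grows approximately linearly over
    the intended interval; a ``fraction_on_off`` subset has inverted polarity.
    """
    rng = np.random.default_rng(seed)
    fracs = np.linspace(delay_range[0], delay_range[1], n_units)
    rng.shuffle(fracs)
    units = []
    for i in range(n_units):
        on_off = rng.random() < fraction_on_off
        pre, post = (rate_high, rate_low) if on_off else (rate_low, rate_high)
        units.append(
            SyntheticNeuron(
                rate_pre=pre, rate_post=post, delay_fraction=float(fracs[i]),
                delay_jitter_sd=delay_jitter_sd, participation=participation,
            )
        )
    return units


def _transient_kernel(params: PhotometryGenParams, fs: float, length_s: float = 6.0):
    """Unit-peak double-exponential kernel, peak at ``peak_latency`` post reward."""
    r, d = params.kernel_rise, params.kernel_decay
    t = np.arange(0.0, length_s, 1.0 / fs)
    natural_peak = r * d / (d - r) * math.log(d / r)
    onset = params.peak_latency - natural_peak
    u = t - onset
    k = np.where(u > 0, np.exp(-np.maximum(u, 0) / d) - np.exp(-np.maximum(u, 0) / r), 0.0)
    peak = k.max()
    return k / peak if peak > 0 else k


def patch_reward_covariates(events: SessionEvents) -> pd.DataFrame:
    """Per patch reward: time, NRI (entry-to-reward), IRI, and context.

    IRI for the first reward of a visit is defined as the NRI (there is no
    prior reward to measure from).
    """
    rows = []
    entry = None
    prev_reward = None
    visit = -1
    for row in events.records.itertuples(index=False):
        if row.event == "patch_entry":
            entry, prev_reward = row.time, None
            visit += 1
        elif row.event == "patch_reward" and entry is not None:
            nri = row.time - entry
            iri = nri if prev_reward is None else row.time - prev_reward
            rows.append(dict(visit=visit, reward_time=row.time, nri=nri,
                             iri=iri, context=row.context))
            prev_reward = row.time
        elif row.event == "patch_exit":
            entry = None
    return pd.DataFrame(rows, columns=["visit", "reward_time", "nri", "iri", "context"])


def simulate_photometry(
    events: SessionEvents, params: PhotometryGenParams, seed: int
):
    """Two-channel fluorescence trace plus ground-truth transient amplitudes.

    Returns ``(trace, truth)`` where ``trace`` is a
    :class:`patchtime.photometry.PhotometryTrace` (raw channels only) and
    ``truth`` extends :func:`patch_reward_covariates` with the generated
    amplitude ``amp_true`` (in ΔF/F0 units) of every patch-reward transient.
    """
    from .photometry import PhotometryTrace

    fs = params.sampling_rate
    if fs <= 0:
        raise ValueError("sampling_rate must be positive")
    rng = np.random.default_rng(seed)
    duration = float(events.config.session_duration) if events.config else float(
        events.records["time"].max() + 10.0
    )
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # slow multiplicative-free drift (two incommensurate sinusoids) and a
    # shared low-frequency motion artifact injected identically in both channels
    ph = rng.uniform(0, 2 * math.pi, 2)
    drift = np.sin(2 * math.pi * t / 600.0 + ph[0]) + 0.5 * np.sin(
        2 * math.pi * t / 173.0 + ph[1]
    )
    white = rng.normal(0.0, 1.0, n)
    if params.artifact_amplitude > 0:
        from scipy.signal import butter, sosfiltfilt

        sos = butter(2, 0.5, btype="low", fs=fs, output="sos")
        art = sosfiltfilt(sos, white)
        art = art / (art.std() or 1.0)
    else:
        art = np.zeros(n)

    truth = patch_reward_covariates(events)
    sess_offset = rng.normal(0.0, params.amp_session_sd)
    amps = []
    transients = np.zeros(n)
    kernel = _transient_kernel(params, fs)
    for row in truth.itertuples(index=False):
        a = (
            params.amp_base
            + params.amp_nri_gain * math.log(max(row.nri, 1e-3))
            + (params.amp_context_low_gain if row.context == "low" else 0.0)
            + sess_offset
        )
        if row.iri < params.iri_suppression_threshold:
            a *= params.amp_iri_suppression
        a = max(a, 0.0)
        amps.append(a)
        i0 = int(round(row.reward_time * fs))
        seg = min(len(kernel), n - i0)
        if seg > 0:
            transients[i0 : i0 + seg] += a * kernel[:seg]
    truth = truth.assign(amp_true=amps)

    raw_470 = (
        params.baseline_470 * (1.0 + transients)
        + params.drift_amplitude * drift
        + params.artifact_amplitude * art
        + rng.normal(0.0, params.noise_sd, n)
    )
    raw_405 = (
        params.baseline_405
        + params.drift_scale_405 * params.drift_amplitude * drift
        + params.artifact_amplitude * art
        + rng.normal(0.0, params.noise_sd, n)
    )
    trace = PhotometryTrace(
        time=t, raw_470=raw_470, raw_405=raw_405, sampling_rate=fs,
        session_id=events.session_id,
    )
    return trace, truth
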