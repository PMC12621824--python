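# Methods

## The task and its generative model

`patchtime` models a two-port patch-foraging task for freely moving mice. A
*context port* pays a fixed bundle of `n_context_rewards = 4` water rewards,
evenly spaced over 5 s ("high" reward-rate blocks) or 10 s ("low" blocks);
blocks alternate every 180 s across a 1080 s session. A *time-investment
port* — the patch — offers reward opportunities on a discrete 100 ms grid
with per-bin Bernoulli probability

    p(t) = p0 · exp(−t / τ),    t = time since patch entry,

with τ = 8 s and p0 solved from the calibration constraint that the series
sums to 8 expected rewards (p0 = 8·(1 − e^(−Δ/τ)) ≈ 0.0994 for Δ = 0.1 s).
τ is a free simulation parameter — the task's published description fixes
only the sum-to-eight constraint and the 100 ms minimum reward spacing — and
both are configurable. Travel between ports costs 0.3 s each way.

### MVT-optimal exit

The reward-rate-maximizing exit time follows the Marginal Value Theorem:
leave when the patch's instantaneous rate falls to the best achievable
overall rate. The overall rate of a cycle with patch occupancy T is

    R(T) = (E[rewards by T] + 4) / (T + D_context + 2·travel),

where E[rewards by T] is the partial geometric sum of per-bin probabilities.
E steps only at bin edges and R declines within each piece, so the maximizer
lies exactly on a bin start; the solver enumerates bin starts, which is
exact at the task's native resolution (verified against a 1 ms brute-force
grid). The search domain is exits at or after the first reward opportunity;
for non-depleting hazards the boundary optimum is flagged unbounded rather
than returned as a number. The MVT stationarity gap |p(T*)/Δ − R(T*)| / R(T*)
is reported as a diagnostic; on the discrete grid it is ~10⁻² rather than 0.

## The synthetic agent (reward-reset policy)

The simulated agent re-arms an intended wait at each patch reward:

    wait = intercept(context) + slope · (reward time from entry) + ε,
    ε ~ N(0, noise_sd),  truncated at 0.2 s,

and exits when the wait elapses without a further reward. Defaults:
slope = −0.1 (dimensionless), intercept_high = 3.0 s, intercept_low = 4.5 s,
baseline wait (before the first reward) 4.0 s, noise_sd = 0.3 s. These were
chosen once to reproduce the qualitative behavioral pattern the analyses
assume — post-reward waits of a few seconds, longer in the low context,
declining with patch occupancy, with trial-to-trial variability small
relative to the context difference — and give ~60–80 trials per 18-minute
session with ~5 rewards per visit. The linear form makes generator and
analyzer self-consistent by construction: the projected-exit regression fits
exactly the model the agent uses.

### A censoring bias the projected-exit regression inherits

The projected-exit regression (exit-from-last-reward on last-reward time,
final rewards only) conditions on the event "no further reward arrived
during the wait". Longer realized waits are less likely to survive that
condition, and the strength of the selection varies with the regressor
(hazard is higher early in the patch), so plain OLS recovers the slope with
a systematic ~3–5% attenuation toward zero at the default noise level
(≈ −σ²·λ(exit) per observation, λ the per-second reward hazard at the exit).
This is a property of the estimator under the task's own generative
process, not an implementation artifact; parameter-recovery checks on the
slope should expect it.

## Behavioral analyses

* **Trial table** — one row per completed patch visit; a truncated final
  visit is dropped. "Time since most recent reward" before any reward is
  defined as time since entry (entry starts the first waiting epoch).
* **Leaving hazard** — discrete hazard: exits in bin / at-risk at bin start,
  aligned to entry or to each reward. Reward-aligned epochs ending in a new
  reward are censored at that reward. The cumulative product of (1 − hazard)
  reproduces the empirical survival curve exactly on the same bins.
* **Stay/leave SVM** — each visit's occupancy is cut into 10 ms "stay" bins
  and the 5 s after each exit into "leave" bins; features are time since
  reward, time since entry, and the low-context indicator, z-scored. The
  classifier is a linear SVM (unit regularization, class-balanced weights —
  leave bins are the rarer class). Coefficient magnitudes rank the factors.
* **Projected exits** — per-context OLS of exit-from-last-reward on
  last-reward time, applied to every reward to produce the exit the animal
  was projected to accept had that reward been the last.

## Step detection

Rates are one over the interspike interval on a 10 ms grid. The enclosing
interval is taken from the full spike train; the gap to the window edge is
used only when no spike exists beyond that edge (using the window edge
unconditionally inflates rates at interval boundaries — E[1/gap] diverges —
and that bias masquerades as a step).

Per unit, a 4-parameter logistic y0 + h/(1 + e^(−k(t−c))) is fit to the
pooled post-reward rates ("session sigmoid"); the slope is reported as the
derivative at the center, k·h/4, in (spikes/s)/s, so the minimum-slope bound
of 11 (spikes/s)/s applies in those units regardless of parameterization.
Every reward-to-reward and reward-to-exit interval is then refit with y0 and
h confined to ±20% of the session values, |slope| ≥ 11, and the center
allowed the interval ±10%; a fit succeeds when the center lands ≥100 ms
inside the interval. Intervals shorter than 0.3 s cannot hold a valid center
and are failed without fitting. The optimizer is a single-start bounded
trust-region fit with an analytic Jacobian (a deterministic multi-start
variant exists behind `n_center_starts`; it was not better on synthetic
sessions and is off by default).

Two additions harden the published recipe, both on by default and both
separately switchable:

1. **Contrast gate.** 1/(ISI) rate samples are heavy-tailed and serially
   dependent (all bins inside one ISI share a value), so bounded interval
   fits can "succeed" on units with no two-state structure. A unit is only
   classifiable step-like if its pooled pre/post contrast around the session
   center exceeds 3 standard errors, with each side's effective sample size
   taken as its spike count rather than its bin count. On constant-rate
   Poisson units this brings unit-level false positives from ~20% to <5%
   while keeping units with genuine 3–4× rate contrasts.
2. **Changepoint refinement.** The sigmoid center can localize a transition
   only to within the ISI that straddles it (~0.1 s at 5→20 Hz). For
   successful fits the step time is refined by profiling the two-state
   Poisson likelihood over split times within ±0.3 s of the center,
   which pins the transition at spike resolution. `refine_step=False`
   restores the raw center.

Classification uses the single-pass reading of the eligibility rule: mean
and SD of step time are computed from all successful fits, intervals longer
than mean + SD are eligible, and the unit is step-like when ≥50% of eligible
intervals (at least 5, from at least 10 fitted intervals) succeeded and the
session contrast passes the gate (|h| ≥ 3 Hz and z ≥ 3). Polarity is the
sign of the session height (positive = off/on).

## Accumulation to threshold

Within each interval, the cumulative count of step-like units past their
detected transition is a nondecreasing step function. A line is fit by OLS
on the step function's support points — (0, 0), each post-jump value, and
the final value at the interval end (dense 10 ms sampling is available but
overweights long flat tails). The threshold is the mean count at true exits
over reward-exit intervals; each interval's predicted exit is where its line
crosses the threshold (no prediction for non-positive slopes — reported,
not extrapolated). Sessions need ≥6 step-like units and ≥5 reward-exit
intervals. With ground-truth transition times this model reproduces exits
exactly (r = 1.0 on noiseless sessions); every departure from that is
detector error.

## Photometry

Pipeline order: 2nd-order zero-phase Butterworth high-pass (0.01 Hz default)
on both channels with each channel's DC level restored — detrending removes
drift, not the fluorescence scale — then a 200 ms moving average, OLS
scaling of the isosbestic onto the signal channel and subtraction, then
ΔF/F0 with ΔF the corrected trace and F0 the centered 10 s moving mean of
the processed 470 channel. F0 is deliberately *not* the corrected trace:
after isosbestic subtraction the corrected trace is near zero-mean and
cannot serve as a normalizer. Windows at the trace edges are truncated and
flagged. Transient amplitude per reward is the maximum ΔF/F0 within 0.5 s
after the reward minus the minimum before that peak (zero when the peak is
the first sample).

The generator's transient kernel is a unit-peak double exponential
(rise 0.07 s, decay 1.0 s — GRAB-class sensor kinetics) with its onset
delayed so the peak lands 300 ms after the reward. The onset then clears the
first 40 Hz sample and the 200 ms smoothing window, which matters: a kernel
that has already risen at the first post-reward sample loses ~15–20% of its
amplitude to the peak-minus-minimum rule by construction. With the default
kernel the quantifier recovers isolated amplitudes to within ~7% (median);
closely spaced rewards ride on the previous kernel's tail and no peak-based
measure can separate the contributions, so per-reward recovery is assessed
on transients ≥2 s from both neighbors.

Amplitudes are modeled as

    amplitude ~ z(log NRI) + 1[low context] + z(log IRI),

with a random intercept per session (statsmodels MixedLM; singular or
non-convergent fits fall back to OLS with a logged downgrade). IRI of a
visit's first reward is defined as its NRI. The generator's amplitudes are
amp_base 0.05 + 0.02·log(NRI) + 0.01·1[low], halved when IRI < 1 s, plus a
per-session offset (SD 0.005) that gives the random intercept something to
absorb; all in ΔF/F0 units relative to a 100 a.u. baseline.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: the calibrated
reward hazard, reward-reset exits modulated by context and occupancy,
two-state Poisson units whose delays scale with intended waits (participation
0.9, jitter 0.05 s, delay fractions spread over (0.05, 0.95), ~25% inverted
polarity), and transients with the three amplitude dependencies plus shared
motion artifact and slow drift. It does not emulate: non-Poisson spiking,
electrode drift or sorting errors, lick or video signals, bleaching
dynamics beyond slow drift, cross-animal hierarchies, or mice that leave the
context port early. Passing recovery tests therefore demonstrates the
pipeline's correctness on data obeying its own assumptions — not robustness
to every pathology of real recordings.

## Problem sizes used by the benchmarks

Chosen as the package's own benchmark conditions: step recovery on 500
constructed 2–4 s intervals (5→20 Hz, no jitter); false positives on 200
constant-rate units × 20 intervals; policy recovery on 50 sessions of ~200
trials; the accumulation sign check on 50 two-block (6-minute) sessions with
16-unit populations; the noiseless threshold check pooling reward-exit
intervals over 5 such sessions; photometry sign recovery on 20 runs of ~7
default sessions (~1,100 transients each). All randomness flows from a
single per-call seed; identical seeds give byte-identical outputs.

## Known limitations

* The sigmoid-center error floor is set by the interspike interval at the
  lower firing rate; recovery degrades for contrasts below ~3× or rates
  below ~5 Hz.
* The contrast gate trades sensitivity for specificity: genuine step units
  whose transitions sit in the last ~10% of the interval are sparsely
  sampled in their post state and may fail the gate.
* The threshold model's predictions inherit detector noise; with ~13–16
  units the count granularity limits per-interval precision to ~0.2–0.3 s.
* The amplitude model treats overlap-contaminated amplitudes as data, as the
  published analysis does; its coefficient signs are robust to this, their
  magnitudes are not.
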