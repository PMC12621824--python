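# patchtime

Simulation and analysis of a patch-foraging time-investment task, for
computational and systems neuroscientists studying when animals decide to
abandon a depleting reward source — and how striatal activity times that
decision.

In the task, a mouse alternates between a *context port* (four evenly spaced
rewards over 5 s in "high" blocks or 10 s in "low" blocks) and a
*time-investment port* — a patch whose per-bin reward probability decays as
p(t) = p0·e^(−t/τ), calibrated so the series sums to 8 expected rewards.
The package provides, as one tested pipeline:

* **Task model** — the generative reward schedule and the Marginal Value
  Theorem (MVT) optimum: exit when the patch's instantaneous rate falls to
  the best achievable overall rate R(T) = (E[rewards by T] + 4)/(T + D + 2d).
* **Synthetic data** — seeded generators for behavioral event logs (a
  *reward-reset* agent whose intended wait re-arms at each reward as
  `intercept(context) + slope·t_entry→reward + ε`), two-state Poisson spike
  trains that switch rate at characteristic fractions of the intended wait,
  and two-channel photometry (signal + isosbestic) with reward transients.
* **Behavioral analysis** — trial tables, leaving-hazard curves aligned to
  entry or last reward, a linear SVM ranking stay/leave decision factors,
  and per-reward projected exit times.
* **Step detection** — discrete firing-rate transitions after each reward,
  found by bounded sigmoid fits to unsmoothed 1/ISI rates (|slope| ≥ 11
  (spikes/s)/s, center ≥100 ms inside the interval), with a contrast gate
  and Poisson changepoint refinement; units are step-like when ≥50% of
  sufficiently long intervals yield a step.
* **Accumulation to threshold** — the cumulative count of transitioned units
  per interval, its line fit, the mean count at exits as threshold, and
  neurally predicted exit times.
* **Photometry** — ΔF/F0 with isosbestic motion correction, per-reward
  transient amplitudes, and a mixed-effects model
  `amplitude ~ z(log NRI) + context + z(log IRI)` with a session random
  intercept (NRI = entry→reward interval, IRI = inter-reward interval).

Every stage is testable by parameter recovery against the generators' ground
truth. See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import patchtime as pt

cfg = pt.TaskConfig()                       # calibrated defaults
for ctx in ("high", "low"):
    opt = pt.mvt_optimal_exit(cfg, ctx)
    print(f"MVT optimal exit ({ctx}): {opt.optimal_exit_time:.1f} s "
          f"at overall rate {opt.achieved_overall_rate:.3f} rewards/s")

events = pt.simulate_session(cfg, pt.ExitPolicy(), seed=1)
table = pt.build_trial_table(events)
w = pt.fit_stay_leave_svm(table)
proj = pt.project_exit_times(table)
```

prints

```
MVT optimal exit (high): 2.2 s at overall rate 0.759 rewards/s
MVT optimal exit (low): 5.6 s at overall rate 0.496 rewards/s
```

and the session-level analyses give

```
69 patch visits; mean occupancy high = 6.81 s, low = 10.44 s
SVM |coefficients|: time since reward = 3.89, time since entry = 0.83, context = 1.34
projected-exit regression (high): slope = -0.109, intercept = 2.98 s (n = 43)
projected-exit regression (low): slope = -0.087, intercept = 4.45 s (n = 23)
```

Read: the optimal patch stay is longer when the alternative is poorer
(5.6 s vs 2.2 s), and the simulated agent is — like real mice — overpatient
relative to both. The SVM ranks *time since the last reward* as the dominant
stay/leave factor, the signature of a reward-reset strategy; the
projected-exit regression recovers the agent's generating policy
(slope −0.1, intercepts 3.0/4.5 s) from its behavior alone.

## Command line

```bash
patchtime simulate --seed 1 --out session/          # events, spikes, photometry
patchtime behavior session/events.tsv --out report/
patchtime steps session/events.tsv session/spikes --out steps.tsv
patchtime accumulate steps.tsv session/events.tsv --out accum/
patchtime photometry session/photometry.tsv session/events.tsv --out da.tsv
patchtime benchmark --out bench/                    # end-to-end recovery report
```

All tunables live in one YAML config (`configs/default.yaml`,
regenerate with `patchtime write-config`); every command takes `--config`.

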