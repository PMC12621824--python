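import numpy as np
import pandas as pd
import pytest
from scipy import stats

from patchtime import synthetic_data as sd
from patchtime import task_model as tm
from conftest import make_step_epochs, stub_events_for


class TestSessionSimulation:
    def test_identical_seeds_identical_output(self, short_config, policy):
        a = sd.simulate_session(short_config, policy, seed=7)
        b = sd.simulate_session(short_config, policy, seed=7)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.epochs, b.epochs)

    def test_event_structure_valid(self, events):
        events.validate()
        ev = events.records["event"]
        assert (ev == "block_switch").sum() == events.config.n_blocks - 1
        # entries and exits alternate per port
        patch = events.records[ev.isin(["patch_entry", "patch_exit"])]["event"]
        assert all(
            a != b for a, b in zip(patch.to_numpy()[:-1], patch.to_numpy()[1:])
        )

    def test_rewards_lie_inside_patch_occupancy(self, events):
        inside = False
        for rec in events.records.itertuples(index=False):
            if rec.event == "patch_entry":
                inside = True
            elif rec.event == "patch_exit":
                inside = False
            elif rec.event == "patch_reward":
                assert inside

    def test_no_rewards_means_baseline_wait(self, policy):
        cfg = tm.TaskConfig(hazard_p0=1e-12, hazard_tau=8.0, expected_total_rewards=8e-11)
        ev = sd.simulate_session(cfg, policy, seed=3, start_context="high")
        occ = []
        entry = None
        for rec in ev.records.itertuples(index=False):
            if rec.event == "patch_entry":
                entry = rec.time
            elif rec.event == "patch_exit":
                occ.append(rec.time - entry)
        occ = np.asarray(occ)
        assert abs(occ.mean() - policy.baseline_wait) < 4 * policy.noise_sd
        assert occ.std() < 3 * policy.noise_sd

    def test_mean_rewards_exhaustive_visit(self, task_config, policy):
        # never-exiting agent harvests the full expected reward count
        ev = sd.simulate_session(
            task_config.recalibrated(session_duration=3600.0, n_blocks=20),
            policy, seed=11, exit_disabled=True,
        )
        counts = []
        n = 0
        for rec in ev.records.itertuples(index=False):
            if rec.event == "patch_entry":
                n = 0
            elif rec.event == "patch_reward":
                n += 1
            elif rec.event == "patch_exit":
                counts.append(n)
        assert len(counts) >= 20
        # wide tolerance: only ~25 visits fit in one long session
        assert np.mean(counts) == pytest.approx(8.0, abs=3 * 2.8 / np.sqrt(len(counts)))

    def test_low_context_occupancy_longer(self, short_config, policy):
        occ = {"high": [], "low": []}
        for s in range(8):
            ev = sd.simulate_session(short_config, policy, seed=200 + s)
            entry, ctx = None, None
            for rec in ev.records.itertuples(index=False):
                if rec.event == "patch_entry":
                    entry, ctx = rec.time, rec.context
                elif rec.event == "patch_exit":
                    occ[ctx].append(rec.time - entry)
        assert np.mean(occ["low"]) > np.mean(occ["high"])

    def test_per_bin_reward_frequency_matches_hazard(self, policy):
        # empirical Bernoulli frequency in the first bins across many visits
        cfg = tm.TaskConfig().recalibrated(session_duration=7200.0, n_blocks=40)
        ev = sd.simulate_session(cfg, policy, seed=5)
        first_bin_hits = 0
        visits = 0
        entry = None
        for rec in ev.records.itertuples(index=False):
            if rec.event == "patch_entry":
                entry = rec.time
                visits += 1
            elif rec.event == "patch_reward" and entry is not None:
                if rec.time - entry <= cfg.hazard_bin + 1e-9:
                    first_bin_hits += 1
        p_hat = first_bin_hits / visits
        se = np.sqrt(cfg.hazard_p0 * (1 - cfg.hazard_p0) / visits)
        assert abs(p_hat - cfg.hazard_p0) < 4 * se


class TestSpikeSimulation:
    def test_transition_at_delay_fraction(self):
        epochs = pd.DataFrame(
            dict(visit=[0], epoch=[1], start=[10.0], end=[14.0],
                 kind=["reward_exit"], intended_wait=[4.0], context=["high"])
        )
        ev = stub_events_for(epochs)
        unit = sd.SyntheticNeuron(rate_pre=5.0, rate_post=20.0, delay_fraction=0.5,
                                  delay_jitter_sd=0.0, participation=1.0)
        sts = sd.simulate_spike_trains(ev, [unit], seed=1)
        assert len(sts.transitions) == 1
        assert sts.transitions["time"].iloc[0] == pytest.approx(12.0, abs=1e-6)

    def test_equal_rates_rejected(self):
        with pytest.raises(ValueError):
            sd.SyntheticNeuron(rate_pre=10.0, rate_post=10.0)

    def test_empty_events_rejected(self, short_config):
        ev = sd.SessionEvents(
            pd.DataFrame(columns=["time", "event", "context"]),
            config=short_config, epochs=pd.DataFrame(),
        )
        with pytest.raises(ValueError):
            sd.simulate_spike_trains(ev, [sd.SyntheticNeuron()], seed=1)

    def test_reproducible(self, events):
        pop = sd.make_population(4, seed=9)
        a = sd.simulate_spike_trains(events, pop, seed=42)
        b = sd.simulate_spike_trains(events, pop, seed=42)
        for u in a.spikes:
            np.testing.assert_array_equal(a.spikes[u], b.spikes[u])
        pd.testing.assert_frame_equal(a.transitions, b.transitions)

    def test_population_transitions_spread_linearly(self):
        # delay fractions spread over (0.05, 0.95) with a fixed wait give a
        # cumulative transition count that is approximately linear in time;
        # oracle: uniform order statistics
        epochs = make_step_epochs(40, seed=3, wait_lo=3.0, wait_hi=3.0)
        ev = stub_events_for(epochs)
        pop = sd.make_population(16, seed=3, fraction_on_off=0.0,
                                 delay_jitter_sd=0.0, participation=1.0)
        sts = sd.simulate_spike_trains(ev, pop, seed=3)
        rel = []
        starts = epochs.set_index(["visit", "epoch"])["start"]
        for row in sts.transitions.itertuples(index=False):
            rel.append((row.time - starts.loc[(row.visit, row.epoch)]) / 3.0)
        rel = np.sort(rel)
        uniform_grid = np.linspace(0.05, 0.95, len(rel))
        assert np.max(np.abs(rel - uniform_grid)) < 0.1

    def test_poisson_rates_recovered(self):
        epochs = pd.DataFrame(
            dict(visit=[0], epoch=[1], start=[0.0], end=[200.0],
                 kind=["reward_exit"], intended_wait=[200.0], context=["high"])
        )
        ev = stub_events_for(epochs)
        unit = sd.SyntheticNeuron(rate_pre=5.0, rate_post=20.0, delay_fraction=0.5,
                                  delay_jitter_sd=0.0, participation=1.0)
        sts = sd.simulate_spike_trains(ev, [unit], seed=2)
        spk = sts.spikes[0]
        t_tr = sts.transitions["time"].iloc[0]
        r_pre = (spk < t_tr).sum() / t_tr
        r_post = ((spk >= t_tr) & (spk < 200.0)).sum() / (200.0 - t_tr)
        assert r_pre == pytest.approx(5.0, rel=0.25)
        assert r_post == pytest.approx(20.0, rel=0.25)


class TestPhotometrySimulation:
    def test_single_reward_single_kernel(self, short_config):
        records = pd.DataFrame(
            dict(time=[10.0, 20.0, 40.0], event=["patch_entry", "patch_reward",
                                                 "patch_exit"], context=["high"] * 3)
        )
        ev = sd.SessionEvents(records, config=short_config)
        p = sd.PhotometryGenParams(drift_amplitude=0.0, artifact_amplitude=0.0,
                                   noise_sd=0.0, amp_session_sd=0.0)
        trace, truth = sd.simulate_photometry(ev, p, seed=1)
        assert len(truth) == 1
        peak_i = np.argmax(trace.raw_470)
        assert trace.time[peak_i] == pytest.approx(20.0 + p.peak_latency, abs=0.05)

    def test_close_rewards_suppressed(self, short_config):
        records = pd.DataFrame(
            dict(time=[10.0, 15.0, 15.5, 40.0],
                 event=["patch_entry", "patch_reward", "patch_reward", "patch_exit"],
                 context=["high"] * 4)
        )
        ev = sd.SessionEvents(records, config=short_config)
        p = sd.PhotometryGenParams(amp_session_sd=0.0)
        _, truth = sd.simulate_photometry(ev, p, seed=1)
        a1, a2 = truth["amp_true"]
        expected_unsuppressed = a1 + p.amp_nri_gain * (np.log(5.5) - np.log(5.0))
        assert a2 == pytest.approx(p.amp_iri_suppression * expected_unsuppressed, rel=1e-6)

    def test_ols_on_truth_recovers_nri_gain(self, events):
        p = sd.PhotometryGenParams(amp_session_sd=0.0, amp_iri_suppression=1.0)
        _, truth = sd.simulate_photometry(events, p, seed=4)
        high = truth[truth["context"] == "high"]  # avoid context confound
        fit = stats.linregress(np.log(high["nri"]), high["amp_true"])
        assert fit.slope == pytest.approx(p.amp_nri_gain, rel=1e-6)

    def test_reproducible(self, events):
        p = sd.PhotometryGenParams()
        t1, g1 = sd.simulate_photometry(events, p, seed=8)
        t2, g2 = sd.simulate_photometry(events, p, seed=8)
        np.testing.assert_array_equal(t1.raw_470, t2.raw_470)
        pd.testing.assert_frame_equal(g1, g2)
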