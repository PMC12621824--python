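import numpy as np
import pandas as pd
import pytest

from patchtime import step_detection as sdt
from patchtime import synthetic_data as sd
from conftest import make_step_epochs, stub_events_for


class TestInstantaneousRate:
    def test_regular_train_gives_constant_rate(self):
        spikes = np.arange(0.05, 20.0, 0.1)  # 10 Hz
        series = sdt.instantaneous_rate(spikes, (5.0, 10.0))
        np.testing.assert_allclose(series.rate, 10.0, rtol=1e-9)

    def test_single_spike_window_no_discontinuity(self):
        series = sdt.instantaneous_rate(np.array([2.0]), (0.0, 4.0))
        # the lone spike splits the window into two boundary-defined rates
        assert len(np.unique(np.round(series.rate, 9))) <= 2
        assert np.all(series.rate >= 0)

    def test_empty_window_rate_zero(self):
        series = sdt.instantaneous_rate(np.array([]), (0.0, 2.0))
        assert np.all(series.rate == 0)

    def test_unsorted_spikes_rejected(self):
        with pytest.raises(ValueError):
            sdt.instantaneous_rate(np.array([2.0, 1.0]), (0.0, 3.0))

    def test_two_state_rates_recovered_on_average(self):
        rng = np.random.default_rng(0)
        pre = np.cumsum(rng.exponential(1 / 5.0, 200))
        t_switch = pre[pre < 20.0][-1]
        post = t_switch + np.cumsum(rng.exponential(1 / 20.0, 800))
        spikes = np.concatenate([pre[pre < t_switch], post[post < 40.0]])
        series = sdt.instantaneous_rate(spikes, (0.0, 40.0))
        centers = series.bin_starts + 0.005
        pre_mean = series.rate[centers < t_switch - 0.5].mean()
        post_mean = series.rate[centers > t_switch + 0.5].mean()
        assert pre_mean == pytest.approx(5.0, rel=0.3)
        assert post_mean == pytest.approx(20.0, rel=0.3)


def _pooled(spikes, intervals, bin=0.01):
    ts, rs = [], []
    for row in intervals.itertuples(index=False):
        s = sdt.instantaneous_rate(spikes, (row.start, row.end), bin=bin)
        ts.append(s.bin_starts + bin / 2)
        rs.append(s.rate)
    return np.concatenate(ts), np.concatenate(rs)


@pytest.fixture(scope="module")
def step_unit_data():
    epochs = make_step_epochs(60, seed=13)
    ev = stub_events_for(epochs)
    unit = sd.SyntheticNeuron(rate_pre=5.0, rate_post=20.0, delay_fraction=0.5,
                              delay_jitter_sd=0.0, participation=1.0)
    sts = sd.simulate_spike_trains(ev, [unit], seed=13)
    return epochs, sts


class TestSessionSigmoid:
    def test_height_near_rate_contrast(self, step_unit_data):
        epochs, sts = step_unit_data
        t, r = _pooled(sts.spikes[0], epochs)
        params = sdt.fit_session_sigmoid(t, r)
        assert params.height == pytest.approx(15.0, rel=0.35)
        assert params.height > 0  # off_on polarity sign convention

    def test_on_off_unit_negative_height(self):
        epochs = make_step_epochs(60, seed=14)
        ev = stub_events_for(epochs)
        unit = sd.SyntheticNeuron(rate_pre=20.0, rate_post=5.0, delay_fraction=0.5,
                                  delay_jitter_sd=0.0, participation=1.0)
        sts = sd.simulate_spike_trains(ev, [unit], seed=14)
        t, r = _pooled(sts.spikes[0], epochs)
        params = sdt.fit_session_sigmoid(t, r)
        assert params.height < 0

    def test_flat_unit_small_height_blocks_interval_fits(self):
        rng = np.random.default_rng(15)
        epochs = make_step_epochs(30, seed=15)
        duration = float(epochs["end"].iloc[-1] + 0.5)
        spikes = np.sort(rng.uniform(0, duration, rng.poisson(12.0 * duration)))
        t, r = _pooled(spikes, epochs)
        params = sdt.fit_session_sigmoid(t, r)
        z = sdt.contrast_zscore(t, r, params.center)
        assert z < sdt.StepDetectionConfig().min_height_z


class TestIntervalSigmoid:
    def test_known_step_recovered(self, step_unit_data):
        epochs, sts = step_unit_data
        t, r = _pooled(sts.spikes[0], epochs)
        session = sdt.fit_session_sigmoid(t, r)
        truth = sts.transitions.set_index(["visit", "epoch"])["time"]
        errors = []
        for row in epochs.itertuples(index=False):
            series = sdt.instantaneous_rate(
                sts.spikes[0], (row.start, row.end), interval_id=(row.visit, row.epoch)
            )
            fit = sdt.fit_interval_sigmoid(series, session, row.end - row.start)
            if fit.success:
                true_rel = truth.loc[(row.visit, row.epoch)] - row.start
                errors.append(abs(fit.step_time - true_rel))
        assert len(errors) >= 0.8 * len(epochs)
        assert np.median(errors) < 0.15

    def test_short_interval_auto_failed(self, step_unit_data):
        epochs, sts = step_unit_data
        t, r = _pooled(sts.spikes[0], epochs)
        session = sdt.fit_session_sigmoid(t, r)
        series = sdt.instantaneous_rate(sts.spikes[0], (0.0, 0.2))
        fit = sdt.fit_interval_sigmoid(series, session, 0.2)
        assert not fit.success
        assert fit.reason == "too_short"

    def test_ramp_rejected_by_slope_bound(self):
        # linear ramp spanning the interval: max attainable center slope is
        # below the minimum, so the bounded fit cannot place a valid step
        rng = np.random.default_rng(16)
        duration, n_int = 4.0, 40
        spikes_all, rows = [], []
        t0 = 0.0
        for i in range(n_int):
            # inhomogeneous Poisson with linearly rising rate 5 -> 15 Hz
            tt = []
            t = 0.0
            while t < duration:
                lam = 5.0 + 10.0 * t / duration
                t += rng.exponential(1.0 / 15.0)
                if t < duration and rng.random() < lam / 15.0:
                    tt.append(t0 + t)
            spikes_all.extend(tt)
            rows.append(dict(visit=i, epoch=1, start=t0, end=t0 + duration,
                             kind="reward_exit"))
            t0 += duration + 0.5
        spikes = np.asarray(spikes_all)
        intervals = pd.DataFrame(rows)
        profile = sdt.analyze_unit(spikes, intervals)
        # a 2.5 (sp/s)/s ramp cannot satisfy the |slope| >= 11 bound as a
        # valid interior step on most intervals
        frac_success = np.mean([f.success for f in profile.fits])
        assert frac_success < 0.5


class TestClassification:
    def _fits(self, flags, durations, times=None):
        fits = []
        for i, (ok, d) in enumerate(zip(flags, durations)):
            fits.append(sdt.IntervalStepFit(
                (0, i), None, ok, times[i] if times else (1.0 if ok else np.nan), d,
            ))
        return fits

    def test_all_eligible_detected_is_step_like(self):
        session = sdt.SigmoidParams(5.0, 15.0, 30.0, 1.0)
        fits = self._fits([True] * 12, [3.0] * 12)
        prof = sdt.classify_unit(fits, session)
        assert prof.is_step_like
        assert prof.polarity == "off_on"

    def test_forty_percent_success_not_step_like(self):
        session = sdt.SigmoidParams(5.0, 15.0, 30.0, 1.0)
        # 4 successes at step time 1.0 among 10 eligible intervals
        fits = self._fits([True] * 4 + [False] * 6, [5.0] * 10)
        prof = sdt.classify_unit(fits, session)
        assert prof.n_eligible == 10
        assert prof.n_success_on_eligible == 4
        assert not prof.is_step_like

    def test_zero_successes_not_step_like(self):
        session = sdt.SigmoidParams(5.0, 15.0, 30.0, 1.0)
        prof = sdt.classify_unit(self._fits([False] * 12, [3.0] * 12), session)
        assert not prof.is_step_like
        assert np.isnan(prof.mean_step_time)

    def test_early_transition_unit_has_small_mean_step_time(self):
        epochs = make_step_epochs(40, seed=17)
        ev = stub_events_for(epochs)
        unit = sd.SyntheticNeuron(rate_pre=20.0, rate_post=5.0, delay_fraction=0.08,
                                  delay_jitter_sd=0.0, participation=1.0)
        sts = sd.simulate_spike_trains(ev, [unit], seed=17)
        prof = sdt.analyze_unit(
            sts.spikes[0], epochs[["visit", "epoch", "start", "end", "kind"]],
        )
        assert prof.is_step_like
        assert prof.polarity == "on_off"
        assert prof.mean_step_time < 0.6

    def test_interval_order_invariance(self, step_unit_data):
        epochs, sts = step_unit_data
        iv = epochs[["visit", "epoch", "start", "end", "kind"]]
        a = sdt.analyze_unit(sts.spikes[0], iv)
        shuffled = iv.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = sdt.analyze_unit(sts.spikes[0], shuffled)
        ta = {f.interval_id: f.step_time for f in a.fits if f.success}
        tb = {f.interval_id: f.step_time for f in b.fits if f.success}
        assert ta.keys() == tb.keys()
        for k in ta:
            assert ta[k] == pytest.approx(tb[k], abs=1e-9)

    def test_delay_structure_recovered_across_population(self):
        # recovered mean step times track the generating delay fractions
        epochs = make_step_epochs(50, seed=18, wait_lo=3.0, wait_hi=3.0)
        ev = stub_events_for(epochs)
        pop = sd.make_population(10, seed=18, fraction_on_off=0.0,
                                 delay_range=(0.15, 0.85),
                                 delay_jitter_sd=0.0, participation=1.0)
        sts = sd.simulate_spike_trains(ev, pop, seed=18)
        iv = epochs[["visit", "epoch", "start", "end", "kind"]]
        fracs, means = [], []
        for u, nrn in enumerate(pop):
            prof = sdt.analyze_unit(sts.spikes[u], iv)
            if prof.is_step_like:
                fracs.append(nrn.delay_fraction)
                means.append(prof.mean_step_time)
        assert len(fracs) >= 7
        r = np.corrcoef(fracs, means)[0, 1]
        assert r > 0.9
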