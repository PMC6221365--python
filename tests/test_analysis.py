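"""Analysis toolkit: spike detection, alignment, tuning, phase locking,
stochastic-resonance sweeps and reverse correlation."""

import numpy as np
import pandas as pd
import pytest

from spikesim import (
    RecordingLog,
    align_to_stimulus,
    count_sign_changes,
    detect_spikes,
    sta,
    stochastic_resonance_sweep,
    subthreshold_filter,
    tuning_curves,
    vector_strength,
    vs_null_threshold,
)
from spikesim.analysis import UndefinedResultError


def _log_from(t, v, spike=None, unit_id="u"):
    data = {"t": t, "v": v}
    if spike is not None:
        data["spike"] = spike
    return RecordingLog(unit_id=unit_id, dt=float(t[1] - t[0]),
                        data=pd.DataFrame(data))


class TestDetectSpikes:
    def test_flags_are_authoritative(self):
        t = np.arange(10.0)
        v = np.full(10, -70.0)
        spike = np.zeros(10, dtype=int)
        spike[[2, 5, 9]] = 1
        log = _log_from(t, v, spike)
        assert np.array_equal(detect_spikes(log), [2.0, 5.0, 9.0])

    def test_flat_flagless_trace_is_empty(self):
        t = np.arange(100.0)
        assert len(detect_spikes(_log_from(t, np.full(100, -65.0)))) == 0

    def test_threshold_fallback_finds_reset_shaped_spike(self):
        """A single spike-like excursion in a bare t,v log is one event."""
        t = np.arange(50.0)
        v = np.full(50, -70.0)
        v[20], v[21], v[22] = -20.0, 30.0, -65.0  # upstroke crosses 0 once
        log = _log_from(t, v)
        assert np.array_equal(detect_spikes(log), [21.0])

    def test_refractory_merge(self):
        t = np.arange(0.0, 20.0, 0.5)
        v = np.full(len(t), -70.0)
        v[10] = 10.0
        v[11] = -50.0
        v[12] = 10.0   # second crossing 1 ms later: merged
        log = _log_from(t, v)
        assert len(detect_spikes(log)) == 1


class TestAlignToStimulus:
    def _periodic_log(self):
        t = np.arange(1000.0)
        v = -70.0 + 5.0 * np.sin(2 * np.pi * t / 100.0)
        return _log_from(t, v)

    def test_identical_trials_average_equals_any_row(self):
        log = self._periodic_log()
        aligned = align_to_stimulus(log, np.arange(0.0, 900.0, 100.0), 100.0)
        assert np.allclose(aligned.v_mean, aligned.v_trials[0])

    def test_out_of_range_onsets_dropped_and_counted(self):
        log = self._periodic_log()
        aligned = align_to_stimulus(log, [-100.0, 0.0, 100.0, 980.0], 100.0)
        assert aligned.n_trials == 2
        assert aligned.n_dropped == 2

    def test_no_retained_trial_is_an_error(self):
        log = self._periodic_log()
        with pytest.raises(UndefinedResultError):
            align_to_stimulus(log, [-500.0], 100.0)


class TestTuningCurves:
    def test_metrics_from_synthetic_rasters(self):
        """Known spike patterns map to known count/rate/latency/jitter."""
        def simulate(value, rep):
            if value == 0:
                return []
            # latency shrinks and count grows with value
            lat = 20.0 / value + (0.5 if rep % 2 else 0.0)
            return [lat + 10.0 * k for k in range(int(value))]

        curve = tuning_curves([0.0, 1.0, 2.0, 4.0], simulate, n_repeats=6)
        assert curve.spike_count[0] == 0
        assert np.isnan(curve.latency[0])
        assert np.all(np.diff(curve.spike_count) > 0)
        assert np.all(np.diff(curve.latency[1:]) < 0)
        assert curve.rate_inst[2] == pytest.approx(100.0)  # ISI 10 ms
        assert np.all(curve.jitter[1:] > 0)

    def test_sweep_size_validation(self):
        simulate = lambda v, r: []
        with pytest.raises(ValueError):
            tuning_curves([1.0, 2.0], simulate)
        with pytest.raises(ValueError):
            tuning_curves([1.0, 2.0, 3.0], simulate, n_repeats=3)


class TestVectorStrength:
    def test_perfect_locking(self):
        vs, phase = vector_strength([10.0, 110.0, 210.0], 100.0)
        assert vs == pytest.approx(1.0)
        assert phase == pytest.approx(2 * np.pi * 0.1)

    def test_antiphase_pair_cancels(self):
        vs, _ = vector_strength([0.0, 50.0], 100.0)
        assert vs == pytest.approx(0.0, abs=1e-12)

    def test_uniform_phases_near_zero(self):
        rng = np.random.default_rng(1)
        vs, _ = vector_strength(rng.uniform(0, 1e6, size=10_000), 100.0)
        assert vs < 0.03

    def test_empty_train_rejected(self):
        with pytest.raises(UndefinedResultError):
            vector_strength([], 100.0)

    def test_null_threshold_scales_with_sqrt_n(self):
        """The 95th percentile of the uniform null tracks ~1.73/sqrt(N)."""
        thr = vs_null_threshold(400, seed=0)
        assert thr == pytest.approx(np.sqrt(-np.log(0.05) / 400), rel=0.15)


class TestStochasticResonanceSweep:
    def test_precondition_zero_noise_must_be_silent(self):
        def run_trial(amp, seed):
            return [10.0]  # spikes even at zero noise

        with pytest.raises(ValueError, match="subthreshold"):
            stochastic_resonance_sweep([0.0, 1.0], run_trial, 100.0, n_seeds=2)

    def test_sweep_table_and_best_amplitude(self):
        def run_trial(amp, seed):
            if amp == 0.0:
                return []
            if amp == 1.0:  # perfectly locked spikes
                return [25.0, 125.0, 225.0]
            rng = np.random.default_rng(seed)
            return list(rng.uniform(0, 1000.0, size=20))  # sloppy at high noise

        out = stochastic_resonance_sweep([0.0, 1.0, 5.0], run_trial, 100.0,
                                         n_seeds=4)
        assert out.loc[0, "mean_spike_count"] == 0
        assert np.isnan(out.loc[0, "mean_vs"])
        assert out.attrs["best_amplitude"] == 1.0
        assert out.loc[1, "mean_vs"] > out.loc[2, "mean_vs"]

    def test_amplitudes_must_start_at_zero_sorted(self):
        run_trial = lambda a, s: []
        with pytest.raises(ValueError):
            stochastic_resonance_sweep([1.0, 2.0], run_trial, 100.0)
        with pytest.raises(ValueError):
            stochastic_resonance_sweep([0.0, 2.0, 1.0], run_trial, 100.0)


class TestSta:
    def test_constructed_lag_recovery(self):
        """Spikes placed 3 frames after every +1 frame recover a unit
        impulse at lag 3; other lags stay inside the binomial bound."""
        rng = np.random.default_rng(0)
        frames = rng.choice([-1.0, 1.0], size=5000)
        frame_ms = 20.0
        onsets = np.arange(5000) * frame_ms
        spike_frames = np.nonzero(frames == 1.0)[0] + 3
        spike_frames = spike_frames[spike_frames < 5000]
        spikes = onsets[spike_frames] + 1.0
        filt = sta(frames, onsets, spikes, window=10 * frame_ms)
        assert filt.values[3] == pytest.approx(1.0)
        others = np.delete(filt.values, 3)
        assert np.all(np.abs(others) < 3.0 / np.sqrt(filt.n_spikes))

    def test_early_spikes_excluded_and_counted(self):
        frames = np.ones(100)
        onsets = np.arange(100) * 20.0
        filt = sta(frames, onsets, [30.0, 1500.0], window=200.0)
        assert filt.n_excluded == 1
        assert filt.n_spikes == 1

    def test_constant_stimulus_flagged(self):
        frames = np.full(100, 2.0)
        onsets = np.arange(100) * 20.0
        filt = sta(frames, onsets, [1000.0], window=100.0)
        assert filt.uninformative

    def test_no_usable_spikes_rejected(self):
        frames = np.ones(50)
        onsets = np.arange(50) * 20.0
        with pytest.raises(UndefinedResultError):
            sta(frames, onsets, [10.0], window=400.0)

    def test_lnp_oracle_kernel_recovery(self):
        """A linear-nonlinear-Poisson cell with a known biphasic kernel:
        the STA recovers the kernel with normalised correlation >= 0.9."""
        rng = np.random.default_rng(12)
        n_frames = 40_000
        frame_ms = 20.0
        frames = rng.choice([-1.0, 1.0], size=n_frames)
        onsets = np.arange(n_frames) * frame_ms
        lag = np.arange(10)
        kernel = np.exp(-lag / 2.0) - 0.55 * np.exp(-lag / 4.0)  # biphasic
        drive = np.convolve(frames, kernel)[:n_frames]  # causal filtering
        rate = np.clip(0.1 * (1.0 + 0.8 * drive), 0.0, None)  # rectified-linear
        counts = rng.poisson(rate)
        spikes = np.repeat(onsets + 1.0, counts)
        assert len(spikes) >= 2000
        filt = sta(frames, onsets, spikes, window=10 * frame_ms)
        # filt.values is most-recent-first, i.e. kernel[lag]
        corr = np.corrcoef(filt.values, kernel)[0, 1]
        assert corr >= 0.9


class TestSubthresholdFilter:
    def test_identity_system_yields_unit_impulse(self):
        rng = np.random.default_rng(2)
        s = rng.choice([-1.0, 1.0], size=20_000)
        k = 4
        v = np.roll(s, k)
        filt = subthreshold_filter(s, v, window=10.0, dt=1.0)
        assert filt.values[k] == pytest.approx(1.0, abs=0.05)
        others = np.delete(filt.values, k)
        assert np.all(np.abs(others) < 3.0 / np.sqrt(len(s)))

    def test_uncorrelated_response_is_flat(self):
        rng = np.random.default_rng(3)
        s = rng.choice([-1.0, 1.0], size=20_000)
        v = rng.normal(size=20_000)
        filt = subthreshold_filter(s, v, window=10.0, dt=1.0)
        assert np.all(np.abs(filt.values) < 3.0 / np.sqrt(len(s)))

    def test_zero_variance_stimulus_rejected(self):
        with pytest.raises(UndefinedResultError):
            subthreshold_filter(np.ones(100), np.ones(100), 10.0, 1.0)


class TestSignChangeCount:
    @pytest.mark.parametrize("values,expected", [
        ([1.0, 0.8, 0.5, 0.2], 0),                   # monophasic
        ([1.0, 0.5, -0.6, -0.3], 1),                 # biphasic
        ([0.5, 1.0, -0.8, 0.4], 2),                  # triphasic
        ([1.0, -0.05, 0.04, -0.02], 0),              # sub-floor wiggles
    ])
    def test_shape_classes(self, values, expected):
        assert count_sign_changes(values) == expected
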