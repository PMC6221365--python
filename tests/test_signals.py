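"""Input channels: stimulus generators, photoreceptor, synapses, noise."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spikesim import (
    StimulusConfig,
    binary_noise_stimulus,
    get_mode,
    noise_current,
    photo_current,
    square_stimulus,
    sum_currents,
    synapse_current,
)
from spikesim.signals import read_stimulus_trace


class TestSquareStimulus:
    def test_default_duty_cycle_is_exactly_half(self):
        cfg = StimulusConfig(kind="square", rate=1.0, duty=0.5, amplitude=1.0)
        trace = square_stimulus(cfg, 10_000.0, 1.0)
        assert np.mean(trace > 0) == 0.5

    def test_zero_rate_is_all_low(self):
        cfg = StimulusConfig(kind="square", rate=0.0)
        assert not np.any(square_stimulus(cfg, 1000.0, 1.0))

    def test_rising_edge_count(self):
        cfg = StimulusConfig(kind="square", rate=2.0, amplitude=1.0)
        tr = square_stimulus(cfg, 3000.0, 1.0)
        edges = int(tr[0] > 0) + int(np.sum((tr[1:] > 0) & (tr[:-1] == 0)))
        assert edges == 6

    @given(st.sampled_from([0.1, 0.25, 0.5, 0.75, 0.9]),
           st.sampled_from([1.0, 2.0, 4.0, 5.0]))
    def test_fraction_high_matches_duty(self, duty, rate):
        """Fraction-high equals the duty setting up to one sample per
        period (grid quantisation)."""
        cfg = StimulusConfig(kind="square", rate=rate, duty=duty, amplitude=2.0)
        tr = square_stimulus(cfg, 10 * 1000.0 / rate, 1.0)
        assert np.mean(tr > 0) == pytest.approx(duty, abs=rate / 1000.0)

    def test_invalid_duty_rejected(self):
        with pytest.raises(ValueError):
            StimulusConfig(kind="square", duty=1.5)


class TestBinaryNoise:
    def test_frame_count_at_default_rate(self):
        cfg = StimulusConfig(kind="binary_noise", noise_frame_rate=50.0, seed=1)
        trace, onsets = binary_noise_stimulus(cfg, 10_000.0, 1.0)
        assert len(onsets) == 500
        # constant within each 20-ms frame
        assert np.all(trace.reshape(500, 20) == trace.reshape(500, 20)[:, :1])

    def test_same_seed_reproduces(self):
        cfg = StimulusConfig(kind="binary_noise", seed=42)
        t1, _ = binary_noise_stimulus(cfg, 5000.0, 1.0)
        t2, _ = binary_noise_stimulus(cfg, 5000.0, 1.0)
        assert np.array_equal(t1, t2)

    def test_levels_are_unbiased_and_uncorrelated(self):
        """1e6 frames of +/-1: mean and lag-1 autocorrelation within the
        3/sqrt(N) binomial sampling bound of zero."""
        cfg = StimulusConfig(kind="binary_noise", noise_frame_rate=50.0,
                             amplitude=1.0, seed=7)
        frame_ms = 20.0
        n = 1_000_000
        trace, _ = binary_noise_stimulus(cfg, n * frame_ms, frame_ms)
        assert len(trace) == n
        bound = 3.0 / np.sqrt(n)
        assert abs(trace.mean()) < bound
        assert abs(np.mean(trace[1:] * trace[:-1])) < bound

    def test_unipolar_levels(self):
        cfg = StimulusConfig(kind="binary_noise", amplitude=3.0, seed=5)
        tr, _ = binary_noise_stimulus(cfg, 5000.0, 1.0, unipolar=True)
        assert set(np.unique(tr)) <= {0.0, 3.0}

    def test_frame_shorter_than_dt_rejected(self):
        cfg = StimulusConfig(kind="binary_noise", noise_frame_rate=2000.0, seed=1)
        with pytest.raises(ValueError):
            binary_noise_stimulus(cfg, 1000.0, 1.0)

    def test_seed_required(self):
        cfg = StimulusConfig(kind="binary_noise")
        with pytest.raises(ValueError):
            binary_noise_stimulus(cfg, 1000.0, 1.0)


class TestPhotoCurrent:
    def test_dark_with_zero_baseline_is_silent(self):
        p = get_mode(1)
        assert not np.any(photo_current(np.zeros(1000), p, 1.0))

    def test_on_unit_adapts_under_a_light_step(self):
        """Slow ON transduction: onset peak exceeds steady state, both
        positive."""
        p = get_mode(1)  # ON, tau 500 ms
        light = np.zeros(4000)
        light[1000:3000] = 20.0
        cur = photo_current(light, p, 1.0)
        onset_peak = cur[1000:1200].max()
        steady = cur[2900:3000].mean()
        assert onset_peak > 0 and steady > 0
        assert onset_peak / steady > 1.0

    def test_off_unit_rebounds_at_light_offset(self):
        """Fast OFF transduction: hyperpolarising at onset, near zero in
        steady light, positive transient at offset."""
        p = get_mode(2)  # OFF, tau 50 ms
        light = np.zeros(4000)
        light[1000:3000] = 20.0
        cur = photo_current(light, p, 1.0)
        assert cur[1000] < 0
        assert abs(cur[2900:3000].mean()) < 0.1
        assert cur[3000:3200].max() > 10.0

    def test_adaptation_state_reaches_light_level(self):
        """Under constant light the high-pass output decays to the
        baseline (zero for mode 2)."""
        p = get_mode(2)
        cur = photo_current(np.full(2000, 15.0), p, 1.0)
        assert abs(cur[-1]) < 1e-6

    def test_negative_light_rejected(self):
        with pytest.raises(ValueError):
            photo_current(np.array([0.0, -1.0]), get_mode(1), 1.0)


class TestSynapseCurrent:
    def test_no_events_no_current(self):
        assert not np.any(synapse_current([], 5.0, 10.0, 1000.0, 1.0))

    def test_discrete_integral_matches_closed_form(self):
        """One event of gain g decaying with tau integrates to g*tau
        (within 2% at dt = tau/10)."""
        g, tau = 4.0, 10.0
        tr = synapse_current([0.0], g, tau, 2000.0, tau / 10.0)
        integral = np.trapezoid(tr, dx=tau / 10.0)
        assert integral == pytest.approx(g * tau, rel=0.02)

    def test_sign_flip_negates_trace(self):
        spikes = [5.0, 40.0, 41.0, 200.0]
        pos = synapse_current(spikes, 3.0, 10.0, 500.0, 1.0)
        neg = synapse_current(spikes, -3.0, 10.0, 500.0, 1.0)
        assert np.array_equal(pos, -neg)

    @given(st.lists(st.floats(min_value=0.0, max_value=499.0), max_size=8),
           st.lists(st.floats(min_value=0.0, max_value=499.0), max_size=8))
    def test_linearity_over_spike_trains(self, train_a, train_b):
        """Response to two merged trains equals the sum of responses."""
        merged = train_a + train_b
        lhs = synapse_current(merged, 2.0, 10.0, 500.0, 1.0)
        rhs = (synapse_current(train_a, 2.0, 10.0, 500.0, 1.0)
               + synapse_current(train_b, 2.0, 10.0, 500.0, 1.0))
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_bad_tau_and_out_of_range_times_rejected(self):
        with pytest.raises(ValueError):
            synapse_current([0.0], 1.0, 0.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            synapse_current([150.0], 1.0, 10.0, 100.0, 1.0)


class TestNoiseCurrent:
    def test_zero_amplitude_is_silent(self):
        assert not np.any(noise_current(0.0, 1000.0, 1.0, seed=1))

    def test_sample_sd_matches_dial(self):
        tr = noise_current(2.5, 100_000.0, 1.0, seed=3)
        assert np.std(tr) == pytest.approx(2.5, rel=0.05)
        assert abs(np.mean(tr)) < 0.05

    def test_seeded_reproducibility(self):
        t1 = noise_current(1.0, 1000.0, 1.0, seed=9)
        t2 = noise_current(1.0, 1000.0, 1.0, seed=9)
        assert np.array_equal(t1, t2)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            noise_current(-1.0, 100.0, 1.0)


class TestSumCurrents:
    def test_all_zero_channels(self):
        bd = sum_currents(n=100)
        assert not np.any(bd.i_total)

    def test_single_channel_passthrough(self):
        x = np.arange(50.0)
        bd = sum_currents(i_photo=x)
        assert np.array_equal(bd.i_total, x)

    def test_total_is_componentwise_sum(self):
        rng = np.random.default_rng(0)
        parts = {k: rng.normal(size=200) for k in
                 ("i_photo", "i_syn1", "i_syn2", "i_analog", "i_noise", "i_static")}
        bd = sum_currents(**parts)
        assert np.allclose(bd.i_total - sum(parts.values()), 0.0, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sum_currents(i_photo=np.zeros(10), i_noise=np.zeros(11))


class TestExternalTrace:
    def test_two_column_interpolation(self, tmp_path):
        p = tmp_path / "stim.txt"
        p.write_text("0 0.0\n100 10.0\n200 0.0\n")
        tr = read_stimulus_trace(p, 200.0, 1.0)
        assert len(tr) == 200
        assert tr[50] == pytest.approx(5.0)

    def test_single_column_length_check(self, tmp_path):
        p = tmp_path / "stim.txt"
        np.savetxt(p, np.ones(100))
        assert len(read_stimulus_trace(p, 100.0, 1.0)) == 100
        with pytest.raises(ValueError):
            read_stimulus_trace(p, 200.0, 1.0)
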