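"""Behavioral contracts of the phenomenological memristive synapse."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memsyn.device import (
    ConvergenceError,
    DeviceParams,
    PulseWaveform,
    apply_waveform,
    init_device,
    read_conductance,
    relax,
    set_experience,
    simulate_epsc,
    simulate_ppf,
    simulate_rate_train,
    step,
)


class TestInitAndRead:
    def test_init_sets_quiet_state_at_requested_conductance(self, params):
        state = init_device(0.1, params)
        assert state.g == state.g0 == 0.1
        assert state.u == 0.0 and state.t == 0.0

    @pytest.mark.parametrize("bad", [0.05, 9.0])
    def test_out_of_range_init_names_the_bound(self, params, bad):
        with pytest.raises(ValueError, match="g_min|g_max"):
            init_device(bad, params)

    def test_boundary_init_is_allowed(self, params):
        state = init_device(params.g_min, params)
        assert state.g == params.g_min and state.u == 0.0

    def test_noiseless_read_returns_g_exactly_and_repeatably(self, params):
        state = init_device(0.1, params)
        first = read_conductance(state, params)
        second = read_conductance(state, params)
        assert first == second == 0.1
        # read is non-destructive: state is bitwise untouched
        assert state == init_device(0.1, params)

    def test_noisy_read_mean_matches_g(self, params):
        noisy = replace(params, noise_sd=0.02)
        state = init_device(1.0, noisy)
        rng = np.random.default_rng(7)
        reads = np.array([read_conductance(state, noisy, rng) for _ in range(10_000)])
        se = 0.02 * 1.0 / math.sqrt(len(reads))
        assert abs(reads.mean() - 1.0) < 3 * se
        assert state.g == 1.0  # readout never writes


class TestStep:
    def test_rejects_nonfinite_and_nonpositive_dt(self, params):
        state = init_device(0.1, params)
        with pytest.raises(ValueError):
            step(state, math.nan, 1e-3, params)
        with pytest.raises(ValueError):
            step(state, 1.0, 0.0, params)

    def test_internal_state_relaxes_within_five_time_constants(self, params):
        state = init_device(0.1, params)
        for _ in range(100):
            state = step(state, 2.0, 1e-3, params)
        u_start = state.u
        state = relax(state, 5 * params.tau_u, params)
        assert state.u < 0.01 * u_start

    def test_read_bias_never_writes(self, params):
        state = init_device(0.5, params)
        read = state.copy()
        for _ in range(200):
            read = step(read, params.v_read, 1e-3, params)
        # identical to letting the device sit: only the spontaneous leak acts
        assert read.g == pytest.approx(relax(state, 0.2, params).g, abs=1e-9)

    def test_paired_write_pulses_facilitate(self, params):
        # two +2 V, 50 ms steps closer than tau_u raise g by more than twice
        # a single step's increment: the second rides on residual accumulation
        def drive(n):
            s = init_device(0.5, params)
            for _ in range(n):
                for _ in range(50):
                    s = step(s, 2.0, 1e-3, params)
                s = relax(s, 0.05, params)
            return s.g - 0.5

        assert drive(2) > 2 * drive(1) > 0


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_state_stays_within_bounds_under_random_waveforms(data):
    """g within [g_min, g_max] and |u| <= 1 after arbitrary stimulation."""
    params = DeviceParams()
    g_init = data.draw(st.floats(params.g_min, params.g_max))
    state = init_device(g_init, params)
    n = data.draw(st.integers(5, 60))
    for _ in range(n):
        v = data.draw(st.floats(-6.0, 6.0))
        state = step(state, v, 1e-3, params)
    assert params.g_min <= state.g <= params.g_max
    assert abs(state.u) <= 1.0


class TestApplyWaveform:
    def test_empty_waveforms_leave_state_unchanged(self, params):
        state = init_device(0.5, params)
        out, trace = apply_waveform(state, PulseWaveform(), PulseWaveform(), 1e-3, params)
        assert out.g == state.g and len(trace.times) == 0

    def test_identical_pulses_on_both_electrodes_cancel(self, params):
        pulse = PulseWaveform(((0.0, 0.05, 2.0),))
        state = init_device(0.5, params)
        out, trace = apply_waveform(state, pulse, pulse, 1e-3, params)
        assert out.g == pytest.approx(relax(state, 0.05, params).g, abs=1e-9)  # leak only
        assert out.u == 0.0
        assert np.all(trace.current == 0.0)

    def test_top_pulse_mirrors_bottom_pulse_in_conductance_change(self, params):
        sym = replace(
            params,
            eta_dep=params.eta_pot,
            u_on_dep=params.u_on_pot,
            u_sat_dep=params.u_sat_pot,
            tau_forget=math.inf,
        )
        pulse = PulseWaveform(((0.0, 0.05, 2.0),))
        top_only, _ = apply_waveform(init_device(3.0, sym), pulse, PulseWaveform(), 1e-3, sym)
        bottom_only, _ = apply_waveform(init_device(3.0, sym), PulseWaveform(), pulse, 1e-3, sym)
        assert abs((top_only.g - 3.0) + (bottom_only.g - 3.0)) < 1e-9

    def test_overlapping_segments_within_one_waveform_are_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PulseWaveform(((0.0, 0.05, 2.0), (0.02, 0.05, 2.0)))

    def test_from_pulses_sums_overlapping_amplitudes(self):
        wf = PulseWaveform.from_pulses([(0.0, 0.1, 2.0), (0.05, 0.1, 2.0)])
        assert wf.voltage_at(0.075) == 4.0
        assert wf.voltage_at(0.02) == 2.0
        assert wf.voltage_at(0.12) == 2.0


class TestEPSC:
    def test_returns_to_baseline_within_400_ms(self, params):
        state = init_device(0.1, params)
        trace = simulate_epsc(state, params)
        baseline = 0.1 * params.v_read
        after = trace.current[10:]  # past the 10 ms pulse
        inside = np.nonzero(np.abs(after - baseline) <= 0.05 * baseline)[0]
        assert len(inside) > 0
        assert (inside[0] + 1) * 1e-3 <= 0.4

    def test_post_pulse_decay_is_monotone_toward_baseline(self, params):
        trace = simulate_epsc(init_device(0.1, params), params)
        decay = trace.current[10:]
        assert np.all(np.diff(decay) <= 1e-12)

    def test_decay_time_constant_matches_internal_state(self, params):
        trace = simulate_epsc(init_device(0.1, params), params)
        # transient above the final read current is proportional to u
        tail = trace.current[12:260] - trace.current[-1]
        slope = np.polyfit(trace.times[12:260], np.log(tail), 1)[0]
        assert abs(-1.0 / slope - params.tau_u) / params.tau_u < 0.02

    def test_zero_amplitude_gives_flat_trace(self, params):
        trace = simulate_epsc(init_device(0.1, params), params, amplitude=params.v_read)
        assert np.allclose(trace.current, trace.current[0])

    def test_nonpositive_follow_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_epsc(init_device(0.1, params), params, follow=0.0)


class TestPPF:
    def test_facilitation_present_and_decreasing_with_interval(self, params):
        state = init_device(0.1, params)
        ratios = [simulate_ppf(state, params, iv)[1] / simulate_ppf(state, params, iv)[0]
                  for iv in (0.05, 0.2, 0.4)]
        assert ratios[0] > 1.0
        assert ratios[0] > ratios[1] > ratios[2]

    def test_strictly_decreasing_across_the_full_window(self, params):
        state = init_device(0.1, params)
        ivals = (0.02, 0.05, 0.1, 0.2, 0.5, 1.0)
        ratios = [np.divide(*simulate_ppf(state, params, iv)[::-1]) for iv in ivals]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_full_relaxation_limit_returns_to_unity(self, params):
        state = init_device(0.1, params)
        p1, p2 = simulate_ppf(state, params, 10 * params.tau_u)
        assert abs(p2 / p1 - 1.0) < 0.01

    def test_interval_below_width_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_ppf(init_device(0.1, params), params, interval=0.005)


class TestRateTrains:
    def test_amplitude_ordering_20_50_100_Hz(self, params):
        state = init_device(0.1, params)
        peaks = {r: simulate_rate_train(state, params, r).peak for r in (20, 50, 100)}
        assert peaks[100] > peaks[50] > peaks[20]

    def test_single_pulse_train_reduces_to_epsc(self, params):
        state = init_device(0.1, params)
        train = simulate_rate_train(state, params, 20.0, n_pulses=1)
        epsc = simulate_epsc(state, params)
        assert abs(train.peak - epsc.peak) < 1e-12

    def test_low_rate_limit_approaches_single_pulse_amplitude(self, params):
        state = init_device(0.1, params)
        single = simulate_epsc(state, params).peak
        slow = simulate_rate_train(state, params, 0.5, n_pulses=8).peak
        assert abs(slow - single) / single < 0.02

    def test_overlapping_pulses_rejected(self, params):
        with pytest.raises(ValueError, match="overlap"):
            simulate_rate_train(init_device(0.1, params), params, rate=200.0)


class TestSetExperience:
    @pytest.mark.parametrize("target", [0.5, 3.0, 7.0])
    def test_reaches_target_within_two_percent(self, params, target):
        state = set_experience(init_device(0.1, params), target, params)
        assert abs(state.g - target) <= 0.02 * target
        assert state.g0 == state.g

    def test_target_equal_to_current_state_applies_no_pulses(self, params):
        state = init_device(0.5, params)
        out = set_experience(state, 0.5, params)
        # no stimulation: only the settling relaxation (and its leak) acts
        assert out.g == relax(state, out.t, params).g

    def test_out_of_range_target_rejected(self, params):
        with pytest.raises(ValueError):
            set_experience(init_device(0.1, params), 9.0, params)

    def test_unreachable_target_raises_convergence_error(self, params):
        dead = replace(params, eta_pot=0.0)  # no potentiation pathway at all
        with pytest.raises(ConvergenceError):
            set_experience(init_device(0.1, dead), 3.0, dead, max_pulses=200)

    def test_stronger_experience_forgets_more_over_a_minute(self, params):
        high = set_experience(init_device(0.1, params), 3.0, params)
        low = set_experience(init_device(0.1, params), 0.5, params)
        drop_high = high.g - relax(high, 60.0, params).g
        drop_low = low.g - relax(low, 60.0, params).g
        assert drop_high > drop_low > 0


def test_rate_history_modulates_monitored_conductance(params):
    """Four-phase rate sequence (50 → 10 → 5 → 10 Hz) on the transient-inclusive
    conductance: high-rate trains raise the monitored level, lower rates let it
    sag, and returning to the middle rate recovers an intermediate level."""

    def train_level(state, rate, n=25, width=0.01):
        s = state.copy()
        level = 0.0
        for _ in range(n):
            for _ in range(int(width / 1e-3)):
                s = step(s, 2.0, 1e-3, params)  # post spike on the bottom electrode
            level = s.g * (1 + params.epsc_gain * s.u)
            s = relax(s, max(1.0 / rate - width, 0.0), params)
        return s, level

    state = init_device(0.5, params)
    state.g0 = 0.5
    state, at50 = train_level(state, 50)
    state, at10 = train_level(state, 10)
    state, at5 = train_level(state, 5)
    state, at10_again = train_level(state, 10)
    assert at50 > at10 > at5
    assert at5 < at10_again < at50
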