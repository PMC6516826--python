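"""Intrinsic-feature extraction: spike detection, SFA, firing-pattern rules,
input-resistance and time-constant estimation, sag ratio, rheobase."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icvip import ephys
from icvip.errors import (
    ConfigurationError,
    InsufficientDataError,
    NotClassifiableError,
)
from icvip.ephys import (
    SweepRecording,
    classify_firing,
    compute_sfa,
    detect_spikes,
    estimate_tau,
    extract_profile,
    fit_input_resistance,
    rheobase,
    sag_ratio,
)
from icvip.synth.membrane import (
    MembraneConfig,
    model_sag_ratio,
    model_steady_state_resistance,
    model_peak_resistance,
    simulate_step_protocol,
)

from conftest import make_rc_sweep, insert_spike


def flat_sweep(v=-70.0, amp=100.0, rate=50.0, dur=500.0):
    t = np.arange(int(dur * rate) + 1) / rate
    return SweepRecording(time=t, voltage=np.full_like(t, v),
                          command_current=amp, step_onset=100.0,
                          step_offset=400.0, sampling_rate=rate)


def sweep_with_spikes(spike_times, amp=100.0, onset=100.0, offset=400.0,
                      rate=50.0, dur=500.0, v=-70.0):
    t = np.arange(int(dur * rate) + 1) / rate
    volt = np.full_like(t, v)
    for ts in spike_times:
        insert_spike(volt, t, ts, rate)
    return SweepRecording(time=t, voltage=volt, command_current=amp,
                          step_onset=onset, step_offset=offset,
                          sampling_rate=rate)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert detect_spikes(flat_sweep()).size == 0

    def test_single_inserted_spike_found_at_its_time(self):
        sw = sweep_with_spikes([50.0], dur=200.0, offset=150.0)
        st_ = detect_spikes(sw)
        assert st_.size == 1
        assert st_[0] == pytest.approx(50.0, abs=0.2)

    def test_count_matches_simulator_ground_truth(self):
        cfg = MembraneConfig(adaptation_increment=30.0)
        sweeps = simulate_step_protocol(cfg, [75.0, 150.0, 225.0], 300.0,
                                        seed=3)
        for sw in sweeps:
            assert detect_spikes(sw).size == sw.true_spike_times.size

    def test_coarse_sampling_rejected(self):
        t = np.arange(0, 500.0, 0.5)   # 2 kHz
        sw = SweepRecording(t, np.full_like(t, -70.0), 0.0, 100.0, 400.0,
                            sampling_rate=2.0)
        with pytest.raises(ConfigurationError):
            detect_spikes(sw)


class TestSFA:
    def test_uniform_isis_give_unity(self):
        assert compute_sfa(np.arange(10) * 10.0) == pytest.approx(1.0)

    def test_last_over_first_isi(self):
        # ISIs 5, 8, 12, 20 -> 20/5 = 4
        assert compute_sfa([0.0, 5.0, 13.0, 25.0, 45.0]) == pytest.approx(4.0)

    def test_too_few_spikes_is_undefined(self):
        with pytest.raises(InsufficientDataError):
            compute_sfa([10.0, 20.0])

    @given(scale=st.floats(0.1, 10.0), shift=st.floats(0.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_time_rescaling_and_shift(self, scale, shift):
        base = np.array([0.0, 5.0, 13.0, 25.0, 45.0])
        assert compute_sfa(base * scale + shift) == pytest.approx(
            compute_sfa(base), rel=1e-9)


class TestClassifyFiring:
    def test_sfa_threshold_at_two(self):
        # ISIs chosen so last/first is exactly 1.99 (sustained) or 2.00
        for ratio, expected in [(1.99, "sustained"), (2.00, "adapting")]:
            isis = np.linspace(10.0, 10.0 * ratio, 12)
            times = 110.0 + np.concatenate([[0.0], np.cumsum(isis)])
            sw = sweep_with_spikes(times, offset=400.0)
            cls = classify_firing([sw])
            assert cls.firing_class == expected
            assert cls.sfa == pytest.approx(ratio, rel=1e-6)

    def test_firing_that_stops_early_is_transient(self):
        # 100 ms step, spikes at 5/10/15 ms after onset, then silence
        sw = sweep_with_spikes([105.0, 110.0, 115.0], onset=100.0,
                               offset=200.0, dur=300.0)
        assert classify_firing([sw]).firing_class == "transient"

    def test_every_sweep_one_spike_is_single_spike(self):
        sweeps = [sweep_with_spikes([105.0], amp=a) for a in (100.0, 200.0)]
        assert classify_firing(sweeps).firing_class == "single_spike"

    def test_selection_prefers_count_closest_to_ten_then_lower_current(self):
        s8 = sweep_with_spikes(110.0 + np.arange(8) * 20.0, amp=100.0)
        s12 = sweep_with_spikes(110.0 + np.arange(12) * 20.0, amp=200.0)
        cls = classify_firing([s8, s12])
        assert cls.step_current == 100.0      # |8-10| == |12-10|, tie -> lower
        assert cls.n_spikes == 8

    def test_no_suprathreshold_sweep_is_not_classifiable(self):
        with pytest.raises(NotClassifiableError):
            classify_firing([flat_sweep()])

    def test_cohort_recovers_generating_mixture(self):
        # 18 low-adaptation + 6 high-adaptation neurons; the classifier's
        # sustained/adapting split should match the generating labels
        from icvip.synth import cohort as co
        rng = np.random.default_rng(0)
        n_low, n_high = 18, 6
        got = {"low": 0, "high": 0}
        for kind, n in (("low", n_low), ("high", n_high)):
            pop = ({"sfa_mean": 1.2, "sfa_sd": 0.1} if kind == "low"
                   else {"sfa_mean": 3.0, "sfa_sd": 0.3})
            for neuron in co.generate_ephys_cohort(
                    n, seed=int(rng.integers(2**31)), population=pop,
                    n_tau_repeats=2):
                cls = classify_firing(neuron.sweeps)
                if cls.firing_class == "sustained":
                    got["low"] += 1
                elif cls.firing_class == "adapting":
                    got["high"] += 1
        # binomial tolerance: misclassification only near the SFA=2 border
        assert abs(got["low"] - n_low) <= 3
        assert abs(got["high"] - n_high) <= 3


class TestInputResistance:
    def test_ohmic_family_recovers_resistance(self):
        sweeps = [make_rc_sweep(a, 200.0) for a in (-25.0, -50.0, -75.0)]
        r_pk, r_ss = fit_input_resistance(sweeps)
        assert r_pk == pytest.approx(200.0, rel=1e-3)
        assert r_ss == pytest.approx(200.0, rel=1e-3)

    def test_peak_window_excludes_large_steps(self):
        # -75 pA at 200 MOhm peaks at exactly -15 mV: outside (0, -15)
        sweeps = [make_rc_sweep(a, 200.0) for a in (-25.0, -50.0, -75.0)]
        v_rest = ephys.resting_potential(sweeps)
        qual = ephys._qualifying_resistance_sweeps(sweeps, v_rest)
        assert [s.command_current for s in qual] == [-25.0, -50.0]

    def test_sweep_peaking_at_minus_twenty_is_excluded(self):
        sweeps = [make_rc_sweep(-25.0, 200.0), make_rc_sweep(-50.0, 200.0),
                  make_rc_sweep(-100.0, 200.0)]   # peak -20 mV
        v_rest = ephys.resting_potential(sweeps)
        qual = ephys._qualifying_resistance_sweeps(sweeps, v_rest)
        assert all(s.command_current != -100.0 for s in qual)

    def test_single_qualifying_sweep_is_insufficient(self):
        sweeps = [make_rc_sweep(-25.0, 200.0), make_rc_sweep(-100.0, 200.0)]
        with pytest.raises(InsufficientDataError):
            fit_input_resistance(sweeps)

    def test_sag_neuron_matches_closed_form_resistances(self):
        cfg = MembraneConfig(noise_sd=0.0, adaptation_increment=0.0)
        amps = [-60.0, -45.0, -30.0, -15.0]
        sweeps = simulate_step_protocol(cfg, amps, 300.0, seed=0)
        r_pk, r_ss = fit_input_resistance(sweeps)
        assert r_ss < r_pk
        assert r_pk == pytest.approx(model_peak_resistance(cfg), rel=0.01)
        assert r_ss == pytest.approx(model_steady_state_resistance(cfg),
                                     rel=0.01)


class TestTau:
    def test_ideal_rc_recovered_exactly(self):
        # C = 150 pF, g = 10 nS -> tau = 15 ms; -20 pA deflects by 2 mV
        sweeps = [make_rc_sweep(-20.0, 100.0, tau_ms=15.0)]
        assert estimate_tau(sweeps) == pytest.approx(15.0, abs=0.1)

    def test_median_of_known_per_sweep_fits(self):
        sweeps = [make_rc_sweep(-20.0, 100.0, tau_ms=tau)
                  for tau in (10.0, 15.0, 22.0)]
        assert estimate_tau(sweeps) == pytest.approx(15.0, abs=0.1)

    def test_noisy_repeats_recover_within_five_percent(self):
        cfg = MembraneConfig(noise_sd=0.3, adaptation_increment=0.0)
        g = cfg.leak_conductance + cfg.sag_conductance
        sweeps = simulate_step_protocol(cfg, [-2.5 * g] * 50, 300.0, seed=11)
        assert estimate_tau(sweeps) == pytest.approx(cfg.membrane_tau,
                                                     rel=0.05)

    def test_no_small_sweep_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            estimate_tau([make_rc_sweep(-100.0, 200.0)])


class TestSagRatio:
    def test_no_sag_gives_unity(self):
        sw = make_rc_sweep(-105.0, 200.0, v_rest=-70.0)   # peak -91 mV
        assert sag_ratio([sw], target_peak=-91.0) == pytest.approx(1.0,
                                                                   abs=1e-3)

    def test_arithmetic_of_partial_sag(self):
        # V_rest -70, V_pk -91, V_ss -85 -> (85-70)/(91-70) = 15/21
        rate = 50.0
        t = np.arange(int(500 * rate) + 1) / rate
        v = np.full_like(t, -70.0)
        instep = (t >= 100.0) & (t < 400.0)
        v[instep] = -91.0 + 6.0 * (1.0 - np.exp(-(t[instep] - 100.0) / 30.0))
        sw = SweepRecording(t, v, -105.0, 100.0, 400.0, rate)
        assert sag_ratio([sw], target_peak=-91.0) == pytest.approx(
            15.0 / 21.0, abs=1e-3)

    def test_simulated_sag_matches_closed_form(self):
        cfg = MembraneConfig(noise_sd=0.0, adaptation_increment=0.0)
        g_pk = model_peak_resistance(cfg) * 1e-3
        amp = -21.5 / g_pk                     # peak ~ -91 mV from -69.5
        sweeps = simulate_step_protocol(cfg, [amp], 400.0, seed=0)
        ratio = sag_ratio(sweeps, target_peak=-91.0)
        assert ratio == pytest.approx(model_sag_ratio(cfg), rel=0.02)

    def test_no_sweep_near_target_is_missing(self):
        sw = make_rc_sweep(-25.0, 200.0)       # peak -75 mV, far from -111
        assert sag_ratio([sw], target_peak=-111.0) is None


class TestRheobase:
    def test_first_spiking_amplitude(self):
        sweeps = [sweep_with_spikes([], amp=a) for a in (25.0, 50.0)]
        sweeps += [sweep_with_spikes([150.0, 160.0], amp=75.0),
                   sweep_with_spikes([140.0] + list(range(150, 200, 10)),
                                     amp=100.0)]
        assert rheobase(sweeps) == 75.0

    def test_all_subthreshold_is_missing(self):
        assert rheobase([flat_sweep(amp=a) for a in (25.0, 50.0)]) is None

    def test_simulated_neuron_matches_analytic_threshold(self):
        cfg = MembraneConfig(noise_sd=0.0, adaptation_increment=0.0)
        amps = [25.0 * k for k in range(1, 13)]
        sweeps = simulate_step_protocol(cfg, amps, 300.0, seed=0)
        # depolarizing responses are RC only (rectified sag), so the
        # threshold current is (V_th - E_L) * g_L
        i_th = (cfg.spike_threshold - cfg.leak_reversal) * cfg.leak_conductance
        measured = rheobase(sweeps)
        assert measured - 25.0 <= i_th <= measured


class TestExtractProfile:
    def test_missing_features_are_none_not_errors(self):
        prof = extract_profile([flat_sweep(amp=-25.0),
                                flat_sweep(amp=25.0)])
        assert prof.v_rest == pytest.approx(-70.0)
        assert prof.rheobase is None
        assert prof.firing_class is None
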