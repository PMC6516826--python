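import numpy as np
import pytest

from icvip.ephys import SweepRecording


def make_rc_sweep(amplitude_pa, resistance_mohm, tau_ms=15.0,
                  v_rest=-70.0, onset=100.0, duration=300.0,
                  rate_khz=50.0, post=100.0, sag_fraction=0.0,
                  sag_tau=40.0):
    """Analytic step response (optionally with a slow sag relaxation toward
    a shallower steady state), built without the simulator."""
    dt = 1.0 / rate_khz
    t = np.arange(int(round((onset + duration + post) / dt)) + 1) * dt
    dv_peak = amplitude_pa * resistance_mohm * 1e-3   # pA * MOhm -> mV
    dv_ss = dv_peak * (1.0 - sag_fraction)
    v = np.full_like(t, v_rest)
    instep = (t >= onset) & (t < onset + duration)
    x = t[instep] - onset
    fast = dv_peak * (1.0 - np.exp(-x / tau_ms))
    relax = (dv_ss - dv_peak) * (1.0 - np.exp(-x / sag_tau)) if sag_fraction else 0.0
    v[instep] = v_rest + fast + (relax if sag_fraction else 0.0)
    after = t >= onset + duration
    v[after] = v_rest + (v[instep][-1] - v_rest) * np.exp(
        -(t[after] - (onset + duration)) / tau_ms)
    return SweepRecording(time=t, voltage=v, command_current=amplitude_pa,
                          step_onset=onset, step_offset=onset + duration,
                          sampling_rate=rate_khz)


def insert_spike(voltage, time, at_ms, rate_khz, peak=35.0, width_ms=0.6):
    """Paste a triangular spike waveform into a trace at ``at_ms``."""
    i = int(round(at_ms * rate_khz))
    half = max(2, int(round(width_ms * rate_khz / 2)))
    base = voltage[i]
    up = np.linspace(base, peak, half + 1)[1:]
    down = np.linspace(peak, base, half + 1)[1:]
    voltage[i + 1:i + 1 + 2 * half] = np.concatenate([up, down])
    return voltage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
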