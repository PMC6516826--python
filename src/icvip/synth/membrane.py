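"""Single-compartment membrane model for synthetic current-clamp sweeps.

The model is an adaptive threshold-reset (leaky integrate-and-fire) neuron
with a slow, linear sag current standing in for I_h:

    C dV/dt     = -g_L (V - E_L) - I_h - w + I_inj(t)
    tau_h dI_h/dt = g_h min(V - V_on, 0) - I_h,   V_on = E_L - delta
    tau_w dw/dt = -w,   w -> w + b at each spike

The sag current is rectified and offset -- hyperpolarization-activated like
I_h, which is far from its half-activation voltage at rest -- so it engages
only once the membrane falls ``sag_activation_offset`` (delta) below the
resting potential.  Depolarizing responses and small hyperpolarizations
(the 1-3 mV steps of the time-constant protocol) are therefore purely
RC (+ adaptation), while larger steps show the characteristic sag.

Units: mV, pA, nS, pF, ms (so pA/nS = mV and pF/nS = ms).  When V crosses the
spike threshold, a spike is recorded, V is reset, and the adaptation current
w is incremented by ``adaptation_increment``.  Hyperpolarizing steps activate
the sag current (g_h > 0), producing a peak deflection larger than the
steady-state deflection, as in recordings with I_h.  The subthreshold system
is linear, so its step response has a closed form used for oracle checks and
for calibrating cohorts (:func:`subthreshold_response`).

Integration is fixed-step exponential Euler at the configured sampling rate:
each state variable relaxes exactly toward its instantaneous target over one
time step while the other states are held.  A stereotyped spike peak (+30 mV)
is pasted into the recorded trace at each spike time so that slope-based
spike detection sees a realistic upstroke.  Gaussian measurement noise
(``noise_sd``) is added to the recorded trace only; the dynamics themselves
are deterministic given the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numba
import numpy as np
from scipy.optimize import minimize_scalar

from ..errors import ConfigurationError
from ..ephys import SweepRecording

#: Pasted spike peak (mV).
SPIKE_PEAK_MV = 30.0


@dataclass
class MembraneConfig:
    """Parameters of the synthetic membrane.

    Defaults describe a typical VIP neuron: resting potential near -69.5 mV,
    peak input resistance in the low-200 MOhm range, membrane time constant
    around 15 ms, and a modest sag conductance giving sag ratios near 0.87.
    """

    capacitance: float = 62.0            # pF
    leak_conductance: float = 4.13       # nS
    leak_reversal: float = -69.5         # mV
    sag_conductance: float = 0.62        # nS, >= 0
    sag_time_constant: float = 40.0      # ms
    sag_activation_offset: float = 3.0   # mV below rest before sag engages
    spike_threshold: float = -53.0       # mV
    reset_potential: float = -60.0       # mV
    adaptation_increment: float = 15.0   # pA per spike
    adaptation_time_constant: float = 60.0  # ms
    noise_sd: float = 0.2                # mV, measurement noise
    sampling_rate: float = 50.0          # kHz

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ConfigurationError(f"{f.name} must be finite, got {v!r}")
        if self.capacitance <= 0:
            raise ConfigurationError("capacitance must be > 0")
        if self.leak_conductance <= 0:
            raise ConfigurationError("leak_conductance must be > 0")
        if self.sag_conductance < 0:
            raise ConfigurationError("sag_conductance must be >= 0")
        if self.sag_time_constant <= 0 or self.adaptation_time_constant <= 0:
            raise ConfigurationError("time constants must be > 0")
        if self.sag_activation_offset < 0:
            raise ConfigurationError("sag_activation_offset must be >= 0")
        if self.adaptation_increment < 0:
            raise ConfigurationError("adaptation_increment must be >= 0")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def membrane_tau(self) -> float:
        """Fast (onset) time constant C/g_L in ms."""
        return self.capacitance / self.leak_conductance


def simulate_step_protocol(config: MembraneConfig,
                           step_amplitudes: Sequence[float],
                           step_duration: float,
                           seed: int,
                           pre_ms: float = 100.0,
                           post_ms: float = 100.0,
                           neuron_id: Optional[str] = None,
                           ) -> list[SweepRecording]:
    """Simulate one sweep per step amplitude; deterministic given ``seed``.

    All sweeps share a time base: ``pre_ms`` of baseline, ``step_duration``
    of constant current injection, ``post_ms`` of recovery.
    """
    amps = np.asarray(step_amplitudes, dtype=float)
    if amps.size == 0:
        raise ConfigurationError("step_amplitudes must be non-empty")
    if not np.all(np.isfinite(amps)):
        raise ConfigurationError("step amplitudes must be finite")
    if step_duration <= 0:
        raise ConfigurationError("step_duration must be > 0")

    dt = 1.0 / config.sampling_rate
    n = int(round((pre_ms + step_duration + post_ms) / dt)) + 1
    time = np.arange(n) * dt
    onset, offset = pre_ms, pre_ms + step_duration

    traces, spike_lists = _integrate(config, amps, time, onset, offset)

    rng = np.random.default_rng(seed)
    if config.noise_sd > 0:
        traces = traces + _band_limited_noise(rng, traces.shape,
                                              config.noise_sd)

    sweeps = []
    for j, amp in enumerate(amps):
        sweeps.append(SweepRecording(
            time=time.copy(), voltage=traces[j], command_current=float(amp),
            step_onset=onset, step_offset=offset,
            sampling_rate=config.sampling_rate, neuron_id=neuron_id,
            true_spike_times=np.asarray(spike_lists[j])))
    return sweeps


def _band_limited_noise(rng: np.random.Generator, shape, sd: float,
                        kernel_sigma_samples: float = 2.0) -> np.ndarray:
    """Gaussian measurement noise smoothed to emulate the acquisition
    low-pass filter; the kernel is L2-normalized so the output SD stays
    ``sd``."""
    from scipy.signal import fftconvolve
    white = rng.normal(0.0, sd, size=shape)
    half = int(math.ceil(4 * kernel_sigma_samples))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / kernel_sigma_samples) ** 2)
    k /= np.linalg.norm(k)
    return fftconvolve(white, k[None, :], mode="same", axes=-1)


@numba.njit(cache=False)
def _integrate_core(amps, time, in_step, g_l, g_h, v_on, e_l, e_m, e_h, e_w,
                    v_th, v_reset, b, spike_peak):  # pragma: no cover - jit
    m = amps.size
    n = time.size
    traces = np.empty((m, n))
    max_spikes = n // 10 + 8
    spike_times = np.full((m, max_spikes), np.nan)
    n_spikes = np.zeros(m, dtype=np.int64)
    for j in range(m):
        v = e_l
        ih = 0.0
        w = 0.0
        traces[j, 0] = v
        for i in range(1, n):
            i_inj = amps[j] if in_step[i - 1] else 0.0
            # I_h is hyperpolarization-activated: the sag current engages
            # only once the membrane falls below V_on = E_L - delta
            dv = v - v_on
            ih_tgt = g_h * (dv if dv < 0.0 else 0.0)
            ih = ih_tgt + (ih - ih_tgt) * e_h
            w = w * e_w
            v_inf = e_l + (i_inj - ih - w) / g_l
            v = v_inf + (v - v_inf) * e_m
            if v >= v_th:
                k = n_spikes[j]
                if k < max_spikes:
                    spike_times[j, k] = time[i]
                    n_spikes[j] = k + 1
                v = v_reset
                w = w + b
                traces[j, i] = spike_peak
            else:
                traces[j, i] = v
    return traces, spike_times, n_spikes


def _integrate(config: MembraneConfig, amps: np.ndarray, time: np.ndarray,
               onset: float, offset: float):
    """Exponential-Euler integration across sweep amplitudes (jit core)."""
    dt = time[1] - time[0]
    # current over the update interval (t[i-1], t[i]]: on when the interval
    # starts inside the step, so v(onset) is still the resting value
    in_step = (time >= onset) & (time < offset)
    traces, spike_times, n_spikes = _integrate_core(
        np.ascontiguousarray(amps, dtype=np.float64),
        np.ascontiguousarray(time, dtype=np.float64), in_step,
        config.leak_conductance, config.sag_conductance,
        config.leak_reversal - config.sag_activation_offset,
        config.leak_reversal,
        math.exp(-dt * config.leak_conductance / config.capacitance),
        math.exp(-dt / config.sag_time_constant),
        math.exp(-dt / config.adaptation_time_constant),
        config.spike_threshold, config.reset_potential,
        config.adaptation_increment, SPIKE_PEAK_MV)
    spike_lists = [spike_times[j, :n_spikes[j]].tolist()
                   for j in range(amps.size)]
    return traces, spike_lists


# ---------------------------------------------------------------------------
# Closed-form subthreshold response (linear 2-state system)

def _system_matrices(config: MembraneConfig):
    c = config.capacitance
    a = np.array([
        [-config.leak_conductance / c, -1.0 / c],
        [config.sag_conductance / config.sag_time_constant,
         -1.0 / config.sag_time_constant],
    ])
    return a


def _linear_engaged_response(config: MembraneConfig, forcing: float,
                             t: np.ndarray) -> np.ndarray:
    """Deflection u(t) of the engaged linear (u, I_h) system from zero
    initial state under constant forcing current (pA), via the
    eigendecomposition of the 2x2 system."""
    t = np.asarray(t, dtype=float)
    a = _system_matrices(config)
    b = np.array([forcing / config.capacitance, 0.0])
    x_ss = -np.linalg.solve(a, b)
    lam, vecs = np.linalg.eig(a)
    coef = np.linalg.solve(vecs, -x_ss)   # x(0) = 0
    expt = np.exp(np.outer(t, lam))
    x = x_ss[0] + (expt * coef) @ vecs[0]
    return np.real(x)


def subthreshold_response(config: MembraneConfig, amplitude: float,
                          t: np.ndarray) -> np.ndarray:
    """Exact voltage deflection V(t) - E_L for a subthreshold step of
    ``amplitude`` pA switched on at t = 0 (piecewise closed form).

    Small or depolarizing steps never engage the sag conductance and decay
    as a pure RC; once a hyperpolarizing response crosses delta =
    ``sag_activation_offset`` below rest (at the analytic crossing time t1,
    with I_h still zero there), the trajectory continues as the engaged
    linear (V, I_h) system with effective forcing I + g_L * delta.
    """
    t = np.asarray(t, dtype=float)
    g_l = config.leak_conductance
    tau_m = config.membrane_tau
    delta = config.sag_activation_offset
    rc = (amplitude / g_l) * (1.0 - np.exp(-t / tau_m))
    if (config.sag_conductance == 0 or amplitude >= 0
            or -amplitude / g_l <= delta):
        return rc
    t1 = -tau_m * math.log(1.0 - delta * g_l / (-amplitude))
    out = rc.copy()
    late = t >= t1
    forcing = amplitude + g_l * delta
    out[late] = -delta + _linear_engaged_response(config, forcing,
                                                  t[late] - t1)
    return out


def _closed_form_peak_and_ss(config: MembraneConfig, amplitude: float,
                             ) -> tuple[float, float]:
    """(peak, steady-state) deflection of the closed-form step response."""
    horizon = 15.0 * max(config.membrane_tau, config.sag_time_constant)
    tg = np.linspace(0.0, horizon, 6000)
    v = subthreshold_response(config, amplitude, tg)
    k = int(np.argmin(v))
    lo, hi = tg[max(k - 1, 0)], tg[min(k + 1, tg.size - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda x: subthreshold_response(config, amplitude,
                                            np.array([x]))[0],
            bounds=(lo, hi), method="bounded")
        peak = float(res.fun)
    else:
        peak = float(v[k])
    g_tot = config.leak_conductance + config.sag_conductance
    delta = config.sag_activation_offset
    if (config.sag_conductance == 0 or amplitude >= 0
            or -amplitude / config.leak_conductance <= delta):
        ss = amplitude / config.leak_conductance
    else:
        ss = -delta + (amplitude + config.leak_conductance * delta) / g_tot
    return peak, float(ss)


def model_steady_state_resistance(config: MembraneConfig) -> float:
    """Steady-state input resistance 1/(g_L + g_h) in MOhm, the slope of
    the engaged regime (steps hyperpolarizing past the sag threshold)."""
    return 1e3 / (config.leak_conductance + config.sag_conductance)


def model_peak_resistance(config: MembraneConfig) -> float:
    """Peak input resistance (MOhm): slope of the closed-form peak
    deflection versus current in the engaged regime."""
    if config.sag_conductance == 0:
        return 1e3 / config.leak_conductance
    delta = config.sag_activation_offset
    g_l = config.leak_conductance
    # two engaged amplitudes; peak vs current is affine there
    a1 = -(delta + 5.0) * g_l
    a2 = -(delta + 10.0) * g_l
    p1, _ = _closed_form_peak_and_ss(config, a1)
    p2, _ = _closed_form_peak_and_ss(config, a2)
    return float((p2 - p1) / (a2 - a1)) * 1e3


def model_resistance_slopes(config: MembraneConfig,
                            amplitudes: Sequence[float],
                            peak_window: tuple = (-15.0, 0.0),
                            ) -> tuple[float, float]:
    """(R_pk, R_ss) in MOhm exactly as the measurement defines them:
    closed-form peak and steady-state deflections at ``amplitudes``, the
    peak-window qualification rule, and least-squares slopes."""
    amps, pks, sss = [], [], []
    for a in amplitudes:
        if a >= 0:
            continue
        pk, ss = _closed_form_peak_and_ss(config, a)
        if peak_window[0] + 1e-3 < pk < peak_window[1]:
            amps.append(a)
            pks.append(pk)
            sss.append(ss)
    if len(amps) < 2:
        raise ConfigurationError("fewer than 2 qualifying amplitudes")
    r_pk = float(np.polyfit(amps, pks, 1)[0]) * 1e3
    r_ss = float(np.polyfit(amps, sss, 1)[0]) * 1e3
    return r_pk, r_ss


def model_sag_ratio(config: MembraneConfig,
                    target_peak_deflection: float = -21.5) -> float:
    """Closed-form sag ratio V_ss/V_pk at the amplitude whose peak
    deflection equals ``target_peak_deflection`` (default: the deflection
    that brings a typical VIP neuron from rest to about -91 mV)."""
    if config.sag_conductance == 0:
        return 1.0
    g_l = config.leak_conductance

    def peak_err(amp):
        return _closed_form_peak_and_ss(config, amp)[0] - target_peak_deflection

    lo = target_peak_deflection * (config.leak_conductance
                                   + config.sag_conductance)
    hi = target_peak_deflection * g_l * 0.5
    from scipy.optimize import brentq
    amp = brentq(peak_err, lo, hi, xtol=1e-6)
    pk, ss = _closed_form_peak_and_ss(config, amp)
    return float(ss / pk)
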