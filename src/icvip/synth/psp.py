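"""Synthetic optogenetically-evoked PSP sweeps with pharmacology logic.

Each sweep is baseline + EPSP + (optional, delayed) IPSP + Gaussian noise.
Both components are difference-of-exponentials waveforms normalized to their
peak amplitude.  The IPSP follows the EPSP onset by a disynaptic latency of
2-3 ms, emulating feedforward inhibition.  Condition logic: gabazine removes
the IPSP; NBQX removes the AMPA EPSP (and, for a disynaptic IPSP, the IPSP
it drives); TTX removes everything evoked; AP5 and strychnine leave this
AMPA-EPSP / GABAergic-IPSP model unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from ..errors import ConfigurationError

KNOWN_CONDITIONS = ("control", "gabazine", "strychnine", "AP5", "NBQX", "TTX")


@dataclass
class PSPConfig:
    epsp_amplitude: float = 2.85        # mV (peak)
    epsp_rise_tau: float = 2.3          # ms
    epsp_decay_tau: float = 25.0        # ms
    ipsp_amplitude: float = -1.5        # mV (peak, <= 0)
    ipsp_latency_after_epsp: float = 2.5  # ms after EPSP onset (drawn 2-3)
    ipsp_rise_tau: float = 5.0          # ms
    ipsp_decay_tau: float = 30.0        # ms
    n_sweeps: int = 25                  # sweeps per condition (20-50 typical)
    noise_sd: float = 0.15              # mV per sweep
    conditions: tuple = ("control", "gabazine")
    ipsp_is_disynaptic: bool = True
    stim_onset: float = 100.0           # ms
    sweep_duration: float = 500.0       # ms
    sampling_rate: float = 50.0         # kHz

    def __post_init__(self) -> None:
        if self.epsp_rise_tau >= self.epsp_decay_tau:
            raise ConfigurationError("EPSP rise tau must be < decay tau")
        if self.ipsp_rise_tau >= self.ipsp_decay_tau:
            raise ConfigurationError("IPSP rise tau must be < decay tau")
        if self.ipsp_amplitude > 0:
            raise ConfigurationError("ipsp_amplitude must be <= 0")
        if self.n_sweeps < 1:
            raise ConfigurationError("n_sweeps must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        unknown = set(self.conditions) - set(KNOWN_CONDITIONS)
        if unknown:
            raise ConfigurationError(f"unknown conditions {unknown}")
        for v in (self.epsp_amplitude, self.ipsp_latency_after_epsp,
                  self.stim_onset, self.sweep_duration):
            if not math.isfinite(v):
                raise ConfigurationError("non-finite PSP parameters")


def psp_waveform(t: np.ndarray, onset: float, amplitude: float,
                 rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials PSP normalized so its peak = ``amplitude``."""
    t = np.asarray(t, dtype=float)
    x = t - onset
    shape = np.where(x > 0,
                     np.exp(-np.clip(x, 0, None) / decay_tau)
                     - np.exp(-np.clip(x, 0, None) / rise_tau), 0.0)
    t_peak = math.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)
    peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    return amplitude * shape / peak


def condition_waveform(config: PSPConfig, condition: str,
                       t: np.ndarray) -> np.ndarray:
    """Noise-free averaged waveform under one pharmacological condition."""
    epsp_on = condition not in ("NBQX", "TTX")
    ipsp_on = config.ipsp_amplitude < 0 and condition not in ("gabazine", "TTX")
    if config.ipsp_is_disynaptic and condition == "NBQX":
        ipsp_on = False
    y = np.zeros_like(np.asarray(t, dtype=float))
    if epsp_on:
        y = y + psp_waveform(t, config.stim_onset, config.epsp_amplitude,
                             config.epsp_rise_tau, config.epsp_decay_tau)
    if ipsp_on:
        y = y + psp_waveform(t, config.stim_onset + config.ipsp_latency_after_epsp,
                             config.ipsp_amplitude,
                             config.ipsp_rise_tau, config.ipsp_decay_tau)
    return y


def simulate_psp_sweeps(config: PSPConfig, seed: int) -> dict:
    """Simulate sweeps for every configured condition.

    Returns ``{condition: (time, traces)}`` with ``traces`` of shape
    (n_sweeps, n_samples); deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / config.sampling_rate
    n = int(round(config.sweep_duration / dt)) + 1
    time = np.arange(n) * dt
    out = {}
    for condition in config.conditions:
        clean = condition_waveform(config, condition, time)
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_sweeps, n)) \
            if config.noise_sd > 0 else np.zeros((config.n_sweeps, n))
        out[condition] = (time, clean[None, :] + noise)
    return out


# ---------------------------------------------------------------------------
# Calibration helpers (used by the cohort generator)

def _metrics_of_waveform(rise_tau: float, decay_tau: float):
    """(rise_10_90, halfwidth) of a unit double-exponential, measured on a
    dense grid of the closed form."""
    t = np.linspace(0.0, 30.0 * decay_tau, 60_000)
    y = psp_waveform(t, 0.0, 1.0, rise_tau, decay_tau)
    k = int(np.argmax(y))

    def crossing(level, seg_t, seg_y, rising):
        if rising:
            idx = np.flatnonzero((seg_y[:-1] < level) & (seg_y[1:] >= level))
        else:
            idx = np.flatnonzero((seg_y[:-1] >= level) & (seg_y[1:] < level))
        i = idx[0]
        f = (level - seg_y[i]) / (seg_y[i + 1] - seg_y[i])
        return seg_t[i] + f * (seg_t[i + 1] - seg_t[i])

    t10 = crossing(0.1, t[:k + 1], y[:k + 1], True)
    t90 = crossing(0.9, t[:k + 1], y[:k + 1], True)
    up = crossing(0.5, t[:k + 1], y[:k + 1], True)
    down = crossing(0.5, t[k:], y[k:], False)
    return t90 - t10, down - up


def solve_epsp_taus(rise_10_90: float, halfwidth: float,
                    ) -> tuple[float, float]:
    """Find (rise_tau, decay_tau) whose waveform has the requested measured
    10-90% rise time and halfwidth."""
    def hw_given_rise(rt):
        # decay tau that matches the halfwidth for this rise tau; None when
        # the halfwidth is already too wide at the shortest admissible decay
        lo, hi = rt * 1.01, 60.0 * halfwidth
        if _metrics_of_waveform(rt, lo)[1] > halfwidth:
            return None
        return brentq(lambda dt_: _metrics_of_waveform(rt, dt_)[1] - halfwidth,
                      lo, hi, xtol=1e-4)

    def rise_err(rt):
        dt_ = hw_given_rise(rt)
        if dt_ is None:
            return float("inf")
        return _metrics_of_waveform(rt, dt_)[0] - rise_10_90

    # bracket the root on a geometric grid (long rise taus have no matching
    # decay, so the error is +inf there)
    grid = np.geomspace(0.02 * halfwidth, 0.95 * halfwidth, 25)
    errs = [rise_err(rt) for rt in grid]
    rt = None
    for a, b, ea, eb in zip(grid[:-1], grid[1:], errs[:-1], errs[1:]):
        if np.isfinite(ea) and np.isfinite(eb) and ea * eb <= 0:
            rt = brentq(rise_err, a, b, xtol=1e-4)
            break
    if rt is None:
        raise ConfigurationError(
            f"no double-exponential matches rise {rise_10_90} ms with "
            f"halfwidth {halfwidth} ms")
    return rt, hw_given_rise(rt)
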