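"""Intrinsic-physiology feature extraction from current-clamp sweep families.

A neuron is characterized from a family of hyperpolarizing and depolarizing
current steps: resting potential, peak and steady-state input resistance
(``R_pk``, ``R_ss``) from the slopes of voltage-deflection-vs-current lines,
membrane time constant from exponential fits to small-step onsets, sag ratios
at target peak potentials, rheobase, and the spike-frequency-adaptation (SFA)
ratio used to classify the firing pattern (sustained / adapting / transient /
single-spike).

Voltages are assumed to be liquid-junction corrected; all potentials are in
mV, currents in pA, times in ms, resistances in MOhm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    AnalysisError,
    ConfigurationError,
    InsufficientDataError,
    NotClassifiableError,
)

#: dV/dt threshold (mV/ms) for spike detection.
DEFAULT_SPIKE_SLOPE = 20.0

#: Window (ms) before step onset used to measure the resting potential.
V_REST_WINDOW_MS = 50.0

#: Steady state is the average of the last 10 ms of the step response.
STEADY_STATE_WINDOW_MS = 10.0


@dataclass
class SweepRecording:
    """One current-clamp sweep: a voltage trace and its command step.

    ``command_current`` is the amplitude of the rectangular step delivered
    between ``step_onset`` and ``step_offset``; outside the step the command
    is zero.
    """

    time: np.ndarray            # ms, strictly increasing
    voltage: np.ndarray         # mV, liquid-junction corrected
    command_current: float      # pA (step amplitude)
    step_onset: float           # ms
    step_offset: float          # ms
    sampling_rate: float        # kHz
    neuron_id: Optional[str] = None
    # Ground-truth spike times when the sweep came from the simulator.
    true_spike_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape:
            raise ConfigurationError("time and voltage must have the same shape")
        if self.time.size < 2 or np.any(np.diff(self.time) <= 0):
            raise ConfigurationError("time base must be strictly increasing")
        if not (self.step_onset < self.step_offset <= self.time[-1] + 1e-9):
            raise ConfigurationError("step must satisfy onset < offset <= trace end")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def _mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.time >= lo) & (self.time < hi)

    def baseline_voltage(self, window_ms: float = V_REST_WINDOW_MS) -> float:
        """Mean voltage over the ``window_ms`` preceding step onset."""
        lo = max(self.time[0], self.step_onset - window_ms)
        m = self._mask(lo, self.step_onset)
        if not m.any():
            raise InsufficientDataError("no pre-step samples for baseline")
        return float(self.voltage[m].mean())

    def step_voltage(self) -> np.ndarray:
        return self.voltage[self._mask(self.step_onset, self.step_offset)]

    def peak_deflection(self, v_rest: float) -> float:
        """Most negative voltage during the step, relative to ``v_rest``."""
        return float(self.step_voltage().min() - v_rest)

    def steady_state_deflection(self, v_rest: float) -> float:
        m = self._mask(self.step_offset - STEADY_STATE_WINDOW_MS, self.step_offset)
        return float(self.voltage[m].mean() - v_rest)


@dataclass
class FiringClassification:
    firing_class: str                    # sustained | adapting | transient | single_spike
    sfa: Optional[float]
    step_current: float                  # pA of the classification sweep
    n_spikes: int


@dataclass
class IntrinsicProfile:
    """Per-neuron intrinsic physiology summary."""

    neuron_id: Optional[str] = None
    v_rest: Optional[float] = None           # mV
    r_pk: Optional[float] = None             # MOhm
    r_ss: Optional[float] = None             # MOhm
    tau_m: Optional[float] = None            # ms
    rheobase: Optional[float] = None         # pA
    sag_ratio_91: Optional[float] = None
    sag_ratio_111: Optional[float] = None
    sfa: Optional[float] = None
    firing_class: Optional[str] = None
    n_spikes_at_classification_step: Optional[int] = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def resting_potential(sweeps: Sequence[SweepRecording],
                      window_ms: float = V_REST_WINDOW_MS) -> float:
    """Mean pre-step voltage averaged across all sweeps."""
    if not sweeps:
        raise InsufficientDataError("no sweeps")
    return float(np.mean([s.baseline_voltage(window_ms) for s in sweeps]))


def detect_spikes(sweep: SweepRecording,
                  threshold_slope: float = DEFAULT_SPIKE_SLOPE,
                  refractory_ms: float = 1.0,
                  peak_window_ms: float = 3.0,
                  min_peak_rise_mv: float = 5.0,
                  slope_span_ms: float = 0.1) -> np.ndarray:
    """Spike times (ms) from upward dV/dt threshold crossings.

    The slope is evaluated over a short span (``slope_span_ms``) rather than
    adjacent samples so high-rate recordings do not trigger on sample-to-
    sample noise.  A crossing is accepted only if the trace reaches a local
    maximum at least ``min_peak_rise_mv`` above the crossing voltage within
    ``peak_window_ms``, and crossings within ``refractory_ms`` of an
    accepted spike are discarded.
    """
    if sweep.sampling_rate < 5.0:
        raise ConfigurationError(
            f"sampling rate {sweep.sampling_rate} kHz too coarse for spike "
            "detection (need >= 5 kHz)")
    v = sweep.voltage
    t = sweep.time
    if not np.all(np.isfinite(v)):
        raise ConfigurationError("non-finite voltage trace")
    span = max(1, int(round(slope_span_ms * sweep.sampling_rate)))
    dvdt = (v[span:] - v[:-span]) / (t[span:] - t[:-span])
    above = dvdt >= threshold_slope
    crossings = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    spikes = []
    n = v.size
    win = max(1, int(round(peak_window_ms * sweep.sampling_rate)))
    for i in crossings:
        if spikes and t[i] - spikes[-1] < refractory_ms:
            continue
        seg = v[i:min(n, i + win + 1)]
        if seg.max() >= v[i] + min_peak_rise_mv:
            spikes.append(t[i])
    return np.asarray(spikes)


def compute_sfa(spike_times: Sequence[float]) -> float:
    """Spike-frequency-adaptation ratio: last interspike interval / first.

    Requires at least three spikes (two ISIs).
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size < 3:
        raise InsufficientDataError(
            f"SFA undefined for {st.size} spikes (need >= 3)")
    isi = np.diff(st)
    return float(isi[-1] / isi[0])


def classify_firing(sweeps: Sequence[SweepRecording],
                    target_spikes: int = 10,
                    transient_fraction: float = 0.5,
                    threshold_slope: float = DEFAULT_SPIKE_SLOPE) -> FiringClassification:
    """Classify the firing pattern from the depolarizing step family.

    The classification sweep is the one whose spike count is closest to
    ``target_spikes`` (ties resolved toward the lower step current).
    Classes:

    * ``single_spike`` -- every suprathreshold sweep has exactly one spike;
    * ``transient`` -- at the classification sweep, firing stops more than
      ``transient_fraction`` of the step duration before step offset;
    * ``sustained`` -- SFA < 2;
    * ``adapting`` -- SFA >= 2.
    """
    supra = []
    for s in sweeps:
        if s.command_current <= 0:
            continue
        st = detect_spikes(s, threshold_slope=threshold_slope)
        if st.size >= 1:
            supra.append((s, st))
    if not supra:
        raise NotClassifiableError("no suprathreshold depolarizing sweep")

    if all(st.size == 1 for _, st in supra):
        s, st = min(supra, key=lambda p: p[0].command_current)
        return FiringClassification("single_spike", None, s.command_current, 1)

    s, st = min(
        supra,
        key=lambda p: (abs(p[1].size - target_spikes), p[0].command_current))
    duration = s.step_offset - s.step_onset
    if s.step_offset - st[-1] > transient_fraction * duration:
        return FiringClassification("transient", None, s.command_current, int(st.size))
    try:
        sfa = compute_sfa(st)
    except InsufficientDataError:
        # Two spikes, last of them late in the step: no adaptation evidence.
        return FiringClassification("sustained", None, s.command_current, int(st.size))
    cls = "sustained" if sfa < 2.0 else "adapting"
    return FiringClassification(cls, sfa, s.command_current, int(st.size))


def _qualifying_resistance_sweeps(
        sweeps: Sequence[SweepRecording], v_rest: float,
        window: tuple[float, float] = (-15.0, 0.0)):
    """Hyperpolarizing sweeps whose peak deflection lies strictly inside
    ``window`` mV (a microvolt guard keeps responses asymptoting to the
    lower bound out of the fit)."""
    out = []
    for s in sweeps:
        if s.command_current >= 0:
            continue
        pk = s.peak_deflection(v_rest)
        if window[0] + 1e-3 < pk < window[1]:
            out.append(s)
    return out


def fit_input_resistance(sweeps: Sequence[SweepRecording],
                         peak_window: tuple[float, float] = (-15.0, 0.0),
                         ) -> tuple[float, float]:
    """(R_pk, R_ss) in MOhm from slopes of deflection-vs-current lines.

    Only hyperpolarizing steps whose peak deflection (most negative value
    relative to rest) lies strictly between 0 and -15 mV enter the fits;
    steady state is the mean of the last 10 ms of the response.
    """
    if not sweeps:
        raise InsufficientDataError("no sweeps")
    v_rest = resting_potential(sweeps)
    qual = _qualifying_resistance_sweeps(sweeps, v_rest, peak_window)
    if len(qual) < 2:
        raise InsufficientDataError(
            f"only {len(qual)} sweep(s) with peak deflection in "
            f"[{peak_window[0]}, {peak_window[1]}) mV (need >= 2)")
    amps = np.array([s.command_current for s in qual])
    pk = np.array([s.peak_deflection(v_rest) for s in qual])
    ss = np.array([s.steady_state_deflection(v_rest) for s in qual])
    # slope of mV vs pA is GOhm -> report MOhm
    r_pk = float(np.polyfit(amps, pk, 1)[0]) * 1e3
    r_ss = float(np.polyfit(amps, ss, 1)[0]) * 1e3
    return r_pk, r_ss


def _fit_onset_exponential(sweep: SweepRecording,
                           window_factor: float = 6.0,
                           n_iter: int = 3) -> float:
    """Single-exponential fit to the onset of a small step response; tau in ms.

    The fit runs from step onset to the time of peak deflection (peak found
    on a lightly smoothed trace so noise does not truncate the window), then
    the window is clipped to ``window_factor`` times the fitted tau and the
    fit repeated.  The default window covers essentially the whole approach
    to steady state, which anchors the asymptote; the small steps of the
    time-constant protocol stay above the sag activation threshold, so no
    slow component contaminates the fit.
    """
    # decimate to ~5 kHz by block averaging: suppresses acquisition noise
    # without altering the slow onset trajectory
    dec = max(1, int(round(sweep.sampling_rate / 5.0)))
    n_blocks = sweep.time.size // dec
    t = sweep.time[:n_blocks * dec].reshape(n_blocks, dec).mean(axis=1)
    v = sweep.voltage[:n_blocks * dec].reshape(n_blocks, dec).mean(axis=1)
    rate = sweep.sampling_rate / dec
    # first block fully inside the step (blocks straddling the onset mix
    # pre- and post-step samples)
    i0 = int(np.searchsorted(t, sweep.step_onset + 0.5 * dec * sweep.dt))
    istep = np.flatnonzero((t >= sweep.step_onset) & (t < sweep.step_offset))
    k = max(1, int(round(2.0 * rate)))  # 2 ms boxcar for peak location
    vs = np.convolve(v, np.ones(k) / k, mode="same")
    ipk = istep[np.argmin(vs[istep])]
    if ipk - i0 < 5:
        raise AnalysisError("fit window too short")

    # the response starts from rest, so anchor the curve at the (precisely
    # measured) baseline: v(t) = v_inf + (v_rest - v_inf) exp(-t/tau)
    v0 = sweep.baseline_voltage()

    def model(x, v_inf, tau):
        return v_inf + (v0 - v_inf) * np.exp(-x / tau)

    iend = ipk
    tau = None
    for _ in range(n_iter + 1):
        tt = t[i0:iend + 1] - sweep.step_onset   # model time runs from onset
        vv = v[i0:iend + 1]
        p0 = (vv[-1], max(tt[-1] / 4.0, 1e-3))
        try:
            popt, _ = curve_fit(
                model, tt, vv, p0=p0, maxfev=5000,
                bounds=([-np.inf, 1e-4], [np.inf, 20.0 * tt[-1]]))
        except (RuntimeError, ValueError) as exc:
            raise AnalysisError(f"exponential fit failed: {exc}") from None
        tau = float(popt[1])
        if not np.isfinite(tau) or tau <= 0:
            raise AnalysisError("non-physical time constant")
        iend_new = min(ipk, i0 + max(5, int(round(
            window_factor * tau * rate))))
        if iend_new == iend:
            break
        iend = iend_new
    return tau


def estimate_tau(sweeps: Sequence[SweepRecording],
                 deflection_window: tuple[float, float] = (1.0, 3.0),
                 ) -> float:
    """Median membrane time constant from small hyperpolarizing steps.

    Sweeps qualify when the magnitude of their steady-state hyperpolarization
    lies within ``deflection_window`` (mV).  Each qualifying sweep is fit with
    a single exponential from step onset to its peak deflection, and the
    median of the per-sweep time constants is returned.
    """
    if not sweeps:
        raise InsufficientDataError("no sweeps")
    v_rest = resting_potential(sweeps)
    lo, hi = deflection_window
    qual = [s for s in sweeps
            if s.command_current < 0
            and lo <= -s.steady_state_deflection(v_rest) <= hi]
    if not qual:
        raise InsufficientDataError(
            f"no hyperpolarizing sweep with steady-state deflection in "
            f"[{lo}, {hi}] mV")
    taus, failures = [], 0
    for s in qual:
        try:
            taus.append(_fit_onset_exponential(s))
        except (AnalysisError, RuntimeError):
            failures += 1
    if failures > len(qual) / 2:
        raise AnalysisError(
            f"exponential fit failed on {failures}/{len(qual)} sweeps")
    return float(np.median(taus))


def sag_ratio(sweeps: Sequence[SweepRecording],
              target_peak: float,
              tolerance_mv: float = 3.0) -> Optional[float]:
    """Sag ratio (V_ss - V_rest) / (V_pk - V_rest) at a target peak potential.

    The sweep whose peak potential is closest to ``target_peak`` is used; if
    no sweep peaks within ``tolerance_mv`` of the target the value is missing
    (``None``).  Ratios < 1 indicate I_h-mediated sag.
    """
    hyper = [s for s in sweeps if s.command_current < 0]
    if not hyper:
        return None
    v_rest = resting_potential(sweeps)
    peaks = np.array([s.step_voltage().min() for s in hyper])
    k = int(np.argmin(np.abs(peaks - target_peak)))
    if abs(peaks[k] - target_peak) > tolerance_mv:
        return None
    s = hyper[k]
    v_pk = float(peaks[k])
    v_ss = v_rest + s.steady_state_deflection(v_rest)
    if v_pk == v_rest:
        return None
    return float((v_ss - v_rest) / (v_pk - v_rest))


def rheobase(sweeps: Sequence[SweepRecording],
             threshold_slope: float = DEFAULT_SPIKE_SLOPE) -> Optional[float]:
    """Smallest depolarizing step amplitude (pA) evoking at least one spike."""
    spiking = [s.command_current for s in sweeps
               if s.command_current > 0
               and detect_spikes(s, threshold_slope=threshold_slope).size >= 1]
    if not spiking:
        return None
    return float(min(spiking))


def extract_profile(sweeps: Sequence[SweepRecording],
                    tau_sweeps: Optional[Sequence[SweepRecording]] = None,
                    sag_targets: tuple[float, float] = (-91.0, -111.0),
                    target_spikes: int = 10,
                    threshold_slope: float = DEFAULT_SPIKE_SLOPE,
                    neuron_id: Optional[str] = None) -> IntrinsicProfile:
    """Assemble an :class:`IntrinsicProfile` from a sweep family.

    ``tau_sweeps`` may supply a dedicated family of small repeated steps for
    the time-constant estimate (the measurement protocol uses repeats that
    hyperpolarize the membrane by 1-3 mV); when omitted, qualifying sweeps
    from the main family are used.  Features that cannot be computed are left
    ``None`` rather than raising.
    """
    prof = IntrinsicProfile(neuron_id=neuron_id)
    prof.v_rest = resting_potential(sweeps)
    try:
        prof.r_pk, prof.r_ss = fit_input_resistance(sweeps)
    except InsufficientDataError:
        pass
    try:
        prof.tau_m = estimate_tau(tau_sweeps if tau_sweeps is not None else sweeps)
    except (InsufficientDataError, AnalysisError):
        pass
    prof.sag_ratio_91 = sag_ratio(sweeps, sag_targets[0])
    prof.sag_ratio_111 = sag_ratio(sweeps, sag_targets[1])
    prof.rheobase = rheobase(sweeps, threshold_slope=threshold_slope)
    try:
        cls = classify_firing(sweeps, target_spikes=target_spikes,
                              threshold_slope=threshold_slope)
        prof.firing_class = cls.firing_class
        prof.sfa = cls.sfa
        prof.n_spikes_at_classification_step = cls.n_spikes
    except NotClassifiableError:
        pass
    return prof
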