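"""Evoked postsynaptic-potential kinetics and pharmacological comparisons.

Sweeps are baseline-subtracted and averaged per condition; from the averaged
trace, the event amplitude (extremum minus baseline, signed by polarity),
10-90% rise time, full width at half amplitude (linear interpolation between
samples), and single-exponential decay time constant are measured.  Paired
t-tests and repeated-measures ANOVA with Tukey post-hoc comparisons support
drug-condition contrasts (Bonferroni critical p = 0.0125 where four
comparisons are made), and the feedforward-inhibition effect is quantified
as the percent reduction of the EPSP halfwidth relative to the disinhibited
(gabazine) condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from statsmodels.stats.anova import AnovaRM

from .errors import (
    AnalysisError,
    ConfigurationError,
    InsufficientDataError,
    NoEventError,
)

DEFAULT_BASELINE_MS = 50.0
BONFERRONI_CRITICAL_P = 0.0125


@dataclass
class PSPMetrics:
    amplitude: float       # mV, signed by polarity
    rise_10_90: float      # ms
    halfwidth: float       # ms
    decay_tau: float       # ms


@dataclass
class PSPRecord:
    condition: str
    time: np.ndarray
    averaged_trace: np.ndarray
    stim_onset: float
    polarity: str                     # EPSP | IPSP
    amplitude: Optional[float] = None
    rise_10_90: Optional[float] = None
    halfwidth: Optional[float] = None
    decay_tau: Optional[float] = None
    n_sweeps: int = 1
    cell_id: Optional[str] = None


@dataclass
class ConditionComparison:
    metric: str
    conditions: tuple
    values: pd.DataFrame              # cells x conditions
    test: str                         # paired_t | rm_anova_tukey
    statistic: float
    p_value: float
    pairwise: Optional[pd.DataFrame] = None
    bonferroni_critical_p: float = BONFERRONI_CRITICAL_P

    @property
    def significant(self) -> bool:
        return self.p_value < self.bonferroni_critical_p


def average_sweeps(time: np.ndarray, traces: np.ndarray, stim_onset: float,
                   baseline_ms: float = DEFAULT_BASELINE_MS) -> np.ndarray:
    """Pointwise mean of baseline-subtracted sweeps.

    Each sweep's baseline is the mean of the ``baseline_ms`` preceding the
    stimulus.  ``traces`` may be (n_sweeps, n_samples) or a list of 1-D
    arrays on the common time base.
    """
    time = np.asarray(time, dtype=float)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] == 0:
        raise InsufficientDataError("no sweeps to average")
    if traces.shape[1] != time.size:
        raise ConfigurationError("sweeps do not share the common time base")
    pre = (time >= stim_onset - baseline_ms) & (time < stim_onset)
    if not pre.any():
        raise ConfigurationError("no pre-stimulus samples for baseline")
    baselines = traces[:, pre].mean(axis=1, keepdims=True)
    return (traces - baselines).mean(axis=0)


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float,
                     rising: bool) -> float:
    """Linear-interpolated time of the first crossing of ``level``."""
    if rising:
        idx = np.flatnonzero((y[:-1] < level) & (y[1:] >= level))
    else:
        idx = np.flatnonzero((y[:-1] >= level) & (y[1:] < level))
    if idx.size == 0:
        raise NoEventError(f"no crossing of level {level:.4g}")
    i = idx[0]
    frac = (level - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def psp_metrics(time: np.ndarray, trace: np.ndarray, stim_onset: float,
                polarity: str = "EPSP",
                baseline_ms: float = DEFAULT_BASELINE_MS,
                min_amplitude: float = 1e-6) -> PSPMetrics:
    """Amplitude and kinetics of an averaged evoked potential.

    Raises :class:`NoEventError` when the trace never crosses half of the
    detected extremum (no event).  For IPSPs the trace is sign-flipped for
    the kinetic analysis and the amplitude reported negative.
    """
    if polarity not in ("EPSP", "IPSP"):
        raise ConfigurationError("polarity must be 'EPSP' or 'IPSP'")
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    pre = (time >= stim_onset - baseline_ms) & (time < stim_onset)
    post = time >= stim_onset
    if not pre.any() or post.sum() < 4:
        raise ConfigurationError("event window missing from trace")
    y = trace - trace[pre].mean()
    if polarity == "IPSP":
        y = -y
    noise_floor = 5.0 * float(y[pre].std())
    tp = time[post]
    yp = y[post]
    k = int(np.argmax(yp))
    amp = float(yp[k])
    if amp <= max(noise_floor, min_amplitude):
        raise NoEventError("no event: peak does not exceed the baseline noise")
    t_peak = tp[k]
    # rising phase (stimulus to peak): last 10% / 90% crossings before peak
    t10 = _interp_crossing(tp[:k + 1], yp[:k + 1], 0.10 * amp, rising=True)
    t90 = _interp_crossing(tp[:k + 1], yp[:k + 1], 0.90 * amp, rising=True)
    half = 0.5 * amp
    t_half_up = _interp_crossing(tp[:k + 1], yp[:k + 1], half, rising=True)
    t_half_down = _interp_crossing(tp[k:], yp[k:], half, rising=False)
    # decay: single exponential from the peak down to 20% of amplitude
    try:
        t20 = _interp_crossing(tp[k:], yp[k:], 0.20 * amp, rising=False)
    except NoEventError:
        t20 = tp[-1]
    win = (tp >= t_peak) & (tp <= t20)
    if win.sum() < 4:
        raise AnalysisError("decay window too short for an exponential fit")
    td = tp[win] - t_peak
    yd = yp[win]

    def model(x, a, tau):
        return a * np.exp(-x / tau)

    popt, _ = curve_fit(model, td, yd, p0=(amp, max(td[-1] / 2.0, 1e-3)),
                        maxfev=5000)
    decay_tau = float(popt[1])
    signed_amp = amp if polarity == "EPSP" else -amp
    return PSPMetrics(amplitude=signed_amp, rise_10_90=float(t90 - t10),
                      halfwidth=float(t_half_down - t_half_up),
                      decay_tau=decay_tau)


def analyze_condition(time: np.ndarray, traces: np.ndarray, stim_onset: float,
                      condition: str, polarity: str = "EPSP",
                      baseline_ms: float = DEFAULT_BASELINE_MS,
                      cell_id: Optional[str] = None) -> PSPRecord:
    """Average the sweeps of one pharmacological condition and measure the
    evoked event; metric fields stay ``None`` when no event is detected."""
    avg = average_sweeps(time, traces, stim_onset, baseline_ms)
    rec = PSPRecord(condition=condition, time=np.asarray(time, dtype=float),
                    averaged_trace=avg, stim_onset=stim_onset,
                    polarity=polarity, n_sweeps=np.atleast_2d(traces).shape[0],
                    cell_id=cell_id)
    try:
        mt = psp_metrics(time, avg, stim_onset, polarity, baseline_ms)
    except NoEventError:
        return rec
    rec.amplitude = mt.amplitude
    rec.rise_10_90 = mt.rise_10_90
    rec.halfwidth = mt.halfwidth
    rec.decay_tau = mt.decay_tau
    return rec


def paired_t_comparison(metric: str, values: pd.DataFrame,
                        condition_a: str, condition_b: str,
                        ) -> ConditionComparison:
    """Two-tailed paired t-test between two conditions (rows = cells)."""
    a = values[condition_a].to_numpy(dtype=float)
    b = values[condition_b].to_numpy(dtype=float)
    if a.size != b.size or np.isnan(a).any() or np.isnan(b).any():
        raise ConfigurationError("paired samples must be complete and equal length")
    if a.size < 3:
        raise InsufficientDataError("need >= 3 cells for a paired t-test")
    if np.array_equal(a, b):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(a, b)
    return ConditionComparison(metric=metric,
                               conditions=(condition_a, condition_b),
                               values=values[[condition_a, condition_b]],
                               test="paired_t", statistic=float(t_stat),
                               p_value=float(p))


def rm_anova_tukey(metric: str, values: pd.DataFrame) -> ConditionComparison:
    """Repeated-measures ANOVA across >= 3 conditions with Tukey post-hoc.

    ``values``: rows = cells, columns = conditions, complete (no NaN).  The
    omnibus F comes from the within-subjects ANOVA; pairwise comparisons use
    the Tukey studentized-range test with the RM error term,
    q = |mean_i - mean_j| / sqrt(MS_error / n).
    """
    if values.shape[1] < 3:
        raise InsufficientDataError("need >= 3 conditions for RM-ANOVA")
    if values.isna().any().any():
        raise ConfigurationError("unpaired (incomplete) data for RM-ANOVA")
    n, k = values.shape
    long = values.reset_index(names="cell").melt(
        id_vars="cell", var_name="condition", value_name="value")
    res = AnovaRM(long, depvar="value", subject="cell",
                  within=["condition"]).fit()
    f_stat = float(res.anova_table["F Value"].iloc[0])
    p = float(res.anova_table["Pr > F"].iloc[0])
    # error term for Tukey: residual mean square of the within-subjects model
    grand = values.to_numpy().mean()
    cond_means = values.mean(axis=0).to_numpy()
    cell_means = values.mean(axis=1).to_numpy()
    resid = (values.to_numpy() - cond_means[None, :]
             - cell_means[:, None] + grand)
    df_err = (n - 1) * (k - 1)
    ms_err = float((resid ** 2).sum() / df_err)
    se = np.sqrt(ms_err / n)
    rows = []
    cols = list(values.columns)
    for i in range(k):
        for j in range(i + 1, k):
            diff = cond_means[i] - cond_means[j]
            q = abs(diff) / se if se > 0 else 0.0
            p_ij = float(stats.studentized_range.sf(q, k, df_err)) if se > 0 else 1.0
            rows.append({"condition_a": cols[i], "condition_b": cols[j],
                         "mean_diff": diff, "q": q, "p_value": p_ij})
    return ConditionComparison(metric=metric, conditions=tuple(cols),
                               values=values, test="rm_anova_tukey",
                               statistic=f_stat, p_value=p,
                               pairwise=pd.DataFrame(rows))


def compare_conditions(metric: str, values: pd.DataFrame,
                       test: Optional[str] = None) -> ConditionComparison:
    """Dispatch to a paired t-test (2 conditions) or RM-ANOVA + Tukey."""
    k = values.shape[1]
    if test is None:
        test = "paired_t" if k == 2 else "rm_anova_tukey"
    if test == "paired_t":
        if k != 2:
            raise ConfigurationError("paired t-test needs exactly 2 conditions")
        return paired_t_comparison(metric, values, *values.columns)
    return rm_anova_tukey(metric, values)


def ffi_halfwidth_reduction(control: PSPRecord, disinhibited: PSPRecord,
                            denominator: str = "disinhibited") -> float:
    """Percent reduction of the EPSP halfwidth by feedforward inhibition.

    ``control`` is the intact-inhibition recording, ``disinhibited`` the same
    cell after gabazine.  The primary convention reports the reduction
    relative to the disinhibited halfwidth,
    100 * (hw_dis - hw_ctrl) / hw_dis (gabazine restores the full EPSP, so
    the disinhibited state is the reference maximum); ``denominator`` may be
    set to ``"control"`` for the alternative normalization.
    """
    if control.halfwidth is None or disinhibited.halfwidth is None:
        raise InsufficientDataError("EPSP halfwidth missing in one condition")
    if control.cell_id is not None and disinhibited.cell_id is not None \
            and control.cell_id != disinhibited.cell_id:
        raise ConfigurationError("records come from different cells")
    hw_c, hw_d = control.halfwidth, disinhibited.halfwidth
    denom = hw_d if denominator == "disinhibited" else hw_c
    return float(100.0 * (hw_d - hw_c) / denom)
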