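"""Independent oracle implementations used only by the tests.

Each oracle re-derives a quantity by a different route than the package
(fine-step integration, brute-force filtering, exhaustive enumeration, dense
closed-form evaluation) so agreement is a genuine cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def fine_step_membrane(config, amplitude, duration, pre_ms=10.0,
                       refine: int = 10):
    """Integrate the membrane ODEs with simple Euler steps at ``refine``
    times the configured sampling rate; returns (times, voltages,
    spike_times).

        C dV/dt = -gL (V - EL) - Ih - w + I
        tau_h dIh/dt = g_h min(V - (EL - delta), 0) - Ih
        tau_w dw/dt = -w;  spike: V -> reset, w += b
    """
    dt = 1.0 / (config.sampling_rate * refine)
    n = int(round((pre_ms + duration) / dt))
    v = config.leak_reversal
    ih = 0.0
    w = 0.0
    spikes = []
    times = np.arange(n + 1) * dt
    volts = np.empty(n + 1)
    volts[0] = v
    for i in range(1, n + 1):
        t_prev = times[i - 1]
        current = amplitude if (pre_ms <= t_prev < pre_ms + duration) else 0.0
        dvdt = (-config.leak_conductance * (v - config.leak_reversal)
                - ih - w + current) / config.capacitance
        v_on = config.leak_reversal - config.sag_activation_offset
        dih = (config.sag_conductance * min(v - v_on, 0.0)
               - ih) / config.sag_time_constant
        dw = -w / config.adaptation_time_constant
        v += dt * dvdt
        ih += dt * dih
        w += dt * dw
        if v >= config.spike_threshold:
            spikes.append(times[i])
            v = config.reset_potential
            w += config.adaptation_increment
        volts[i] = v
    return times, volts, np.asarray(spikes)


def brute_force_pca(coords):
    """Covariance eigen-decomposition written out explicitly: returns
    (eigenvalues desc, eigenvectors as columns, extents after rotation)."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    n = coords.shape[0]
    cov = np.zeros((coords.shape[1], coords.shape[1]))
    for row in centered:
        cov += np.outer(row, row)
    cov /= (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    rotated = centered @ evecs
    extents = rotated.max(axis=0) - rotated.min(axis=0)
    return evals, evecs, extents


def brute_force_frame_count(points, x0, y0, size, z_top, z_bottom, guard,
                            depth):
    """Literal re-statement of the counting rules on a point table."""
    zc = 0.5 * (z_top + z_bottom)
    zlo, zhi = zc - depth / 2.0, zc + depth / 2.0
    total = labeled = double = 0
    for row in points.itertuples(index=False):
        if not (x0 < row.x_um <= x0 + size):
            continue
        if not (y0 < row.y_um <= y0 + size):
            continue
        if not (zlo <= row.z_um <= zhi):
            continue
        total += 1
        if row.labeled:
            labeled += 1
            double += 1
    return total, labeled, double


def exact_rank_sum_p(a, b):
    """Two-sided rank-sum p-value by exhaustive enumeration of all
    assignments of the pooled ranks to group a (tie-free samples only)."""
    a = list(a)
    b = list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "enumeration oracle needs no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n = len(pooled)
    na = len(a)
    mean_w = na * (n + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), na):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def dense_psp_metrics(amplitude, rise_tau, decay_tau, n=400_000,
                      horizon_factor=40.0):
    """(amplitude, rise_10_90, halfwidth, decay_tau) of the normalized
    double-exponential, from a dense closed-form grid; the decay constant is
    a log-linear regression from the peak to the 20%-of-amplitude point."""
    t = np.linspace(0.0, horizon_factor * decay_tau, n)
    t_peak = (math.log(decay_tau / rise_tau) * rise_tau * decay_tau
              / (decay_tau - rise_tau))
    norm = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    y = amplitude * (np.exp(-t / decay_tau) - np.exp(-t / rise_tau)) / norm

    def crossing(level, lo, hi, rising):
        seg = slice(lo, hi)
        yy, tt = y[seg], t[seg]
        if rising:
            idx = np.flatnonzero((yy[:-1] < level) & (yy[1:] >= level))
        else:
            idx = np.flatnonzero((yy[:-1] >= level) & (yy[1:] < level))
        i = idx[0]
        f = (level - yy[i]) / (yy[i + 1] - yy[i])
        return tt[i] + f * (tt[i + 1] - tt[i])

    k = int(np.argmax(y))
    t10 = crossing(0.1 * amplitude, 0, k + 1, True)
    t90 = crossing(0.9 * amplitude, 0, k + 1, True)
    up = crossing(0.5 * amplitude, 0, k + 1, True)
    down = crossing(0.5 * amplitude, k, n, False)
    t20 = crossing(0.2 * amplitude, k, n, False)
    win = (t >= t[k]) & (t <= t20)
    td = t[win] - t[k]
    yd = y[win]

    def sse(tau):
        e = np.exp(-td / tau)
        a_opt = (yd @ e) / (e @ e)
        r = yd - a_opt * e
        return r @ r

    # least-squares single-exponential by dense 1-D scan plus refinement
    taus = np.linspace(0.2 * decay_tau, 3.0 * decay_tau, 2000)
    tau0 = taus[int(np.argmin([sse(x) for x in taus]))]
    from scipy.optimize import minimize_scalar
    res = minimize_scalar(sse, bounds=(0.8 * tau0, 1.25 * tau0),
                          method="bounded", options={"xatol": 1e-8})
    return amplitude, t90 - t10, down - up, float(res.x)
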