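# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `icvip`. Units throughout: mV, pA, nS, pF, ms (so
pA/nS = mV and pF/nS = ms), µm for anatomy.

## Synthetic membrane model

The current-clamp generator is a single-compartment adaptive threshold-reset
(aLIF) neuron with a slow sag current standing in for the
hyperpolarization-activated cation current I_h:

    C dV/dt       = −g_L (V − E_L) − I_h − w + I_inj(t)
    τ_h dI_h/dt   = g_h · min(V − (E_L − δ), 0) − I_h
    τ_w dw/dt     = −w,    w → w + b at each spike

When V crosses the spike threshold, a spike is recorded, V resets, and the
adaptation current w increments by b. A stereotyped +30 mV peak is pasted
into the recorded trace at each spike so slope-based detection sees a
realistic upstroke.

The sag current is *rectified and offset*: it engages only once the membrane
falls δ = `sag_activation_offset` (default 3 mV) below rest. This mirrors
the physiology of I_h, whose half-activation voltage lies far below the
resting potential, and it has two consequences the analyses rely on:
depolarizing responses are pure RC + adaptation (so the SFA ratio reflects
adaptation, not sag), and the small 1–3 mV steps of the time-constant
protocol stay in the RC regime (which is why that protocol uses small steps
in the first place). Larger hyperpolarizing steps show the characteristic
sag: peak deflection exceeding steady state.

Integration is fixed-step exponential Euler at the configured sampling rate
(default 50 kHz): each state relaxes exactly toward its instantaneous target
over one step with the other states held. Correctness is guarded by a
10×-finer-step Euler integration written independently in the test suite.
Because the subthreshold system is piecewise linear, its step response has a
closed form (pure RC until the analytic crossing of E_L − δ, then the
eigen-solution of the 2-state linear system with effective forcing
I + g_L δ); `subthreshold_response` implements it and is validated against
both the simulator and the fine-step oracle.

Measurement noise (default SD 0.2 mV, a typical whole-cell baseline at
physiological temperature) is band-limited (Gaussian-kernel smoothed,
L2-normalized so the SD is preserved) to emulate the acquisition low-pass
filter, and is added to the recorded trace only — the dynamics are
deterministic given the configuration, so ground-truth spike times are exact.

## Intrinsic-feature estimators

* **Spike detection**: upward dV/dt crossings at 20 mV/ms, with the slope
  evaluated over a 0.1 ms span (adjacent-sample slopes at 50 kHz would
  trigger on noise), a requirement that the trace rise ≥5 mV to a local
  maximum within 3 ms, and a 1 ms refractory floor.
* **R_pk / R_ss**: least-squares slopes of peak (most negative value) and
  steady-state (mean of last 10 ms) deflections versus current, over
  hyperpolarizing steps whose peak lies strictly between 0 and −15 mV of
  rest (a 1 µV guard keeps responses that asymptote to exactly −15 mV out of
  the fit). The resting potential is the mean over the 50 ms preceding the
  step, averaged across sweeps.
* **τ_m**: per-sweep single-exponential fit to the onset of small repeated
  steps (qualification: steady-state hyperpolarization of 1–3 mV), median
  across sweeps. Each sweep is block-averaged to ~5 kHz before fitting
  (noise suppression without distorting the slow onset), the curve is
  anchored at the precisely measured resting baseline with time running from
  the exact step onset, and the fit window extends to min(peak time, 6 τ̂),
  iterated. For a pure RC response the estimator is exact; under the default
  noise, the median over 50 repeats recovers the generating τ to well under
  5 %.
* **Sag ratio**: `(V_ss − V_rest)/(V_pk − V_rest)` on the sweep whose peak
  potential falls closest to the target (−91 or −111 mV), accepted only
  within ±3 mV — nearest-sweep selection, no interpolation.
* **Rheobase**: smallest step amplitude with ≥1 detected spike, at the
  protocol's resolution.
* **Firing class**: classification sweep = spike count closest to 10, ties
  to the lower current. *single-spike* if every suprathreshold sweep has
  exactly one spike; *transient* if the last spike precedes step offset by
  more than half the step duration; otherwise *sustained* (SFA < 2) or
  *adapting* (SFA ≥ 2). A two-spike classification sweep that is not
  transient is reported *sustained* with SFA undefined (no adaptation
  evidence).

## Cohort generators: the study conditions

`icvip.synth.cohort` draws per-neuron feature targets from the published
VIP population and inverts them to generator parameters:

* R_pk lognormal with mean 242.1 and SD 139.4 MΩ (clipped to 60–900 MΩ);
  τ_m lognormal 15.0 ± 8.8 ms; sag ratio normal 0.87 ± 0.16 (clipped to
  0.5–1); threshold offset normal 16 ± 5 mV above rest, giving rheobases
  around the published ~68 pA. The SFA target is 1 + Gamma with mean 1.47
  and SD 0.5: the published SD (1.62) is dominated by a few strongly
  adapting outliers, and the mean is the anchored condition; the gamma tail
  still yields roughly one adapting cell in ten.
* Calibration inverts the *measurement definitions*, not raw parameters:
  g_L and g_h are fixed-point-adjusted until the closed-form slope-fitted
  R_pk over the default protocol and the closed-form sag ratio at the
  −91 mV-like deflection match their targets; C = τ·g_L; the adaptation
  increment is found by a guarded bisection that simulates the same
  depolarizing family and sweep-selection rule the classifier uses (SFA is
  monotone in the increment over the physiological range but collapses when
  the increment suppresses firing; unreachable targets fall back to the
  closest achievable point).
* The default step protocol is −200…−25 pA in 25 pA decrements plus fine
  −20…−5 pA steps (so every neuron, whatever its resistance, has several
  sweeps peaking within 0 to −15 mV), 25–300 pA depolarizing steps, 300 ms
  step duration, and 50 repeats of a step sized to hyperpolarize by
  ~2.5 mV for τ_m. The published protocol states 100 ms hyperpolarizing
  steps and leaves the depolarizing family unspecified; the longer fixture
  duration lets the slow sag settle within each sweep.

Morphology cohorts place 42 ICc neurons, 3 of them disc-shaped (target
extent ratios 3.3–4.5; stellate cells 1.2–2.6, matching the observed
clustering of ratios well below 3), orientations uniform on [0°, 180°)
(consistent with "no preferred orientation"; the expected within-±15°
fraction is then exactly 7/42), and primary-dendrite counts drawn from
N(4.77, 1.38), rounded and clipped to ≥1. Arbor points are sampled
uniformly inside the configured ellipsoid (bounded support keeps measured
extents stable near 2× the semi-axes) and chained into stems by distance
from the soma so the output is a valid rooted SWC tree.

Location cohorts place n = 60 somata uniformly in an ICc-like coronal
region (ml 600–1600, dv 400–1600 µm) and generate sag ratios increasing
along the ventromedial diagonal with in-sample signal SD r·σ and residual
SD σ√(1 − r²), σ = 0.16, so the fitted multiple correlation concentrates on
the configured r = 0.536.

The feedforward-inhibition cohort holds five control/gabazine cells. EPSP
time constants are solved so the noise-free waveform measures a 4.2 ms
10–90 % rise and 20.6 ms halfwidth; per-cell IPSP amplitudes are calibrated
(monotone root-find on the noise-free waveform) so halfwidth reductions
equal {22, 29, 36, 54.5, 73} % — the published range endpoints and median,
with interpolated intermediates. IPSP latency is drawn uniformly from
2–3 ms after EPSP onset (the disynaptic delay).

Point fields are homogeneous Poisson at 235 000 cells/mm³ (≈120 neurons per
counting frame, matching the per-sample tallies), with label probability
interpolated linearly along the gradient axis.

## Stereology conventions

A site is the upper-left corner of any grid square that overlaps the
section with positive area; the grid origin is uniform on [0, spacing)².
Cells are counted by the *top* of the cell: the synthetic z coordinate is
the cell-top depth, counted when it lies in the central slab
[z_center − 7.5, z_center + 7.5] µm after ≥2 µm guards are removed.
The border rule is exclusive on left/bottom and inclusive on right/top, so
tiled frames partition the plane and no cell can be counted twice —
this complementarity is what makes the fractionator unbiased, verified by
Monte Carlo in the tests. Group SEMs are computed across per-frame
percentages; pooled counts are reported alongside (the two need not agree,
and both are emitted, as in the source tables). Frames with zero
denominators (e.g. frames falling outside the tissue) are excluded with a
warning. The GAD67-style co-label analysis is the depth-restricted special
case with the labeled-cell denominator (`denominator="labeled"`).

## Plane fits and p-values

The plane is linear in its parameters, so Levenberg–Marquardt converges to
the normal-equations solution (asserted to 1e-9 in the tests); LM is kept
as the fitting route for fidelity to the original workflow. R is the
Pearson correlation between observed and fitted values (reported in [0, 1]),
and adjusted R² uses the two-predictor formula 1 − (1 − R²)(n − 1)/(n − 3),
which reproduces the published (R = 0.536, R²_adj = 0.262, n = 60) pair.
Two p-values are reported: the overall-regression F test (primary), and a
chi-squared tail probability of the residual sum of squares with n − 3
degrees of freedom under unit weights — a legacy convention retained for
comparison only, since its original weighting is not recoverable. Only ICc
rows enter tonotopy fits; the ventromedial unit direction in (ml, dv)
coordinates is (−1, +1)/√2, and a positive projection of the slope vector
on it is reported as "slower ventromedially".

## PSP analysis

Baselines are the mean of the 50 ms preceding the stimulus (per sweep,
before averaging). Half-amplitude and 10/90 % crossings are linearly
interpolated between samples; no smoothing is applied by default. The decay
constant is a single-exponential least-squares fit from the extremum to the
return to 20 % of amplitude — the early cutoff avoids contamination by a
delayed IPSP in mixed traces. An event is declared only when the peak
exceeds five baseline standard deviations; otherwise the record's metric
fields stay empty. The feedforward-inhibition effect uses the disinhibited
(gabazine) halfwidth as the denominator — gabazine restores the full EPSP,
so that state is the reference maximum; the control-denominator variant is
available via an argument. Repeated-measures ANOVA comes from the
within-subjects decomposition (statsmodels `AnovaRM` for the omnibus F);
Tukey pairwise comparisons use q = |Δmean|/√(MS_error/n) against the
studentized-range distribution with the RM error degrees of freedom.

## Statistics

The Wilcoxon rank-sum test uses the exact null distribution when both
groups are ≤25 and tie-free, and the normal approximation with continuity
and tie correction otherwise; for n ≤ 10 it matches exhaustive enumeration
over all rank assignments to 1e-12 (test-suite oracle). Proportions are
rounded to the table conventions (one decimal for physiology, integers for
morphology). `build_report` merges per-neuron tables on `neuron_id`
(duplicate ids are an error listing the offenders) and recomputes every
summary from the merged table, so no report number carries hidden state.

## Problem sizes

The test suite simulates a 60-neuron intrinsic cohort (with model-truth
comparisons), 100-seed gradient-power and 1000-seed grid-uniformity /
null-plane Monte Carlos, and 20–30-seed fractionator checks. The acceptance
script uses a 200-neuron intrinsic cohort, 25 replicate location cohorts,
six synthetic sections, and the five-cell FFI cohort; it completes in a few
minutes on one CPU.

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* the analyses assume:
feature distributions, sag/adaptation phenomenology, counting-frame
statistics, planar gradients, and PSP waveform composition. They do not
reproduce biophysically detailed conductances, dendritic filtering, spike
waveform shape (spikes are pasted stereotypes), electrode artifacts,
section shrinkage, or staining variability. Passing tests therefore
demonstrate that the estimators recover known ground truth under realistic
noise and sampling — not that they are robust to every pathology of real
recordings. The sag/τ coupling is a genuine example: with a purely linear
(non-offset) sag current, the onset fit under-estimates τ_m by up to ~10 %,
and the same contamination would affect real neurons whose I_h is
appreciably active at rest.

## Known limitations

* The aLIF model couples R_ss, R_pk and the sag ratio through two
  conductances; real neurons can dissociate them (e.g. the published mean
  R_ss slightly exceeds sag × R_pk).
* SFA targets above a cell-dependent ceiling are unreachable (strong
  adaptation suppresses firing before the ratio reaches the target); the
  calibration then uses the closest achievable value.
* The legacy chi-squared p-value is not comparable to the published one
  without the original weights; it is excluded from all assertions.
* `estimate_tau`'s onset fit assumes the qualifying sweeps are sag-free;
  applying it to deep hyperpolarizations would re-introduce the slow-
  component bias.
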