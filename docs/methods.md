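# Methods

`stepclamp` analyses whole-cell current-clamp recordings acquired with a
serial square-step protocol and compares intrinsic-excitability features
between two groups of cells.  This note documents the operational
definitions, the synthetic neuron model behind the test cohorts, the
numerical choices, and the limits of what the synthetic validation shows.

## The step protocol

The canonical schedule is 14 square current steps from −400 to +900 pA in
100 pA increments, 800 ms long, each repeated for 3 trials, sampled at
10 kHz.  Pre- and post-step epoch durations are not part of the schedule
itself; the defaults are 100 ms of baseline (the resting-potential window
needs at least that much) and 200 ms of tail.  All are configurable on
`StepProtocol`.

Units are fixed package-wide: mV, pA, nS, pF, MΩ; trace time in seconds,
membrane time constants in ms.  These choices make the model arithmetic
exact: pF/nS = ms, nS·mV = pA, 1000/nS = MΩ.

## Feature definitions

**Resting membrane potential (RMP)** — mean voltage over the final 100 ms
before step onset.  By default the baseline of the first-recorded sweep
(the −400 pA step), averaged across its trials; an all-sweep average is
available.  The per-cell indicator `RMP < −80 mV` feeds a descriptive k/n
tally, not a test.

**Steady state** — mean over the final 160 ms of the step.  This window is
defined once and used for every steady-state quantity (voltage response,
input resistance, sag); using one convention everywhere avoids
incommensurable denominators in the normalized sag.

**Voltage response** — |steady state − baseline| at a given amplitude.
Spiking sweeps are spike-clipped per trial *before* trial averaging: each
detected action potential is replaced by a linear bridge from its threshold
sample to the first later sample back at/below threshold.  Averaging raw
trials first would smear jittered spikes into the steady-state window.

**Input resistance (R_in)** — voltage response at −100 pA divided by
100 pA, in MΩ.  −100 pA is used because the hyperpolarization-activated
(H / sag) conductance is essentially deactivated at the resulting
potentials, so the measurement reflects the leak.

**Membrane time constant** — the 67% settling rule: the first time after
step onset at which the trial-averaged trace crosses
baseline + 0.67·(steady − baseline), located by linear interpolation
between samples (discretization error ≤ 0.1 ms at 10 kHz).  This is a
threshold-crossing definition, deliberately not an exponential fit.  For a
pure RC membrane it equals 1.109·τ (τ·ln(1/0.33)).

**Sag** — at −400 pA: steady-state voltage minus the most negative voltage
during the step.  Negative values (steady state below the peak) are
reported as-is and flagged as QC anomalies, never clamped.  Normalized sag
divides by the voltage response at the same step.

**Spike detection** — local maxima above a peak floor (−10 mV) preceded
within 5 ms by dV/dt ≥ 20 mV/ms; minimum inter-peak separation 1 ms.  The
threshold point is the sample at which dV/dt last rises through the rate
criterion before the peak.  All constants are config-exposed
(`DetectorConfig`); the defaults follow common current-clamp practice.
Note that a rate-based threshold on an exponential spike-initiation model
sits at V ≈ V_T + Δ_T·ln(C·θ/(g_L·Δ_T)) — several Δ_T above the model's
nominal threshold parameter — which the tests assert explicitly.

**Rheobase** — per trial, the smallest depolarizing amplitude with ≥ 1
spike; the cell's value is the mean over trials that fired.  The companion
`rheobase_step_pA` (smallest protocol amplitude that fired in any trial)
is the integer-valued variant used for ground-truth comparison.

**Waveform morphometrics** — from the first AP of the rheobase sweep:
amplitude (peak − threshold), half-width at 50% of that amplitude, 10–90%
rise and 90–10% decay times (the printed literature names these without
defining them; 10–90% is the convention adopted here), and AHP =
threshold − post-spike minimum, searched to the next spike's threshold or
50 ms, whichever is first.  All crossings are linearly interpolated.

**Firing probability** — per-cell 0/1 indicator of ≥ 1 spike at a given
amplitude (majority of trials by default; any-trial rule available), and
the group fraction of indicators.

**Accommodation** — instantaneous frequency 1/ISI indexed by spike-interval
number, from spike peaks, per trial and then averaged per interval index.
Summaries: intervals 1–3 verbatim plus the collapsed mean of a late
inclusive interval range — [15, 20] at +200 pA and [19, 25] at +300 pA by
default.  ("Final 5 intervals (15–20)" is arithmetically six intervals;
the inclusive index range wins over the count.)

## Quality control

* Series resistance: a cell fails if |Rs_end − Rs_start|/Rs_start ≥ 20%
  (inclusive boundary).  Cells without Rs metadata pass as "not assessed".
* Minimum spikes for accommodation: > 5 spikes at +100 pA; ≥ 17 at
  ≥ +200 pA (both reported variants of the health rule are encoded), plus
  enough spikes to cover the late interval range being collapsed
  (range end + 1 peaks).
* Outliers: two-sided single-iteration Grubbs per measure per group at
  α = 0.05 — G = max|x−x̄|/s against
  G* = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) t-quantile on n−2 df.
  Flagged values are masked before testing and logged with the cell id,
  G and G*; nothing is silently dropped.

## Statistics

Welch's unequal-variance t-test (Satterthwaite df) or the Mann–Whitney
U-test, both two-sided, per measure with pairwise missing-value dropping.
The selection policy defaults to a Shapiro–Wilk gate (rank test iff either
group rejects normality at α = 0.05); a fixed per-measure map (rank tests
for input resistance and delay-to-first-spike) and forced policies are
available.  Mann–Whitney p is exact when the pooled sample is ≤ 20 and
tie-free, otherwise a tie- and continuity-corrected normal approximation;
U is reported as min(U_x, U_y).  Binary measures are reported as k/n and
percent.  No multiplicity correction by default (each measure is reported
on its own terms); Holm adjustment is available.  SEM uses the n−1 sd.

## The synthetic cohort model

Recordings are generated from an adaptive exponential integrate-and-fire
(AdEx) neuron with a first-order H-type conductance:

    C dV/dt = −g_L(V−E_L) + g_L Δ_T e^{(V−V_T)/Δ_T} − g_h h (V−E_h) − w + I(t)
    τ_w dw/dt = a(V−E_L) − w
    τ_h dh/dt = h_∞(V) − h,   h_∞(V) = 1/(1+e^{(V−V_h)/k_h})

with spike emission at V ≥ V_cut (stylised one-sample excursion to V_cut on
the output trace), reset to V_reset, w ← w + b, and a 2 ms refractory
clamp.  This is the simplest model producing everything the pipeline
measures — ohmic R_in, RC charging, sag and rebound, rheobase, delay to
first spike, and spike-frequency accommodation — while keeping closed-form
truth for the passive properties (R_in = 1000/g_L, τ = C/g_L, and
rheobase = g_L(V_T−E_L−Δ_T) when a = g_h = 0).  The adaptation current is a
phenomenological stand-in for whatever K⁺ machinery produces
accommodation in real granule cells; no mechanistic claim is attached.

Key defaults (full set in `NeuronParams`): C = 180 pF, g_L = 7.47 nS,
E_L = −79 mV, V_T = −61 mV, Δ_T = 2 mV, V_reset = −68 mV, a = 0,
τ_w = 120 ms, g_h = 0.8 nS, E_h = −30 mV, V_h = −110 mV, k_h = 4 mV,
τ_h = 80 ms, noise off.  Subthreshold adaptation is kept at a = 0 so the
steady-state deflection at −100 pA is purely leak-driven and the
R_in = 1000/g_L anchor holds; accommodation is carried entirely by the
spike-triggered increment b.  The sag midpoint −110 mV makes activation
negligible at the −100 pA steady state (~−92 mV) yet near-complete at
−400 pA (~−125 mV), mirroring the empirical observation that sag is
undetectable at −100 pA.

**Group regimes.** Two truncated-normal regimes emulate the study's
conditions: a wild-type-like group (g_L ≈ 7.47 nS → R_in ≈ 134 MΩ,
E_L ≈ −79 mV, g_h ≈ 0.8 nS, b ≈ 4 pA) and a transgenic-like group
(g_L ≈ 5.95 nS → R_in ≈ 168 MΩ, E_L 2.5 mV depolarized, g_h ≈ 0.4 nS,
b ≈ 18 pA).  The centres are calibrated to the reported group medians of
input resistance and to the reported effect *directions* only — higher
R_in, lower rheobase, higher firing fraction at the minimal step, lower
normalized sag, stronger late accommodation in the transgenic-like group.
The b values were additionally chosen so typical cells in both regimes
emit enough spikes at +200/+300 pA (≥ 21 / ≥ 26) to cover the late
accommodation windows.  No quantitative biophysical fidelity is claimed.

**Noise.** Ornstein–Uhlenbeck current noise (exact AR(1) discretisation,
stationary start) is available but off by default; per-sweep streams are
derived from (cohort seed, group, cell, amplitude, trial), so any single
sweep is reproducible in isolation.

## Numerics

Integration uses exponential-Euler on the instantaneous linear system in V
(given h and w), the spike-initiation exponential treated as a constant
current over the step and capped at (V_cut−V_T)/Δ_T to avoid overflow, and
exact exponential relaxation for w and h.  The internal step is 0.05 ms
(an integer subdivision of the output grid); each sweep starts from the
resting state found by settling 2 s at I = 0.  Halving dt changes
noise-free subthreshold samples by < 0.1 mV and interspike intervals by
< 0.2 ms; absolute spike times late in a long train accumulate the
per-spike reset quantisation (the reset happens at the end of the step
that detects the crossing), so convergence is asserted on counts, the
first spike and ISIs, not on late absolute times.  Rheobase ground truth
is bisection on constant-current steps (default bracket tolerance 0.5 pA,
upper bound 2000 pA); comparisons of protocol-step rheobase against this
truth are bracket-aware at step boundaries.

Bundle serialisation stores voltages at 0.1 µV fixed precision (round-trip
error < 1e-4 mV) and times at nanosecond precision so grid-spacing checks
hold at any sampling rate ≥ 5 kHz.

## Validation designs and their limits

* **Recovery cohort** (20 noise-free cells, half without g_h): extracted
  R_in within 2% of 1000/g_L, 67% time within 5% of 1.109·C/g_L on the
  sag-free half, protocol-step rheobase consistent with bisection truth
  for every cell.  The sag subgroup uses an activation midpoint of
  −118 mV so that residual H activation at the −100 pA steady state
  (error ≈ g_h·h_∞·66 pA per 100 pA injected) stays below ~0.7% even for
  corner cells — the validity premise of the passive oracle.
* **Null calibration**: 100 cohorts with both groups drawn from the
  identical wild-type-like regime (12 cells/group, reduced three-step
  schedule carrying exactly the sweeps the five calibrated passive
  measures need; Grubbs off so the tests' own level is what is measured).
  Per-measure rejection counts at α = 0.05 fall within the central 95%
  binomial interval around 5/100.
* **Directional cohort** (20 cells/group): reproduces the five reported
  effect signs listed above.

What this does **not** show: the generator produces stylised spikes (no
Na⁺/K⁺ waveform), no electrode artefacts, bridge imbalance, drift, or
seal degradation, and trials are exact replicas when noise is off.
Passing these designs therefore validates the *operational definitions and
statistical machinery*, not robustness to the full messiness of real
patch-clamp data.  Waveform metrics are instead validated on parametric
piecewise-linear AP shapes with closed-form geometry.

## Known limitations

* Cells are treated as independent units; cells-within-animal nesting is
  not modelled (no mixed-effects option).
* The threshold criterion is rate-based only; curvature-based definitions
  would give systematically different absolute thresholds.
* The AHP of a spike followed closely by another is bounded by the next
  threshold point and can be missing for < 1 ms separations.
* ABF/NWB adapters are import-on-demand contracts and are only as good as
  the sweep-ordering convention of the source file.
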