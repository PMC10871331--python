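# Methods

`patchfeat` analyses whole-cell patch-clamp recordings from cultured
neurons: current-clamp step series for intrinsic excitability and spike
morphology, voltage-clamp step series for voltage-gated currents, and small
voltage test pulses for passive membrane properties.  A synthetic cohort
generator with exact ground truth exercises every stage.  This note records
the models, the estimators, the tunable parameters, and the design choices
made where the procedure was genuinely open.

Units are fixed throughout: mV, pA, ms, MΩ, pF.  Sampling is 10 kHz
(dt = 0.1 ms) with 5 kHz low-pass filtering assumed done in hardware.  Time
is 0-based within a sweep and stimulus windows are half-open
[onset, onset + duration).  No liquid-junction-potential correction is
applied anywhere.

## Protocols

- **Current clamp**: 20 pA steps from −100 to 480 pA (30 levels), each level
  repeated 5 times, run once from the cell's resting potential and once
  while a bias current holds the cell near −60 mV.  Step duration is 500 ms
  with 100 ms pre-stimulus and 150 ms post-stimulus; these segment lengths
  are the package's own choice of field-typical values (they are not
  dictated by the analysis, which only requires a stable pre-stimulus
  baseline and a complete step window).
- **Voltage clamp**: 10 mV steps relative to a −60 mV holding potential,
  −10 to +100 mV (so a "+40 mV step" commands −20 mV absolute).  The −10 mV
  step doubles as the leak template.  Step duration 100 ms with 50 ms
  baseline on either side.
- **Test pulse**: −5 mV, 100 ms, from the −60 mV holding, for passive
  properties; repeated as checkpoints through a session.

## Spike detection

An action potential is an upward crossing of the first derivative through
+30 mV/ms followed within 10 ms by a downward crossing through −15 mV/ms,
with the voltage between the crossings required to exceed 0 mV.  Numerical
conventions the criteria leave open are fixed as follows:

- first derivative by forward difference (d[i] uses samples i, i+1); second
  derivative by central second difference;
- a crossing occurs between derivative samples i and i+1 when
  d[i] < θ ≤ d[i+1] (upward; mirrored for downward), stamped at sample i+1;
- after an accepted spike the scan resumes at the first sample after the
  downward crossing, so one spike is never counted twice;
- no pre-smoothing by default; an optional boxcar is config-gated
  (`DetectionConfig.smoothing_boxcar`).

Evoked spikes are those whose upward crossing falls inside a depolarizing
(amplitude > 0) current window; everything else is treated as spontaneous
or rebound activity and excluded.  Using the up-cross (not the peak) for
window membership is what excludes rebound spikes at step offset.

F-I summaries average evoked counts over the 5 repeats per level.  A level
counts as "at least one spike" when the mean count is positive, and as
"exactly one spike" when additionally the mean is below 1.5 (i.e. the
rounded mean is a single spike).  The collapse rule across repeats is a
package decision; per-repeat counts are retained on the `FICurve` for
alternative summaries.

## Rheobase features

Rheobase is the smallest level at which any repeat evoked a spike; features
come from the first evoked spike of the first such repeat, computed
independently per holding condition.  The threshold is the voltage at the
maximum of the second derivative in the window from 3 ms before the
30 mV/ms up-cross to the up-cross itself (ties break to the earliest
sample, for determinism).  Latency is threshold time minus step onset;
amplitude is peak minus threshold voltage; width is the full width at half
amplitude with half-level crossings linearly interpolated between
bracketing samples (at 0.1 ms sampling, sample-snapped widths would
quantize a ~1 ms spike by up to ±10%).  The spike ends at the first sample
after the peak below the threshold voltage; a spike that never re-crosses
is flagged `excluded_no_recross` and reports no width.  The peak is sought
in [threshold, down-cross], falling back to the 10 ms pairing window so a
peak exists even for excluded spikes.

## Passive membrane properties

The cell is a series access resistance Rs into a parallel Rm‖Cm membrane.
For a −5 mV step the clamp current jumps by ΔV/Rs and relaxes with
τ = Cm·Rs·Rm/(Rs+Rm) to ΔV/(Rs+Rm).  The estimator: baseline from the
pre-pulse segment; peak within 1 ms of onset; steady state as the mean of
the final 25% of the pulse; τ by least-squares single-exponential fit of
the decay from peak to pulse end with the steady level pinned.  Then
Rs = ΔV/ΔI_peak, R_input = ΔV/ΔI_ss, Rm = R_input − Rs and
Cm = τ(Rs+Rm)/(Rs·Rm).  A purely resistive trace (no transient) reports
R_input exactly and Cm = 0.  Whether a published capacitance is the τ-based
whole-cell value or an amplifier readout is generally ambiguous; the
τ-based estimator is this package's stated choice.

Resting potential is the mean over the first 200 ms (configurable) of a
zero-current baseline at least 100 ms long; a detected spike inside the
window raises a contaminated-baseline error rather than biasing the mean.
Checkpoints across a session are combined by field-wise arithmetic mean.
Session stability QC passes when the series-resistance coefficient of
variation is ≤ 20% and the resting-potential range ≤ 5 mV (defaults;
the criterion is inherently a lab convention, so both are configurable).

## Voltage-clamp analysis

The −10 mV step measures passive leak + capacitive current; because a
passive cell is linear, the correction for a step ΔV is
corrected(t) = raw(t) − (ΔV/−10)·leak(t), sample-wise.  Traces are then
zeroed on the pre-step baseline.  Maximum inward (negative) and outward
(positive) currents are read from the first 10 ms after onset; steady-state
current is the mean over the last third of the step.  Windows are computed
from the declared epoch, never inferred from the data.  A single leak sweep
is used by default (averaging across repeats is available).  No additional
capacitive-transient blanking is applied beyond the subtraction, and no
space-clamp correction is attempted.

## Group statistics

- **Kruskal–Wallis** (tie-corrected, χ² reference) with **Dunn** post-hoc z
  tests on mean ranks; the Dunn family adjustment defaults to Bonferroni
  across tested pairs (unadjusted values are reported alongside).
- **Mann–Whitney U**, exact for ≤ 8 per group without ties, tie-corrected
  normal approximation otherwise.
- **Mixed repeated-measures ANOVA**: between-subject factors genotype and
  treatment, within-subject factor current/voltage step.  Between effects
  are tested against the subjects-within-groups mean square (Type II sums
  of squares on subject means); within effects against the subject×level
  residual with numerator and denominator df scaled by the
  Greenhouse–Geisser epsilon, estimated from the pooled within-group
  covariance of the level responses and clipped to [1/(k−1), 1].  With two
  within-subject levels ε = 1 exactly.  The decomposition is computed by
  nested-model least squares, so unbalanced group sizes are handled; the
  single-between-factor case reproduces `pingouin.mixed_anova` F statistics
  to 1e-6 (epsilon differs in the third decimal because pingouin pools the
  covariance without group-centering).
- **Tukey(–Kramer)** post-hoc on the four genotype×treatment means using
  the studentized-range distribution and the subjects-within-groups error.
- **Firing-probability curves**: "one or more spikes" percentages are fit
  by a one-phase association through the origin, y = Ymax(1 − e^(−Kx));
  "exactly one spike" percentages by a line through the origin (closed-form
  slope Σxy/Σx²).  Groups are compared pairwise by extra-sum-of-squares
  F-tests of a shared fit vs separate fits, Bonferroni-corrected over the
  pairs.  The nested comparison tests the full parameter set of the curve,
  not a single parameter.

α = 0.05 package-wide.

## Synthetic cohorts

The generator is an oracle, not a biophysics study: every measured quantity
has an exact generative counterpart.

- **Spiking model**: leaky integrate-and-fire with spike-triggered
  adaptation (increment b per spike, exponential recovery τ_w).  The
  membrane ODE is solved exactly per sample for piecewise-constant input,
  propagated segment-wise between spikes as a first-order linear recursion,
  so integration error is zero up to float round-off.  At each threshold
  crossing the exact event time is recorded and an analytic
  piecewise-linear spike waveform is pasted (rise slope 150 mV/ms, fall
  −50 mV/ms, peak +30 mV for the WT preset), which by construction
  satisfies the detection criteria and has closed-form amplitude
  (peak − threshold) and FWHM ((A/2)(1/rise + 1/|fall|)).  Ground-truth
  spike times are grid-resolution event times.
- **Voltage-clamp templates**: passive leak + capacitive transient (linear
  in ΔV, hence removed exactly by leak subtraction), a Na-like inward
  alpha-function transient with Gaussian voltage dependence peaking near
  −20 mV absolute, and a K-like outward component (alpha transient plus
  saturating sustained part) with Boltzmann activation.  Template time
  constants are grid-aligned so analytic extrema land on samples.  The
  −10 mV leak sweep carries < 0.1% template contamination at −70 mV
  absolute, which bounds the leak-subtraction bias on extracted peaks well
  below the 2% recovery tolerance used in tests.
- **Phenotype presets** (`presets.json`, versioned): the Tau group encodes
  the qualitative tauopathy phenotype — elevated membrane resistance,
  reduced capacitance, depolarized rest, reduced inward/outward
  voltage-gated currents, reduced spike amplitude, and a tendency to fire a
  single spike implemented via a large adaptation increment; the AR-treated
  Tau preset restores WT-like values with a slightly narrower spike, and
  the AR-treated WT preset equals WT.  Magnitudes are order-of-magnitude
  physiological choices for cultured cortical neurons (the source data for
  the phenotype are not public), so tests assert orderings and recovery,
  never specific group medians.  Per-cell jitter is log-normal (σ = 0.15 in
  log space) for positive parameters and normal (σ = 1.5 mV) for voltages.
  Default group sizes mirror the cohort design (WT 63, WT+AR 13, Tau 37,
  Tau+AR 31); calibration and propagation checks use 30 per group.
- **Determinism**: a master seed expands into per-cell seeds via
  `numpy.random.SeedSequence.spawn`, so cohorts are bit-reproducible for a
  given (presets, n, seed).

### What the generator does not emulate

Electrode drift and access-resistance changes over a session, seal leaks,
bridge-balance artifacts, channel kinetics (activation/inactivation are
phenomenological templates), dendritic filtering and space-clamp error,
synaptic bombardment, and genuine spontaneous firing.  Passing tests
therefore demonstrate that the estimators are correct for the stated
models and robust at the simulated noise levels — not that they are immune
to every artifact of real recordings.

## Problem sizes and numerical tolerances

Detection-oracle equivalence is asserted over ≥ 1000 randomized traces;
passive recovery over a 27-point (Rs, Rm, Cm) grid noiseless (1% relative)
plus 100 noisy replicates (median Cm error < 5% at σ = 5 pA); leak
subtraction over 50 random linear cells at machine precision; rheobase over
a 9-point LIF grid (within one 20 pA step of (V_th − E_L)/R_m); ANOVA and
nested-F null calibration at 1000 replicates (acceptance band 0.035–0.065
at α = 0.05); phenotype propagation on a seeded 30-per-group WT/Tau cohort
with the resting-potential Kruskal–Wallis power check at 100 replicates.
Exponential fits use `scipy.optimize.curve_fit` with τ bounded below at
dt/10; degenerate inputs (all-zero associations, purely resistive cells,
empty sweeps) take documented closed-form branches instead of fits.
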