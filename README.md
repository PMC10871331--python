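# patchfeat

Analysis pipeline for whole-cell patch-clamp recordings from cultured
neurons, built for studies of intrinsic excitability and voltage-gated
currents in disease models (e.g. tauopathy vs wild-type cortical cultures,
with and without drug treatment).  It covers:

- **Spike detection** by slope criteria: an upward dV/dt crossing of
  +30 mV/ms followed within 10 ms by a downward crossing of −15 mV/ms, with
  the spike required to pass above 0 mV; spontaneous and rebound spikes
  (outside a depolarizing current window) are excluded.
- **Rheobase features**: the minimum current step that evokes a spike, and
  for the first spike fired there — threshold (voltage at the maximum of
  d²V/dt² in the 3 ms before the upstroke crossing), latency from step
  onset, amplitude (threshold to peak), and full width at half amplitude.
- **Passive membrane properties** from −5 mV test pulses at −60 mV holding:
  series resistance Rs = ΔV/ΔI_peak, input resistance ΔV/ΔI_ss, membrane
  resistance Rm = R_input − Rs, and capacitance Cm = τ(Rs+Rm)/(Rs·Rm) from
  the fitted decay constant; plus resting potential and session-stability
  QC.
- **Voltage-clamp currents**: ohmic leak subtraction scaled from the −10 mV
  step, baseline zeroing, maximum inward/outward currents in the first
  10 ms after the step, and steady-state I-V from the last third.
- **Group statistics**: Kruskal–Wallis + Dunn, Mann–Whitney U, mixed
  repeated-measures two-way ANOVA with Greenhouse–Geisser correction and
  Tukey post-hoc, and pairwise extra-sum-of-squares F-tests of
  origin-constrained curves (one-phase association y = Ymax(1 − e^(−Kx)) and
  lines y = ax) with Bonferroni correction.
- **A synthetic cohort generator** (integrate-and-fire with pasted analytic
  spike waveforms; closed-form voltage-clamp current templates) that
  emulates the recording protocols and the WT/Tau/±treatment phenotype
  contrasts with exact ground truth, so the whole pipeline is testable with
  no external data.

Canonical protocols: current clamp in 20 pA steps from −100 to 480 pA
(30 levels × 5 repeats), run from rest and from −60 mV; voltage clamp in
10 mV steps from a −60 mV holding.  All quantities are in mV, pA, ms, MΩ
and pF.  See `docs/methods.md` for the models, estimators and design
decisions.

## Worked example

Simulate one wild-type-like neuron, then extract its F-I curve, rheobase
spike features and passive properties:

```python
from patchfeat import (CellParams, simulate_current_clamp, simulate_test_pulse,
                       fi_curve, extract_rheobase_features, fit_test_pulse)

params = CellParams(e_leak=-65.0, r_mem=150.0, c_mem=100.0,
                    v_threshold=-45.0, noise_sd=0.0, adapt_increment=0.0)
rec, truth = simulate_current_clamp(params, seed=1)

fi = fi_curve(rec)
feat = extract_rheobase_features(rec)
props = fit_test_pulse(simulate_test_pulse(params, seed=1))

print(f"analytic rheobase {params.analytic_rheobase():.1f} pA, "
      f"measured {feat.rheobase:.0f} pA")
print(f"threshold {feat.threshold_voltage:.1f} mV, latency {feat.latency:.1f} ms, "
      f"amplitude {feat.amplitude:.1f} mV, width {feat.width:.2f} ms")
print(f"Rs {props.series_resistance:.1f} MOhm, Rm {props.membrane_resistance:.1f} "
      f"MOhm, Cm {props.capacitance:.1f} pF")
```

prints

```
analytic rheobase 133.3 pA, measured 140 pA
threshold -45.0 mV, latency 45.6 ms, amplitude 75.0 mV, width 1.00 ms
Rs 10.0 MOhm, Rm 150.0 MOhm, Cm 100.0 pF
```

The measured rheobase is the analytic value (V_th − E_L)/R_m = 133 pA
rounded up to the 20 pA protocol grid; threshold, amplitude and width match
the simulated cell's spike waveform (amplitude = peak − threshold = 75 mV;
FWHM = (A/2)(1/rise + 1/|fall|) = 1.0 ms); the passive fit recovers the
true membrane parameters exactly on noiseless data.  The latency of
45.6 ms reflects the slow charge toward threshold at a just-suprathreshold
step.

A thin CLI mirrors the library for file-based work, operating on the native
sweep-table dialect (long-format CSV plus a JSON metadata sidecar):

```sh
patchfeat simulate --preset Tau --n 5 --seed 7 --out traces/
patchfeat detect --in traces/Tau_000_cc_rest.csv --out spikes.csv
patchfeat fi     --in traces/Tau_000_cc_rest.csv --out fi.csv
patchfeat passive --in traces/Tau_000_test_pulse.csv --out props.csv
```

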