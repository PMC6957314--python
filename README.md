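# rhythmphase

Analysis of rhythmic population recordings from inspiratory rhythm-generating
networks — above all the preBötzinger complex (preBötC), the medullary
network that drives breathing in slice preparations — organized around a
three-phase view of each cycle: a **burst phase**, a **refractory phase** of
reduced excitability, and a **percolation phase** during which recurrent
excitation ramps back up to burst threshold.

It is written for electrophysiologists who record the integrated population
signal ∫preBötC together with single-neuron spiking, and who want the
commercial point-and-click steps of that workflow (peak detection,
interval statistics, curve fits) as reproducible, testable code.

## What it computes

* **Burst detection** on the integrated trace: running-median baseline,
  MAD noise scale, threshold crossings, merge/minimum-duration rules,
  per-burst duration and half-width.
* **Cycle segmentation**: the inter-burst interval (IBI) is offset→onset,
  the period onset→onset; summary mean/SD/frequency per condition.
* **Per-neuron metrics**: pre-inspiratory (pre-I) classification; burst
  spike frequency `(N−1)/(t_last−t_first)`; phase-normalized burst shape and
  its peak position; the pre-inspiratory ramp slope by OLS on binned IBI
  rates; burst-onset latencies and their jitter `ln(RMSSD)` (RMSSD in ms).
* **The optogenetic refractory assay**: stimulation trials are binned by
  elapsed time since the preceding burst onset; the evoked-probability curve
  `P(t) = plateau / (1 + exp(−(t − t50)/k))` is fit by weighted bounded
  least squares, and the refractory period is
  `RP = t50 + k·ln(c/(1−c))` at criterion `c = 0.9` of plateau.
  Curves are compared with an extra-sum-of-squares F test.
* **A synthetic-recording generator** implementing the cycle model
  `IBI_i = T_r + θ/s_i + ε_i` with a lognormal per-cycle ramp gain `s_i`,
  per-class inhomogeneous-Poisson spiking templates, and gated stimulation
  experiments — so every stage of the pipeline is verified by parameter
  recovery against known ground truth.  Presets `"baseline"` and `"SP"`
  encode the network state before and during substance P, an excitatory
  neuropeptide that speeds and stabilizes the rhythm by acting on the
  percolation phase while leaving the refractory phase untouched.

## Worked example

```python
from rhythmphase import (preset, generate_rhythm, detect_population_bursts,
                         segment_cycles, ibi_summary, population_burst_stats,
                         generate_stim_experiment, assemble_trials,
                         evoked_probability, fit_sigmoid, refractory_period)

cfg = preset("baseline")
trace, _, _ = generate_rhythm(cfg, n_cycles=100, seed=1)
bursts = detect_population_bursts(trace)
s = ibi_summary(segment_cycles(bursts, condition="baseline"))
b = population_burst_stats(bursts)
print(f"{len(bursts)} bursts, mean IBI {s.mean_ibi:.2f} s (SD {s.sd_ibi:.2f}), "
      f"frequency {s.frequency:.3f} Hz")
print(f"burst duration {1e3*b['mean_duration']:.0f} ms, "
      f"half-width {1e3*b['mean_halfwidth']:.0f} ms")

pulses, stim_bursts, _ = generate_stim_experiment(cfg, n_pulses=60, seed=1)
trials = assemble_trials(pulses, stim_bursts)
fit = fit_sigmoid(evoked_probability(trials, bin_width=0.5))
print(f"refractory period {refractory_period(fit, criterion=0.9):.2f} s "
      f"({sum(not t.excluded for t in trials)} included trials)")
```

prints

```
101 bursts, mean IBI 4.50 s (SD 1.22), frequency 0.192 Hz
burst duration 710 ms, half-width 423 ms
refractory period 2.27 s (51 included trials)
```

A detected mean IBI of 4.50 s with SD 1.22 s recovers the baseline preset
(4.5 ± 1.3 s model truth); the ~0.7 s bursts with ~0.43 s half-widths match
the configured envelope; and the assay places the refractory period near the
2 s hard gate built into the generator.  Exclusion of 9/60 trials reflects
pulses that landed inside an ongoing burst, which the assay discards by rule.

There is also a CLI for shell use:

```bash
rhythmphase simulate --preset baseline --slices 2 --cycles 100 --seed 1 --out sim/
rhythmphase detect --bundle sim/slice_00 --out bursts.csv
rhythmphase all --seed 1 --out report/          # simulate→analyze→figures
```

## Layout

| module | contents |
| --- | --- |
| `rhythmphase.core` | domain types, bundle I/O (manifest + CSV), condition windows |
| `rhythmphase.detect` | population-burst and spike detection |
| `rhythmphase.cycles` | cycle segmentation, IBI summaries, phase normalization |
| `rhythmphase.metrics` | classification, burst/ramp/shape/onset metrics |
| `rhythmphase.refractory` | stimulation trials, probability curves, sigmoid fits |
| `rhythmphase.stats` | paired/Welch t, ANOVA + Bonferroni, linear regression |
| `rhythmphase.synth` | presets, rhythm/neuron/stimulation generators, ledger |
| `rhythmphase.pipeline`, `rhythmphase.cli` | orchestration, figures, CLI |

See `docs/methods.md` for the model, its assumptions, parameter defaults,
and known limitations.
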