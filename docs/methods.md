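# Methods

## The three-phase cycle model

Each inspiratory cycle is treated as a population burst followed by an
inter-burst interval (IBI) with two hidden parts: a refractory phase of
fixed duration `T_r` during which the network cannot burst, and a
percolation phase during which recurrent excitation ramps back toward
threshold.  The generator's interval model is

    IBI_i = T_r + θ / s_i + ε_i ,   s_i ~ LogNormal(μ_s, σ_s),
                                    ε_i ~ Normal(0, σ_ε),  IBI_i > T_r,

with the percolation threshold normalized to θ = 1 (arbitrary excitability
units).  A cycle with a steep excitability ramp (large `s_i`) reaches
threshold sooner, so the inverse relationship between the pre-inspiratory
ramp slope and the IBI holds by construction, and the slope of the ramp a
pre-I neuron fires during cycle *i* is proportional to `s_i`.

`(μ_s, σ_s)` are calibrated by the lognormal reciprocal moments
(`E[1/s] = exp(−μ + σ²/2)`, `Var[1/s] = E[1/s]²(exp(σ²) − 1)`) so the IBI
mean and SD equal the preset targets exactly:

| preset | mean IBI (s) | SD IBI (s) | μ_s | σ_s |
| --- | --- | --- | --- | --- |
| baseline | 4.5 | 1.3 | −0.800576 | 0.481071 |
| SP | 3.5 | 0.84 | −0.279766 | 0.501396 |

with `T_r = 2.0 s` and `σ_ε = 0.25 s` shared.  The truncation `IBI > T_r`
is enforced by redraw; at these parameters it essentially never binds, so
the analytic moments hold to the quoted precision.

The two presets differ **only** in percolation-phase parameters, the
pre-I/recruited IBI templates, the burst-envelope width targets, and the
non-pre-I onset jitter.  The refractory duration, all burst-phase rates,
the stimulation protocol and the inhibitory templates are byte-identical
between presets: the substance P condition is encoded as a percolation-phase
phenomenon, and the pipeline is expected to *discover* that the refractory
period and inhibitory activity are unchanged rather than being told.

## Population trace and burst envelope

The integrated population signal is unit-variance Gaussian noise, low-pass
smoothed with a 50 ms kernel (the scale of typical integration time
constants for rectified population signals), plus one trapezoidal envelope
per burst with peak 30 noise SD.  The trapezoid is not parameterized by its
corners but by two measurement targets — the width `D` at the detection
level (3 noise SD) and the width `H` at half peak.  With `ρ` the detection
level as a fraction of peak, the flank total and plateau are

    F = (D − H) / (0.5 − ρ),     plateau = H − F/2 ,

split 15 % rise / 85 % fall (sharp inspiratory onset, slower decay).  The
solver rejects target pairs with a negative plateau; both preset pairs
(baseline 707/429 ms, SP 854/478 ms) are feasible at ρ = 0.1.  The default
sample rate is 200 Hz — ample for ~0.7 s bursts while keeping hour-scale
simulations small.

## Burst detection

Baseline = running median over 30 s (evaluated on a 1 s stride and
interpolated; the exact per-sample running median adds nothing at these
time scales).  The noise scale is estimated in two passes because bursts
contaminate one-sidedly: a coarse one-sided MAD on the below-median
deviations, then a re-centered MAD over the samples below two coarse scales.
(The naive two-sided MAD runs ~20 % high at a 17 % burst duty cycle, which
biases onsets late and durations short.)  Candidate events are maximal runs
above `baseline + 3·noise`, runs closer than 0.2 s are merged so multi-peak
bursts stay single events, and merged events whose *total supra-threshold
content* is under 0.15 s are discarded — content, not span, so that two
isolated noise blips 0.15 s apart can never masquerade as a burst while a
dipping multi-peaked burst keeps its full extent.  Onset, offset and the
half-width crossings are interpolated linearly between samples.

Defaults: `baseline_window 30 s`, `threshold_k 3`, `min_duration 0.15 s`,
`merge_gap 0.2 s`, `halfwidth_level 0.5`.

## Cycles and conventions

All intervals are half-open `[start, end)`; a boundary event belongs to the
interval that starts there.  The IBI is offset→onset; the period and all
elapsed-time measurements (including the refractory assay) are referenced to
burst **onset**.  Frequency is `1/mean(period)`.  These conventions are
internally consistent but mean that frequency, mean IBI and burst duration
are three separate quantities, not two plus a residual.

## Per-neuron spiking templates and metrics

Burst-phase rates follow a beta density over normalized burst time
(mode = the class peak position, concentration 6) mixed with a uniform
floor, scaled so the time-averaged rate equals the class mean.  The floor
(0.35 pre-I, 0.3 others) gives decrementing classes a nonzero onset rate —
without it the first-spike latency is dominated by the Poisson first-arrival
wait rather than by timing jitter.  Class parameters (rate in Hz / peak
position in % of burst / IBI behavior):

| class | burst | IBI baseline | IBI in SP |
| --- | --- | --- | --- |
| pre-I excitatory | 28.0 / 49 | ramp, 5.1 Hz mean, 1.7 Hz/s slope | ramp, 9.9 Hz, 3.7 Hz/s |
| non-pre-I excitatory | 34.9 / 34 | silent | silent |
| recruited excitatory | 28.9 / 34 | silent | ramp, 6.6 Hz, 4.1 Hz/s |
| inhibitory | 48.6 / 24 | silent | silent |
| rostral excitatory | 11.1 / 34 | silent | silent |
| rostral inhibitory | 5.3 / 34 | tonic 1.5 Hz, zero slope | tonic 1.5 Hz |

The per-cycle ramp is `max(0, b_i + g_i·t)` with `g_i = (class slope /
E[s])·s_i` and the intercept `b_i` solved so the time-averaged IBI rate is
exactly the class mean (clipped-ramp branch when the solution is negative).
Onset jitter is injected as a whole-burst time shift per cycle,
`Normal(0, σ_j)`: σ_j = 40 ms for pre-I (both conditions), 10 → 25 ms for
non-pre-I and recruited classes (baseline → SP), 15 ms for inhibitory.

Analysis-side conventions: pre-I classification requires a mean rate
≥ 0.5 Hz over the *second half* of the IBI in ≥ 50 % of cycles (an explicit,
reproducible stand-in for classification by inspection); burst spike
frequency is `(N−1)/(t_last − t_first)` over cycles with ≥ 2 spikes (note
this estimator carries a ~`2/duration` edge bias for uniform spiking — the
tests assert against the order-statistics expectation, not the naive rate);
ramp fits use 0.25 s bins with the final partial bin dropped and need ≥ 4
bins; jitter latencies are converted to ms before `ln(RMSSD)` (values of
2–5 are only dimensionally consistent with milliseconds).

The pooled slope-vs-IBI regression takes each neuron's first 20 analyzable
cycles, normalizes the per-cycle IBI and slope by that neuron's own means,
pools, and regresses normalized IBI on normalized slope by OLS.

## Stimulation assay

Pulses (200 ms, every 20 s, ≥ 50 per experiment) are paired with the
rhythm: a pulse inside an ongoing burst is excluded; otherwise elapsed time
runs from the preceding burst onset and the pulse counts as evoked if a
burst onset falls within pulse duration + 0.3 s response window.  In the
generator the pulse never evokes within the hard gate (`elapsed ≤ T_r`) and
beyond it evokes with probability `sigmoid(elapsed)` whose parameters
(steepness 0.25 s, `t50 = T_r − 0.25·ln 9`) are chosen so the gated true
curve first reaches 0.9 of plateau exactly at `T_r` — i.e. the generative
refractory period *is* the 2 s gate.  An evoked burst (onset 150 ms after
pulse onset) restarts the cycle clock.

The evoked-probability curve uses 0.5 s bins (empty bins carry no point);
the sigmoid fit is bounded weighted least squares (weights = trial counts,
plateau ∈ (0,1], deterministic initialization, a tight polishing pass after
convergence).  The refractory-period readout
`t50 + steepness·ln(c/(1−c))`, c = 0.9, sits slightly above the hard gate
on binned data (bin-discretization; ~2.0–2.3 s across seeds).  Curve
comparison is the extra-sum-of-squares F test between a shared 3-parameter
fit and separate 6-parameter fits; two numerically perfect fits short-circuit
to p = 1.

## Statistics

Paired and Welch t tests, one-way ANOVA with Bonferroni-multiplied pairwise
post hocs, and OLS regression are thin wrappers over scipy.stats with the
inputs validated and degenerate cases (zero-variance differences, constant
regressors) raised as errors rather than returned as NaN.  Test selection is
named explicitly in pipeline configs, never inferred from the data.
Significance tiers: \*\*\*\*/\*\*\*/\*\*/\* at 1e-4/1e-3/1e-2/5e-2.

## What the generator does and does not emulate

It emulates: rhythmic bursts with realistic interval statistics and a hard
refractory gate; envelope widths matching measured burst duration and
half-width; per-class burst shapes, IBI ramps tied cycle-by-cycle to the
interval model, onset jitter, and gated stimulation experiments.

It does **not** emulate: biophysics (no conductances, synapses or network
graph); per-class neuronal burst durations as a separate degree of freedom
(spike spans emerge from the beta profile, so a class configured at 48.6 Hz
does not also reproduce a 316 ms measured span); amplitude adaptation,
sighs, or drift in burst amplitude; heavy-tailed or bursty IBI outliers; and
the rostral-excitatory rate suppression under SP (burst-phase rates are held
preset-invariant by design).  Passing recovery tests therefore validates the
*estimators* under the stated statistical structure, not the biology of any
particular slice.

Known estimator limitations, visible in the tests: the per-cycle ramp OLS
is unbiased on unclipped linear ramps but the grand mean slope runs ~5–8 %
low under the presets because steep-ramp cycles hit the clipped-intercept
branch; the `max_rate_change` onset rule (inverse-ISI forward difference)
is heavy-tailed on Poisson trains, so pre-I jitter estimates are dominated
by estimator noise rather than injected jitter — the between-class jitter
*ordering* is preserved, the absolute pre-I value is not a calibrated
quantity.

## Numerical choices

Seeded `numpy.random.default_rng` everywhere; identical seed + config give
byte-identical traces, spike trains and reports.  Spike-train assembly
enforces strictly increasing times (1 ns nudges on exact collisions).
Sigmoid fits bound steepness to [1e-3, 10] s and plateau to (0, 1];
non-convergence raises with the initialization and data attached.  Problem
sizes in the acceptance script (6 slices × 100 cycles, 60 pulses × 5 seeds,
9 pre-I / 7 inhibitory neurons, 200 cycles for burst widths) are the sizes
of the corresponding slice experiments; the whole script runs in a few
seconds.
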