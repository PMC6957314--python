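"""Synthetic recording generator for the three-phase cycle model.

Each inspiratory cycle has a burst phase, a hard refractory phase, and a
percolation phase in which excitability ramps to threshold.  The cycle
model is

    IBI_i = T_r + theta / s_i + eps_i          (truncated to > T_r)

with a per-cycle ramp gain ``s_i ~ LogNormal(mu_s, sigma_s)``: a steep ramp
reaches the percolation threshold ``theta`` sooner, which builds the
observed inverse relationship between pre-inspiratory slope and IBI into
the ground truth.  Per-neuron spiking is an inhomogeneous Poisson process:
a beta-family rate profile over normalized burst time (plus a uniform
floor, so decrementing classes start firing at burst onset), and an IBI
template that is silent, tonic, or a linear ramp whose slope is
proportional to that cycle's ``s_i``.  Stimulation experiments gate an
evoking sigmoid with the hard refractory duration.

Presets ``"baseline"`` and ``"SP"`` encode the substance P findings as
generative truth: SP shortens and stabilizes the percolation phase,
recruits a class of excitatory neurons into ramping, raises non-pre-I
onset jitter, and broadens population bursts — while the refractory
duration, burst-phase rates and inhibitory templates are identical in both
presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d

from .core import BurstEvent, SpikeTrain, StimPulse, Trace


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurstEnvelope:
    """Trapezoidal population-burst envelope, defined by *measurement targets*.

    ``duration_target`` is the width at the detection threshold
    (``detect_level`` noise multiples) and ``halfwidth_target`` the width at
    half peak; plateau and flank lengths are solved from these.
    """

    duration_target: float  # s, threshold-crossing width
    halfwidth_target: float  # s, width at half peak
    peak_amplitude: float = 30.0  # noise multiples above baseline
    detect_level: float = 3.0  # noise multiples: reference threshold
    rise_fraction: float = 0.15  # rise share of the total flank time

    def solve(self):
        """Return (rise, plateau, fall) in seconds; raises if unsatisfiable."""
        rho = self.detect_level / self.peak_amplitude
        if not rho < 0.5:
            raise ValueError("detection level must sit below half peak")
        flank = (self.duration_target - self.halfwidth_target) / (0.5 - rho)
        plateau = self.halfwidth_target - 0.5 * flank
        if flank <= 0 or plateau < 0:
            raise ValueError(
                f"envelope targets unsatisfiable: duration {self.duration_target}, "
                f"halfwidth {self.halfwidth_target}, level {rho:.3f} of peak"
            )
        return self.rise_fraction * flank, plateau, (1 - self.rise_fraction) * flank


@dataclass(frozen=True)
class ClassTemplate:
    """Spiking template of one neuron class.

    burst_rate      : Hz, time-averaged rate over the population burst
    burst_peak_pos  : mode of the burst-phase beta profile (fraction of burst)
    burst_floor     : uniform admixture (0..1) giving nonzero edge rate
    ibi_kind        : "none" | "tonic" | "ramp"
    ibi_mean_rate   : Hz, time-averaged IBI rate (tonic and ramp kinds)
    ramp_slope_mean : Hz/s, population-mean ramp slope (ramp kind)
    jitter_sd       : s, SD of the whole-burst onset shift per cycle
    """

    burst_rate: float
    burst_peak_pos: float
    burst_floor: float = 0.3
    burst_concentration: float = 6.0
    ibi_kind: str = "none"
    ibi_mean_rate: float = 0.0
    ramp_slope_mean: float = 0.0
    jitter_sd: float = 0.01

    def __post_init__(self):
        if self.ibi_kind not in ("none", "tonic", "ramp"):
            raise ValueError(f"unknown IBI template {self.ibi_kind!r}")


@dataclass(frozen=True)
class StimProtocol:
    interval: float = 20.0  # s between pulses
    pulse_duration: float = 0.2  # s
    sigmoid_t50: float = 2.0 - 0.25 * float(np.log(9.0))  # s; see preset notes
    sigmoid_steepness: float = 0.25  # s
    sigmoid_plateau: float = 1.0
    evoked_latency: float = 0.15  # s from pulse onset to evoked burst onset


@dataclass(frozen=True)
class SynthConfig:
    name: str
    refractory_T: float  # s, hard refractory duration
    theta: float  # percolation threshold (arbitrary excitability units)
    mu_s: float  # LogNormal location of the per-cycle ramp gain
    sigma_s: float  # LogNormal scale
    sigma_eps: float  # s, additive IBI noise
    envelope: BurstEnvelope
    templates: MappingProxyType  # class name -> ClassTemplate
    stim: StimProtocol = field(default_factory=StimProtocol)
    noise_scale: float = 1.0  # trace noise SD, arbitrary units
    sample_rate: float = 200.0  # Hz
    lead_in: float = 5.0  # s of quiet trace before the first burst

    @property
    def mean_gain(self) -> float:
        """E[s] of the lognormal ramp gain."""
        return float(np.exp(self.mu_s + self.sigma_s**2 / 2))

    @property
    def mean_ibi(self) -> float:
        """Analytic E[IBI] = T_r + theta * E[1/s]."""
        return self.refractory_T + self.theta * float(
            np.exp(-self.mu_s + self.sigma_s**2 / 2)
        )

    @property
    def sd_ibi(self) -> float:
        """Analytic SD[IBI] from lognormal reciprocal moments + eps."""
        m1 = np.exp(-self.mu_s + self.sigma_s**2 / 2)
        var = self.theta**2 * m1**2 * (np.exp(self.sigma_s**2) - 1)
        return float(np.sqrt(var + self.sigma_eps**2))


# Preset parameter tables.  The IBI lognormals are calibrated by reciprocal
# moments so that (mean, SD) of T_r + theta/s + eps hit the target interval
# statistics exactly; class templates carry the per-class rates, shapes and
# slopes; both presets share refractory_T, burst-phase rates, the stim
# protocol and the inhibitory template.
_SHARED_BURST = dict(
    exc_preI=dict(burst_rate=28.0, burst_peak_pos=0.49, burst_floor=0.35),
    exc_nonpreI=dict(burst_rate=34.9, burst_peak_pos=0.34, burst_floor=0.3),
    exc_recruited=dict(burst_rate=28.9, burst_peak_pos=0.34, burst_floor=0.3),
    inhibitory=dict(burst_rate=48.6, burst_peak_pos=0.24, burst_floor=0.3),
    rostral_exc=dict(burst_rate=11.1, burst_peak_pos=0.34, burst_floor=0.3),
    rostral_inh=dict(burst_rate=5.3, burst_peak_pos=0.34, burst_floor=0.3),
)

_PRESETS = {
    "baseline": dict(
        mu_s=-0.800576,
        sigma_s=0.481071,
        envelope=BurstEnvelope(duration_target=0.707, halfwidth_target=0.429),
        ibi_templates=dict(
            exc_preI=dict(ibi_kind="ramp", ibi_mean_rate=5.1, ramp_slope_mean=1.7),
            exc_nonpreI=dict(ibi_kind="none"),
            exc_recruited=dict(ibi_kind="none"),
            inhibitory=dict(ibi_kind="none"),
            rostral_exc=dict(ibi_kind="none"),
            rostral_inh=dict(ibi_kind="tonic", ibi_mean_rate=1.5),
        ),
        jitter=dict(
            exc_preI=0.040,
            exc_nonpreI=0.010,
            exc_recruited=0.010,
            inhibitory=0.015,
            rostral_exc=0.025,
            rostral_inh=0.025,
        ),
    ),
    "SP": dict(
        mu_s=-0.279766,
        sigma_s=0.501396,
        envelope=BurstEnvelope(duration_target=0.854, halfwidth_target=0.478),
        ibi_templates=dict(
            exc_preI=dict(ibi_kind="ramp", ibi_mean_rate=9.9, ramp_slope_mean=3.7),
            exc_nonpreI=dict(ibi_kind="none"),
            exc_recruited=dict(ibi_kind="ramp", ibi_mean_rate=6.6, ramp_slope_mean=4.1),
            inhibitory=dict(ibi_kind="none"),
            rostral_exc=dict(ibi_kind="none"),
            rostral_inh=dict(ibi_kind="tonic", ibi_mean_rate=1.5),
        ),
        jitter=dict(
            exc_preI=0.040,
            exc_nonpreI=0.025,
            exc_recruited=0.025,
            inhibitory=0.015,
            rostral_exc=0.040,
            rostral_inh=0.025,
        ),
    ),
}


def preset(name: str) -> SynthConfig:
    """Return the immutable ``"baseline"`` or ``"SP"`` parameter set."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    p = _PRESETS[name]
    templates = {}
    for cls, burst in _SHARED_BURST.items():
        templates[cls] = ClassTemplate(
            **burst, **p["ibi_templates"][cls], jitter_sd=p["jitter"][cls]
        )
    return SynthConfig(
        name=name,
        refractory_T=2.0,
        theta=1.0,
        mu_s=p["mu_s"],
        sigma_s=p["sigma_s"],
        sigma_eps=0.25,
        envelope=p["envelope"],
        templates=MappingProxyType(templates),
    )


# ---------------------------------------------------------------------------
# ledger
# ---------------------------------------------------------------------------

@dataclass
class GeneratorLedger:
    """Ground truth sufficient to recompute every comparison without rerunning."""

    config: SynthConfig
    cycles: pd.DataFrame = None  # per-cycle truth: s, ibi, onset, offset, ...
    neurons: dict = field(default_factory=dict)  # neuron_id -> per-neuron truth
    trials: pd.DataFrame = None  # per-trial truth for stim experiments


# ---------------------------------------------------------------------------
# rhythm generation
# ---------------------------------------------------------------------------

def _draw_ibis(config: SynthConfig, n: int, rng) -> tuple:
    """Draw (s_i, ibi_i) with the truncation IBI > T_r enforced by redraw."""
    s = rng.lognormal(config.mu_s, config.sigma_s, n)
    eps = rng.normal(0.0, config.sigma_eps, n)
    ibi = config.refractory_T + config.theta / s + eps
    bad = np.flatnonzero(ibi <= config.refractory_T)
    while bad.size:
        s[bad] = rng.lognormal(config.mu_s, config.sigma_s, bad.size)
        eps_new = rng.normal(0.0, config.sigma_eps, bad.size)
        ibi[bad] = config.refractory_T + config.theta / s[bad] + eps_new
        bad = bad[ibi[bad] <= config.refractory_T]
    return s, ibi


def _smoothed_noise(n: int, rng, fs: float, corr_s: float = 0.05) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed with a ``corr_s`` kernel."""
    sig = corr_s * fs
    white = rng.normal(0.0, 1.0, n)
    smooth = gaussian_filter1d(white, sig, mode="reflect")
    return smooth * np.sqrt(2.0 * sig * np.sqrt(np.pi))


def generate_rhythm(config: SynthConfig, n_cycles: int, seed: int):
    """Simulate the integrated population trace for ``n_cycles`` cycles.

    Produces ``n_cycles + 1`` bursts (a cycle is a burst plus the following
    IBI).  Returns ``(trace, bursts, ledger)`` where burst onsets/offsets
    are the threshold-crossing times of the noiseless envelope.
    """
    if n_cycles < 1:
        raise ValueError("need n_cycles >= 1")
    rng = np.random.default_rng(seed)
    rise, plateau, fall = config.envelope.solve()
    env = config.envelope
    D = env.duration_target
    rho = env.detect_level / env.peak_amplitude
    peak = env.peak_amplitude * config.noise_scale
    fs = config.sample_rate

    n_bursts = n_cycles + 1
    s, ibis = _draw_ibis(config, n_cycles, rng)
    onsets = np.empty(n_bursts)
    onsets[0] = config.lead_in
    for i in range(n_cycles):
        onsets[i + 1] = onsets[i] + D + ibis[i]
    offsets = onsets + D

    total = offsets[-1] + config.lead_in
    n_samp = int(round(total * fs))
    values = config.noise_scale * _smoothed_noise(n_samp, rng, fs)
    t = np.arange(n_samp) / fs

    # envelope node points relative to the threshold-crossing onset
    base0 = -rho * rise
    nodes_t = np.array([base0, base0 + rise, base0 + rise + plateau, base0 + rise + plateau + fall])
    nodes_v = np.array([0.0, peak, peak, 0.0])
    for on in onsets:
        i0 = max(int(np.floor((on + nodes_t[0]) * fs)), 0)
        i1 = min(int(np.ceil((on + nodes_t[-1]) * fs)) + 1, n_samp)
        values[i0:i1] += np.interp(t[i0:i1] - on, nodes_t, nodes_v, left=0.0, right=0.0)

    trace = Trace("population", "population_integrated", fs, values)
    bursts = [
        BurstEvent(
            onset=float(on),
            offset=float(off),
            peak_time=float(on + (1 - rho) * rise + plateau / 2),
            peak_amplitude=float(peak),
            halfwidth=env.halfwidth_target,
            provenance="simulated",
        )
        for on, off in zip(onsets, offsets)
    ]
    ledger = GeneratorLedger(
        config=config,
        cycles=pd.DataFrame(
            {
                "index": np.arange(n_cycles),
                "s": s,
                "ibi": ibis,
                "onset": onsets[:-1],
                "offset": offsets[:-1],
                "next_onset": onsets[1:],
            }
        ),
    )
    return trace, bursts, ledger


# ---------------------------------------------------------------------------
# neuron generation
# ---------------------------------------------------------------------------

def _beta_profile_sampler(template: ClassTemplate, n_grid: int = 512):
    """Inverse-CDF sampler of normalized burst time for a class profile."""
    m = template.burst_peak_pos
    k = template.burst_concentration
    a = 1.0 + m * (k - 2.0)
    b = 1.0 + (1.0 - m) * (k - 2.0)
    u = np.linspace(0.0, 1.0, n_grid)
    pdf = (1.0 - template.burst_floor) * sps.beta.pdf(u, a, b) + template.burst_floor
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2.0 * np.diff(u))])
    cdf /= cdf[-1]

    def sample(q):
        return np.interp(q, cdf, u)

    return sample


def _sample_ramp_times(L: float, g: float, mean_rate: float, rng):
    """Spike times of one IBI under the linear-ramp template.

    Rate r(t) = max(0, b + g t) on [0, L) with intercept b solved so the
    time-averaged rate equals ``mean_rate`` exactly: b = mean - gL/2 when
    that is nonnegative, otherwise the ramp is clipped at zero and starts at
    t0 = L - sqrt(2 mean L / g).  Returns (times, b).
    """
    if mean_rate <= 0:
        return np.empty(0), 0.0
    n = rng.poisson(mean_rate * L)
    b = mean_rate - g * L / 2.0
    if g <= 0:  # degenerate: uniform
        return np.sort(rng.uniform(0.0, L, n)), mean_rate
    if b >= 0:
        q = rng.uniform(0.0, 1.0, n)
        Z = b * L + g * L**2 / 2.0
        times = (-b + np.sqrt(b**2 + 2.0 * g * q * Z)) / g
    else:
        t0 = L - np.sqrt(2.0 * mean_rate * L / g)
        b = -g * t0
        q = rng.uniform(0.0, 1.0, n)
        times = t0 + (L - t0) * np.sqrt(q)
    return np.sort(times), float(b)


def _strictly_increasing(times: np.ndarray) -> np.ndarray:
    times = np.sort(times)
    if times.size < 2:
        return times
    dup = np.flatnonzero(np.diff(times) <= 0)
    while dup.size:
        times[dup + 1] = times[dup] + 1e-9
        times = np.sort(times)
        dup = np.flatnonzero(np.diff(times) <= 0)
    return times


def generate_neuron(
    config: SynthConfig, cls: str, cycles: pd.DataFrame, seed: int, neuron_id: str = None
):
    """Simulate one neuron's spike train over the ledger cycles.

    Burst-phase spikes are an inhomogeneous Poisson draw from the class
    profile over the (jitter-shifted) population burst window; IBI spikes
    follow the class IBI template, with the ramp slope of cycle i equal to
    ``(ramp_slope_mean / E[s]) * s_i``.  Returns ``(SpikeTrain, truth)``
    where truth holds the injected per-cycle onset shifts and ramp
    parameters.
    """
    if cls not in config.templates:
        raise KeyError(f"no template for class {cls!r}")
    tpl = config.templates[cls]
    rng = np.random.default_rng(seed)
    sampler = _beta_profile_sampler(tpl)
    slope_scale = tpl.ramp_slope_mean / config.mean_gain if tpl.ibi_kind == "ramp" else 0.0

    all_times = []
    shifts = np.empty(len(cycles))
    gains = np.zeros(len(cycles))
    intercepts = np.zeros(len(cycles))
    for i, row in enumerate(cycles.itertuples()):
        delta = rng.normal(0.0, tpl.jitter_sd)
        shifts[i] = delta
        dur = row.offset - row.onset
        n_burst = rng.poisson(tpl.burst_rate * dur)
        u = sampler(rng.uniform(0.0, 1.0, n_burst))
        all_times.append(row.onset + delta + u * dur)
        L = row.next_onset - row.offset
        if tpl.ibi_kind == "tonic":
            n_ibi = rng.poisson(tpl.ibi_mean_rate * L)
            all_times.append(row.offset + np.sort(rng.uniform(0.0, L, n_ibi)))
        elif tpl.ibi_kind == "ramp":
            g = slope_scale * row.s
            times, b = _sample_ramp_times(L, g, tpl.ibi_mean_rate, rng)
            gains[i] = g
            intercepts[i] = b
            all_times.append(row.offset + times)
    times = _strictly_increasing(np.concatenate(all_times))
    nid = neuron_id or f"{cls}_{seed}"
    truth = {
        "class": cls,
        "template": tpl,
        "onset_shifts": shifts,
        "ramp_gains": gains,
        "ramp_intercepts": intercepts,
    }
    return SpikeTrain(nid, times), truth


# ---------------------------------------------------------------------------
# stimulation experiments
# ---------------------------------------------------------------------------

def generate_stim_experiment(config: SynthConfig, n_pulses: int, seed: int):
    """Simulate a photostimulation experiment.

    Pulses arrive every ``stim.interval`` seconds into the ongoing rhythm.
    At each pulse the elapsed time since the preceding burst *onset* is
    computed: within the hard refractory gate the pulse never evokes;
    beyond it, it evokes with probability ``sigmoid(elapsed)``.  An evoked
    burst restarts the cycle clock.  Returns ``(pulses, bursts, ledger)``.
    """
    if n_pulses < 1:
        raise ValueError("need n_pulses >= 1")
    rng = np.random.default_rng(seed)
    st = config.stim
    D = config.envelope.duration_target
    H = config.envelope.halfwidth_target
    peak = config.envelope.peak_amplitude * config.noise_scale

    def sigmoid(t):
        return st.sigmoid_plateau / (1.0 + np.exp(-(t - st.sigmoid_t50) / st.sigmoid_steepness))

    def draw_ibi():
        return float(_draw_ibis(config, 1, rng)[1][0])

    def make_burst(onset, evoked):
        return BurstEvent(
            onset=float(onset),
            offset=float(onset + D),
            peak_time=float(onset + 0.3 * D),
            peak_amplitude=peak,
            halfwidth=H,
            provenance="simulated",
        ), evoked

    bursts = []  # (BurstEvent, evoked flag)
    pending = config.lead_in  # next spontaneous onset
    trial_rows = []
    pulse_times = st.interval * np.arange(1, n_pulses + 1)
    pulses = [StimPulse(float(t), st.pulse_duration) for t in pulse_times]
    for tp in pulse_times:
        while pending <= tp:
            bursts.append(make_burst(pending, False))
            pending = pending + D + draw_ibi()
        last_onset, last_offset = bursts[-1][0].onset, bursts[-1][0].offset
        if tp <= last_offset:
            trial_rows.append((tp, np.nan, False, False, True, "pulse_during_burst"))
            continue
        elapsed = tp - last_onset
        gated = elapsed > config.refractory_T
        evoked = bool(gated and rng.uniform() < sigmoid(elapsed))
        if evoked:
            onset = tp + st.evoked_latency
            bursts.append(make_burst(onset, True))
            pending = onset + D + draw_ibi()
        observed = evoked or (pending <= tp + st.pulse_duration + 0.3)
        trial_rows.append((tp, elapsed, evoked, observed, False, ""))
    ledger = GeneratorLedger(
        config=config,
        trials=pd.DataFrame(
            trial_rows,
            columns=["pulse_time", "elapsed", "evoked", "observed", "excluded", "reason"],
        ),
    )
    burst_events = [b for b, _ in bursts]
    ledger.cycles = pd.DataFrame(
        {
            "onset": [b.onset for b in burst_events],
            "offset": [b.offset for b in burst_events],
            "evoked": [ev for _, ev in bursts],
        }
    )
    return pulses, burst_events, ledger


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------

def simulate_bundle(
    config: SynthConfig,
    n_cycles: int,
    neuron_spec: dict,
    seed: int,
    condition: str = None,
):
    """Simulate a full recording bundle: trace + neurons under one preset.

    ``neuron_spec`` maps class name -> count.  Returns ``(bundle, ledger)``;
    the bundle's single condition window covers the whole recording and is
    labeled with the preset name (or ``condition``).
    """
    from .core import NeuronRecord, RecordingBundle

    label = condition or config.name
    trace, bursts, ledger = generate_rhythm(config, n_cycles, seed)
    bundle = RecordingBundle(bundle_id=f"synthetic_{config.name}_{seed}")
    bundle.traces["population"] = trace
    bundle.condition_windows[label] = (0.0, trace.end_time)
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=1000)
    k = 0
    for cls in sorted(neuron_spec):
        for j in range(neuron_spec[cls]):
            nid = f"{cls}_{j}"
            spikes, truth = generate_neuron(
                config, cls, ledger.cycles, int(child[k]), neuron_id=nid
            )
            k += 1
            rec = NeuronRecord(neuron_id=nid, cls=cls)
            rec.spikes[label] = spikes
            bundle.neurons[nid] = rec
            ledger.neurons[nid] = truth
    return bundle, ledger
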