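"""Per-neuron inspiratory metrics.

Classification of pre-inspiratory (pre-I) activity, burst spiking, burst
shape, the pre-inspiratory ramp, burst-onset latencies and their jitter
(ln RMSSD).  Conventions:

* burst spike frequency per cycle = (count - 1)/(last - first spike) for
  cycles with >= 2 burst spikes; cycles with < 2 spikes contribute their
  count but are excluded from duration/frequency means;
* the ramp fit bins IBI spikes in fixed-width bins and fits rate vs
  bin-center time by ordinary least squares;
* jitter is computed on latencies in milliseconds — ln(RMSSD) values in the
  2–5 range are only dimensionally consistent with ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import NeuronRecord, SpikeTrain
from .cycles import CycleSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pre_i(
    spikes: SpikeTrain,
    cycleset: CycleSet,
    rate_threshold: float = 0.5,
    cycle_fraction: float = 0.5,
) -> bool:
    """True iff the neuron shows pre-inspiratory spiking.

    Rule: mean spike rate over the *second half* of the IBI is at least
    ``rate_threshold`` Hz in at least ``cycle_fraction`` of cycles.  The
    second half is used because ramping pre-I activity is strongest just
    before the next burst, which separates it robustly from ectopic isolated
    spikes early in the IBI.
    """
    if len(cycleset) < 10:
        raise ValueError("need >= 10 cycles to classify pre-I activity")
    hits = 0
    for c in cycleset:
        mid = c.ibi_start + c.ibi / 2.0
        n = len(spikes.restrict(mid, c.ibi_end))
        if n / (c.ibi / 2.0) >= rate_threshold:
            hits += 1
    return hits / len(cycleset) >= cycle_fraction


def classify_neuron(neuron: NeuronRecord, cycleset: CycleSet, condition: str) -> bool:
    return classify_pre_i(neuron.spikes[condition], cycleset)


# ---------------------------------------------------------------------------
# burst spiking
# ---------------------------------------------------------------------------

@dataclass
class BurstSpiking:
    """Per-cycle burst spike counts/durations/frequencies and their means."""

    spike_counts: np.ndarray
    durations: np.ndarray  # s, first-to-last spike; NaN where < 2 spikes
    frequencies: np.ndarray  # Hz; NaN where < 2 spikes
    mean_count: float
    mean_duration: float
    mean_frequency: float
    n_cycles: int
    n_excluded: int  # cycles with < 2 spikes


def burst_spiking(spikes: SpikeTrain, cycleset: CycleSet) -> BurstSpiking:
    counts, durs, freqs = [], [], []
    for c in cycleset:
        st = spikes.restrict(c.burst.onset, c.burst.offset).spike_times
        counts.append(st.size)
        if st.size >= 2:
            span = st[-1] - st[0]
            durs.append(span)
            freqs.append((st.size - 1) / span)
        else:
            durs.append(np.nan)
            freqs.append(np.nan)
    counts = np.array(counts, dtype=float)
    durs = np.array(durs)
    freqs = np.array(freqs)
    ok = np.isfinite(freqs)
    if not ok.any():
        raise ValueError("neuron never spikes (>=2) during bursts: not inspiratory")
    return BurstSpiking(
        spike_counts=counts,
        durations=durs,
        frequencies=freqs,
        mean_count=float(counts.mean()),
        mean_duration=float(np.nanmean(durs)),
        mean_frequency=float(np.nanmean(freqs)),
        n_cycles=len(cycleset),
        n_excluded=int((~ok).sum()),
    )


# ---------------------------------------------------------------------------
# burst shape
# ---------------------------------------------------------------------------

@dataclass
class ShapeProfile:
    bin_rates: np.ndarray  # Hz, one per bin over normalized burst time
    bin_counts: np.ndarray
    peak_position: float  # % of burst duration (center of argmax bin)
    n_bins: int
    n_cycles: int
    n_spikes: int


def shape_profile(spikes: SpikeTrain, cycleset: CycleSet, n_bins: int = 20) -> ShapeProfile:
    """Pooled, phase-normalized burst firing-rate profile.

    Spikes of each cycle are mapped to normalized burst time, pooled and
    binned; the rate per bin divides the pooled count by
    ``n_cycles * mean bin duration``.  Peak position is the center of the
    argmax bin as a percent of burst duration (ties -> earliest bin).
    """
    if len(cycleset) < 10:
        raise ValueError("need >= 10 cycles for a shape profile")
    pooled = []
    durations = []
    for c in cycleset:
        b = c.burst
        st = spikes.restrict(b.onset, b.offset).spike_times
        pooled.append((st - b.onset) / b.duration)
        durations.append(b.duration)
    u = np.concatenate(pooled)
    if u.size == 0:
        raise ValueError("empty shape profile: no burst spikes")
    counts, _ = np.histogram(u, bins=n_bins, range=(0.0, 1.0))
    bin_dur = float(np.mean(durations)) / n_bins
    rates = counts / (len(cycleset) * bin_dur)
    peak_bin = int(np.argmax(rates))  # argmax returns the earliest tie
    peak_position = (peak_bin + 0.5) / n_bins * 100.0
    return ShapeProfile(
        bin_rates=rates,
        bin_counts=counts,
        peak_position=float(peak_position),
        n_bins=n_bins,
        n_cycles=len(cycleset),
        n_spikes=int(counts.sum()),
    )


# ---------------------------------------------------------------------------
# pre-inspiratory ramp
# ---------------------------------------------------------------------------

@dataclass
class RampFit:
    """One cycle's pre-inspiratory ramp fit."""

    slope: float  # Hz/s
    intercept: float  # Hz
    r2: float
    ibi_mean_rate: float  # Hz, total IBI spikes / IBI
    ibi: float
    n_bins: int
    n_spikes: int


def ramp_fit(spikes: SpikeTrain, cycle, bin_width: float = 0.25):
    """OLS fit of IBI firing rate vs time for one cycle.

    Spikes in ``[ibi_start, ibi_end)`` are counted in consecutive
    ``bin_width`` bins (final partial bin dropped); rate = count/bin_width
    regressed on bin-center time.  Cycles whose IBI holds fewer than 4 bins
    are skipped (returns None).  A spikeless IBI yields slope 0, rate 0.
    """
    n_bins = int(np.floor(cycle.ibi / bin_width))
    if n_bins < 4:
        log.info("ramp_fit: cycle %s IBI %.3fs too short, skipped", cycle.index, cycle.ibi)
        return None
    st = spikes.restrict(cycle.ibi_start, cycle.ibi_end, shift=True).spike_times
    ibi_mean_rate = st.size / cycle.ibi
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(st, bins=edges)
    rates = counts / bin_width
    if counts.sum() == 0:
        return RampFit(0.0, 0.0, 0.0, 0.0, cycle.ibi, n_bins, 0)
    t = (edges[:-1] + edges[1:]) / 2.0
    res = sps.linregress(t, rates)
    return RampFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        ibi_mean_rate=float(ibi_mean_rate),
        ibi=float(cycle.ibi),
        n_bins=n_bins,
        n_spikes=int(st.size),
    )


def ramp_fits(spikes: SpikeTrain, cycleset: CycleSet, bin_width: float = 0.25):
    """Per-cycle ramp fits for every analyzable cycle of a cycle set."""
    fits = [ramp_fit(spikes, c, bin_width) for c in cycleset]
    return [f for f in fits if f is not None]


def slope_vs_ibi_regression(per_neuron_fits, cycles_per_neuron: int = 20):
    """Pooled regression of normalized IBI on normalized ramp slope.

    ``per_neuron_fits`` is a list (one entry per neuron) of per-cycle
    :class:`RampFit` lists.  For each neuron the first ``cycles_per_neuron``
    consecutive analyzable cycles are taken; each cycle's IBI is divided by
    that neuron's mean IBI and each slope by the neuron's mean slope, the
    normalized pairs are pooled, and normalized IBI is regressed on
    normalized slope by OLS.  Neurons whose mean slope is <= 0 are excluded.
    Returns ``(slope, intercept, r, p, n_points)``.
    """
    xs, ys = [], []
    for i, fits in enumerate(per_neuron_fits):
        if len(fits) < cycles_per_neuron:
            raise ValueError(
                f"neuron {i} has {len(fits)} analyzable cycles, "
                f"needs {cycles_per_neuron}"
            )
        sel = fits[:cycles_per_neuron]
        slopes = np.array([f.slope for f in sel])
        ibis = np.array([f.ibi for f in sel])
        if slopes.mean() <= 0:
            log.info("slope_vs_ibi_regression: neuron %d mean slope <= 0, excluded", i)
            continue
        xs.append(slopes / slopes.mean())
        ys.append(ibis / ibis.mean())
    if not xs:
        raise ValueError("no neurons with positive mean ramp slope")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.var(x) == 0:
        raise ValueError("slopes have zero variance: regression undefined")
    res = sps.linregress(x, y)
    return (
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.pvalue),
        x.size,
    )


# ---------------------------------------------------------------------------
# onset latencies and jitter
# ---------------------------------------------------------------------------

@dataclass
class OnsetSeries:
    latencies: np.ndarray  # s, relative to population burst onset
    rule: str
    n_skipped: int = 0
    jitter: float = field(default=np.nan)  # ln(RMSSD in ms), filled by onset_jitter


def onset_times(spikes: SpikeTrain, cycleset: CycleSet, rule: str) -> OnsetSeries:
    """Per-cycle burst-onset latency relative to the population burst onset.

    ``first_spike`` (non-pre-I and inhibitory neurons): the first spike at or
    after (population onset - 0.2 s).  ``max_rate_change`` (pre-I neurons):
    the instantaneous rate is the inverse interspike-interval series over
    [ibi_start, burst offset] of the *preceding* IBI plus the burst; the
    onset is the spike time at which the forward difference of that rate
    series is maximal.  Latencies may be negative.  Cycles with no usable
    spikes are skipped and counted.
    """
    if rule not in ("first_spike", "max_rate_change"):
        raise ValueError(f"unknown onset rule {rule!r}")
    latencies = []
    skipped = 0
    cycles = list(cycleset)
    for i, c in enumerate(cycles):
        b = c.burst
        if rule == "first_spike":
            st = spikes.restrict(b.onset - 0.2, b.offset).spike_times
            if st.size == 0:
                skipped += 1
                continue
            latencies.append(st[0] - b.onset)
        else:
            # search window: the IBI leading into this burst, plus the burst
            start = cycles[i - 1].ibi_start if i > 0 else b.onset - 5.0
            st = spikes.restrict(start, b.offset).spike_times
            if st.size < 4:
                skipped += 1
                continue
            isi = np.diff(st)
            rate = 1.0 / isi  # rate[j] belongs to time st[j+1]
            d = np.diff(rate)  # forward difference over one interspike interval
            j = int(np.argmax(d))
            latencies.append(st[j + 2] - b.onset)
    if skipped:
        log.info("onset_times: skipped %d cycles with no usable spikes", skipped)
    return OnsetSeries(latencies=np.array(latencies), rule=rule, n_skipped=skipped)


def onset_jitter(onsets: OnsetSeries) -> float:
    """ln(RMSSD) of the onset latencies, RMSSD in milliseconds.

    RMSSD = sqrt(mean of squared successive differences).  Adding a constant
    to all latencies leaves it unchanged; scaling by c adds ln(c).
    """
    lat_ms = np.asarray(onsets.latencies, dtype=float) * 1000.0
    if lat_ms.size < 3:
        raise ValueError("need >= 3 latencies for jitter")
    rmssd = float(np.sqrt(np.mean(np.diff(lat_ms) ** 2)))
    if rmssd == 0:
        raise ValueError("RMSSD is zero: ln undefined (report -inf explicitly if wanted)")
    onsets.jitter = float(np.log(rmssd))
    return onsets.jitter
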