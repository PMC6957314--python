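"""Burst and spike detection.

The population-burst detector works on the integrated population trace with
a robust running-median baseline and an MAD noise scale, so slow drift in
slice recordings does not move the threshold.  Spike detection on membrane
traces is a plain threshold-crossing detector with a dead time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BurstEvent, SpikeTrain, Trace

MAD_TO_SIGMA = 1.4826  # Gaussian consistency factor


@dataclass(frozen=True)
class BurstDetectParams:
    """Parameters of the population-burst detector.

    baseline_window : s, running-median window for the slow baseline
    threshold_k     : detection threshold in multiples of the noise scale
    min_duration    : s, runs shorter than this are discarded (after merging)
    merge_gap       : s, supra-threshold runs closer than this are merged, so
                      multi-peaked inspiratory bursts stay single events
    halfwidth_level : fraction of peak-above-baseline for the half-width
    """

    baseline_window: float = 30.0
    threshold_k: float = 3.0
    min_duration: float = 0.15
    merge_gap: float = 0.2
    halfwidth_level: float = 0.5
    baseline_stride: float = 1.0  # s between baseline evaluation points

    def __post_init__(self):
        for name in ("baseline_window", "threshold_k", "min_duration", "merge_gap", "baseline_stride"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.halfwidth_level < 1:
            raise ValueError("halfwidth_level must be in (0, 1)")


@dataclass(frozen=True)
class SpikeDetectParams:
    mode: str = "absolute_threshold"  # or "derivative"
    threshold: float = -20.0  # mV, or mV/ms in derivative mode
    dead_time: float = 0.002  # s

    def __post_init__(self):
        if self.mode not in ("absolute_threshold", "derivative"):
            raise ValueError(f"unknown spike-detection mode {self.mode!r}")
        if not self.dead_time > 0:
            raise ValueError("dead_time must be > 0")


def running_median(values: np.ndarray, window_samples: int, stride: int) -> np.ndarray:
    """Running median evaluated every ``stride`` samples, linearly interpolated.

    Centered windows, clipped at the edges.
    """
    n = values.size
    half = window_samples // 2
    centers = np.arange(0, n, max(stride, 1))
    if centers[-1] != n - 1:
        centers = np.append(centers, n - 1)
    meds = np.array(
        [np.median(values[max(c - half, 0) : min(c + half + 1, n)]) for c in centers]
    )
    return np.interp(np.arange(n), centers, meds)


def detect_population_bursts(trace: Trace, params: BurstDetectParams = BurstDetectParams()):
    """Detect population bursts on an integrated trace.

    Returns a sorted, non-overlapping list of :class:`BurstEvent`.  Onset and
    offset are the threshold crossings; the half-width is measured at
    ``halfwidth_level`` of the peak above baseline around the peak sample.
    """
    if trace.role != "population_integrated":
        raise ValueError("detect_population_bursts needs a population_integrated trace")
    fs = trace.sample_rate
    x = trace.values
    w = int(round(params.baseline_window * fs))
    if x.size < w:
        raise ValueError("trace shorter than baseline_window")
    baseline = running_median(x, w, int(round(params.baseline_stride * fs)))
    resid = x - baseline
    # Two-pass noise estimate.  Bursts deviate only upward and also pull the
    # running median above the noise floor, so (1) a one-sided MAD on the
    # below-median deviations gives a coarse scale, (2) the center and MAD
    # are re-estimated on the samples below 2 coarse scales (burst-free).
    med = np.median(resid)
    below = resid[resid <= med]
    coarse = MAD_TO_SIGMA * np.median(med - below)
    if coarse <= 0:
        raise ValueError(
            "flat trace: noise scale is zero; supply an explicit threshold instead"
        )
    quiet = resid[resid < med + 2.0 * coarse]
    center = np.median(quiet)
    noise = MAD_TO_SIGMA * np.median(np.abs(quiet - center))
    if noise <= 0:
        raise ValueError(
            "flat trace: noise scale is zero; supply an explicit threshold instead"
        )
    resid = resid - center
    thr = params.threshold_k * noise

    above = resid > thr
    raw_runs = _runs(above)
    merged = _merge_runs(raw_runs, int(round(params.merge_gap * fs)))
    # Discard merged events whose total supra-threshold content is shorter
    # than min_duration: brief noise excursions never accumulate enough
    # content, while a multi-peaked burst keeps its full extent.
    min_len = params.min_duration * fs
    runs = []
    for a, b in merged:
        content = sum(min(rb, b) - max(ra, a) for ra, rb in raw_runs if ra < b and rb > a)
        if content >= min_len:
            runs.append((a, b))

    events = []
    for a, b in runs:
        seg = resid[a:b]
        ipk = a + int(np.argmax(seg))
        peak = resid[ipk]
        onset = _cross_time(resid, a, thr, fs, side="up")
        offset = _cross_time(resid, b, thr, fs, side="down")
        half = params.halfwidth_level * peak
        # walk outwards from the peak to the half-level crossings
        lo = ipk
        while lo > 0 and resid[lo - 1] > half:
            lo -= 1
        hi = ipk
        while hi < x.size - 1 and resid[hi + 1] > half:
            hi += 1
        halfwidth = _cross_time(resid, hi + 1, half, fs, side="down") - _cross_time(
            resid, lo, half, fs, side="up"
        )
        halfwidth = min(halfwidth, offset - onset)
        peak_time = ipk / fs
        if not onset < peak_time <= offset:
            peak_time = (onset + offset) / 2.0
        events.append(
            BurstEvent(
                onset=trace.start_time + onset,
                offset=trace.start_time + offset,
                peak_time=trace.start_time + peak_time,
                peak_amplitude=float(peak),
                halfwidth=float(halfwidth),
                provenance="detected",
            )
        )
    return events


def _cross_time(resid: np.ndarray, idx: int, level: float, fs: float, side: str) -> float:
    """Sub-sample crossing time of ``level`` at a run boundary.

    ``idx`` is the first sample above the level (side="up") or the first
    sample at/below it after the run (side="down"); the crossing is linearly
    interpolated between ``idx - 1`` and ``idx``.
    """
    if idx <= 0:
        return 0.0
    if idx >= resid.size:
        return (resid.size - 1) / fs
    lo, hi = resid[idx - 1], resid[idx]
    if side == "up":
        frac = (level - lo) / (hi - lo) if hi != lo else 0.0
    else:
        frac = (lo - level) / (lo - hi) if hi != lo else 0.0
    return (idx - 1 + float(np.clip(frac, 0.0, 1.0))) / fs


def _runs(mask: np.ndarray):
    """Maximal True runs as half-open (start, stop) sample index pairs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def _merge_runs(runs, gap_samples: int):
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < gap_samples:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [tuple(r) for r in merged]


def detect_spikes(trace: Trace, params: SpikeDetectParams = SpikeDetectParams()) -> SpikeTrain:
    """Detect spikes on a membrane trace.

    The spike time is the first sample of each upward threshold crossing;
    further crossings within ``dead_time`` are ignored.
    """
    if trace.role != "membrane":
        raise ValueError("detect_spikes needs a membrane trace")
    fs = trace.sample_rate
    if params.mode == "derivative":
        sig = np.diff(trace.values) * fs / 1000.0  # mV/ms
        sig = np.append(sig, sig[-1])
    else:
        sig = trace.values
    if params.threshold <= sig.min():
        raise ValueError("threshold below trace minimum: everything would be a spike")
    above = sig > params.threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        crossings = np.insert(crossings, 0, 0)
    dead = params.dead_time * fs
    kept = []
    last = -np.inf
    for c in crossings:
        if c - last >= dead:
            kept.append(c)
            last = c
    times = trace.start_time + np.asarray(kept, dtype=float) / fs
    return SpikeTrain(trace.trace_id, times)


def population_burst_stats(bursts) -> dict:
    """Mean duration and half-width of a burst list, plus a per-burst table."""
    if not bursts:
        raise ValueError("no bursts to summarize")
    durations = np.array([b.duration for b in bursts])
    halfwidths = np.array([b.halfwidth for b in bursts])
    return {
        "n": len(bursts),
        "mean_duration": float(durations.mean()),
        "mean_halfwidth": float(halfwidths.mean()),
        "durations": durations,
        "halfwidths": halfwidths,
    }
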