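"""Domain types and recording-bundle I/O.

A *recording bundle* is a directory holding everything one slice experiment
produces: a ``manifest.json`` describing traces and condition windows, the
trace CSVs themselves, and per-neuron spike / stimulation-pulse / metadata
tables.  All times are seconds on a single monotone clock that starts at 0
at the beginning of the recording; every time interval in the package is
half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

TRACE_ROLES = ("population_integrated", "membrane")
NEURON_CLASSES = (
    "exc_preI",
    "exc_recruited",
    "exc_nonpreI",
    "inhibitory",
    "rostral_exc",
    "rostral_inh",
    "unknown",
)
RECORDING_MODES = ("whole_cell", "cell_attached")
BURST_PROVENANCE = ("detected", "simulated", "imported")


class BundleValidationError(ValueError):
    """Raised with every validation problem found, aggregated."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("bundle validation failed:\n" + "\n".join(self.problems))


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled signal.

    ``values`` are arbitrary units for the integrated population signal and
    mV for membrane traces.
    """

    trace_id: str
    role: str
    sample_rate: float  # samples/s
    values: np.ndarray
    start_time: float = 0.0

    def __post_init__(self):
        if self.role not in TRACE_ROLES:
            raise ValueError(f"unknown trace role {self.role!r}")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(vals)):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.sample_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.values.size / self.sample_rate

    def crop(self, start: float, end: float) -> "Trace":
        """Return the sub-trace with samples in ``[start, end)``, re-zeroed."""
        i0 = int(np.ceil((start - self.start_time) * self.sample_rate - 1e-9))
        i1 = int(np.ceil((end - self.start_time) * self.sample_rate - 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.values.size)
        if i1 - i0 < 2:
            raise ValueError(f"window [{start}, {end}) leaves <2 samples of {self.trace_id}")
        return replace(
            self,
            values=self.values[i0:i1],
            start_time=self.start_time + i0 / self.sample_rate - start,
        )


@dataclass(frozen=True)
class BurstEvent:
    """One detected (or simulated) population burst."""

    onset: float
    offset: float
    peak_time: float
    peak_amplitude: float  # signal units above baseline
    halfwidth: float
    provenance: str = "detected"

    def __post_init__(self):
        if not (self.onset < self.peak_time <= self.offset):
            raise ValueError("need onset < peak_time <= offset")
        if self.halfwidth > self.duration + 1e-12:
            raise ValueError("halfwidth cannot exceed duration")
        if self.provenance not in BURST_PROVENANCE:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class Cycle:
    """One burst plus the following inter-burst interval.

    The IBI runs from this burst's offset to the *next* burst's onset; the
    period is onset-to-onset.
    """

    index: int
    burst: BurstEvent
    ibi_end: float  # next burst onset
    condition: str = "baseline"

    def __post_init__(self):
        if self.ibi <= 0:
            raise ValueError("IBI must be positive")

    @property
    def ibi_start(self) -> float:
        return self.burst.offset

    @property
    def ibi(self) -> float:
        return self.ibi_end - self.ibi_start

    @property
    def period(self) -> float:
        return self.ibi_end - self.burst.onset


@dataclass(frozen=True)
class SpikeTrain:
    neuron_id: str
    spike_times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.spike_times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError(f"spike times of {self.neuron_id} not strictly increasing")
        object.__setattr__(self, "spike_times", t)

    def __len__(self):
        return self.spike_times.size

    def restrict(self, start: float, end: float, shift: bool = False) -> "SpikeTrain":
        """Spikes in ``[start, end)``; optionally re-zeroed at ``start``."""
        t = self.spike_times
        sel = t[(t >= start) & (t < end)]
        return SpikeTrain(self.neuron_id, sel - start if shift else sel)


@dataclass
class NeuronRecord:
    """A recorded neuron: class, mode, location, spikes per condition.

    ``cls`` comes from metadata (optogenetic identification) or from
    :func:`rhythmphase.metrics.classify_pre_i`; it is never silently
    overwritten — use :meth:`with_class`.
    """

    neuron_id: str
    cls: str = "unknown"
    recording_mode: str = "cell_attached"
    location: Optional[tuple] = None  # (x mm from midline, y mm from VII nerve)
    spikes: dict = field(default_factory=dict)  # condition -> SpikeTrain

    def __post_init__(self):
        if self.cls not in NEURON_CLASSES:
            raise ValueError(f"unknown neuron class {self.cls!r}")
        if self.recording_mode not in RECORDING_MODES:
            raise ValueError(f"unknown recording mode {self.recording_mode!r}")

    def with_class(self, cls: str) -> "NeuronRecord":
        if self.cls != "unknown" and self.cls != cls:
            raise ValueError(
                f"refusing to overwrite class {self.cls!r} of {self.neuron_id} with {cls!r}"
            )
        return NeuronRecord(self.neuron_id, cls, self.recording_mode, self.location, self.spikes)


@dataclass(frozen=True)
class StimPulse:
    pulse_time: float
    duration: float = 0.2

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("pulse duration must be > 0")


@dataclass
class RecordingBundle:
    """Everything one experiment produced, on a common clock."""

    bundle_id: str
    traces: dict = field(default_factory=dict)  # trace_id -> Trace
    neurons: dict = field(default_factory=dict)  # neuron_id -> NeuronRecord
    pulses: list = field(default_factory=list)  # [StimPulse]
    condition_windows: dict = field(default_factory=dict)  # label -> (start, end)

    def span(self) -> tuple:
        """(start, end) covered by the traces, or by events if trace-less."""
        if self.traces:
            return (
                min(t.start_time for t in self.traces.values()),
                max(t.end_time for t in self.traces.values()),
            )
        times = [p.pulse_time for p in self.pulses]
        for n in self.neurons.values():
            for st in n.spikes.values():
                if len(st):
                    times += [st.spike_times[0], st.spike_times[-1]]
        if not times:
            return (0.0, 0.0)
        return (min(times), max(times))

    def validate(self) -> None:
        problems = []
        windows = sorted(self.condition_windows.values())
        for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
            if s1 < e0:
                problems.append(f"condition windows overlap at {s1}")
        lo, hi = self.span()
        if self.traces:
            for nid, rec in self.neurons.items():
                for cond, st in rec.spikes.items():
                    t = st.spike_times
                    if t.size and (t[0] < lo - 1e-9 or t[-1] > hi + 1e-9):
                        problems.append(
                            f"neuron {nid} ({cond}) has spikes outside the trace span"
                        )
        if problems:
            raise BundleValidationError(problems)


# ---------------------------------------------------------------------------
# bundle reading / writing
#
# manifest.json + delimited-text tables (UTF-8, '.' decimal):
#   traces:      time_s,value (one file per trace)
#   spikes.csv:  neuron_id,condition,spike_time_s
#   neurons.csv: neuron_id,class,recording_mode,x_mm,y_mm
#   pulses.csv:  pulse_time_s,duration_s
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.9g"


def write_bundle(bundle: RecordingBundle, path) -> None:
    """Write ``bundle`` to directory ``path`` (deterministic byte output)."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "bundle_id": bundle.bundle_id,
        "traces": [],
        "condition_windows": [
            {"label": lab, "start_s": float(w[0]), "end_s": float(w[1])}
            for lab, w in sorted(bundle.condition_windows.items())
        ],
        "tables": {},
    }
    for tid in sorted(bundle.traces):
        tr = bundle.traces[tid]
        fname = f"trace_{tid}.csv"
        df = pd.DataFrame({"time_s": tr.times, "value": tr.values})
        df.to_csv(path / fname, index=False, float_format=_FLOAT_FMT)
        manifest["traces"].append(
            {
                "trace_id": tid,
                "role": tr.role,
                "file": fname,
                "sample_rate_hz": tr.sample_rate,
                "units": "a.u." if tr.role == "population_integrated" else "mV",
                "start_time_s": tr.start_time,
            }
        )
    if bundle.neurons:
        rows, srows = [], []
        for nid in sorted(bundle.neurons):
            rec = bundle.neurons[nid]
            x, y = rec.location if rec.location is not None else (np.nan, np.nan)
            rows.append((nid, rec.cls, rec.recording_mode, x, y))
            for cond in sorted(rec.spikes):
                for t in rec.spikes[cond].spike_times:
                    srows.append((nid, cond, t))
        pd.DataFrame(
            rows, columns=["neuron_id", "class", "recording_mode", "x_mm", "y_mm"]
        ).to_csv(path / "neurons.csv", index=False, float_format=_FLOAT_FMT)
        pd.DataFrame(srows, columns=["neuron_id", "condition", "spike_time_s"]).to_csv(
            path / "spikes.csv", index=False, float_format=_FLOAT_FMT
        )
        manifest["tables"]["neurons"] = "neurons.csv"
        manifest["tables"]["spikes"] = "spikes.csv"
    if bundle.pulses:
        pd.DataFrame(
            [(p.pulse_time, p.duration) for p in bundle.pulses],
            columns=["pulse_time_s", "duration_s"],
        ).to_csv(path / "pulses.csv", index=False, float_format=_FLOAT_FMT)
        manifest["tables"]["pulses"] = "pulses.csv"
    (path / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_bundle(path) -> RecordingBundle:
    """Read a bundle directory written by :func:`write_bundle`.

    Validation problems (missing files, non-monotonic spikes, out-of-span
    spikes) are aggregated and raised together.
    """
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise FileNotFoundError(f"missing manifest file: {mf}")
    manifest = json.loads(mf.read_text(encoding="utf-8"))
    problems = []
    bundle = RecordingBundle(bundle_id=manifest["bundle_id"])
    for w in manifest.get("condition_windows", []):
        bundle.condition_windows[w["label"]] = (w["start_s"], w["end_s"])
    for tr in manifest.get("traces", []):
        f = path / tr["file"]
        if not f.exists():
            problems.append(f"missing trace file: {tr['file']}")
            continue
        df = pd.read_csv(f)
        bundle.traces[tr["trace_id"]] = Trace(
            trace_id=tr["trace_id"],
            role=tr["role"],
            sample_rate=tr["sample_rate_hz"],
            values=df["value"].to_numpy(),
            start_time=tr.get("start_time_s", 0.0),
        )
    tables = manifest.get("tables", {})
    if "neurons" in tables:
        f = path / tables["neurons"]
        if not f.exists():
            problems.append(f"missing table file: {tables['neurons']}")
        else:
            ndf = pd.read_csv(f)
            sdf = None
            if "spikes" in tables:
                sf = path / tables["spikes"]
                if not sf.exists():
                    problems.append(f"missing table file: {tables['spikes']}")
                else:
                    sdf = pd.read_csv(sf)
            for _, row in ndf.iterrows():
                loc = None
                if np.isfinite(row.get("x_mm", np.nan)):
                    loc = (float(row["x_mm"]), float(row["y_mm"]))
                rec = NeuronRecord(
                    neuron_id=str(row["neuron_id"]),
                    cls=row["class"],
                    recording_mode=row["recording_mode"],
                    location=loc,
                )
                if sdf is not None:
                    grp = sdf[sdf["neuron_id"].astype(str) == rec.neuron_id]
                    for cond, g in grp.groupby("condition"):
                        times = g["spike_time_s"].to_numpy()
                        try:
                            rec.spikes[cond] = SpikeTrain(rec.neuron_id, times)
                        except ValueError as exc:
                            problems.append(str(exc))
                bundle.neurons[rec.neuron_id] = rec
    if "pulses" in tables:
        f = path / tables["pulses"]
        if not f.exists():
            problems.append(f"missing table file: {tables['pulses']}")
        else:
            pdf = pd.read_csv(f)
            bundle.pulses = [
                StimPulse(r.pulse_time_s, r.duration_s) for r in pdf.itertuples()
            ]
    if problems:
        raise BundleValidationError(problems)
    try:
        bundle.validate()
    except BundleValidationError:
        raise
    return bundle


def slice_by_condition(bundle: RecordingBundle, condition: str) -> RecordingBundle:
    """Restrict a bundle to one condition window (half-open ``[start, end)``).

    All times in the result are re-zeroed at the window start; events exactly
    on a boundary belong to the window that starts there.
    """
    if condition not in bundle.condition_windows:
        raise KeyError(f"unknown condition label {condition!r}")
    start, end = bundle.condition_windows[condition]
    out = RecordingBundle(bundle_id=f"{bundle.bundle_id}:{condition}")
    out.condition_windows = {condition: (0.0, end - start)}
    for tid, tr in bundle.traces.items():
        out.traces[tid] = tr.crop(start, end)
    for nid, rec in bundle.neurons.items():
        new = NeuronRecord(nid, rec.cls, rec.recording_mode, rec.location)
        for cond, st in rec.spikes.items():
            new.spikes[cond] = st.restrict(start, end, shift=True)
        out.neurons[nid] = new
    out.pulses = [
        StimPulse(p.pulse_time - start, p.duration)
        for p in bundle.pulses
        if start <= p.pulse_time < end
    ]
    return out
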