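"""Cycle segmentation, IBI statistics, and phase normalization.

A *cycle* is one population burst plus the inter-burst interval (IBI) that
follows it: the IBI runs from the burst's offset to the next burst's onset,
and the period is onset-to-onset.  Frequency is computed from periods, IBIs
from offset-to-onset; the two conventions are documented rather than mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Cycle, SpikeTrain

log = logging.getLogger(__name__)


@dataclass
class CycleSet:
    cycles: list  # consecutive Cycle objects
    condition: str = "baseline"

    def __post_init__(self):
        for a, b in zip(self.cycles, self.cycles[1:]):
            if abs(a.ibi_end - b.burst.onset) > 1e-9:
                raise ValueError("cycles are not consecutive")

    def __len__(self):
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    def ibis(self) -> np.ndarray:
        return np.array([c.ibi for c in self.cycles])

    def periods(self) -> np.ndarray:
        return np.array([c.period for c in self.cycles])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [c.index for c in self.cycles],
                "onset_s": [c.burst.onset for c in self.cycles],
                "offset_s": [c.burst.offset for c in self.cycles],
                "ibi_s": [c.ibi for c in self.cycles],
                "period_s": [c.period for c in self.cycles],
                "condition": self.condition,
            }
        )


@dataclass(frozen=True)
class IbiSummary:
    mean_ibi: float
    sd_ibi: float
    mean_period: float
    frequency: float  # Hz, = 1/mean_period
    n_cycles: int


def segment_cycles(bursts, span=None, condition: str = "baseline") -> CycleSet:
    """Build cycles from detected bursts within ``span`` (half-open).

    One cycle per burst except the last; bursts straddling the span edge are
    excluded.
    """
    if span is not None:
        lo, hi = span
        bursts = [b for b in bursts if b.onset >= lo and b.offset < hi]
    bursts = sorted(bursts, key=lambda b: b.onset)
    if len(bursts) < 2:
        raise ValueError("need at least 2 bursts to segment cycles")
    cycles = [
        Cycle(index=i, burst=b, ibi_end=nxt.onset, condition=condition)
        for i, (b, nxt) in enumerate(zip(bursts, bursts[1:]))
    ]
    return CycleSet(cycles, condition=condition)


def ibi_summary(cycleset: CycleSet) -> IbiSummary:
    """Sample mean/SD (n-1 denominator) of IBIs; frequency from mean period."""
    if len(cycleset) < 2:
        raise ValueError("need at least 2 cycles")
    ibis = cycleset.ibis()
    periods = cycleset.periods()
    return IbiSummary(
        mean_ibi=float(ibis.mean()),
        sd_ibi=float(ibis.std(ddof=1)),
        mean_period=float(periods.mean()),
        frequency=float(1.0 / periods.mean()),
        n_cycles=len(cycleset),
    )


def phase_normalize(spikes: SpikeTrain, cycle: Cycle):
    """Map spike times of one cycle onto normalized burst / IBI time.

    Burst spikes map to ``(t - onset)/duration`` in domain ``"burst"``; IBI
    spikes to ``(t - ibi_start)/ibi`` in domain ``"ibi"``.  Returns
    ``(pairs, n_dropped)`` where pairs is a list of ``(domain, u)`` with
    ``u`` in [0, 1); spikes outside both half-open windows are dropped and
    counted.
    """
    b = cycle.burst
    if b.duration <= 0:
        raise ValueError("zero-length burst")
    t = spikes.spike_times
    in_burst = (t >= b.onset) & (t < b.offset)
    in_ibi = (t >= cycle.ibi_start) & (t < cycle.ibi_end)
    pairs = [("burst", (ti - b.onset) / b.duration) for ti in t[in_burst]]
    pairs += [("ibi", (ti - cycle.ibi_start) / cycle.ibi) for ti in t[in_ibi]]
    considered = (t >= b.onset) & (t < cycle.ibi_end)
    n_dropped = int(considered.sum() - in_burst.sum() - in_ibi.sum())
    if n_dropped:
        log.info("phase_normalize: dropped %d spikes outside burst/IBI windows", n_dropped)
    return pairs, n_dropped
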