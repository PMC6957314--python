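import numpy as np
import pytest

from rhythmphase.core import BurstEvent, Cycle, RecordingBundle, SpikeTrain, Trace
from rhythmphase.cycles import CycleSet


def make_burst(onset, duration=1.0, halfwidth=None, peak_frac=0.3, amp=10.0):
    return BurstEvent(
        onset=onset,
        offset=onset + duration,
        peak_time=onset + peak_frac * duration,
        peak_amplitude=amp,
        halfwidth=halfwidth if halfwidth is not None else 0.6 * duration,
        provenance="simulated",
    )


def cycleset_from_ledger(ledger_cycles, condition="baseline"):
    """Build a CycleSet directly from generator ground truth (no detection)."""
    cycles = []
    for r in ledger_cycles.itertuples():
        b = BurstEvent(
            onset=r.onset,
            offset=r.offset,
            peak_time=(r.onset + r.offset) / 2,
            peak_amplitude=30.0,
            halfwidth=0.8 * (r.offset - r.onset),
            provenance="simulated",
        )
        cycles.append(Cycle(index=int(r.index), burst=b, ibi_end=r.next_onset, condition=condition))
    return CycleSet(cycles, condition=condition)


@pytest.fixture(scope="session")
def baseline_rhythm():
    """One 100-cycle baseline-preset simulation shared across tests."""
    from rhythmphase.synth import generate_rhythm, preset

    cfg = preset("baseline")
    trace, bursts, ledger = generate_rhythm(cfg, 100, seed=1)
    return cfg, trace, bursts, ledger


@pytest.fixture(scope="session")
def baseline_cycles(baseline_rhythm):
    _, _, _, ledger = baseline_rhythm
    return cycleset_from_ledger(ledger.cycles)


@pytest.fixture()
def tiny_bundle():
    """A small two-condition bundle with one trace, two neurons and pulses."""
    rng = np.random.default_rng(7)
    trace = Trace("pop", "population_integrated", 100.0, rng.normal(0, 1, 4000))
    bundle = RecordingBundle(bundle_id="tiny")
    bundle.traces["pop"] = trace
    bundle.condition_windows = {"baseline": (0.0, 20.0), "SP": (20.0, 40.0)}
    from rhythmphase.core import NeuronRecord, StimPulse

    n1 = NeuronRecord("n1", cls="exc_preI", recording_mode="whole_cell", location=(0.4, -1.2))
    n1.spikes["baseline"] = SpikeTrain("n1", [0.5, 1.0, 2.5, 19.99])
    n1.spikes["SP"] = SpikeTrain("n1", [21.0, 22.0])
    n2 = NeuronRecord("n2", cls="inhibitory")
    n2.spikes["baseline"] = SpikeTrain("n2", [3.0, 4.0, 5.0])
    bundle.neurons = {"n1": n1, "n2": n2}
    bundle.pulses = [StimPulse(6.0), StimPulse(26.0, 0.2)]
    return bundle
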