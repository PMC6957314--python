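"""The optogenetic refractory-period assay.

Light pulses delivered at random phases of the cycle either evoke a
population burst or fail; binning the evoked outcomes by elapsed time since
the preceding spontaneous burst onset yields an evoked-probability curve
that rises out of the refractory phase.  The curve is fit with a sigmoid and
the refractory period is read off as the time at which the fitted
probability reaches a criterion fraction of its plateau.  The comparison
between curves (e.g. baseline vs substance P) is an extra-sum-of-squares
F test between shared and separate sigmoid fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats as sps

from .core import StimPulse
from .cycles import CycleSet


@dataclass
class StimTrial:
    pulse: StimPulse
    elapsed: Optional[float]  # s since onset of preceding spontaneous burst
    evoked: bool
    excluded: bool
    reason: str = ""
    evoked_burst_index: Optional[int] = None


@dataclass
class ProbabilityCurve:
    bin_edges: np.ndarray  # s
    probabilities: np.ndarray  # one per non-empty bin, in [0, 1]
    counts: np.ndarray  # trials (or cycles) per bin
    kind: str  # "evoked" | "spontaneous"

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def points(self):
        """(t, p, n) for non-empty bins; evoked curves use bin centers,
        spontaneous CDFs the bin upper edges."""
        t = self.bin_centers if self.kind == "evoked" else self.bin_edges[1:]
        keep = self.counts > 0
        return t[keep], self.probabilities[keep], self.counts[keep]


@dataclass
class SigmoidFit:
    t50: float  # s
    steepness: float  # s
    plateau: float  # probability
    rss: float
    n_points: int


def assemble_trials(pulses, bursts, response_window: float = 0.3):
    """Pair light pulses with their outcomes.

    A trial is excluded if the pulse onset falls within [onset, offset] of
    any burst (stimulating into an ongoing burst) or if no burst precedes
    it.  ``elapsed`` is measured from the *onset* of the most recent
    preceding burst.  The trial is evoked if a burst onset occurs in
    (pulse onset, pulse onset + pulse duration + response_window]; evoked
    bursts are flagged so they can be removed from the spontaneous-cycle
    population.
    """
    bursts = sorted(bursts, key=lambda b: b.onset)
    onsets = np.array([b.onset for b in bursts])
    offsets = np.array([b.offset for b in bursts])
    trials = []
    for p in pulses:
        t = p.pulse_time
        during = np.any((onsets <= t) & (t <= offsets))
        if during:
            trials.append(StimTrial(p, None, False, True, "pulse_during_burst"))
            continue
        prev = np.searchsorted(onsets, t) - 1
        if prev < 0:
            trials.append(StimTrial(p, None, False, True, "no_preceding_burst"))
            continue
        elapsed = t - onsets[prev]
        lo, hi = t, t + p.duration + response_window
        hit = np.flatnonzero((onsets > lo) & (onsets <= hi))
        if hit.size:
            trials.append(StimTrial(p, elapsed, True, False, evoked_burst_index=int(hit[0])))
        else:
            trials.append(StimTrial(p, elapsed, False, False))
    return trials


def evoked_probability(trials, bin_width: float = 0.5) -> ProbabilityCurve:
    """Fraction of included trials that evoked a burst, per elapsed-time bin.

    Empty bins carry no point (count 0), not probability zero.
    """
    included = [t for t in trials if not t.excluded]
    if not included:
        raise ValueError("all trials excluded")
    elapsed = np.array([t.elapsed for t in included])
    evoked = np.array([t.evoked for t in included])
    n_bins = int(np.ceil(elapsed.max() / bin_width)) or 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.searchsorted(edges, elapsed, side="right") - 1  # [edge_i, edge_i+1)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    hits = np.bincount(idx, weights=evoked.astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        probs = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    return ProbabilityCurve(edges, probs, counts, kind="evoked")


def spontaneous_cdf(cycleset: CycleSet, bin_edges) -> ProbabilityCurve:
    """Empirical CDF of spontaneous IBIs evaluated at the bin upper edges."""
    if len(cycleset) < 10:
        raise ValueError("need >= 10 cycles for a spontaneous CDF")
    ibis = np.sort(cycleset.ibis())
    edges = np.asarray(bin_edges, dtype=float)
    uppers = edges[1:]
    probs = np.searchsorted(ibis, uppers, side="right") / ibis.size
    counts = np.full(uppers.size, ibis.size)
    return ProbabilityCurve(edges, probs, counts, kind="spontaneous")


def _sigmoid(t, plateau, t50, steepness):
    return plateau / (1.0 + np.exp(-(t - t50) / steepness))


def fit_sigmoid(curve: ProbabilityCurve) -> SigmoidFit:
    """Weighted bounded least-squares sigmoid fit of a probability curve.

    P(t) = plateau / (1 + exp(-(t - t50)/steepness)), plateau in (0, 1],
    weights = per-point trial counts.  Deterministic initialization:
    plateau = max P, t50 = first time at half-max, steepness = 0.25 s.
    """
    t, p, n = curve.points()
    if t.size < 5:
        raise ValueError("need >= 5 points to fit a sigmoid")
    w = np.sqrt(n.astype(float))
    plateau0 = max(float(p.max()), 1e-3)
    above = np.flatnonzero(p >= plateau0 / 2.0)
    t50_0 = float(t[above[0]]) if above.size else float(t[t.size // 2])
    x0 = np.array([plateau0, t50_0, 0.25])
    lo = [1e-3, t[0] - (t[-1] - t[0]), 1e-3]
    hi = [1.0, t[-1] + (t[-1] - t[0]), 10.0]
    x0 = np.clip(x0, lo, hi)

    def resid(params):
        return w * (_sigmoid(t, *params) - p)

    res = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf", max_nfev=50000)
    if not res.success:
        raise RuntimeError(
            f"sigmoid fit failed to converge (init {x0.tolist()}, points {list(zip(t, p))})"
        )
    # short polishing pass for full precision on well-conditioned data
    res = optimize.least_squares(
        resid, res.x, bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
    )
    plateau, t50, steepness = res.x
    return SigmoidFit(
        t50=float(t50),
        steepness=float(steepness),
        plateau=float(plateau),
        rss=float(np.sum(res.fun**2)),
        n_points=int(t.size),
    )


def refractory_period(fit: SigmoidFit, criterion: float = 0.9) -> float:
    """Smallest t with P(t) >= criterion * plateau (closed form).

    t = t50 + steepness * ln(criterion / (1 - criterion)).
    """
    if not 0 < criterion < 1:
        raise ValueError("criterion must be in (0, 1)")
    if fit.plateau <= 0:
        raise ValueError("non-positive plateau: refractory period undefined")
    return float(fit.t50 + fit.steepness * np.log(criterion / (1.0 - criterion)))


def compare_curves(curve_a: ProbabilityCurve, curve_b: ProbabilityCurve):
    """Extra-sum-of-squares F test between two probability curves.

    Null model: one sigmoid shared by both curves (3 parameters); alternative:
    separate sigmoids (6 parameters).  Returns ``(F, p, fit_a, fit_b)``.
    """
    fit_a = fit_sigmoid(curve_a)
    fit_b = fit_sigmoid(curve_b)
    ta, pa, na = curve_a.points()
    tb, pb, nb = curve_b.points()
    n_total = ta.size + tb.size
    if n_total <= 6:
        raise ValueError("not enough points for separate fits")

    t = np.concatenate([ta, tb])
    p = np.concatenate([pa, pb])
    w = np.sqrt(np.concatenate([na, nb]).astype(float))
    plateau0 = max(float(p.max()), 1e-3)
    above = np.flatnonzero(p >= plateau0 / 2.0)
    x0 = np.array([plateau0, float(t[above[0]]) if above.size else float(np.median(t)), 0.25])
    lo = [1e-3, t.min() - np.ptp(t), 1e-3]
    hi = [1.0, t.max() + np.ptp(t), 10.0]
    x0 = np.clip(x0, lo, hi)
    shared_resid = lambda q: w * (_sigmoid(t, *q) - p)  # noqa: E731
    res = optimize.least_squares(
        shared_resid, x0, bounds=(lo, hi), method="trf", max_nfev=50000
    )
    res = optimize.least_squares(
        shared_resid, res.x, bounds=(lo, hi), method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
    )
    ss_shared = float(np.sum(res.fun**2))
    ss_sep = fit_a.rss + fit_b.rss
    df_shared = n_total - 3
    df_sep = n_total - 6
    if ss_shared < 1e-12 and ss_sep < 1e-12:
        # both models fit essentially perfectly: no evidence of a difference
        return 0.0, 1.0, fit_a, fit_b
    num = max(ss_shared - ss_sep, 0.0) / (df_shared - df_sep)
    den = ss_sep / df_sep
    if den == 0:
        f_stat = np.inf if num > 0 else 0.0
    else:
        f_stat = num / den
    p_value = float(sps.f.sf(f_stat, df_shared - df_sep, df_sep)) if np.isfinite(f_stat) else 0.0
    return float(f_stat), p_value, fit_a, fit_b
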