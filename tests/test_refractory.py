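import numpy as np
import pytest

from conftest import make_burst
from rhythmphase.core import StimPulse
from rhythmphase.cycles import segment_cycles
from rhythmphase.refractory import (
    ProbabilityCurve,
    assemble_trials,
    compare_curves,
    evoked_probability,
    fit_sigmoid,
    refractory_period,
    spontaneous_cdf,
)


class TestAssembleTrials:
    def test_pulse_during_burst_excluded(self):
        bursts = [make_burst(0.0), make_burst(10.0)]
        trials = assemble_trials([StimPulse(10.5)], bursts)
        assert trials[0].excluded and trials[0].reason == "pulse_during_burst"

    def test_pulse_before_first_burst_excluded(self):
        trials = assemble_trials([StimPulse(1.0)], [make_burst(5.0)])
        assert trials[0].excluded and trials[0].reason == "no_preceding_burst"

    def test_evoked_within_window(self):
        bursts = [make_burst(0.0), make_burst(5.15)]
        trials = assemble_trials([StimPulse(5.0)], bursts)
        t = trials[0]
        assert not t.excluded
        assert t.elapsed == pytest.approx(5.0)
        assert t.evoked and t.evoked_burst_index == 1

    def test_burst_outside_window_not_evoked(self):
        bursts = [make_burst(0.0), make_burst(5.6)]  # 0.6 > 0.2 + 0.3
        trials = assemble_trials([StimPulse(5.0)], bursts)
        assert not trials[0].evoked

    def test_hard_refractory_gating_on_generator(self):
        from rhythmphase.synth import generate_stim_experiment, preset

        cfg = preset("baseline")
        pulses, bursts, ledger = generate_stim_experiment(cfg, 60, seed=2)
        trials = assemble_trials(pulses, bursts)
        for t in trials:
            if not t.excluded and t.elapsed < cfg.refractory_T:
                assert not t.evoked

    def test_elapsed_round_trip_exact(self):
        from rhythmphase.synth import generate_stim_experiment, preset

        cfg = preset("baseline")
        pulses, bursts, ledger = generate_stim_experiment(cfg, 60, seed=3)
        trials = assemble_trials(pulses, bursts)
        included = [t for t in trials if not t.excluded]
        truth = ledger.trials[~ledger.trials.excluded]
        assert len(included) == len(truth)
        np.testing.assert_allclose(
            [t.elapsed for t in included], truth.elapsed.to_numpy(), atol=1e-12
        )
        assert [t.evoked for t in included] == truth.observed.tolist()


class TestEvokedProbability:
    def _trials(self, elapsed, evoked):
        bursts = [make_burst(0.0, 0.5)]
        out = []
        for e, ev in zip(elapsed, evoked):
            ts = assemble_trials([StimPulse(e)], bursts)
            t = ts[0]
            t.evoked = ev
            out.append(t)
        return out

    def test_fraction(self):
        trials = self._trials([1.1, 1.2, 1.3, 1.4, 1.45], [1, 1, 1, 1, 0])
        curve = evoked_probability(trials)
        t, p, n = curve.points()
        assert p[0] == pytest.approx(0.8)
        assert n[0] == 5

    def test_all_evoked_flat_one(self):
        trials = self._trials([0.7, 1.2, 1.7, 2.2], [1, 1, 1, 1])
        curve = evoked_probability(trials)
        _, p, _ = curve.points()
        np.testing.assert_allclose(p, 1.0)

    def test_counts_sum_to_included(self):
        trials = self._trials(np.linspace(0.6, 6.0, 37), np.ones(37))
        curve = evoked_probability(trials)
        assert curve.counts.sum() == 37

    def test_all_excluded_errors(self):
        trials = assemble_trials([StimPulse(0.2)], [make_burst(0.0, 0.5)])
        with pytest.raises(ValueError):
            evoked_probability(trials)

    def test_binned_curve_within_binomial_bounds(self):
        rng = np.random.default_rng(6)
        t50, k = 1.5, 0.3
        elapsed = rng.uniform(0.25, 5.75, 2000)
        ptrue = 1.0 / (1.0 + np.exp(-(elapsed - t50) / k))
        trials = self._trials(elapsed, rng.uniform(size=2000) < ptrue)
        curve = evoked_probability(trials)
        t, p, n = curve.points()
        pt = 1.0 / (1.0 + np.exp(-(t - t50) / k))
        margin = 1.96 * np.sqrt(pt * (1 - pt) / n) + 0.03  # binomial + bin-averaging
        assert np.all(np.abs(p - pt) <= margin)


class TestSpontaneousCdf:
    def _cs(self, ibis):
        onsets = np.concatenate([[0.0], np.cumsum(np.asarray(ibis) + 1.0)])
        return segment_cycles([make_burst(o) for o in onsets])

    def test_hand_values(self):
        cs = self._cs([2, 4] * 5)
        curve = spontaneous_cdf(cs, [0.0, 3.0, 10.0])
        assert curve.probabilities[0] == pytest.approx(0.5)
        assert curve.probabilities[1] == pytest.approx(1.0)

    def test_matches_sort_and_count_oracle_exactly(self):
        rng = np.random.default_rng(13)
        ibis = 2.0 + rng.exponential(2.0, 60)
        cs = self._cs(ibis)
        edges = np.arange(0.0, 16.0, 0.5)
        curve = spontaneous_cdf(cs, edges)
        got_ibis = cs.ibis()
        oracle = np.array([np.sum(np.sort(got_ibis) <= e) / got_ibis.size for e in edges[1:]])
        np.testing.assert_array_equal(curve.probabilities, oracle)
        assert np.all(np.diff(curve.probabilities) >= 0)
        assert curve.probabilities[-1] == 1.0


class TestSigmoidFit:
    @staticmethod
    def exact_curve(plateau=1.0, t50=2.0, k=0.3, edges=np.arange(0.0, 6.5, 0.5)):
        centers = (edges[:-1] + edges[1:]) / 2
        p = plateau / (1.0 + np.exp(-(centers - t50) / k))
        return ProbabilityCurve(edges, p, np.full(centers.size, 50), "evoked")

    def test_noiseless_recovery(self):
        fit = fit_sigmoid(self.exact_curve())
        assert fit.plateau == pytest.approx(1.0, abs=1e-6)
        assert fit.t50 == pytest.approx(2.0, abs=1e-6)
        assert fit.steepness == pytest.approx(0.3, abs=1e-6)
        assert fit.rss < 1e-10

    def test_flat_curve_documented_behavior(self):
        edges = np.arange(0.0, 6.5, 0.5)
        curve = ProbabilityCurve(
            edges, np.ones(edges.size - 1), np.full(edges.size - 1, 20), "evoked"
        )
        fit = fit_sigmoid(curve)  # t50 unidentifiable: pinned at/below first bin
        assert fit.t50 <= edges[1]

    def test_binomial_noise_t50_within_02(self):
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(20):
            curve = self.exact_curve()
            noisy = ProbabilityCurve(
                curve.bin_edges,
                rng.binomial(50, np.clip(curve.probabilities, 0, 1)) / 50.0,
                curve.counts,
                "evoked",
            )
            errs.append(abs(fit_sigmoid(noisy).t50 - 2.0))
        assert np.max(errs) <= 0.2

    def test_too_few_points(self):
        edges = np.array([0.0, 0.5, 1.0, 1.5])
        curve = ProbabilityCurve(edges, np.array([0.1, 0.5, 0.9]), np.full(3, 10), "evoked")
        with pytest.raises(ValueError):
            fit_sigmoid(curve)


class TestRefractoryPeriod:
    def test_closed_form(self):
        from rhythmphase.refractory import SigmoidFit

        fit = SigmoidFit(t50=1.5, steepness=0.25, plateau=1.0, rss=0.0, n_points=10)
        assert refractory_period(fit, 0.9) == pytest.approx(1.5 + 0.25 * np.log(9.0))

    def test_step_limit(self):
        from rhythmphase.refractory import SigmoidFit

        fit = SigmoidFit(t50=2.0, steepness=1e-6, plateau=1.0, rss=0.0, n_points=10)
        assert refractory_period(fit, 0.9) == pytest.approx(2.0, abs=1e-4)

    def test_monotone_in_hard_refractory(self):
        from dataclasses import replace

        from rhythmphase.refractory import assemble_trials as at
        from rhythmphase.synth import StimProtocol, generate_stim_experiment, preset

        cfg0 = preset("baseline")
        rps = []
        for t_r in (1.0, 2.0, 3.0):
            stim = replace(cfg0.stim, sigmoid_t50=t_r - 0.25 * np.log(9.0))
            cfg = replace(cfg0, refractory_T=t_r, stim=stim)
            estimates = []
            for seed in range(1, 4):
                pulses, bursts, _ = generate_stim_experiment(cfg, 60, seed)
                fit = fit_sigmoid(evoked_probability(at(pulses, bursts)))
                estimates.append(refractory_period(fit))
            rps.append(np.mean(estimates))
        assert rps[0] < rps[1] < rps[2]


class TestCompareCurves:
    def test_identical_curves(self):
        curve = TestSigmoidFit.exact_curve()
        f, p, _, _ = compare_curves(curve, curve)
        assert f == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_power_on_shifted_t50(self):
        rng = np.random.default_rng(5)
        edges = np.arange(0.0, 6.5, 0.5)
        centers = (edges[:-1] + edges[1:]) / 2
        rejected = 0
        for _ in range(20):
            pa = 1 / (1 + np.exp(-(centers - 1.5) / 0.25))
            pb = 1 / (1 + np.exp(-(centers - 3.0) / 0.25))
            ca = ProbabilityCurve(edges, rng.binomial(50, pa) / 50, np.full(12, 50), "evoked")
            cb = ProbabilityCurve(edges, rng.binomial(50, pb) / 50, np.full(12, 50), "evoked")
            _, p, _, _ = compare_curves(ca, cb)
            rejected += p < 0.01
        assert rejected == 20
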