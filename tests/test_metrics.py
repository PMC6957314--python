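import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import cycleset_from_ledger, make_burst
from rhythmphase.core import SpikeTrain
from rhythmphase.cycles import segment_cycles
from rhythmphase.metrics import (
    OnsetSeries,
    burst_spiking,
    classify_pre_i,
    onset_jitter,
    onset_times,
    ramp_fit,
    ramp_fits,
    shape_profile,
    slope_vs_ibi_regression,
)
from rhythmphase.synth import generate_neuron, generate_rhythm, preset


def regular_cycleset(n=20, period=5.0, duration=1.0):
    return segment_cycles([make_burst(i * period, duration) for i in range(n + 1)])


class TestClassifyPreI:
    def test_silent_ibi_false(self):
        cs = regular_cycleset()
        # spikes only inside bursts
        times = np.concatenate([[c.burst.onset + 0.3, c.burst.onset + 0.5] for c in cs])
        assert classify_pre_i(SpikeTrain("n", np.sort(times)), cs) is False

    def test_tonic_ibi_true(self):
        cs = regular_cycleset()
        times = np.concatenate([np.arange(c.ibi_start + 0.1, c.ibi_end, 0.4) for c in cs])
        assert classify_pre_i(SpikeTrain("n", np.sort(times)), cs) is True

    def test_too_few_cycles(self):
        cs = regular_cycleset(n=5)
        with pytest.raises(ValueError):
            classify_pre_i(SpikeTrain("n", [0.5]), cs)

    def test_generator_label_agreement(self):
        cfg = preset("baseline")
        _, _, ledger = generate_rhythm(cfg, 50, seed=5)
        cs = cycleset_from_ledger(ledger.cycles)
        agree = 0
        n = 0
        for j in range(20):
            for cls, expect in (("exc_preI", True), ("inhibitory", False)):
                spikes, _ = generate_neuron(cfg, cls, ledger.cycles, 900 + j)
                agree += classify_pre_i(spikes, cs) == expect
                n += 1
        assert agree / n >= 0.95


class TestBurstSpiking:
    def test_hand_frequency(self):
        cs = regular_cycleset(n=1)
        times = np.linspace(0.2, 0.7, 11)  # 11 spikes spanning 0.5 s
        bs = burst_spiking(SpikeTrain("n", times), cs)
        assert bs.frequencies[0] == pytest.approx(20.0)

    def test_single_spike_cycle_excluded(self):
        cs = regular_cycleset(n=2)
        times = [0.5, 5.2, 5.4, 5.6]  # 1 spike in cycle 0, 3 in cycle 1
        bs = burst_spiking(SpikeTrain("n", times), cs)
        assert bs.n_excluded == 1
        assert bs.spike_counts[0] == 1
        assert np.isnan(bs.frequencies[0])
        assert np.isfinite(bs.frequencies[1])

    def test_never_spiking_errors(self):
        cs = regular_cycleset(n=2)
        with pytest.raises(ValueError, match="inspiratory"):
            burst_spiking(SpikeTrain("n", [2.0, 3.0]), cs)  # IBI only

    def test_uniform_template_recovered_within_3_sem(self):
        # Uniform 30 Hz rate over each 1 s burst.  The spec estimator
        # (count-1)/(last-first) has a known edge bias for uniform spikes:
        # given N >= 3 points on [0, L], span/L ~ Beta(N-1, 2), so
        # E[(N-1)/span] = (N-1)/L * N/(N-2).  The oracle expectation
        # averages this over the Poisson count distribution.
        from scipy import stats as sps

        rate, L = 30.0, 1.0
        ns = np.arange(3, 80)
        pmf = sps.poisson.pmf(ns, rate * L)
        expected = np.sum(pmf * (ns - 1) * ns / (ns - 2) / L) / pmf.sum()
        rng = np.random.default_rng(8)
        cs = regular_cycleset(n=100)
        times = []
        for c in cs:
            n = rng.poisson(rate * c.burst.duration)
            times.append(np.sort(rng.uniform(c.burst.onset, c.burst.offset, n)))
        bs = burst_spiking(SpikeTrain("n", np.sort(np.concatenate(times))), cs)
        freqs = bs.frequencies[np.isfinite(bs.frequencies)]
        sem = freqs.std(ddof=1) / np.sqrt(freqs.size)
        assert abs(bs.mean_frequency - expected) <= 3 * sem


class TestShapeProfile:
    def test_single_bin(self):
        cs = regular_cycleset(n=10)
        # all spikes at 0.21-0.24 of the burst -> bin 4 of 20, center 22.5%
        times = np.sort(
            np.concatenate([c.burst.onset + np.linspace(0.21, 0.24, 5) for c in cs])
        )
        prof = shape_profile(SpikeTrain("n", times), cs)
        assert prof.peak_position == pytest.approx(22.5)

    def test_pooled_count_conservation(self):
        rng = np.random.default_rng(1)
        cs = regular_cycleset(n=20)
        times = np.sort(
            np.concatenate(
                [rng.uniform(c.burst.onset, c.burst.offset, 10) for c in cs]
            )
        )
        prof = shape_profile(SpikeTrain("n", times), cs)
        assert prof.bin_counts.sum() == 20 * 10

    def test_triangular_template_peak_recovered(self):
        rng = np.random.default_rng(2)
        cs = regular_cycleset(n=100)
        times = []
        for c in cs:
            n = rng.poisson(40)
            u = sps_triangular(rng, n)  # symmetric triangle peaking at 0.5
            times.append(c.burst.onset + u * c.burst.duration)
        prof = shape_profile(SpikeTrain("n", np.sort(np.concatenate(times))), cs)
        assert prof.peak_position in (47.5, 52.5)

    def test_decrementing_template_within_one_bin(self):
        cfg = preset("baseline")
        _, _, ledger = generate_rhythm(cfg, 100, seed=3)
        cs = cycleset_from_ledger(ledger.cycles)
        spikes, _ = generate_neuron(cfg, "inhibitory", ledger.cycles, 77)
        prof = shape_profile(spikes, cs)
        assert abs(prof.peak_position - 24.0) <= 5.0  # one bin width


def sps_triangular(rng, n):
    return rng.triangular(0.0, 0.5, 1.0, n)


class TestRampFit:
    def test_zero_spikes(self):
        cs = regular_cycleset(n=1)
        fit = ramp_fit(SpikeTrain("n", []), cs.cycles[0])
        assert fit.slope == 0.0 and fit.ibi_mean_rate == 0.0

    def test_hand_ols(self):
        # counts {0,1,2,3} in 0.25 s bins -> rates {0,4,8,12} Hz -> slope 16 Hz/s
        cs = regular_cycleset(n=1, period=2.0, duration=1.0)  # IBI = 1 s, 4 bins
        times = [1.3, 1.55, 1.6, 1.8, 1.85, 1.9]
        fit = ramp_fit(SpikeTrain("n", times), cs.cycles[0])
        assert fit.slope == pytest.approx(16.0)
        assert fit.n_bins == 4

    def test_short_ibi_skipped(self):
        cs = regular_cycleset(n=1, period=1.5, duration=1.0)  # IBI 0.5 s < 4 bins
        assert ramp_fit(SpikeTrain("n", [1.1]), cs.cycles[0]) is None

    @pytest.mark.parametrize("true_slope", [0.0, 3.0])
    def test_poisson_ramp_unbiased(self, true_slope):
        rng = np.random.default_rng(int(10 + true_slope))
        cs = regular_cycleset(n=200, period=5.0, duration=1.0)
        slopes = []
        for c in cs:
            L = c.ibi
            tt = np.linspace(0, L, 400)
            rate = 2.0 + true_slope * tt
            n = rng.poisson(np.trapezoid(rate, tt))
            cdf = np.cumsum(rate) / rate.sum()
            u = np.interp(rng.uniform(0, 1, n), cdf, tt)
            fit = ramp_fit(SpikeTrain("n", np.sort(c.ibi_start + u)), c)
            slopes.append(fit.slope)
        slopes = np.asarray(slopes)
        sem = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - true_slope) <= 3 * sem


class TestSlopeVsIbi:
    def test_inverse_law_detected(self):
        cfg = preset("baseline")
        _, _, ledger = generate_rhythm(cfg, 30, seed=9)
        cs = cycleset_from_ledger(ledger.cycles)
        per = []
        for j in range(9):
            spikes, _ = generate_neuron(cfg, "exc_preI", ledger.cycles, 300 + j)
            per.append(ramp_fits(spikes, cs))
        slope, _, r, p, n = slope_vs_ibi_regression(per)
        assert slope < 0 and r < 0
        assert p < 0.01
        assert n == 9 * 20

    def test_constant_slopes_degenerate(self):
        from rhythmphase.metrics import RampFit

        fits = [RampFit(2.0, 0.0, 1.0, 5.0, 4.0, 16, 20) for _ in range(20)]
        with pytest.raises(ValueError, match="variance"):
            slope_vs_ibi_regression([fits])

    def test_shuffled_pairs_null(self):
        from rhythmphase.metrics import RampFit

        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(10):
            per = []
            for _ in range(9):
                s = rng.lognormal(0.5, 0.4, 20)
                ibi = 2.0 + 1.0 / rng.permutation(s)  # slope paired with wrong ibi
                per.append(
                    [RampFit(si, 0.0, 1.0, 5.0, ib, 16, 20) for si, ib in zip(s, ibi)]
                )
            _, _, r, p, _ = slope_vs_ibi_regression(per)
            pvals.append(p)
        assert np.mean(np.asarray(pvals) > 0.05) >= 0.7


class TestOnsets:
    def test_exact_onset_zero_latency(self):
        cs = regular_cycleset(n=5)
        times = np.sort([c.burst.onset for c in cs] + [c.burst.onset + 0.3 for c in cs])
        series = onset_times(SpikeTrain("n", times), cs, "first_spike")
        np.testing.assert_allclose(series.latencies, 0.0, atol=1e-12)

    def test_rate_jump_located(self):
        # pre-I style: 5 Hz through the IBI, 40 Hz from onset+30 ms
        cs = regular_cycleset(n=3, period=6.0, duration=1.0)
        times = []
        for c in cs:
            times.append(np.arange(c.ibi_start + 0.1, c.ibi_end, 0.2))  # 5 Hz
            times.append(np.arange(c.burst.onset + 0.03, c.burst.offset, 0.025))  # 40 Hz
        series = onset_times(
            SpikeTrain("n", np.sort(np.concatenate(times))), cs, "max_rate_change"
        )
        # the first cycle has no preceding ramp in this fixture: skip it
        np.testing.assert_allclose(series.latencies[1:], 0.03, atol=0.026)

    def test_injected_jitter_recovered(self):
        rng = np.random.default_rng(17)
        cs = regular_cycleset(n=100)
        shifts = rng.normal(0.0, 0.020, len(cs))
        times = np.sort([c.burst.onset + s for c, s in zip(cs, shifts)])
        series = onset_times(SpikeTrain("n", times), cs, "first_spike")
        sd = series.latencies.std(ddof=1)
        sem = sd / np.sqrt(2 * (series.latencies.size - 1))
        assert abs(sd - 0.020) <= 3 * sem

    def test_cycles_without_spikes_skipped(self):
        cs = regular_cycleset(n=5)
        times = [cs.cycles[0].burst.onset + 0.1]
        series = onset_times(SpikeTrain("n", times), cs, "first_spike")
        assert series.n_skipped == 4


class TestJitter:
    def test_alternating_latencies(self):
        series = OnsetSeries(latencies=np.array([0, 10, 0, 10, 0, 10]) / 1000.0, rule="first_spike")
        assert onset_jitter(series) == pytest.approx(np.log(10.0), abs=1e-9)

    def test_hand_example_exact(self):
        series = OnsetSeries(latencies=np.array([0.0, 5.0, -3.0, 7.0]) / 1000.0, rule="first_spike")
        # diffs {5,-8,10} ms -> RMSSD = sqrt(189/3)
        assert onset_jitter(series) == pytest.approx(np.log(np.sqrt(189.0 / 3.0)), abs=1e-9)

    def test_zero_rmssd_errors(self):
        series = OnsetSeries(latencies=np.array([1.0, 1.0, 1.0]), rule="first_spike")
        with pytest.raises(ValueError):
            onset_jitter(series)

    @given(
        lats=st.lists(st.floats(-0.5, 0.5), min_size=3, max_size=30),
        shift=st.floats(-1.0, 1.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_translation_invariance_and_log_homogeneity(self, lats, shift, scale):
        lats = np.asarray(lats)
        if np.sqrt(np.mean(np.diff(lats * 1000) ** 2)) <= 1e-9:
            return
        base = onset_jitter(OnsetSeries(latencies=lats, rule="first_spike"))
        shifted = onset_jitter(OnsetSeries(latencies=lats + shift, rule="first_spike"))
        scaled = onset_jitter(OnsetSeries(latencies=lats * scale, rule="first_spike"))
        assert shifted == pytest.approx(base, abs=1e-7)
        assert scaled == pytest.approx(base + np.log(scale), rel=1e-6)
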