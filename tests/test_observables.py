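"""Unit tests of the reversal statistics and cumulative-history analysis."""

import numpy as np
import pytest

from multistable import (DegenerateFitError, InsufficientDataError, Interval,
                         ReversalSequence, compute_observables,
                         cumulative_history, dominance_statistics,
                         fit_distributions, history_correlation_at_tau,
                         history_null, history_scan, shuffle_sequence)

from conftest import seq_from_durations


class TestDominanceStatistics:
    def test_equal_periods(self):
        t_dom, c_v, balance, n = dominance_statistics(
            seq_from_durations([2.0, 2.0, 2.0]))
        assert t_dom == 2.0 and c_v == 0.0 and n == 3
        assert balance == pytest.approx(4.0 / 6.0)  # A holds periods 1 and 3

    def test_two_periods_hand_computed(self):
        # mean 2, sample sd sqrt(2) -> C_v = sqrt(2)/2
        t_dom, c_v, _, _ = dominance_statistics(seq_from_durations([1.0, 3.0]))
        assert t_dom == 2.0
        assert c_v == pytest.approx(np.sqrt(2) / 2)

    def test_exponential_periods_have_unit_cv(self):
        rng = np.random.default_rng(0)
        seq = seq_from_durations(rng.exponential(2.0, size=10_000))
        _, c_v, _, _ = dominance_statistics(seq)
        assert c_v == pytest.approx(1.0, abs=0.03)

    def test_mixed_and_incomplete_excluded(self):
        ivs = [Interval("A", 0, 2.0), Interval("mixed", 2.0, 1.0),
               Interval("B", 3.0, 2.0), Interval("A", 5.0, 5.0, complete=False)]
        t_dom, _, _, n = dominance_statistics(ReversalSequence([ivs]))
        assert n == 2 and t_dom == 2.0

    def test_insufficient_periods(self):
        with pytest.raises(InsufficientDataError):
            dominance_statistics(seq_from_durations([1.0]))


class TestFitDistributions:
    def test_gamma_recovery_and_ranking(self):
        rng = np.random.default_rng(1)
        data = rng.gamma(3.7, 2.0, size=10_000)
        fits = fit_distributions(data)
        assert 3.1 <= fits.gamma_shape <= 4.3
        assert abs(fits.gamma_shape - 3.7) / 3.7 < 0.05
        assert fits.gamma.ks_p > fits.exponential.ks_p

    def test_exponential_is_gamma_shape_one(self):
        rng = np.random.default_rng(2)
        fits = fit_distributions(rng.exponential(2.0, size=10_000))
        assert fits.gamma_shape == pytest.approx(1.0, abs=0.1)

    def test_degenerate_sample(self):
        with pytest.raises(DegenerateFitError):
            fit_distributions([2.0] * 20)

    def test_too_few_periods(self):
        with pytest.raises(InsufficientDataError):
            fit_distributions([1.0, 2.0, 3.0])


class TestCumulativeHistory:
    def test_saturating_closed_form(self):
        """Uninterrupted dominance: H(t) = 1 - exp(-t/tau)."""
        tau = 2.0
        seq = ReversalSequence([[Interval("A", 0, tau), Interval("B", tau, 1.0)]])
        trace = cumulative_history(seq, tau)
        # boundary after the first interval, of length exactly tau
        assert trace.h_a[0][1] == pytest.approx(1 - np.exp(-1))

    def test_conservation_without_mixed(self, operating_sequence):
        tau = 1.5
        trace = cumulative_history(operating_sequence, tau)
        t = trace.boundaries[0]
        late = t >= 10 * tau
        total = trace.h_a[0][late] + trace.h_b[0][late]
        assert np.all(np.abs(total - 1) <= np.exp(-10) + 1e-12)

    def test_bounds(self, coupled_sequence):
        trace = cumulative_history(coupled_sequence, 3.0)
        for h in trace.h_a + trace.h_b:
            assert np.all(h >= 0) and np.all(h <= 1)

    def test_matches_quadrature_oracle(self):
        """Exact piecewise update vs. adaptive quadrature of the
        convolution form H(t) = (1/tau) * int_0^t S(t') exp(-(t-t')/tau) dt'."""
        from scipy.integrate import quad

        rng = np.random.default_rng(3)
        seq = seq_from_durations(rng.gamma(3.0, 1.0, size=30))
        tau = 1.7
        trace = cumulative_history(seq, tau)
        codes, onsets, durations, _ = seq.block_arrays(0)

        def s_a(t):
            j = np.searchsorted(onsets, t, side="right") - 1
            return 1.0 if codes[j] == 0 else 0.0

        for j in (5, 12, 29):
            t_j = onsets[j]
            val, _ = quad(lambda u: s_a(u) * np.exp(-(t_j - u) / tau) / tau,
                          0, t_j, points=onsets[:j + 1], limit=400)
            assert abs(val - trace.h_a[0][j]) < 1e-6


class TestHistoryCorrelation:
    def test_deterministic(self, coupled_sequence):
        a = history_correlation_at_tau(coupled_sequence, 3.0)
        b = history_correlation_at_tau(coupled_sequence, 3.0)
        assert a == b

    def test_coupled_sequence_exceeds_renewal_level(self, coupled_sequence):
        assert history_correlation_at_tau(coupled_sequence, 3.0) > 0.3

    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            history_correlation_at_tau(seq_from_durations([1, 2, 1, 2]), 1.0)

    def test_scan_grid_of_length_one(self, coupled_sequence):
        c, tau, (taus, curve) = history_scan(coupled_sequence,
                                             np.array([2.5]))
        assert tau == 2.5 and curve.shape == (1,)
        assert c == history_correlation_at_tau(coupled_sequence, 2.5)

    def test_scan_peak_location(self, coupled_sequence):
        """The correlation peak recovers the generator's coupling time
        constant (3 s) within a factor of two."""
        c_h, tau_h, _ = history_scan(coupled_sequence)
        assert c_h > 0.3
        assert 1.5 <= tau_h <= 6.0

    def test_renewal_within_shuffle_null(self, renewal_long):
        """An i.i.d. renewal sequence shows no history-dependence: its c_H
        lies inside the shuffle-null distribution."""
        taus = np.geomspace(0.01, 60, 20)
        c_h, _, _ = history_scan(renewal_long, taus)
        null = history_null(renewal_long, taus, n_shuffles=50, seed=1)
        assert c_h <= np.quantile(null, 0.99)


class TestShuffle:
    def test_durations_are_resampled_multiset(self, coupled_sequence):
        pool = coupled_sequence.dominance_durations()
        shuffled = shuffle_sequence(coupled_sequence, seed=4)
        for _, iv in shuffled.iter_intervals():
            if iv.state != "mixed":
                assert np.any(pool == iv.duration)  # exact copies of pool values

    def test_same_seed_identical(self, coupled_sequence):
        a = shuffle_sequence(coupled_sequence, seed=7)
        b = shuffle_sequence(coupled_sequence, seed=7)
        assert all(x.duration == y.duration
                   for (_, x), (_, y) in zip(a.iter_intervals(),
                                             b.iter_intervals()))

    def test_bootstrap_mean_preserved(self, coupled_sequence):
        orig = dominance_statistics(coupled_sequence)[0]
        means = [dominance_statistics(shuffle_sequence(coupled_sequence, s))[0]
                 for s in range(200)]
        assert np.mean(means) == pytest.approx(orig, rel=0.02)


def test_compute_observables_bundle(operating_sequence):
    obs = compute_observables(operating_sequence)
    assert obs.t_dom > 0 and obs.c_v > 0
    assert 0 <= obs.c_h <= 1 and obs.tau_h > 0
    assert obs.gamma_h == pytest.approx(obs.tau_h / obs.t_dom)
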