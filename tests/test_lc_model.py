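"""Unit tests of the rate-model simulator and regime classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multistable import (InsufficientDataError, InvalidParameterError,
                         ModelParams, SimProtocol, Trajectory, classify_regime,
                         gain_function, label_dominance, simulate_reversals,
                         simulate_trajectory)


class TestGainFunction:
    def test_symmetry_point(self):
        assert gain_function(0.0, 0.1) == pytest.approx(0.5)

    def test_closed_form_value(self):
        # F(0.1, k=0.1) = 1 / (1 + e^-1)
        assert gain_function(0.1, 0.1) == pytest.approx(1 / (1 + np.exp(-1)))

    @given(st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_odd_symmetry_and_bounds(self, x):
        f, g = gain_function(x, 0.1), gain_function(-x, 0.1)
        assert f + g == pytest.approx(1.0)
        assert 0.0 < f < 1.0 or x > 2  # exp underflow saturates at large |x|

    def test_strictly_increasing(self):
        x = np.linspace(-1, 1, 201)
        assert np.all(np.diff(gain_function(x, 0.1)) > 0)

    def test_invalid_steepness(self):
        with pytest.raises(InvalidParameterError):
            gain_function(0.0, k=0.0)


class TestSimulateTrajectory:
    def test_deterministic_given_seed(self, operating_params):
        proto = SimProtocol(duration=20.0, seed=123)
        t1 = simulate_trajectory(operating_params, proto)
        t2 = simulate_trajectory(operating_params, proto)
        assert np.array_equal(t1.r1, t2.r1)
        assert np.array_equal(t1.n1, t2.n1)

    def test_noiseless_run_has_zero_noise(self, operating_params):
        p = operating_params.replace(sigma_n=0.0)
        traj = simulate_trajectory(p, SimProtocol(duration=5.0, seed=1))
        assert np.all(traj.n1 == 0) and np.all(traj.n2 == 0)

    def test_rates_bounded_after_transient(self, operating_params):
        traj = simulate_trajectory(operating_params,
                                   SimProtocol(duration=30.0, seed=2))
        after = traj.times > 10 * operating_params.tau_r
        for r in (traj.r1[after], traj.r2[after]):
            assert np.all(r > 0) and np.all(r < 1)

    def test_index_swap_symmetry_noiseless(self, operating_params):
        """Swapping the two populations' initial states mirrors the dynamics."""
        p = operating_params.replace(sigma_n=0.0)
        proto = SimProtocol(duration=30.0, initial_state=(0.2, 0.9, 0.1, 0.8))
        swapped = SimProtocol(duration=30.0, initial_state=(0.9, 0.2, 0.8, 0.1))
        t1 = simulate_trajectory(p, proto)
        t2 = simulate_trajectory(p, swapped)
        assert np.array_equal(t1.r1, t2.r2)
        assert np.array_equal(t1.a1, t2.a2)

    def test_symmetric_initial_condition_stays_symmetric(self, operating_params):
        p = operating_params.replace(sigma_n=0.0)
        proto = SimProtocol(duration=10.0, initial_state=(0.3, 0.3, 0.1, 0.1))
        traj = simulate_trajectory(p, proto)
        assert np.array_equal(traj.r1, traj.r2)

    def test_dt_halving_changes_little(self, operating_params):
        """First-order integration sanity: halving dt moves the noiseless
        trajectory by less than 1e-3 in sup-norm."""
        p = operating_params.replace(sigma_n=0.0)
        coarse = simulate_trajectory(p, SimProtocol(duration=20.0, dt=0.001))
        fine = simulate_trajectory(p, SimProtocol(duration=20.0, dt=0.0005),
                                   record_stride=2)
        assert coarse.r1.size == fine.r1.size
        assert np.max(np.abs(coarse.r1 - fine.r1)) < 1e-3

    def test_dt_too_coarse_rejected(self, operating_params):
        with pytest.raises(InvalidParameterError):
            simulate_trajectory(operating_params,
                                SimProtocol(duration=1.0, dt=0.005))

    def test_ou_channel_moments(self):
        """Stationary OU statistics: variance sigma_n^2 and exponential
        autocorrelation with time constant tau_n."""
        sigma, tau_n = 0.3, 0.1
        p = ModelParams(beta=0.0, phi_a=0.0, i0=0.0, sigma_n=sigma)
        traj = simulate_trajectory(p, SimProtocol(duration=1000.0, seed=9))
        n = traj.n1
        assert np.var(n) == pytest.approx(sigma ** 2, rel=0.05)
        lag = 50  # 50 ms
        rho = np.corrcoef(n[:-lag], n[lag:])[0, 1]
        assert rho == pytest.approx(np.exp(-lag * 0.001 / tau_n), abs=0.02)


class TestLabelDominance:
    def _traj(self, r1, r2, dt=0.1):
        n = len(r1)
        z = np.zeros(n)
        return Trajectory(np.arange(n) * dt, np.asarray(r1, float),
                          np.asarray(r2, float), z, z, z, z)

    def test_constant_dominance_single_incomplete_period(self):
        traj = self._traj([1.3] * 50, [1.0] * 50)
        seq = label_dominance(traj, 0.25)
        ivs = seq.blocks[0]
        assert len(ivs) == 1
        assert ivs[0].state == "A" and not ivs[0].complete

    def test_square_wave_alternation(self):
        r1 = np.tile([0.8] * 20 + [0.2] * 20, 5)
        r2 = np.tile([0.2] * 20 + [0.8] * 20, 5)
        seq = label_dominance(self._traj(r1, r2, dt=0.1), 0.25)
        complete = [iv for _, iv in seq.iter_intervals() if iv.complete]
        assert all(iv.duration == pytest.approx(2.0) for iv in complete)
        states = [iv.state for _, iv in seq.iter_intervals()]
        assert all(a != b for a, b in zip(states, states[1:]))

    def test_near_equal_activities_stay_mixed(self):
        traj = self._traj([1.0] * 40, [0.9] * 40)  # within 25% of each other
        seq = label_dominance(traj, 0.25)
        ivs = seq.blocks[0]
        assert len(ivs) == 1 and ivs[0].state == "mixed"
        assert seq.n_periods == 0

    def test_empty_trajectory_rejected(self):
        empty = Trajectory(*[np.empty(0)] * 7)
        with pytest.raises(InsufficientDataError):
            label_dominance(empty)

    def test_online_labelling_matches_trajectory_labelling(self, operating_params):
        proto = SimProtocol(duration=120.0, seed=42)
        via_traj = label_dominance(simulate_trajectory(operating_params, proto))
        online = simulate_reversals(operating_params, proto)
        d1, d2 = via_traj.dominance_durations(), online.dominance_durations()
        assert np.allclose(d1, d2)


class TestClassifyRegime:
    def test_uncoupled_point_is_stationary(self):
        p = ModelParams(beta=0.0, phi_a=0.0, i0=0.5)
        assert classify_regime(p) == "stationary"

    def test_strong_adaptation_oscillates(self):
        p = ModelParams(beta=1.75, phi_a=0.95, i0=0.5)
        assert classify_regime(p) == "oscillatory"

    def test_weak_adaptation_is_bistable(self):
        p = ModelParams(beta=1.75, phi_a=0.05, i0=0.5)
        assert classify_regime(p) == "bistable"

    def test_agrees_with_refined_integration(self):
        """The label at the reference point is robust to integrating 10x
        longer at 10x finer resolution."""
        p = ModelParams(beta=1.75, phi_a=0.25, i0=0.5)
        coarse = classify_regime(p)
        refined = classify_regime(p, duration=6000.0, dt=0.0001,
                                  record_stride=100)
        assert coarse == refined
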