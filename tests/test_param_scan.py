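"""Unit tests of grid evaluation, matching and volume assembly."""

import numpy as np
import pytest

from multistable import (ConfigurationError, EmptyVolumeError, GridSpec,
                         InvalidParameterError, MatchVolume, ModelParams,
                         ObservableSet, ScanProtocol, classify_humanlike,
                         evaluate_point, is_match, scan_grid, volume_summary)
from multistable.empirical import EMPIRICAL
from multistable.observables import DistributionFits, FitResult
import multistable.param_scan as ps


def _fits(shape, p_gamma, p_exp=0.01, p_norm=0.01):
    return DistributionFits(
        gamma=FitResult((shape, 1.0), 0.02, p_gamma),
        exponential=FitResult((1.0,), 0.2, p_exp),
        gaussian=FitResult((1.0, 1.0), 0.2, p_norm))


class TestIsMatch:
    KD = EMPIRICAL["KD"]

    def test_identity_matches(self):
        assert is_match(self.KD, self.KD)

    def test_twenty_percent_deviation_matches(self):
        pred = ObservableSet(t_dom=1.2 * 11.4, c_v=1.2 * 0.67,
                             c_h=1.2 * 0.24, tau_h=1.2 * 5.2)
        assert is_match(pred, self.KD, tol=0.25)

    def test_thirty_percent_on_one_statistic_fails(self):
        pred = ObservableSet(t_dom=11.4, c_v=0.67, c_h=1.3 * 0.24, tau_h=5.2)
        assert not is_match(pred, self.KD, tol=0.25)

    def test_boundary_inclusive(self):
        pred = ObservableSet(t_dom=1.25 * 11.4, c_v=0.67, c_h=0.24, tau_h=5.2)
        assert is_match(pred, self.KD, tol=0.25)

    def test_zero_empirical_rejected(self):
        emp = ObservableSet(t_dom=11.4, c_v=0.0, c_h=0.24, tau_h=5.2)
        with pytest.raises(InvalidParameterError):
            is_match(self.KD, emp)


class TestClassifyHumanlike:
    def test_table_values_pass(self):
        assert classify_humanlike(_fits(3.7, 0.74, 0.09, 0.09))

    def test_exponential_shape_fails(self):
        assert not classify_humanlike(_fits(1.0, 0.9))

    def test_low_p_fails(self):
        assert not classify_humanlike(_fits(3.7, 0.5))

    def test_gamma_must_beat_alternatives(self):
        assert not classify_humanlike(_fits(3.7, 0.75, p_exp=0.8))


class TestEvaluatePoint:
    PROTO = ScanProtocol(n_short=2, t_short=200.0, n_long=2, t_long=400.0)

    def test_deterministic(self, operating_params):
        a = evaluate_point(operating_params, self.PROTO, seed=3)
        b = evaluate_point(operating_params, self.PROTO, seed=3)
        assert a.observables == b.observables
        assert a.protocol_used == b.protocol_used

    def test_noiseless_bistable_is_non_reversing(self):
        p = ModelParams(beta=1.75, phi_a=0.05, i0=0.5, sigma_n=0.0, tau_a=2.0)
        ev = evaluate_point(p, self.PROTO, seed=1)
        assert ev.non_reversing and ev.observables is None

    def test_escalation_on_forced_dispersion(self, operating_params,
                                              monkeypatch):
        """Across-run coefficient of variation above threshold escalates to
        the long protocol."""
        values = iter([2.0, 20.0, 5.0, 5.0, 5.0, 5.0, 5.0])

        def fake_run(params, duration, dt, seed, tau_grid):
            t = next(values)
            obs = ObservableSet(t_dom=t, c_v=0.5, c_h=0.2, tau_h=2.0,
                                balance=0.5, n_periods=50)
            return obs, np.full(50, t)

        monkeypatch.setattr(ps, "_run_observables", fake_run)
        ev = evaluate_point(operating_params, ScanProtocol(
            n_short=2, t_short=100.0, n_long=5, t_long=200.0), seed=1)
        assert ev.protocol_used == "long"
        assert ev.observables.t_dom == pytest.approx(5.0)

    def test_no_escalation_when_consistent(self, operating_params,
                                           monkeypatch):
        def fake_run(params, duration, dt, seed, tau_grid):
            obs = ObservableSet(t_dom=3.0, c_v=0.5, c_h=0.2, tau_h=2.0,
                                balance=0.5, n_periods=50)
            return obs, np.full(50, 3.0)

        monkeypatch.setattr(ps, "_run_observables", fake_run)
        ev = evaluate_point(operating_params, self.PROTO, seed=1)
        assert ev.protocol_used == "short"

    def test_agrees_with_longer_run(self, operating_params):
        """Short-protocol means are consistent with a single 5x longer run."""
        from multistable import SimProtocol, compute_observables
        from multistable.lc_model import simulate_reversals
        from multistable.param_scan import _trim_simulated

        ev = evaluate_point(operating_params,
                            ScanProtocol(n_short=3, t_short=500.0,
                                         n_long=3, t_long=1500.0), seed=5)
        long_seq = _trim_simulated(simulate_reversals(
            operating_params, SimProtocol(duration=2500.0, seed=99)))
        ref = compute_observables(long_seq)
        assert ev.observables.t_dom == pytest.approx(ref.t_dom, rel=0.3)
        assert ev.observables.c_v == pytest.approx(ref.c_v, rel=0.3)


class TestVolumes:
    def test_volume_summary_single_point(self):
        vol = MatchVolume(matched_points=[{"i0": 0.5, "beta": 1.0,
                                           "phi_a": 0.2, "sigma_n": 0.15,
                                           "tau_a": 2.0, "deviation": 0.1}],
                          center=np.array([0.5, 1.0, 0.2]),
                          fraction_of_possible=0.25, n_possible=4)
        center, frac = volume_summary(vol)
        assert np.allclose(center, [0.5, 1.0, 0.2]) and frac == 0.25

    def test_volume_summary_two_points(self):
        pts = [{"i0": 0.0, "beta": 0.0, "phi_a": 0.0},
               {"i0": 1.0, "beta": 1.0, "phi_a": 1.0}]
        vol = MatchVolume(matched_points=pts,
                          center=np.array([0.5, 0.5, 0.5]),
                          fraction_of_possible=0.5, n_possible=4)
        center, _ = volume_summary(vol)
        assert np.allclose(center, [0.5, 0.5, 0.5])

    def test_empty_volume_rejected(self):
        vol = MatchVolume(matched_points=[], center=None,
                          fraction_of_possible=0.0, n_possible=4)
        with pytest.raises(EmptyVolumeError):
            volume_summary(vol)

    def test_all_stationary_regime_map_rejected(self):
        grid = GridSpec(i0_axis=[0.5], beta_axis=[1.0], phi_a_axis=[0.2],
                        sigma_n_axis=[0.15], tau_a_axis=[2.0])
        regimes = {(0.5, 1.0, 0.2): "stationary"}
        with pytest.raises(ConfigurationError):
            scan_grid(grid, EMPIRICAL["KD"], regimes, seed=1)

    def test_tolerance_monotonicity(self, operating_params):
        """Points matched at a strict tolerance are matched at a loose one."""
        from multistable import SimProtocol, compute_observables
        from multistable.lc_model import simulate_reversals
        from multistable.param_scan import _trim_simulated

        # target = the statistics simulated at the single grid point itself
        seq = _trim_simulated(simulate_reversals(
            operating_params, SimProtocol(duration=1000.0, seed=8)))
        emp = compute_observables(seq)
        grid = GridSpec(i0_axis=[0.5], beta_axis=[1.75], phi_a_axis=[0.25],
                        sigma_n_axis=[0.15], tau_a_axis=[2.0])
        regimes = {(0.5, 1.75, 0.25): "bistable"}
        proto = ScanProtocol(n_short=2, t_short=400.0, n_long=2, t_long=800.0)
        strict = scan_grid(grid, emp, regimes, seed=2, protocol=proto,
                           tol=0.10, prefilter_factor=None)
        loose = scan_grid(grid, emp, regimes, seed=2, protocol=proto,
                          tol=0.25, prefilter_factor=None)
        key = lambda m: (m["i0"], m["beta"], m["phi_a"], m["sigma_n"], m["tau_a"])  # noqa: E731
        assert {key(m) for m in strict.matched_combos} <= \
               {key(m) for m in loose.matched_combos}


class TestGridSpec:
    def test_axes_validated(self):
        with pytest.raises(ConfigurationError):
            GridSpec(i0_axis=[2.0, 1.0])
        with pytest.raises(ConfigurationError):
            GridSpec(phi_a_axis=[0.0, 1.5])

    def test_triplet_enumeration(self):
        grid = GridSpec(i0_axis=[0.5, 1.0], beta_axis=[1.0],
                        phi_a_axis=[0.1, 0.2], sigma_n_axis=[0.15],
                        tau_a_axis=[2.0])
        assert len(list(grid.triplets())) == 4
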