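"""Two-population competition model with adaptation and colored noise.

Two populations code for the competing appearances of an ambiguous display:

    tau_r * dr_i/dt = -r_i + F(alpha*r_i - beta*r_j - phi_a*a_i + I_i + n_i)
    tau_a * da_i/dt = -a_i + r_i

with logistic gain ``F(x) = 1 / (1 + exp(-x/k))`` and independent
Ornstein-Uhlenbeck noise channels ``n_i`` of standard deviation ``sigma_n``
and correlation time ``tau_n``.  Depending on the balance of inhibition
(beta), adaptation (phi_a) and drive (I0), the noiseless system is
stationary (one symmetric fixed point), oscillatory (adaptation-driven limit
cycle), or bistable (two winner-take-all attractors; reversals require
noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from . import _kernels
from .errors import (InsufficientDataError, InvalidParameterError,
                     NumericalFailureError, UnclassifiableRegimeError)
from .params import ASYMMETRIC_INIT, ModelParams, SimProtocol
from .sequences import Interval, ReversalSequence

__all__ = [
    "gain_function",
    "Trajectory",
    "simulate_trajectory",
    "simulate_reversals",
    "label_dominance",
    "classify_regime",
    "REGIME_LABELS",
]

#: dominance criterion: a reversal to percept x requires r_x to exceed the
#: competing activity by this fraction (hysteretic; 25%)
DOMINANCE_THRESHOLD = 0.25

REGIME_LABELS = ("stationary", "oscillatory", "bistable")


def gain_function(x: Union[float, np.ndarray], k: float = 0.1):
    """Logistic population gain ``F(x) = 1 / (1 + exp(-x/k))``.

    Strictly increasing, maps onto the open interval (0, 1), with
    ``F(0) = 1/2`` and odd symmetry ``F(x) + F(-x) = 1``.
    """
    if k <= 0:
        raise InvalidParameterError(f"gain steepness k must be > 0, got {k}")
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(-x / k))
    return out if out.ndim else float(out)


@dataclass
class Trajectory:
    """Sampled model state: times in seconds, activities, adaptation, noise."""

    times: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    n1: np.ndarray
    n2: np.ndarray

    @property
    def dt_sample(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def __len__(self):
        return self.times.size


def _kernel_args(params: ModelParams, protocol: SimProtocol):
    protocol.validate_against(params)
    n_steps = int(round(protocol.duration / protocol.dt))
    mod = protocol.modulation
    mod_amp = mod.amplitude if mod is not None else 0.0
    mod_period = mod.period if mod is not None else 0.0
    r1, r2, a1, a2 = (float(v) for v in protocol.initial_state)
    # unit Gaussian draws for the OU channels, generated vectorised; the
    # initial noise states are drawn from the stationary distribution
    if params.sigma_n > 0:
        rng = np.random.default_rng(int(protocol.seed) & 0x7FFFFFFF)
        init = params.sigma_n * rng.standard_normal(2)
        n1_0, n2_0 = float(init[0]), float(init[1])
        # single-precision draws: the OU channel needs no more granularity
        # and generation is a large share of a run's cost
        xi1 = rng.standard_normal(n_steps, dtype=np.float32)
        xi2 = rng.standard_normal(n_steps, dtype=np.float32)
    else:
        n1_0 = n2_0 = 0.0
        xi1 = xi2 = np.empty(0, dtype=np.float32)
    return (params.beta, params.phi_a, params.i0, params.sigma_n,
            params.tau_a, params.tau_r, params.tau_n, params.k, params.alpha,
            n_steps, protocol.dt, r1, r2, a1, a2, n1_0, n2_0, xi1, xi2,
            mod_amp, mod_period)


def simulate_trajectory(params: ModelParams, protocol: SimProtocol,
                        record_stride: int = 1) -> Trajectory:
    """Integrate the model and return the recorded state trajectory.

    Fixed-step Euler for rates and adaptation; the noise channel uses the
    exact Ornstein-Uhlenbeck update.  Deterministic given ``protocol.seed``.
    ``record_stride`` keeps every n-th sample (t=0 always included).
    """
    args = _kernel_args(params, protocol)
    n_steps, dt = args[9], args[10]
    r1s, r2s, a1s, a2s, n1s, n2s, bad = _kernels.integrate_trajectory(
        *args, record_stride)
    if bad >= 0:
        raise NumericalFailureError(
            f"non-finite state at integration step {bad} (t={bad * dt:.4f} s)")
    times = np.arange(r1s.size) * (dt * record_stride)
    return Trajectory(times, r1s, r2s, a1s, a2s, n1s, n2s)


def _sequence_from_onsets(states: np.ndarray, onsets: np.ndarray,
                          duration: float) -> ReversalSequence:
    """Build a single-block ReversalSequence from reversal events."""
    intervals = []
    if states.size == 0:
        intervals.append(Interval("mixed", 0.0, duration, complete=False))
        return ReversalSequence([intervals])
    if onsets[0] > 0:
        intervals.append(Interval("mixed", 0.0, float(onsets[0]), complete=True))
    for j in range(states.size):
        state = "A" if states[j] == 1 else "B"
        start = float(onsets[j])
        end = float(onsets[j + 1]) if j + 1 < states.size else duration
        if end <= start:  # reversal at the very last sample
            continue
        intervals.append(Interval(state, start, end - start,
                                  complete=(j + 1 < states.size)))
    return ReversalSequence([intervals])


def reversal_events(params: ModelParams, protocol: SimProtocol,
                    threshold_ratio: float = DOMINANCE_THRESHOLD
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Raw reversal events: (percept codes 1/2, onset seconds).

    The array-level fast path behind :func:`simulate_reversals`: successive
    onset differences are the complete dominance durations (the leading mixed
    segment and the final incomplete period never appear).  Used by the grid
    scans, where building interval objects would dominate at short dominance
    times.
    """
    args = _kernel_args(params, protocol)
    dt = args[10]
    states, onsets, bad = _kernels.integrate_reversals(*args, threshold_ratio)
    if bad >= 0:
        raise NumericalFailureError(
            f"non-finite state at integration step {bad} (t={bad * dt:.4f} s)")
    return states, onsets


def simulate_reversals(params: ModelParams, protocol: SimProtocol,
                       threshold_ratio: float = DOMINANCE_THRESHOLD
                       ) -> ReversalSequence:
    """Integrate the model and label dominance online (no stored trajectory).

    Equivalent to ``label_dominance(simulate_trajectory(...))`` at stride 1,
    but memory-light.
    """
    states, onsets = reversal_events(params, protocol, threshold_ratio)
    return _sequence_from_onsets(states, onsets, float(protocol.duration))


def label_dominance(traj: Trajectory,
                    threshold_ratio: float = DOMINANCE_THRESHOLD
                    ) -> ReversalSequence:
    """Hysteretic dominance labelling of a trajectory.

    Percept x becomes dominant at the first sample where
    ``r_x >= (1 + threshold_ratio) * r_y`` and stays dominant until the
    opposite crossing.  The segment before the first crossing is ``mixed``;
    the final interval is flagged incomplete.
    """
    if len(traj) == 0:
        raise InsufficientDataError("empty trajectory")
    if threshold_ratio <= 0:
        raise InvalidParameterError("threshold_ratio must be > 0")
    states, onsets = _kernels.label_samples(
        np.ascontiguousarray(traj.r1), np.ascontiguousarray(traj.r2),
        traj.dt_sample, threshold_ratio)
    duration = float(traj.times[-1]) if len(traj) > 1 else traj.dt_sample
    return _sequence_from_onsets(states, onsets, duration)


# regime-classification tolerances (the criteria are inherently qualitative;
# these make them operational)
_STATIONARY_GAP = 1e-3      # max |r1 - r2| over the final window
_DERIV_TOL = 1e-5           # max |d state/dt| (1/s) over the final window
_FINAL_WINDOW = 60.0        # seconds used for stationary/bistable checks
_OSC_WINDOW = 300.0         # seconds scanned for rank-order reversals


def classify_regime(params: ModelParams, duration: float = 600.0,
                    dt: float = 0.001, record_stride: int = 10) -> str:
    """Classify the noiseless dynamical regime at a parameter point.

    Runs 600 s without noise (sigma_n = 0, tau_a = 1 s) from the asymmetric
    initial condition r1=a1=0, r2=a2=1 and inspects the trajectory tail:

    - ``stationary``: activities converge to identical values
      (|r1 - r2| < 1e-3 throughout the final 60 s);
    - ``oscillatory``: the rank order of r1, r2 reverses at least twice in
      the final 300 s;
    - ``bistable``: a steady state with preserved rank order is reached
      (max state derivative < 1e-5 /s over the final 60 s).

    Raises :class:`UnclassifiableRegimeError` if none applies.
    """
    p = params.replace(sigma_n=0.0, tau_a=1.0)
    proto = SimProtocol(duration=duration, dt=dt, seed=0,
                        initial_state=ASYMMETRIC_INIT)
    traj = simulate_trajectory(p, proto, record_stride=record_stride)

    t = traj.times
    diff = traj.r1 - traj.r2
    final = t >= t[-1] - _FINAL_WINDOW

    if np.max(np.abs(diff[final])) < _STATIONARY_GAP:
        return "stationary"

    osc = t >= t[-1] - _OSC_WINDOW
    sign = np.sign(diff[osc])
    sign = sign[sign != 0]
    if np.count_nonzero(np.diff(sign) != 0) >= 2:
        return "oscillatory"

    dts = traj.dt_sample
    window = np.flatnonzero(final)
    max_deriv = 0.0
    for arr in (traj.r1, traj.r2, traj.a1, traj.a2):
        d = np.abs(np.diff(arr[window])) / dts
        if d.size:
            max_deriv = max(max_deriv, float(np.max(d)))
    rank_preserved = np.all(diff[final] > 0) or np.all(diff[final] < 0)
    if max_deriv < _DERIV_TOL and rank_preserved:
        return "bistable"

    tail = np.column_stack([t[final][-10:], traj.r1[final][-10:],
                            traj.r2[final][-10:]])
    raise UnclassifiableRegimeError(
        f"no regime criterion met at beta={params.beta}, phi_a={params.phi_a}, "
        f"i0={params.i0}; max|r1-r2|={np.max(np.abs(diff[final])):.3g}, "
        f"max deriv={max_deriv:.3g}/s", tail=tail)
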