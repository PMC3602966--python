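"""Parameter-grid scans: regime maps, observable evaluation, matching volumes.

The (I0, beta, phi_a) cube determines the dynamical regime; for every triplet
a set of hidden parameters (sigma_n, tau_a) is additionally explored.  A
triplet "matches" an observer when, for at least one hidden combination, all
four simulated statistics (T_dom, C_v, c_H, tau_H) fall within a fractional
tolerance (default 25%) of the observer's values.  Matching volumes are
reported as fractions of the "possible" volume — the triplets whose
noiseless regime is bistable or oscillatory (the stationary regime produces
no reversals and cannot match anything).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (ConfigurationError, EmptyVolumeError,
                     InsufficientDataError, InvalidParameterError,
                     UnclassifiableRegimeError)
from .lc_model import classify_regime, reversal_events, simulate_reversals
from .observables import (DistributionFits, ObservableSet, compute_observables,
                          default_tau_grid, fit_distributions)
from .params import ASYMMETRIC_INIT, ModelParams, SimProtocol
from .sequences import ReversalSequence

__all__ = [
    "GridSpec",
    "ScanProtocol",
    "PointEvaluation",
    "MatchVolume",
    "regime_map",
    "evaluate_point",
    "is_match",
    "classify_humanlike",
    "scan_grid",
    "volume_summary",
    "humanlike_volume",
]

#: hidden-parameter axes explored at every triplet (seconds / dimensionless)
DEFAULT_TAU_A = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 3.0, 4.0, 5.0, 6.5, 8.0)
DEFAULT_SIGMA_N = tuple(np.round(np.arange(0.01, 0.3501, 0.02), 2))

MATCH_STATS = ("t_dom", "c_v", "c_h", "tau_h")


def _axis(values, lo, hi, name) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ConfigurationError(f"{name} axis must be a non-empty 1-D list")
    if np.any(np.diff(arr) <= 0):
        raise ConfigurationError(f"{name} axis must be strictly increasing")
    if arr[0] < lo or arr[-1] > hi:
        raise ConfigurationError(f"{name} axis must lie within [{lo}, {hi}]")
    return arr


@dataclass(frozen=True)
class GridSpec:
    """Axes of the exploration grid.

    Triplet axes span I0, beta in [0, 2] and phi_a in [0, 1]; hidden axes
    span sigma_n in [0.01, 0.35] and tau_a in [1, 8] s.
    """

    i0_axis: Sequence[float] = tuple(np.linspace(0, 2, 11))
    beta_axis: Sequence[float] = tuple(np.linspace(0, 2, 11))
    phi_a_axis: Sequence[float] = tuple(np.linspace(0, 1, 11))
    sigma_n_axis: Sequence[float] = DEFAULT_SIGMA_N
    tau_a_axis: Sequence[float] = DEFAULT_TAU_A

    def __post_init__(self):
        object.__setattr__(self, "i0_axis", tuple(_axis(self.i0_axis, 0, 2, "i0")))
        object.__setattr__(self, "beta_axis", tuple(_axis(self.beta_axis, 0, 2, "beta")))
        object.__setattr__(self, "phi_a_axis", tuple(_axis(self.phi_a_axis, 0, 1, "phi_a")))
        object.__setattr__(self, "sigma_n_axis",
                           tuple(_axis(self.sigma_n_axis, 0.01, 0.35, "sigma_n")))
        object.__setattr__(self, "tau_a_axis",
                           tuple(_axis(self.tau_a_axis, 1.0, 8.0, "tau_a")))

    def triplets(self):
        for i0 in self.i0_axis:
            for beta in self.beta_axis:
                for phi_a in self.phi_a_axis:
                    yield (i0, beta, phi_a)


@dataclass(frozen=True)
class ScanProtocol:
    """Simulation protocol of the matching scan.

    The short protocol runs ``n_short`` simulations of ``t_short`` seconds;
    if the across-run coefficient of variation of any observable exceeds
    ``escalation_cv``, the point is re-evaluated with ``n_long`` runs of
    ``t_long`` seconds.
    """

    n_short: int = 3
    t_short: float = 500.0
    n_long: int = 5
    t_long: float = 3000.0
    escalation_cv: float = 0.5
    dt: float = 0.001
    tau_grid: Optional[np.ndarray] = None


@dataclass
class PointEvaluation:
    params: ModelParams
    observables: Optional[ObservableSet]
    across_run_cv: Dict[str, float]
    fits: Optional[DistributionFits]
    protocol_used: str  # "short" | "long"
    non_reversing: bool = False


@dataclass
class MatchVolume:
    """Grid points matching one observer's statistics."""

    #: records: (i0, beta, phi_a, sigma_n, tau_a, deviation) for the best
    #: hidden combination of each matched triplet
    matched_points: List[Dict[str, float]]
    center: Optional[np.ndarray]
    fraction_of_possible: float
    n_possible: int
    #: every matching (triplet, sigma_n, tau_a) combination, not just the
    #: best one per triplet
    matched_combos: List[Dict[str, float]] = field(default_factory=list)

    @property
    def matched_triplets(self) -> List[Tuple[float, float, float]]:
        return [(m["i0"], m["beta"], m["phi_a"]) for m in self.matched_points]


def _point_seed(root: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(root) & 0x7FFFFFFF, *map(int, indices)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def regime_map(grid: GridSpec, duration: float = 600.0, dt: float = 0.001
               ) -> Dict[Tuple[float, float, float], str]:
    """Noiseless regime label for every (i0, beta, phi_a) triplet.

    Points meeting none of the three criteria within tolerance are labelled
    ``unclassifiable`` and excluded from the possible volume downstream.
    """
    labels = {}
    for (i0, beta, phi_a) in grid.triplets():
        params = ModelParams(beta=beta, phi_a=phi_a, i0=i0, sigma_n=0.0, tau_a=1.0)
        try:
            labels[(i0, beta, phi_a)] = classify_regime(params, duration=duration, dt=dt)
        except UnclassifiableRegimeError:
            labels[(i0, beta, phi_a)] = "unclassifiable"
    return labels


def _trim_simulated(seq: ReversalSequence) -> ReversalSequence:
    """Drop the pre-first-crossing mixed segment (and rebase onsets).

    Mirrors the trimming applied to human reports: statistics start at the
    first clear dominance onset.  Incomplete final periods are already
    excluded from statistics via their flag.
    """
    from .sequences import Interval
    blocks = []
    for block in seq.blocks:
        ivs = [iv for iv in block if not (iv.state == "mixed" and iv.onset == block[0].onset)]
        if ivs:
            shift = ivs[0].onset
            ivs = [Interval(iv.state, iv.onset - shift, iv.duration, iv.complete)
                   for iv in ivs]
        blocks.append(ivs)
    return ReversalSequence(blocks)


def _run_observables(params: ModelParams, duration: float, dt: float,
                     seed: int, tau_grid) -> Tuple[Optional[ObservableSet], np.ndarray]:
    proto = SimProtocol(duration=duration, dt=dt, seed=seed,
                        initial_state=ASYMMETRIC_INIT)
    seq = _trim_simulated(simulate_reversals(params, proto))
    durations = seq.dominance_durations()
    try:
        obs = compute_observables(seq, tau_grid)
    except InsufficientDataError:
        obs = None
    return obs, durations


def evaluate_point(params: ModelParams, protocol: ScanProtocol = ScanProtocol(),
                   seed: int = 0) -> PointEvaluation:
    """Simulated observables at one parameter point, averaged across runs.

    Runs the short protocol; escalates to the long protocol when the
    across-run coefficient of variation of any observable exceeds the
    escalation threshold (or when some but not all short runs produced too
    few reversals to score).  Points where no run produces at least two
    dominance periods are flagged non-reversing.
    """
    tau_grid = protocol.tau_grid
    if tau_grid is None:
        tau_grid = default_tau_grid()

    def run_batch(n_runs, duration, salt):
        obs_list, dur_list = [], []
        for r in range(n_runs):
            obs, durs = _run_observables(params, duration, protocol.dt,
                                         _point_seed(seed, salt, r), tau_grid)
            obs_list.append(obs)
            dur_list.append(durs)
        return obs_list, dur_list

    def summarize(obs_list, dur_list, label):
        ok = [o for o in obs_list if o is not None]
        if not ok:
            return PointEvaluation(params, None, {}, None, label,
                                   non_reversing=True)
        cv = {}
        for stat in MATCH_STATS:
            vals = np.array([getattr(o, stat) for o in ok])
            m = vals.mean()
            cv[stat] = float(vals.std(ddof=1) / m) if (len(vals) > 1 and m != 0) else 0.0
        mean_obs = ObservableSet(
            t_dom=float(np.mean([o.t_dom for o in ok])),
            c_v=float(np.mean([o.c_v for o in ok])),
            c_h=float(np.mean([o.c_h for o in ok])),
            tau_h=float(np.mean([o.tau_h for o in ok])),
            balance=float(np.mean([o.balance for o in ok])),
            n_periods=int(np.sum([o.n_periods for o in ok])),
        )
        pooled = np.concatenate(dur_list) if dur_list else np.empty(0)
        fits = (fit_distributions(pooled)
                if pooled.size >= 10 and np.std(pooled) > 0 else None)
        incomplete = len(ok) < len(obs_list)
        return PointEvaluation(params, mean_obs, cv, fits, label,
                               non_reversing=False), incomplete

    obs_list, dur_list = run_batch(protocol.n_short, protocol.t_short, salt=0)
    short = summarize(obs_list, dur_list, "short")
    if isinstance(short, PointEvaluation):  # all runs non-reversing
        return short
    evaluation, incomplete = short
    needs_long = incomplete or any(v > protocol.escalation_cv
                                   for v in evaluation.across_run_cv.values())
    if not needs_long:
        return evaluation
    obs_list, dur_list = run_batch(protocol.n_long, protocol.t_long, salt=1)
    long_eval = summarize(obs_list, dur_list, "long")
    if isinstance(long_eval, PointEvaluation):
        return long_eval
    return long_eval[0]


def is_match(pred: ObservableSet, emp: ObservableSet, tol: float = 0.25) -> bool:
    """All four statistics within a fractional tolerance of the observer's.

    Inclusive at the boundary: |pred - emp| / emp <= tol for each of T_dom,
    C_v, c_H and tau_H.
    """
    p = pred.matching_vector()
    e = emp.matching_vector()
    if np.any(e == 0):
        raise InvalidParameterError("empirical observables must be non-zero")
    return bool(np.all(np.abs(p - e) / np.abs(e) <= tol))


def _relative_deviation(pred: ObservableSet, emp: ObservableSet) -> float:
    p = pred.matching_vector()
    e = emp.matching_vector()
    return float(np.sum(np.abs(p - e) / np.abs(e)))


def classify_humanlike(fits: DistributionFits,
                       shape_range: Tuple[float, float] = (3.1, 4.3),
                       min_p: float = 0.7) -> bool:
    """Human-like duration distribution: Gamma-shaped, Gamma fitting best.

    True iff the fitted Gamma shape lies in ``shape_range``, the Gamma KS
    p-value exceeds ``min_p``, and the Gamma KS p-value exceeds those of the
    exponential and Gaussian fits.
    """
    shape = fits.gamma_shape
    p_g = fits.gamma.ks_p
    return bool(shape_range[0] <= shape <= shape_range[1] and p_g > min_p
                and p_g > fits.exponential.ks_p and p_g > fits.gaussian.ks_p)


def _probe_t_dom(params: ModelParams, duration: float, dt: float,
                 seed: int) -> Tuple[float, int]:
    """Mean dominance time and period count of a single run (array path)."""
    proto = SimProtocol(duration=duration, dt=dt, seed=seed,
                        initial_state=ASYMMETRIC_INIT)
    _, onsets = reversal_events(params, proto)
    if onsets.size < 2:
        return np.nan, max(0, onsets.size - 1)
    d = np.diff(onsets)
    return float(d.mean()), int(d.size)


def scan_grid(grid: GridSpec, emp: ObservableSet,
              regimes: Dict[Tuple[float, float, float], str],
              seed: int = 0, protocol: ScanProtocol = ScanProtocol(),
              tol: float = 0.25,
              prefilter_factor: Optional[float] = 3.0) -> MatchVolume:
    """Assemble the matching volume of one observer over the grid.

    A triplet is matched if any (sigma_n, tau_a) combination matches; the
    best combination (minimal summed relative deviation over the four
    statistics) is recorded per matched triplet.  The possible volume is the
    set of triplets whose noiseless regime is bistable or oscillatory.

    ``prefilter_factor`` enables two screens that skip work a matching
    combination cannot need: (1) a single short probe run drops hidden
    combinations whose mean dominance time deviates from the observer's by
    more than ``prefilter_factor * tol``; (2) escalation to the long
    protocol is skipped when the short-protocol means of T_dom or C_v
    already deviate by more than half that factor.  Both screens only drop
    combinations far outside the match band; set ``prefilter_factor`` to
    None to evaluate every combination with the full protocol.
    """
    possible = [t for t in grid.triplets()
                if regimes.get(t) in ("bistable", "oscillatory")]
    if not possible:
        raise ConfigurationError("possible volume is empty (no bistable or "
                                 "oscillatory triplets in the regime map)")
    probe_t = min(protocol.t_short, 250.0)
    # skipping a combination with < 2 probe periods is safe only when a
    # truly matching point would produce many periods in a probe run
    skip_sparse = probe_t >= 10 * emp.t_dom * (1 + tol)
    no_escalation = ScanProtocol(
        n_short=protocol.n_short, t_short=protocol.t_short,
        n_long=protocol.n_long, t_long=protocol.t_long,
        escalation_cv=np.inf, dt=protocol.dt, tau_grid=protocol.tau_grid)
    matched = []
    combos = []
    for t_idx, (i0, beta, phi_a) in enumerate(possible):
        best = None
        for s_idx, sigma_n in enumerate(grid.sigma_n_axis):
            for a_idx, tau_a in enumerate(grid.tau_a_axis):
                params = ModelParams(beta=beta, phi_a=phi_a, i0=i0,
                                     sigma_n=sigma_n, tau_a=tau_a)
                point_seed = _point_seed(seed, t_idx, s_idx, a_idx)
                if prefilter_factor is not None:
                    t_hat, n = _probe_t_dom(params, probe_t, protocol.dt,
                                            _point_seed(point_seed, 99))
                    if n < 2:
                        if skip_sparse:
                            continue
                    elif abs(t_hat - emp.t_dom) / emp.t_dom > prefilter_factor * tol:
                        continue
                    # short protocol first; escalate only if the cheap
                    # statistics are still near the match band
                    ev = evaluate_point(params, no_escalation, seed=point_seed)
                    if ev.non_reversing or ev.observables is None:
                        continue
                    gate = prefilter_factor / 2 * tol
                    o = ev.observables
                    if (abs(o.t_dom - emp.t_dom) / emp.t_dom > gate
                            or abs(o.c_v - emp.c_v) / emp.c_v > gate):
                        continue
                    if (ev.protocol_used == "short"
                            and any(v > protocol.escalation_cv
                                    for v in ev.across_run_cv.values())):
                        ev = evaluate_point(params, protocol, seed=point_seed)
                else:
                    ev = evaluate_point(params, protocol, seed=point_seed)
                if ev.non_reversing or ev.observables is None:
                    continue
                if ev.observables.c_h is None:
                    continue
                if is_match(ev.observables, emp, tol):
                    dev = _relative_deviation(ev.observables, emp)
                    rec = {"i0": i0, "beta": beta, "phi_a": phi_a,
                           "sigma_n": float(sigma_n), "tau_a": float(tau_a),
                           "deviation": dev}
                    combos.append(rec)
                    if best is None or dev < best["deviation"]:
                        best = rec
        if best is not None:
            matched.append(best)

    center = (np.mean([[m["i0"], m["beta"], m["phi_a"]] for m in matched], axis=0)
              if matched else None)
    return MatchVolume(matched_points=matched, center=center,
                       fraction_of_possible=len(matched) / len(possible),
                       n_possible=len(possible), matched_combos=combos)


def volume_summary(vol: MatchVolume) -> Tuple[np.ndarray, float]:
    """Center (mean parameter vector of matched triplets) and fraction."""
    if not vol.matched_points:
        raise EmptyVolumeError("matching volume is empty")
    return vol.center, vol.fraction_of_possible


def humanlike_volume(grid: GridSpec,
                     regimes: Optional[Dict[Tuple[float, float, float], str]] = None,
                     seed: int = 0, duration: float = 500.0, dt: float = 0.001
                     ) -> Tuple[float, Dict[Tuple[float, float, float], bool]]:
    """Fraction of the possible volume with human-like duration distributions.

    For every bistable or oscillatory triplet, each (sigma_n, tau_a)
    combination is simulated once for ``duration`` seconds; the triplet
    counts as human-like if any combination passes
    :func:`classify_humanlike`.  Returns the percentage of the possible
    volume and the per-triplet flags.
    """
    if regimes is None:
        regimes = regime_map(grid, dt=dt)
    possible = [t for t in grid.triplets()
                if regimes.get(t) in ("bistable", "oscillatory")]
    if not possible:
        raise ConfigurationError("possible volume is empty")
    flags = {}
    for t_idx, (i0, beta, phi_a) in enumerate(possible):
        humanlike = False
        for s_idx, sigma_n in enumerate(grid.sigma_n_axis):
            for a_idx, tau_a in enumerate(grid.tau_a_axis):
                params = ModelParams(beta=beta, phi_a=phi_a, i0=i0,
                                     sigma_n=sigma_n, tau_a=tau_a)
                proto = SimProtocol(duration=duration, dt=dt,
                                    seed=_point_seed(seed, t_idx, s_idx, a_idx),
                                    initial_state=ASYMMETRIC_INIT)
                _, onsets = reversal_events(params, proto)
                durations = np.diff(onsets)
                if durations.size < 10 or np.std(durations) == 0:
                    continue
                if classify_humanlike(fit_distributions(durations)):
                    humanlike = True
                    break
            if humanlike:
                break
        flags[(i0, beta, phi_a)] = humanlike
    percent = 100.0 * sum(flags.values()) / len(possible)
    return percent, flags
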