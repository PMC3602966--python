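"""Stability/sensitivity analysis: frequency resonance and the sweet spot.

Stability is measured as the mean dominance duration without perturbation;
sensitivity as the resonance coefficient P1 — the multiplicative increase of
dominance-duration probability mass near the modulation half-period when the
two inputs are modulated sinusoidally in anti-phase at the best resonance
period (twice the unperturbed mean dominance time).  The functional sweet
spot is the intersection of the stable (T_dom >= 1 s) and sensitive
(P1 >= 1.2) volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import ConfigurationError
from .lc_model import simulate_reversals
from .param_scan import GridSpec, MatchVolume, _point_seed, _trim_simulated
from .params import ASYMMETRIC_INIT, InputModulation, ModelParams, SimProtocol

__all__ = [
    "ResonanceResult",
    "SweetSpotMap",
    "resonance_at_point",
    "resonance_map",
    "stability_mask",
    "sweet_spot",
    "overlap_fraction",
]

#: resonance protocol constants: medium noise, fast adaptation,
#: modulation amplitude as a fraction of I0
RESONANCE_SIGMA_N = 0.15
RESONANCE_TAU_A = 1.0
MODULATION_FRACTION = 0.2

#: window of the P1 integral, as multiples of the half-period HP; a
#: symmetric multiplicative band around HP that excludes the 3*HP harmonic
P1_WINDOW = (2.0 / 3.0, 1.5)

#: histogram bin width for the retained diagnostic histograms, as a fraction
#: of HP
HIST_BIN_FRACTION = 1.0 / 20.0

#: minimum dominance periods per run for a reliable P1
MIN_PERIODS = 50

STABILITY_THRESHOLD = 1.0   # seconds, inclusive
SENSITIVITY_THRESHOLD = 1.2  # P1, inclusive


@dataclass
class ResonanceResult:
    t_dom_unperturbed: float
    hp: float                       # modulation half-period (seconds)
    p1: float
    p_ref: Tuple[np.ndarray, np.ndarray]  # (density, bin edges)
    p_res: Tuple[np.ndarray, np.ndarray]
    n_ref: int
    n_res: int
    reliable: bool


@dataclass
class SweetSpotMap:
    """Per-triplet stability and sensitivity masks and their intersection."""

    t_dom: Dict[Tuple[float, float, float], float]
    p1: Dict[Tuple[float, float, float], float]
    stable: Dict[Tuple[float, float, float], bool]
    sensitive: Dict[Tuple[float, float, float], bool]

    @property
    def sweet(self) -> Dict[Tuple[float, float, float], bool]:
        return {t: self.stable[t] and self.sensitive[t] for t in self.stable}


def _durations(params: ModelParams, duration: float, dt: float, seed: int,
               modulation: Optional[InputModulation]) -> np.ndarray:
    proto = SimProtocol(duration=duration, dt=dt, seed=seed,
                        initial_state=ASYMMETRIC_INIT, modulation=modulation)
    seq = _trim_simulated(simulate_reversals(params, proto))
    return seq.dominance_durations()


def resonance_at_point(params: ModelParams, seed: int = 0,
                       duration: float = 4000.0, dt: float = 0.001,
                       modulation_fraction: float = MODULATION_FRACTION,
                       period_factor: float = 2.0) -> ResonanceResult:
    """Resonance coefficient P1 at one (i0, beta, phi_a) point.

    Two runs under the resonance protocol (sigma_n = 0.15, tau_a = 1 s): one
    unmodulated run yields the reference duration distribution P_ref and the
    mean dominance time; one run modulated in anti-phase at the best
    resonance period ``T_s = 2 <T_dom>`` yields the distorted distribution
    P_res.  P1 is the ratio of probability mass in the window
    ``[2/3 HP, 3/2 HP]`` around the half-period ``HP = T_s / 2``.  Fewer
    than 50 dominance periods in either run flags the result unreliable.
    ``period_factor`` shifts the modulation period away from resonance
    (T_s = period_factor * <T_dom>); the P1 window stays anchored at the
    unperturbed mean duration, where the resonance peak would appear.
    """
    p = params.replace(sigma_n=RESONANCE_SIGMA_N, tau_a=RESONANCE_TAU_A)
    ref = _durations(p, duration, dt, _point_seed(seed, 0), None)
    if ref.size < 2:
        nanh = (np.empty(0), np.empty(1))
        return ResonanceResult(np.nan, np.nan, np.nan, nanh, nanh,
                               int(ref.size), 0, reliable=False)
    t_dom = float(np.mean(ref))
    hp = t_dom  # at resonance, T_s = 2*T_dom and HP = T_s/2 = T_dom
    mod = InputModulation(amplitude=modulation_fraction * p.i0,
                          period=period_factor * t_dom)
    res = _durations(p, duration, dt, _point_seed(seed, 1), mod)

    lo, hi = P1_WINDOW[0] * hp, P1_WINDOW[1] * hp
    mass_ref = np.mean((ref >= lo) & (ref <= hi)) if ref.size else 0.0
    mass_res = np.mean((res >= lo) & (res <= hi)) if res.size else 0.0
    p1 = float(mass_res / mass_ref) if mass_ref > 0 else np.nan

    bin_w = HIST_BIN_FRACTION * hp
    upper = max(ref.max() if ref.size else hp, res.max() if res.size else hp, 3.5 * hp)
    edges = np.arange(0, upper + bin_w, bin_w)
    h_ref = np.histogram(ref, bins=edges, density=True)[0] if ref.size else np.zeros(len(edges) - 1)
    h_res = np.histogram(res, bins=edges, density=True)[0] if res.size else np.zeros(len(edges) - 1)

    reliable = ref.size >= MIN_PERIODS and res.size >= MIN_PERIODS and mass_ref > 0
    return ResonanceResult(t_dom, hp, p1, (h_ref, edges), (h_res, edges),
                           int(ref.size), int(res.size), reliable)


def resonance_map(grid: GridSpec, seed: int = 0, duration: float = 4000.0,
                  dt: float = 0.001) -> Dict[Tuple[float, float, float], ResonanceResult]:
    """Resonance evaluation at every triplet of the grid."""
    out = {}
    for t_idx, (i0, beta, phi_a) in enumerate(grid.triplets()):
        params = ModelParams(beta=beta, phi_a=phi_a, i0=i0)
        out[(i0, beta, phi_a)] = resonance_at_point(
            params, seed=_point_seed(seed, t_idx), duration=duration, dt=dt)
    return out


def stability_mask(grid_evals: Dict[Tuple[float, float, float], ResonanceResult]
                   ) -> Dict[Tuple[float, float, float], bool]:
    """Stable iff the unperturbed mean dominance time is >= 1 s (inclusive)."""
    return {t: bool(np.isfinite(ev.t_dom_unperturbed)
                    and ev.t_dom_unperturbed >= STABILITY_THRESHOLD)
            for t, ev in grid_evals.items()}


def sweet_spot(grid_evals: Dict[Tuple[float, float, float], ResonanceResult]
               ) -> SweetSpotMap:
    """Intersect the stability and sensitivity masks into the sweet spot."""
    stable = stability_mask(grid_evals)
    sensitive = {t: bool(np.isfinite(ev.p1) and ev.p1 >= SENSITIVITY_THRESHOLD)
                 for t, ev in grid_evals.items()}
    return SweetSpotMap(
        t_dom={t: ev.t_dom_unperturbed for t, ev in grid_evals.items()},
        p1={t: ev.p1 for t, ev in grid_evals.items()},
        stable=stable, sensitive=sensitive)


def overlap_fraction(vol: MatchVolume, sweet_map: SweetSpotMap) -> float:
    """Fraction of matched triplets lying inside the sweet spot."""
    sweet = sweet_map.sweet
    triplets = vol.matched_triplets
    if not triplets:
        raise ConfigurationError("matching volume is empty")
    missing = [t for t in triplets if t not in sweet]
    if missing:
        raise ConfigurationError(
            f"grid mismatch: {len(missing)} matched triplets absent from the "
            f"sweet-spot map (e.g. {missing[0]})")
    return float(np.mean([sweet[t] for t in triplets]))
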