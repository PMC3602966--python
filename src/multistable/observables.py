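"""Reversal-sequence statistics: dominance distribution, distribution fits,
and the cumulative-history analysis.

Four statistics summarise a reversal sequence and are used to match model
parameters to observers:

- ``T_dom``: mean duration of clear dominance periods;
- ``C_v``: coefficient of variation of those durations (sample denominator);
- ``c_H``: peak mean absolute correlation between the cumulative history of a
  percept at period onset and the log-duration of the subsequent period;
- ``tau_H``: the leaky-integrator time constant at which that peak occurs.

The cumulative history ``H_x(t)`` integrates the dominance record
``S_x(t)`` (1 while x dominates, 0.5 during mixed/patchy appearance,
0 otherwise) through ``tau_H * dH_x/dt = -H_x + S_x`` with ``H_x(0) = 0``
per block; it measures how long and how recently percept x dominated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError
from .sequences import Interval, ReversalSequence

__all__ = [
    "ObservableSet",
    "DistributionFits",
    "HistoryTrace",
    "dominance_statistics",
    "fit_distributions",
    "cumulative_history",
    "history_correlation_at_tau",
    "history_scan",
    "shuffle_sequence",
    "history_null",
    "compute_observables",
    "default_tau_grid",
]

#: number of points of the default logarithmic tau_H scan grid on [0.01, 60] s
_TAU_GRID_SIZE = 60
_TAU_MIN, _TAU_MAX = 0.01, 60.0

#: minimum (onset, duration) pairs per history/percept combination
_MIN_PAIRS = 10


def default_tau_grid() -> np.ndarray:
    """60 logarithmically spaced integrator time constants on [0.01, 60] s."""
    return np.geomspace(_TAU_MIN, _TAU_MAX, _TAU_GRID_SIZE)


@dataclass(frozen=True)
class ObservableSet:
    """The matching statistics of one reversal sequence (or one observer)."""

    t_dom: float
    c_v: float
    c_h: Optional[float] = None
    tau_h: Optional[float] = None
    balance: Optional[float] = None
    n_periods: Optional[int] = None

    @property
    def gamma_h(self) -> Optional[float]:
        """tau_H expressed as a multiple of T_dom."""
        if self.tau_h is None:
            return None
        return self.tau_h / self.t_dom

    def matching_vector(self) -> np.ndarray:
        """(T_dom, C_v, c_H, tau_H) as an array; raises if history is unset."""
        if self.c_h is None or self.tau_h is None:
            raise InsufficientDataError("history statistics not available")
        return np.array([self.t_dom, self.c_v, self.c_h, self.tau_h])


@dataclass(frozen=True)
class FitResult:
    params: Tuple[float, ...]
    ks_stat: float
    ks_p: float


@dataclass(frozen=True)
class DistributionFits:
    """Maximum-likelihood Gamma / exponential / Gaussian fits with KS tests.

    ``gamma.params`` is (shape, rate); ``exponential.params`` is (rate,);
    ``gaussian.params`` is (mean, sd).
    """

    gamma: FitResult
    exponential: FitResult
    gaussian: FitResult

    @property
    def gamma_shape(self) -> float:
        return self.gamma.params[0]


def dominance_statistics(seq: ReversalSequence) -> Tuple[float, float, float, int]:
    """Mean dominance time, coefficient of variation, balance, period count.

    Only complete, uniform (A/B) dominance periods enter; mixed intervals and
    incomplete final periods are excluded.  ``C_v`` uses the sample (N-1)
    denominator; ``balance`` is the total dominance time of percept A divided
    by the total dominance time of both percepts.
    """
    durations = seq.dominance_durations()
    if durations.size < 2:
        raise InsufficientDataError(
            f"need >= 2 complete dominance periods, got {durations.size}")
    t_dom = float(np.mean(durations))
    c_v = float(np.std(durations, ddof=1) / t_dom)
    t_a = sum(iv.duration for _, iv in seq.iter_intervals()
              if iv.state == "A" and iv.complete)
    t_b = sum(iv.duration for _, iv in seq.iter_intervals()
              if iv.state == "B" and iv.complete)
    balance = t_a / (t_a + t_b)
    return t_dom, c_v, balance, int(durations.size)


def fit_distributions(periods: Sequence[float]) -> DistributionFits:
    """Fit Gamma, exponential and Gaussian distributions to dominance periods.

    Fits are maximum likelihood (Gamma and exponential anchored at zero);
    goodness of fit is a KS test against each fitted distribution.
    """
    data = np.asarray(periods, dtype=float)
    if data.size < 10:
        raise InsufficientDataError(f"need >= 10 periods to fit, got {data.size}")
    if np.std(data) == 0:
        raise DegenerateFitError("zero-variance sample")

    a, _, scale = stats.gamma.fit(data, floc=0)
    ks_g = stats.kstest(data, "gamma", args=(a, 0, scale))
    gamma = FitResult((float(a), 1.0 / float(scale)), ks_g.statistic, ks_g.pvalue)

    _, escale = stats.expon.fit(data, floc=0)
    ks_e = stats.kstest(data, "expon", args=(0, escale))
    expon = FitResult((1.0 / float(escale),), ks_e.statistic, ks_e.pvalue)

    mu, sd = stats.norm.fit(data)
    ks_n = stats.kstest(data, "norm", args=(mu, sd))
    gauss = FitResult((float(mu), float(sd)), ks_n.statistic, ks_n.pvalue)

    return DistributionFits(gamma=gamma, exponential=expon, gaussian=gauss)


# ---------------------------------------------------------------------------
# cumulative history
# ---------------------------------------------------------------------------

def _signal_values(codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-interval S_A and S_B values (1 dominant, 0.5 mixed, 0 otherwise)."""
    s_a = np.where(codes == 0, 1.0, np.where(codes == 2, 0.5, 0.0))
    s_b = np.where(codes == 1, 1.0, np.where(codes == 2, 0.5, 0.0))
    return s_a, s_b


def _history_boundaries(durations: np.ndarray, s: np.ndarray,
                        taus: np.ndarray) -> np.ndarray:
    """Exact piecewise-constant history at interval boundaries.

    Returns an (n_tau, n_intervals + 1) array; column j holds H at the onset
    of interval j (column -1 is the block end).  Uses the closed-form update
    ``H(t + d) = S + (H(t) - S) * exp(-d / tau)`` per interval.
    """
    n_int = durations.size
    decays = np.exp(-durations[None, :] / taus[:, None])
    h = np.zeros((taus.size, n_int + 1))
    for j in range(n_int):
        h[:, j + 1] = s[j] + (h[:, j] - s[j]) * decays[:, j]
    return h


@dataclass
class HistoryTrace:
    """Cumulative history of both percepts, sampled at interval boundaries."""

    tau_h: float
    #: per block: onsets of intervals plus the block end time
    boundaries: List[np.ndarray]
    #: per block: H_A at each boundary
    h_a: List[np.ndarray]
    #: per block: H_B at each boundary
    h_b: List[np.ndarray]


def cumulative_history(seq: ReversalSequence, tau_h: float) -> HistoryTrace:
    """Leaky-integrated dominance history of both percepts, per block.

    ``H_x`` starts at 0 at each block onset and is propagated exactly across
    the piecewise-constant dominance record.  Without mixed intervals the two
    histories satisfy ``H_A + H_B -> 1`` with residual ``exp(-t/tau_h)``.
    """
    if tau_h <= 0:
        raise InsufficientDataError(f"tau_h must be > 0, got {tau_h}")
    taus = np.array([tau_h])
    boundaries, has, hbs = [], [], []
    for b in range(len(seq.blocks)):
        codes, onsets, durations, _ = seq.block_arrays(b)
        s_a, s_b = _signal_values(codes)
        has.append(_history_boundaries(durations, s_a, taus)[0])
        hbs.append(_history_boundaries(durations, s_b, taus)[0])
        boundaries.append(np.append(onsets, onsets[-1] + durations[-1]))
    return HistoryTrace(tau_h, boundaries, has, hbs)


def _history_pairs(seq: ReversalSequence, taus: np.ndarray):
    """Pool (H_A, H_B, ln T, percept) across blocks at dominance-period onsets.

    Returns (h_a, h_b, ln_t, is_a) where h_a/h_b have shape
    (n_tau, n_periods); only complete uniform periods are used.
    """
    h_a_cols, h_b_cols, ln_t, is_a = [], [], [], []
    for b in range(len(seq.blocks)):
        codes, _, durations, complete = seq.block_arrays(b)
        s_a, s_b = _signal_values(codes)
        ha = _history_boundaries(durations, s_a, taus)
        hb = _history_boundaries(durations, s_b, taus)
        use = (codes < 2) & complete
        idx = np.flatnonzero(use)
        if idx.size:
            h_a_cols.append(ha[:, idx])
            h_b_cols.append(hb[:, idx])
            ln_t.append(np.log(durations[idx]))
            is_a.append(codes[idx] == 0)
    if not ln_t:
        return (np.empty((taus.size, 0)), np.empty((taus.size, 0)),
                np.empty(0), np.empty(0, dtype=bool))
    return (np.concatenate(h_a_cols, axis=1), np.concatenate(h_b_cols, axis=1),
            np.concatenate(ln_t), np.concatenate(is_a))


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each row of ``x`` and the vector ``y``.

    Degenerate rows (zero variance on either side) yield r = 0.
    """
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean()
    num = xm @ ym
    den = np.sqrt((xm ** 2).sum(axis=1) * (ym ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return r


def _mean_abs_correlation(seq: ReversalSequence, taus: np.ndarray) -> np.ndarray:
    """Mean |Pearson r| over the four history/percept combinations, per tau."""
    h_a, h_b, ln_t, is_a = _history_pairs(seq, taus)
    n_a = int(np.count_nonzero(is_a))
    n_b = int(np.count_nonzero(~is_a))
    if n_a < _MIN_PAIRS or n_b < _MIN_PAIRS:
        short = "A" if n_a < _MIN_PAIRS else "B"
        raise InsufficientDataError(
            f"combination with percept {short} periods has fewer than "
            f"{_MIN_PAIRS} (onset, duration) pairs (A: {n_a}, B: {n_b})")
    sel_a, sel_b = is_a, ~is_a
    combos = [
        _pearson_rows(h_a[:, sel_a], ln_t[sel_a]),  # H_A x T_A (own)
        _pearson_rows(h_b[:, sel_b], ln_t[sel_b]),  # H_B x T_B (own)
        _pearson_rows(h_a[:, sel_b], ln_t[sel_b]),  # H_A x T_B (other)
        _pearson_rows(h_b[:, sel_a], ln_t[sel_a]),  # H_B x T_A (other)
    ]
    return np.mean(np.abs(np.vstack(combos)), axis=0)


def history_correlation_at_tau(seq: ReversalSequence, tau_h: float) -> float:
    """Mean absolute history/log-duration correlation at one time constant."""
    return float(_mean_abs_correlation(seq, np.array([float(tau_h)]))[0])


def history_scan(seq: ReversalSequence,
                 tau_grid: Optional[np.ndarray] = None
                 ) -> Tuple[float, float, Tuple[np.ndarray, np.ndarray]]:
    """Scan integrator time constants and locate the correlation peak.

    Returns ``(c_H, tau_H, (tau_grid, curve))`` where ``c_H`` is the maximum
    mean absolute correlation over the grid and ``tau_H`` its argmax (ties
    broken toward smaller tau).
    """
    taus = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, float)
    curve = _mean_abs_correlation(seq, taus)
    best = int(np.argmax(curve))  # first occurrence = smallest tau on ties
    return float(curve[best]), float(taus[best]), (taus, curve)


def shuffle_sequence(seq: ReversalSequence, seed: int) -> ReversalSequence:
    """Shuffle control: resample dominance durations with replacement.

    Keeps each block's interval order, percept labels, mixed durations and
    complete flags; replaces every uniform dominance duration by a draw (with
    replacement) from the pooled complete dominance durations.  This destroys
    history-dependence while preserving the duration distribution.
    """
    pool = seq.dominance_durations()
    if pool.size < 2:
        raise InsufficientDataError("need >= 2 dominance periods to shuffle")
    rng = np.random.default_rng(seed)
    blocks = []
    for block in seq.blocks:
        t = block[0].onset if block else 0.0
        new_block = []
        for iv in block:
            dur = iv.duration if iv.state == "mixed" else float(rng.choice(pool))
            new_block.append(Interval(iv.state, t, dur, iv.complete))
            t += dur
        blocks.append(new_block)
    return ReversalSequence(blocks)


def history_null(seq: ReversalSequence, tau_grid: Optional[np.ndarray] = None,
                 n_shuffles: int = 200, seed: int = 0) -> np.ndarray:
    """Permutation null for ``c_H``: peak correlations of shuffled sequences."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = shuffle_sequence(seq, int(rng.integers(2 ** 31)))
        out[i] = history_scan(shuffled, tau_grid)[0]
    return out


def compute_observables(seq: ReversalSequence,
                        tau_grid: Optional[np.ndarray] = None) -> ObservableSet:
    """All matching statistics of a sequence (distribution + history)."""
    t_dom, c_v, balance, n = dominance_statistics(seq)
    c_h, tau_h, _ = history_scan(seq, tau_grid)
    return ObservableSet(t_dom=t_dom, c_v=c_v, c_h=c_h, tau_h=tau_h,
                         balance=balance, n_periods=n)
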