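"""Synthetic reversal-sequence generators with controlled statistics.

These generators emulate the structure of human reversal reports — strictly
alternating dominance with Gamma-like duration distributions, an optional
negative dependence of log-duration on the percept's own leaky-integrated
dominance history, and optional mixed ("patchy") interludes — so that the
statistics pipeline can be validated with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .sequences import Interval, ReversalSequence

__all__ = ["SynthConfig", "renewal_sequence", "history_coupled_sequence",
           "inject_patchiness"]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic generators.

    ``coupling_b`` scales how strongly the own-percept history at period
    onset suppresses the log-duration of that period (0 = renewal process);
    ``coupling_tau`` is the history integrator time constant; ``shape``
    controls duration variability (Gamma shape of the base draws).
    """

    n_blocks: int = 12
    block_length: float = 240.0
    mean_duration: float = 2.0
    shape: float = 4.0
    coupling_b: float = 0.0
    coupling_tau: float = 3.0
    patchy_prob: float = 0.0
    patchy_mean: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.shape <= 0:
            raise InvalidParameterError(f"shape must be > 0, got {self.shape}")
        if self.mean_duration <= 0 or self.block_length <= 0 or self.n_blocks < 1:
            raise InvalidParameterError("block geometry must be positive")
        if not 0 <= self.patchy_prob <= 1:
            raise InvalidParameterError("patchy_prob must be in [0, 1]")
        if self.coupling_b < 0:
            raise InvalidParameterError("coupling_b must be >= 0")
        if self.coupling_tau <= 0:
            raise InvalidParameterError("coupling_tau must be > 0")


def _fill_block(draw, block_length: float, start_state: int) -> list:
    """Fill one block with alternating periods from a duration sampler."""
    intervals = []
    t = 0.0
    state = start_state
    while t < block_length:
        dur = draw(state, t)
        if t + dur >= block_length:
            if block_length - t > 0:
                intervals.append(Interval("AB"[state], t, block_length - t,
                                          complete=False))
            break
        intervals.append(Interval("AB"[state], t, dur, complete=True))
        t += dur
        state = 1 - state
    return intervals


def renewal_sequence(cfg: SynthConfig) -> ReversalSequence:
    """Strictly alternating i.i.d. Gamma-duration sequence (no history).

    Durations are Gamma(shape, rate = shape / mean_duration); the final
    period of each block is truncated at the block end and flagged
    incomplete.  This is the null process of the shuffle control.
    """
    rng = np.random.default_rng(cfg.seed)
    scale = cfg.mean_duration / cfg.shape

    def draw(_state, _t):
        return float(rng.gamma(cfg.shape, scale))

    blocks = [_fill_block(draw, cfg.block_length, int(rng.integers(2)))
              for _ in range(cfg.n_blocks)]
    return ReversalSequence(blocks)


def history_coupled_sequence(cfg: SynthConfig) -> ReversalSequence:
    """Alternating sequence whose log-durations depend on cumulative history.

    Each new period of percept x has

        ln T = ln G - coupling_b * (H_x(onset) - 1/2)

    where ``G ~ Gamma(shape, rate = shape / mean_duration)`` — i.e. the
    renewal draw modulated multiplicatively by the centred own-percept
    history — and H is maintained by exact leaky integration with
    ``coupling_tau``.  At ``coupling_b -> 0`` the process reduces exactly to
    :func:`renewal_sequence`; centring the history at 1/2 leaves the mean
    duration unchanged in the symmetric steady state.
    """
    if cfg.coupling_b <= 0:
        raise InvalidParameterError(
            "coupling_b must be > 0 for a history-coupled sequence; "
            "use renewal_sequence for the uncoupled case")
    rng = np.random.default_rng(cfg.seed)
    scale = cfg.mean_duration / cfg.shape

    blocks = []
    for _ in range(cfg.n_blocks):
        h = [0.0, 0.0]  # H_A, H_B at current time; reset per block
        state = int(rng.integers(2))
        last_t = 0.0

        def draw(s, t, _h=h):
            # advance both histories across the gap since the last draw
            nonlocal last_t
            dt = t - last_t
            last_t = t
            # during that gap the *other* percept dominated (or nothing, at t=0)
            if dt > 0:
                other = 1 - s
                decay = np.exp(-dt / cfg.coupling_tau)
                _h[other] = 1.0 + (_h[other] - 1.0) * decay
                _h[s] = _h[s] * decay
            g = rng.gamma(cfg.shape, scale)
            return float(g * np.exp(-cfg.coupling_b * (_h[s] - 0.5)))

        last_t = 0.0
        blocks.append(_fill_block(draw, cfg.block_length, state))
    return ReversalSequence(blocks)


def inject_patchiness(seq: ReversalSequence, patchy_prob: float,
                      patchy_mean: float, seed: int = 0) -> ReversalSequence:
    """Insert mixed interludes at reversals with probability ``patchy_prob``.

    Inserted durations are exponential with mean ``patchy_mean``.  Subsequent
    onsets are shifted to preserve contiguity and each block is truncated at
    its original end time, so total block time is conserved; a truncated
    final interval is flagged incomplete.
    """
    if not 0 <= patchy_prob <= 1:
        raise InvalidParameterError("patchy_prob must be in [0, 1]")
    if patchy_prob == 0:
        return seq
    rng = np.random.default_rng(seed)
    blocks = []
    for block in seq.blocks:
        if not block:
            blocks.append([])
            continue
        block_end = block[-1].end
        items = []  # (state, duration)
        for j, iv in enumerate(block):
            items.append((iv.state, iv.duration))
            is_reversal = (j + 1 < len(block) and iv.state != "mixed"
                           and block[j + 1].state != "mixed")
            if is_reversal and rng.random() < patchy_prob:
                items.append(("mixed", float(rng.exponential(patchy_mean))))
        t = block[0].onset
        new_block = []
        for state, dur in items:
            if t >= block_end:
                break
            if t + dur >= block_end:
                new_block.append(Interval(state, t, block_end - t, complete=False))
                break
            new_block.append(Interval(state, t, dur, complete=True))
            t += dur
        blocks.append(new_block)
    return ReversalSequence(blocks)
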