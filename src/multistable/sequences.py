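"""Reversal sequences: the common currency between simulator, generators,
human-report ingestion and statistics.

A :class:`ReversalSequence` is an ordered list of blocks (independent
presentations); each block is a contiguous, non-overlapping list of
:class:`Interval` objects labelled ``A``, ``B`` (the two clear percepts) or
``mixed`` (patchy/transitional appearance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .errors import SequenceValidationError

__all__ = ["Interval", "ReversalSequence", "STATES"]

STATES = ("A", "B", "mixed")

#: tolerance for contiguity of intervals within a block (seconds)
CONTIGUITY_TOL = 1e-3


@dataclass(frozen=True)
class Interval:
    state: str
    onset: float
    duration: float
    complete: bool = True

    def __post_init__(self):
        if self.state not in STATES:
            raise SequenceValidationError(f"unknown state label {self.state!r}")
        if self.duration <= 0:
            raise SequenceValidationError(f"duration must be > 0, got {self.duration}")
        if self.onset < 0:
            raise SequenceValidationError(f"onset must be >= 0, got {self.onset}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class ReversalSequence:
    blocks: List[List[Interval]]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for b, block in enumerate(self.blocks):
            for j in range(1, len(block)):
                gap = block[j].onset - block[j - 1].end
                if abs(gap) > CONTIGUITY_TOL:
                    kind = "gap" if gap > 0 else "overlap"
                    raise SequenceValidationError(
                        f"block {b}: {kind} of {abs(gap):.4f} s between "
                        f"intervals {j - 1} and {j}"
                    )
            for j, iv in enumerate(block[:-1]):
                if not iv.complete:
                    raise SequenceValidationError(
                        f"block {b}: interval {j} flagged incomplete but is not last"
                    )

    # -- convenience accessors -------------------------------------------------

    def iter_intervals(self) -> Iterable[Tuple[int, Interval]]:
        for b, block in enumerate(self.blocks):
            for iv in block:
                yield b, iv

    def dominance_durations(self, states: Sequence[str] = ("A", "B")) -> np.ndarray:
        """Durations of *complete* clear dominance periods, pooled over blocks."""
        return np.array(
            [iv.duration for _, iv in self.iter_intervals()
             if iv.state in states and iv.complete],
            dtype=float,
        )

    @property
    def n_periods(self) -> int:
        return int(self.dominance_durations().size)

    def block_arrays(self, block: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """One block as (state_codes, onsets, durations, complete) arrays.

        State codes: 0 = A, 1 = B, 2 = mixed.
        """
        ivs = self.blocks[block]
        codes = np.array([STATES.index(iv.state) for iv in ivs], dtype=np.int64)
        onsets = np.array([iv.onset for iv in ivs], dtype=float)
        durations = np.array([iv.duration for iv in ivs], dtype=float)
        complete = np.array([iv.complete for iv in ivs], dtype=bool)
        return codes, onsets, durations, complete


def from_onsets(states: Sequence[str], onsets: Sequence[float], block_end: float,
                final_complete: bool = False) -> List[Interval]:
    """Build one contiguous block from interval onsets and a block end time."""
    onsets = list(onsets)
    intervals = []
    for j, (state, onset) in enumerate(zip(states, onsets)):
        end = onsets[j + 1] if j + 1 < len(onsets) else block_end
        complete = True if j + 1 < len(onsets) else final_complete
        intervals.append(Interval(state, onset, end - onset, complete))
    return intervals
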