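"""File formats and report trimming.

Reversal sequences travel as TSV with columns
``block, onset_s, duration_s, state, complete``; trajectories as TSV;
results as JSON; grid configurations as YAML.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import SequenceParseError, SequenceValidationError
from .param_scan import GridSpec
from .sequences import STATES, Interval, ReversalSequence

__all__ = ["read_sequence_file", "write_sequence_file", "trim_block",
           "read_grid_yaml", "ResultBundle", "write_trajectory"]

_COLUMNS = ["block", "onset_s", "duration_s", "state", "complete"]


def read_sequence_file(path: Union[str, Path]) -> ReversalSequence:
    """Read a reversal sequence from TSV, validating all invariants."""
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as a parse error
        raise SequenceParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SequenceParseError(f"{path}: missing columns {missing}")
    blocks: Dict[int, list] = {}
    for row in df.itertuples():
        line = row.Index + 2  # header + 1-based
        if row.state not in STATES:
            raise SequenceParseError(f"{path}:{line}: unknown state {row.state!r}")
        try:
            iv = Interval(str(row.state), float(row.onset_s),
                          float(row.duration_s), bool(int(row.complete)))
        except (ValueError, SequenceValidationError) as exc:
            raise SequenceParseError(f"{path}:{line}: {exc}") from exc
        blocks.setdefault(int(row.block), []).append(iv)
    ordered = [blocks[b] for b in sorted(blocks)]
    return ReversalSequence(ordered)  # validates contiguity


def write_sequence_file(seq: ReversalSequence, path: Union[str, Path]) -> None:
    rows = []
    for b, block in enumerate(seq.blocks):
        for iv in block:
            rows.append((b, repr(iv.onset), repr(iv.duration), iv.state,
                         int(iv.complete)))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def write_trajectory(traj, path: Union[str, Path]) -> None:
    pd.DataFrame({"time_s": traj.times, "r1": traj.r1, "r2": traj.r2,
                  "a1": traj.a1, "a2": traj.a2}).to_csv(path, sep="\t",
                                                        index=False)


def trim_block(seq: ReversalSequence, discard_initial: float = 60.0
               ) -> ReversalSequence:
    """Discard the initial transient of each block and the incomplete tail.

    Periods with onset before the cutoff are dropped whole (a period
    straddling the cutoff is removed, not truncated, to avoid biasing the
    variability of durations); the final incomplete period is dropped.
    Onsets are rebased so each trimmed block starts at 0.
    """
    blocks = []
    for b, block in enumerate(seq.blocks):
        if not block:
            blocks.append([])
            continue
        block_len = block[-1].end - block[0].onset
        if block_len < discard_initial:
            raise SequenceValidationError(
                f"block {b} is shorter ({block_len:.1f} s) than the "
                f"discard window ({discard_initial:.1f} s)")
        cutoff = block[0].onset + discard_initial
        kept = [iv for iv in block if iv.onset >= cutoff and iv.complete]
        if kept:
            shift = kept[0].onset
            kept = [Interval(iv.state, iv.onset - shift, iv.duration, iv.complete)
                    for iv in kept]
        blocks.append(kept)
    return ReversalSequence(blocks)


def read_grid_yaml(path: Union[str, Path]) -> GridSpec:
    """Grid axes from a YAML mapping (keys i0, beta, phi_a, sigma_n, tau_a)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    kw = {}
    for key, field in (("i0", "i0_axis"), ("beta", "beta_axis"),
                       ("phi_a", "phi_a_axis"), ("sigma_n", "sigma_n_axis"),
                       ("tau_a", "tau_a_axis")):
        if key in cfg:
            kw[field] = cfg[key]
    return GridSpec(**kw)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, dict):
            return o
        return super().default(o)


@dataclasses.dataclass
class ResultBundle:
    """A result payload plus the provenance needed to reproduce it."""

    kind: str
    payload: dict
    seed: Optional[int] = None
    parameters: Optional[dict] = None
    timestamp: Optional[str] = None

    def write(self, path: Union[str, Path]) -> None:
        doc = {"kind": self.kind, "seed": self.seed,
               "parameters": self.parameters,
               "timestamp": self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S"),
               "payload": self.payload}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, cls=_Encoder)

    @staticmethod
    def read(path: Union[str, Path]) -> "ResultBundle":
        with open(path) as fh:
            doc = json.load(fh)
        return ResultBundle(kind=doc["kind"], payload=doc["payload"],
                            seed=doc.get("seed"),
                            parameters=doc.get("parameters"),
                            timestamp=doc.get("timestamp"))
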