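"""Spike trains on a 1-ms grid, binned 0/1 sequences, and plain-text serialization.

A :class:`SpikeTrain` stores spike times as integer milliseconds on a grid of
length ``length_ms`` (at most one spike per step — absolute refractoriness at
the grid resolution). A :class:`BinnedTrain` is its temporally coded version:
non-overlapping windows of ``window_ms``, a window being high (1) iff it
contains at least one spike.

Two interchangeable text formats are provided for corpora of trains:

* line format — one train per line, ``episode,neuron,t1 t2 t3 ...``;
* table format — CSV with columns ``episode,neuron,t_ms`` (one row per spike).

Both carry ``length_ms`` in a header so files round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "SpikeTrain",
    "BinnedTrain",
    "write_trains_lines",
    "read_trains_lines",
    "write_trains_table",
    "read_trains_table",
]


@dataclass(frozen=True)
class SpikeTrain:
    """An ordered sequence of spike times on the integer 1-ms grid.

    Parameters
    ----------
    length_ms:
        Duration of the observation window (the episode length L).
    events:
        Strictly increasing integer spike times in ``[0, length_ms)``.
    """

    length_ms: int
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=np.int64)
        object.__setattr__(self, "events", ev)
        if self.length_ms <= 0:
            raise InputError(f"length_ms must be positive, got {self.length_ms}")
        if ev.size:
            if np.any(np.diff(ev) <= 0):
                raise InputError("spike times must be strictly increasing")
            if ev[0] < 0 or ev[-1] >= self.length_ms:
                raise InputError(
                    f"spike times must lie in [0, {self.length_ms}), "
                    f"got range [{ev[0]}, {ev[-1]}]"
                )

    @classmethod
    def from_binary(cls, vec: Sequence[int] | np.ndarray) -> "SpikeTrain":
        """Build a train from a 0/1 vector, one element per millisecond."""
        vec = np.asarray(vec)
        return cls(length_ms=len(vec), events=np.flatnonzero(vec))

    def to_binary(self) -> np.ndarray:
        """Return the train as a 0/1 uint8 vector of length ``length_ms``."""
        out = np.zeros(self.length_ms, dtype=np.uint8)
        out[self.events] = 1
        return out

    @property
    def n_spikes(self) -> int:
        return int(self.events.size)

    @property
    def rate_hz(self) -> float:
        """Mean firing rate over the episode, in Hz."""
        return 1000.0 * self.n_spikes / self.length_ms


@dataclass(frozen=True)
class BinnedTrain:
    """Temporally coded (digital) version of a spike train.

    ``bits[k]`` is 1 iff the half-open window ``[k*window_ms, (k+1)*window_ms)``
    of the source train contained at least one spike.
    """

    bits: np.ndarray
    window_ms: int

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        if bits.ndim != 1:
            raise InputError("bits must be one-dimensional")
        if np.any(bits > 1):
            raise InputError("bits must be 0 or 1")
        if self.window_ms <= 0:
            raise InputError(f"window_ms must be positive, got {self.window_ms}")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def events(self) -> np.ndarray:
        """Indices of the high bins (event times on the bin-index grid)."""
        return np.flatnonzero(self.bits)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_HEADER = "# dynsynrl-trains length_ms="


def write_trains_lines(
    path: str | Path, rows: Iterable[tuple[int, int, SpikeTrain]]
) -> None:
    """Write trains in the line format: ``episode,neuron,t1 t2 ...``."""
    rows = list(rows)
    if rows:
        lengths = {tr.length_ms for _, _, tr in rows}
        if len(lengths) != 1:
            raise InputError("all trains in one file must share length_ms")
        length = lengths.pop()
    else:
        length = 0
    with open(path, "w") as fh:
        fh.write(f"{_HEADER}{length}\n")
        for episode, neuron, train in rows:
            times = " ".join(str(t) for t in train.events)
            fh.write(f"{episode},{neuron},{times}\n")


def read_trains_lines(path: str | Path) -> list[tuple[int, int, SpikeTrain]]:
    rows: list[tuple[int, int, SpikeTrain]] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(_HEADER):
            raise InputError(f"{path}: not a dynsynrl spike-train file")
        length = int(header[len(_HEADER):])
        for line in fh:
            line = line.strip()
            if not line:
                continue
            episode_s, neuron_s, times_s = line.split(",", 2)
            times_s = times_s.strip()
            events = [int(tok) for tok in times_s.split()] if times_s else []
            rows.append((int(episode_s), int(neuron_s), SpikeTrain(length, events)))
    return rows


def write_trains_table(
    path: str | Path, rows: Iterable[tuple[int, int, SpikeTrain]]
) -> None:
    """Write trains as a long CSV table with columns episode, neuron, t_ms."""
    rows = list(rows)
    if rows:
        lengths = {tr.length_ms for _, _, tr in rows}
        if len(lengths) != 1:
            raise InputError("all trains in one file must share length_ms")
        length = lengths.pop()
    else:
        length = 0
    records = []
    for episode, neuron, train in rows:
        for t in train.events:
            records.append((episode, neuron, int(t)))
        if train.n_spikes == 0:  # keep empty trains representable
            records.append((episode, neuron, -1))
    frame = pd.DataFrame(records, columns=["episode", "neuron", "t_ms"])
    with open(path, "w") as fh:
        fh.write(f"{_HEADER}{length}\n")
        frame.to_csv(fh, index=False)


def read_trains_table(path: str | Path) -> list[tuple[int, int, SpikeTrain]]:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(_HEADER):
            raise InputError(f"{path}: not a dynsynrl spike-train file")
        length = int(header[len(_HEADER):])
        frame = pd.read_csv(fh)
    rows = []
    for (episode, neuron), grp in frame.groupby(["episode", "neuron"], sort=True):
        times = grp["t_ms"].to_numpy()
        times = np.sort(times[times >= 0])
        rows.append((int(episode), int(neuron), SpikeTrain(length, times)))
    return rows
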