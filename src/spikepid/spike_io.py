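"""Reading, writing and validating spike-train recordings.

A recording is a set of per-neuron spike-time lists (seconds) plus a total
duration. On disk it is a small delimited table with a header row
``neuron_id<sep>spike_time_s`` and optional ``# key=value`` metadata lines
(``duration_s``, ``label``) before the header. Tab and comma delimiters are
auto-detected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SpikeTableParseError, ValidationError

__all__ = ["Recording", "RateSummary", "read_spike_table", "write_spike_table", "rate_summary"]


@dataclass
class Recording:
    """Spike trains for a population of neurons.

    Parameters
    ----------
    spikes
        Mapping from integer neuron id to a sorted 1-D array of spike times
        in seconds. All times must lie in ``[0, duration]``.
    duration
        Recording length in seconds.
    label
        Free-text provenance string.
    """

    spikes: dict[int, np.ndarray]
    duration: float
    label: str = ""

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for nid, times in self.spikes.items():
            t = np.asarray(times, dtype=float).ravel()
            if t.size and (np.any(t < 0) or np.any(t > self.duration)):
                raise ValidationError(
                    f"neuron {nid}: spike times outside [0, {self.duration}]"
                )
            clean[int(nid)] = np.sort(t)
        self.spikes = clean
        if self.duration < 0:
            raise ValidationError("duration must be nonnegative")

    @property
    def neuron_ids(self) -> list[int]:
        return sorted(self.spikes)

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    def spike_counts(self) -> dict[int, int]:
        return {nid: int(t.size) for nid, t in self.spikes.items()}

    @property
    def n_spikes(self) -> int:
        return sum(t.size for t in self.spikes.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.duration == other.duration
            and self.label == other.label
            and self.neuron_ids == other.neuron_ids
            and all(np.array_equal(self.spikes[i], other.spikes[i]) for i in self.spikes)
        )


@dataclass
class RateSummary:
    """Per-neuron firing rates (spikes/s) and spike counts."""

    frame: pd.DataFrame = field(repr=False)  # columns: neuron_id, n_spikes, rate_hz
    duration: float = 0.0

    @property
    def rates(self) -> np.ndarray:
        return self.frame["rate_hz"].to_numpy()

    @property
    def total_spikes(self) -> int:
        return int(self.frame["n_spikes"].sum())


_HEADER = ("neuron_id", "spike_time_s")


def read_spike_table(path: str | Path) -> Recording:
    """Read a delimited spike table into a :class:`Recording`.

    Duration is taken from a ``# duration_s=...`` metadata line when present,
    otherwise from the maximum spike time rounded up to the next whole second.
    Unsorted input is sorted; a header-only file yields an empty recording.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_line = None
    n_meta = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#"):
                n_meta += 1
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            header_line = line
            break
    if header_line is None:
        raise SpikeTableParseError("file has no header row", n_meta or None)
    sep = "\t" if "\t" in header_line else ","
    cols = [c.strip() for c in header_line.split(sep)]
    if tuple(cols[:2]) != _HEADER:
        raise SpikeTableParseError(
            f"expected header {_HEADER!r}, got {cols!r}", n_meta + 1
        )

    df = pd.read_csv(
        path, sep=sep, comment="#", dtype=str, skipinitialspace=True,
        float_precision="round_trip",
    )
    offset = n_meta + 2  # 1-based line number of the first data row
    roster = [int(x) for x in meta["neuron_ids"].split(",")] if meta.get("neuron_ids") else []
    if df.empty:
        duration = float(meta.get("duration_s", 0.0))
        return Recording(
            {nid: np.empty(0) for nid in roster},
            duration=duration,
            label=meta.get("label", ""),
        )

    ids = pd.to_numeric(df["neuron_id"], errors="coerce")
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = ids.isna() | times.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SpikeTableParseError(
            f"malformed row {df.iloc[row].tolist()!r}", offset + row
        )
    if (ids % 1 != 0).any():
        row = int(np.flatnonzero((ids % 1 != 0).to_numpy())[0])
        raise SpikeTableParseError("neuron_id is not an integer", offset + row)
    # exact decimal -> float conversion (pandas' numeric parser is lossy)
    t = np.array([float(s) for s in df["spike_time_s"]], dtype=float)
    if np.any(t < 0):
        raise ValidationError("negative spike time in table")

    if "duration_s" in meta:
        duration = float(meta["duration_s"])
    else:
        duration = float(math.ceil(t.max())) if t.size else 0.0

    spikes = {
        int(nid): np.sort(t[ids.to_numpy() == nid])
        for nid in np.unique(ids.to_numpy().astype(int))
    }
    for nid in roster:
        spikes.setdefault(nid, np.empty(0))
    return Recording(spikes, duration=duration, label=meta.get("label", ""))


def write_spike_table(recording: Recording, path: str | Path, sep: str = "\t") -> None:
    """Write a :class:`Recording` so that :func:`read_spike_table` round-trips it."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# duration_s={recording.duration!r}\n")
        if recording.label:
            fh.write(f"# label={recording.label}\n")
        if recording.neuron_ids:
            # roster line lets silent (zero-spike) neurons survive a round trip
            fh.write(f"# neuron_ids={','.join(map(str, recording.neuron_ids))}\n")
        fh.write(sep.join(_HEADER) + "\n")
        for nid in recording.neuron_ids:
            for t in recording.spikes[nid]:
                fh.write(f"{nid}{sep}{float(t)!r}\n")


def rate_summary(recording: Recording) -> RateSummary:
    """Per-neuron firing rate = spike count / duration."""
    if recording.duration <= 0:
        raise ValidationError("duration must be positive to compute rates")
    rows = [
        (nid, recording.spikes[nid].size, recording.spikes[nid].size / recording.duration)
        for nid in recording.neuron_ids
    ]
    frame = pd.DataFrame(rows, columns=["neuron_id", "n_spikes", "rate_hz"])
    return RateSummary(frame=frame, duration=recording.duration)
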