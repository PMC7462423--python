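"""Discretization of spike times into binary state sequences.

The analysis runs at ten fixed timescales. Each timescale is a bin width
``w`` plus a set of source delays (in bins); together they define the window
of source history examined when computing delayed transfer entropy. The
three shortest timescales (centered on 3, 5 and 11 ms) cover windows where
monosynaptic interactions live; timescales 7-9 (centered on 225, 485 and
1044 ms) probe extrasynaptic, rate-covariation windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .spike_io import Recording

__all__ = ["TimescaleSpec", "BinnedRaster", "standard_timescales", "get_timescale", "bin_spikes"]


@dataclass(frozen=True)
class TimescaleSpec:
    """One analysis timescale: bin width plus the delay search set.

    ``span_ms`` is the window of source lags covered,
    ``(w * min(delays), w * max(delays))``. ``center_ms`` is the nominal
    label used when reporting; it is carried verbatim, not derived.
    """

    id: int
    bin_width_ms: float
    delays: tuple[int, ...]
    center_ms: float
    group: str  # synaptic | mid | extrasynaptic | longest

    def __post_init__(self) -> None:
        if not self.delays or list(self.delays) != sorted(set(self.delays)):
            raise ValidationError("delays must be nonempty, strictly increasing")
        if min(self.delays) < 1:
            raise ValidationError("delays must be positive")

    @property
    def span_ms(self) -> tuple[float, float]:
        return (self.bin_width_ms * self.delays[0], self.bin_width_ms * self.delays[-1])


# (bin width ms, max delay, center label ms, group); delays are 1..max.
_TIMESCALE_TABLE = [
    (0.05, 60, 3, "synaptic"),
    (1.6, 4, 5, "synaptic"),
    (3.5, 4, 11, "synaptic"),
    (7.5, 4, 23, "mid"),
    (16.15, 4, 48, "mid"),
    (34.8, 4, 104, "mid"),
    (75.0, 4, 225, "extrasynaptic"),
    (161.6, 4, 485, "extrasynaptic"),
    (348.1, 4, 1044, "extrasynaptic"),
    (750.0, 4, 2250, "longest"),
]


def standard_timescales() -> list[TimescaleSpec]:
    """The ten standard timescales, ids 1-10.

    Spans run from (0.05, 3) ms at timescale 1 up to (750, 3000) ms at
    timescale 10. All delay sets are 1..4 bins except timescale 1, whose
    0.05-ms bins carry delays 1..60 to reach the same 3-ms window.
    """
    return [
        TimescaleSpec(
            id=i + 1,
            bin_width_ms=w,
            delays=tuple(range(1, dmax + 1)),
            center_ms=center,
            group=group,
        )
        for i, (w, dmax, center, group) in enumerate(_TIMESCALE_TABLE)
    ]


def get_timescale(ts_id: int) -> TimescaleSpec:
    for spec in standard_timescales():
        if spec.id == ts_id:
            return spec
    raise ValidationError(f"no timescale with id {ts_id} (valid: 1-10)")


@dataclass
class BinnedRaster:
    """Binary occupancy raster: ``states[n, t]`` is 1 iff neuron ``n`` spiked
    in bin ``t``. Bins are half-open ``[k*w, (k+1)*w)``."""

    states: np.ndarray  # (n_neurons, n_bins) uint8
    bin_width_ms: float
    neuron_ids: list[int]

    @property
    def n_bins(self) -> int:
        return self.states.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.states.shape[0]

    def row(self, neuron_id: int) -> np.ndarray:
        return self.states[self.neuron_ids.index(neuron_id)]


def bin_times(times: np.ndarray, bin_width_ms: float, n_bins: int, out: np.ndarray | None = None) -> np.ndarray:
    """Binary-occupancy vector for one spike train. Spikes at or beyond
    ``n_bins * w`` are dropped (half-open final bin)."""
    if out is None:
        out = np.zeros(n_bins, dtype=np.uint8)
    else:
        out[:] = 0
    idx = np.floor(np.asarray(times) * 1000.0 / bin_width_ms).astype(np.int64)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    out[idx] = 1
    return out


def bin_spikes(recording: Recording, bin_width_ms: float, binary: bool = True) -> BinnedRaster:
    """Discretize every neuron at the given bin width.

    ``binary=True`` (the default, used throughout the analysis) records
    occupancy; ``binary=False`` records spike counts per bin, provided as a
    documented switch for coarse-bin sensitivity checks.
    """
    if bin_width_ms <= 0:
        raise ValidationError("bin width must be positive")
    w_s = bin_width_ms / 1000.0
    if recording.duration < w_s:
        raise ValidationError("recording shorter than one bin")
    n_bins = int(np.floor(recording.duration / w_s))
    ids = recording.neuron_ids
    dtype = np.uint8 if binary else np.int32
    states = np.zeros((len(ids), n_bins), dtype=dtype)
    for row, nid in enumerate(ids):
        idx = np.floor(recording.spikes[nid] * 1000.0 / bin_width_ms).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        if binary:
            states[row, idx] = 1
        else:
            np.add.at(states[row], idx, 1)
    return BinnedRaster(states=states, bin_width_ms=bin_width_ms, neuron_ids=list(ids))
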