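"""Jitter-surrogate significance testing and effective-network assembly.

An effective network at one timescale is the directed graph of neuron
pairs whose delayed transfer entropy exceeds what spike-time jittering of
the source can produce. Each spike of the source is displaced by a uniform
random offset wide enough to destroy coupling at the timescale's lags
while preserving slow rate structure; the observed TE (maximized over the
timescale's delay set) is compared against the same statistic on the
jittered trains. Triads are unordered pairs of senders with significant
edges onto a common receiver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .discretize import BinnedRaster, TimescaleSpec, bin_spikes, bin_times
from .errors import ConfigurationError, ValidationError
from .infodyn import (
    PIDResult,
    _h,
    _te_fast,
    mutual_information_norm,
    normalize_result,
    pid_decompose,
    timescale_te,
)
from .spike_io import Recording

__all__ = [
    "Edge",
    "EffectiveNetwork",
    "TriadRecord",
    "jitter_surrogate",
    "default_jitter_halfwindow_ms",
    "connection_significance",
    "build_effective_network",
    "enumerate_triads",
    "evaluate_triads",
    "triads_to_frame",
]


@dataclass(frozen=True)
class Edge:
    source: int
    target: int
    te: float  # bits
    te_norm: float  # proportion of receiver entropy
    peak_delay: int  # bins
    p_value: float


@dataclass
class EffectiveNetwork:
    """Directed graph of significant TE connections at one timescale."""

    timescale: TimescaleSpec
    neuron_ids: list[int]
    duration_s: float
    alpha: float
    n_jitter: int
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.source == e.target:
                raise ValidationError("self-edges are not allowed")
            if not (e.p_value < self.alpha):
                raise ValidationError("stored edges must be significant")

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.neuron_ids)
        for e in self.edges:
            g.add_edge(
                e.source, e.target,
                te=e.te, te_norm=e.te_norm, peak_delay=e.peak_delay, p_value=e.p_value,
            )
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.source, e.target, e.te, e.te_norm, e.peak_delay, e.p_value) for e in self.edges],
            columns=["source", "target", "te", "te_norm", "peak_delay_bins", "p_value"],
        )

    def edge_lookup(self) -> dict[tuple[int, int], Edge]:
        return {(e.source, e.target): e for e in self.edges}

    def write_edge_list(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_digraph(), path)


def jitter_surrogate(train, half_window_ms: float, rng: np.random.Generator, duration_s: float) -> np.ndarray:
    """Displace each spike independently by uniform(-hw, +hw), clip to
    [0, duration], re-sort. Spike count is preserved."""
    if half_window_ms <= 0:
        raise ValidationError("half window must be positive")
    t = np.asarray(train, dtype=float)
    hw = half_window_ms / 1000.0
    jittered = t + rng.uniform(-hw, hw, size=t.size)
    return np.sort(np.clip(jittered, 0.0, duration_s))


def default_jitter_halfwindow_ms(spec: TimescaleSpec) -> float:
    """Five times the timescale's maximum source lag: wide enough to wash
    out coupling anywhere in the delay window, narrow enough to keep
    slower rate fluctuations."""
    return 5.0 * spec.span_ms[1]


@dataclass(frozen=True)
class SignificanceResult:
    te: float
    peak_delay: int
    p_value: float
    significant: bool


def _max_te_states(src: np.ndarray, tgt: np.ndarray, delays) -> tuple[float, int]:
    best, best_d = -np.inf, delays[0]
    for d in delays:
        te = _te_fast(src, tgt, d)
        if te > best:
            best, best_d = te, d
    return best, best_d


def connection_significance(
    source_times,
    target_times,
    duration_s: float,
    spec: TimescaleSpec,
    n_jitter: int = 5000,
    alpha: float = 0.001,
    rng: np.random.Generator | None = None,
    half_window_ms: float | None = None,
    _target_states: np.ndarray | None = None,
) -> SignificanceResult:
    """Test one directed connection against the jitter null.

    The observed statistic is TE maximized over the timescale's delays.
    The null repeats the same delay search with the source jittered and
    the target fixed. The p-value uses the add-one rank estimator
    ``(1 + #{null >= observed}) / (1 + n_jitter)`` so it is never zero.
    """
    if n_jitter < 1.0 / alpha - 1.0:
        raise ConfigurationError(
            f"n_jitter={n_jitter} cannot resolve alpha={alpha}; need >= {1.0/alpha - 1.0:.0f}"
        )
    rng = rng if rng is not None else np.random.default_rng()
    w = spec.bin_width_ms
    n_bins = int(np.floor(duration_s * 1000.0 / w))
    tgt = _target_states if _target_states is not None else bin_times(
        np.asarray(target_times, dtype=float), w, n_bins
    )
    src_times = np.asarray(source_times, dtype=float)
    src = bin_times(src_times, w, n_bins)
    observed, peak_delay = _max_te_states(src, tgt, spec.delays)

    hw = half_window_ms if half_window_ms is not None else default_jitter_halfwindow_ms(spec)
    buf = np.zeros(n_bins, dtype=np.uint8)
    n_ge = 0
    for _ in range(n_jitter):
        surr = jitter_surrogate(src_times, hw, rng, duration_s)
        bin_times(surr, w, n_bins, out=buf)
        null_te, _ = _max_te_states(buf, tgt, spec.delays)
        if null_te >= observed:
            n_ge += 1
    p = (1.0 + n_ge) / (1.0 + n_jitter)
    return SignificanceResult(te=observed, peak_delay=peak_delay, p_value=p, significant=p < alpha)


def build_effective_network(
    recording: Recording,
    spec: TimescaleSpec,
    n_jitter: int = 5000,
    alpha: float = 0.001,
    rng: np.random.Generator | None = None,
    half_window_ms: float | None = None,
) -> EffectiveNetwork:
    """Test every ordered neuron pair and keep the significant edges.

    Edge TE is also stored normalized by the receiving neuron's single-bin
    entropy. Neurons whose raster is constant at this bin width cannot be
    tested and contribute no edges. Deterministic given the generator seed.
    """
    if recording.n_neurons < 3:
        raise ValidationError("need at least 3 neurons")
    rng = rng if rng is not None else np.random.default_rng()
    raster = bin_spikes(recording, spec.bin_width_ms)
    ids = raster.neuron_ids
    occupancy = raster.states.mean(axis=1)
    h_rec = {
        nid: _h(np.array([1.0 - p1, p1])) for nid, p1 in zip(ids, occupancy)
    }
    testable = [nid for nid in ids if h_rec[nid] > 0]
    edges: list[Edge] = []
    for src_id in testable:
        for tgt_id in testable:
            if src_id == tgt_id:
                continue
            res = connection_significance(
                recording.spikes[src_id],
                None,
                recording.duration,
                spec,
                n_jitter=n_jitter,
                alpha=alpha,
                rng=rng,
                half_window_ms=half_window_ms,
                _target_states=raster.row(tgt_id),
            )
            if res.significant:
                edges.append(
                    Edge(
                        source=src_id,
                        target=tgt_id,
                        te=res.te,
                        te_norm=res.te / h_rec[tgt_id],
                        peak_delay=res.peak_delay,
                        p_value=res.p_value,
                    )
                )
    return EffectiveNetwork(
        timescale=spec,
        neuron_ids=list(ids),
        duration_s=recording.duration,
        alpha=alpha,
        n_jitter=n_jitter,
        edges=edges,
    )


def enumerate_triads(network: EffectiveNetwork) -> list[tuple[int, int, int]]:
    """All (J, K, I): unordered distinct sender pairs {J, K} with significant
    edges onto a common receiver I. Count per receiver is C(indegree, 2)."""
    in_neighbors: dict[int, set[int]] = {}
    for e in network.edges:
        in_neighbors.setdefault(e.target, set()).add(e.source)
    triads = []
    for receiver in sorted(in_neighbors):
        senders = sorted(in_neighbors[receiver] - {receiver})
        for j, k in combinations(senders, 2):
            triads.append((j, k, receiver))
    return triads


@dataclass
class TriadRecord:
    """One sender-pair/receiver triad: sender correlation plus the PID of
    the information both senders transmit to the receiver."""

    sender_j: int
    sender_k: int
    receiver: int
    mi_norm: float
    pid: PIDResult
    ok: bool = True
    reason: str = ""


def evaluate_triads(
    recording: Recording,
    network: EffectiveNetwork,
    triads: list[tuple[int, int, int]] | None = None,
    mode: str = "imin",
    normalize: bool = True,
    raster: BinnedRaster | None = None,
) -> list[TriadRecord]:
    """Compute, per triad, the zero-lag normalized MI between senders and
    the (normalized) PID at the edges' peak delays.

    Triads with a zero-entropy sender or receiver are returned flagged
    (``ok=False``) and are excluded from downstream statistics.
    """
    if raster is None:
        raster = bin_spikes(recording, network.timescale.bin_width_ms)
    if triads is None:
        triads = enumerate_triads(network)
    lookup = network.edge_lookup()
    records: list[TriadRecord] = []
    for j, k, i in triads:
        sj, sk, recv = raster.row(j), raster.row(k), raster.row(i)
        mi = mutual_information_norm(sj, sk)
        if np.isnan(mi):
            records.append(TriadRecord(j, k, i, mi, None, ok=False, reason="zero-entropy sender"))
            continue
        dj = lookup[(j, i)].peak_delay
        dk = lookup[(k, i)].peak_delay
        pid = pid_decompose(sj, sk, recv, dj, dk, mode=mode)
        if normalize:
            pid = normalize_result(pid, recv)
            if pid.receiver_entropy <= 0:
                records.append(TriadRecord(j, k, i, mi, pid, ok=False, reason="zero-entropy receiver"))
                continue
        records.append(TriadRecord(j, k, i, mi, pid))
    return records


def triads_to_frame(records: list[TriadRecord], include_flagged: bool = False) -> pd.DataFrame:
    """Tabulate triad records; flagged records are dropped by default."""
    rows = []
    for r in records:
        if not r.ok and not include_flagged:
            continue
        pid = r.pid.terms() if r.pid is not None else {}
        rows.append(
            {
                "sender_j": r.sender_j,
                "sender_k": r.sender_k,
                "receiver": r.receiver,
                "mi_norm": r.mi_norm,
                **pid,
                "receiver_entropy": r.pid.receiver_entropy if r.pid is not None else np.nan,
                "ok": r.ok,
            }
        )
    cols = [
        "sender_j", "sender_k", "receiver", "mi_norm",
        "te_j", "te_k", "mvte", "redundancy", "synergy",
        "unique_j", "unique_k", "receiver_entropy", "ok",
    ]
    return pd.DataFrame(rows, columns=cols)
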