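"""Synthetic spike-train generators with known ground truth.

These generators produce the statistical structure the analysis assumes —
tunable sender-sender correlation, known triad logic gates, lognormal
firing rates, lagged excitatory couplings — so every pipeline stage can be
validated without recorded data.

Sender correlation uses a shared-drive construction: each sender is the
superposition of a common Poisson source (a fraction ``c`` of the slower
sender's rate) and an independent Poisson remainder. This preserves the
marginal rates exactly, makes ``c = 0`` give independent senders and
``c = 1`` (at equal rates) identical ones, and maps monotonically onto the
sender mutual-information axis of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .infodyn import JointTable
from .spike_io import Recording

__all__ = [
    "TriadSpec",
    "NetworkSpec",
    "generate_triad",
    "generate_network",
    "sample_from_table",
    "planted_regime_population",
]

GATES = ("copy_j", "or", "and", "xor")


def _poisson_train(rate_hz: float, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


@dataclass
class TriadSpec:
    """Two sender neurons driving one receiver through a logic gate.

    ``common_drive`` (c) is the fraction of the slower sender's rate drawn
    from a shared Poisson source: the correlation dial. The receiver fires
    with probability ``reliability`` at ``lag_ms`` after every bin (width
    ``gate_bin_ms``) in which the binarized sender states satisfy the
    gate, superposed on an independent Poisson background.
    """

    rate_j: float = 5.0
    rate_k: float = 5.0
    common_drive: float = 0.0
    gate: str = "copy_j"
    lag_ms: float = 5.0
    reliability: float = 0.7
    receiver_rate: float = 1.0
    duration_s: float = 600.0
    gate_bin_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gate not in GATES:
            raise ValidationError(f"gate must be one of {GATES}")
        if not 0.0 <= self.common_drive <= 1.0:
            raise ValidationError("common_drive must lie in [0, 1]")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValidationError("reliability must lie in [0, 1]")
        if min(self.rate_j, self.rate_k, self.receiver_rate) < 0:
            raise ValidationError("rates must be nonnegative")
        shared = self.common_drive * min(self.rate_j, self.rate_k)
        if shared > min(self.rate_j, self.rate_k) + 1e-12:
            raise ValidationError("shared fraction exceeds a sender's target rate")


def _gate_states(j_states: np.ndarray, k_states: np.ndarray, gate: str) -> np.ndarray:
    if gate == "copy_j":
        return j_states.astype(bool)
    if gate == "or":
        return (j_states | k_states).astype(bool)
    if gate == "and":
        return (j_states & k_states).astype(bool)
    return (j_states ^ k_states).astype(bool)  # xor


def generate_triad(spec: TriadSpec) -> Recording:
    """Generate a three-neuron recording (1 = sender J, 2 = sender K,
    3 = receiver). Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shared_rate = spec.common_drive * min(spec.rate_j, spec.rate_k)
    shared = _poisson_train(shared_rate, spec.duration_s, rng)
    j_times = np.sort(
        np.concatenate([shared, _poisson_train(spec.rate_j - shared_rate, spec.duration_s, rng)])
    )
    k_times = np.sort(
        np.concatenate([shared, _poisson_train(spec.rate_k - shared_rate, spec.duration_s, rng)])
    )

    w_s = spec.gate_bin_ms / 1000.0
    n_bins = int(np.floor(spec.duration_s / w_s))
    j_states = np.zeros(n_bins, dtype=np.uint8)
    k_states = np.zeros(n_bins, dtype=np.uint8)
    for times, states in ((j_times, j_states), (k_times, k_states)):
        idx = np.floor(times / w_s).astype(np.int64)
        states[idx[(idx >= 0) & (idx < n_bins)]] = 1
    active = np.flatnonzero(_gate_states(j_states, k_states, spec.gate))
    fire = active[rng.random(active.size) < spec.reliability]
    driven = (fire + 0.5) * w_s + spec.lag_ms / 1000.0
    background = _poisson_train(spec.receiver_rate, spec.duration_s, rng)
    recv = np.sort(np.concatenate([driven, background]))
    recv = recv[(recv >= 0) & (recv < spec.duration_s)]

    return Recording(
        spikes={1: j_times, 2: k_times, 3: recv},
        duration=spec.duration_s,
        label=f"triad_{spec.gate}_c{spec.common_drive}_seed{spec.seed}",
    )


@dataclass
class NetworkSpec:
    """A population with lognormal rates and planted lagged excitatory
    couplings.

    Each directed edge copies source spikes into the target with the
    edge's reliability at the edge's fixed lag, on top of the target's own
    Poisson background. ``n_edges`` plants exactly that many distinct
    ordered pairs; otherwise each ordered pair is included independently
    with ``connection_prob``.
    """

    n_neurons: int = 30
    rate_log_mean: float = float(np.log(2.0))  # median 2 spikes/s
    rate_log_sd: float = 0.6
    connection_prob: float = 0.0
    n_edges: int | None = None
    lag_ms_range: tuple[float, float] = (1.0, 10.0)
    reliability_range: tuple[float, float] = (0.3, 0.9)
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 3:
            raise ValidationError("need at least 3 neurons")
        if not 0.0 <= self.connection_prob <= 1.0:
            raise ValidationError("connection_prob must lie in [0, 1]")


def generate_network(spec: NetworkSpec) -> tuple[Recording, pd.DataFrame]:
    """Generate a recording plus its ground-truth edge table
    (columns: source, target, lag_ms, reliability)."""
    rng = np.random.default_rng(spec.seed)
    ids = list(range(1, spec.n_neurons + 1))
    rates = rng.lognormal(spec.rate_log_mean, spec.rate_log_sd, size=spec.n_neurons)
    base = {nid: _poisson_train(r, spec.duration_s, rng) for nid, r in zip(ids, rates)}

    pairs = [(s, t) for s in ids for t in ids if s != t]
    if spec.n_edges is not None:
        if spec.n_edges > len(pairs):
            raise ValidationError("n_edges exceeds the number of ordered pairs")
        chosen = [pairs[i] for i in rng.choice(len(pairs), size=spec.n_edges, replace=False)]
    else:
        mask = rng.random(len(pairs)) < spec.connection_prob
        chosen = [p for p, m in zip(pairs, mask) if m]

    edges = []
    induced: dict[int, list[np.ndarray]] = {nid: [] for nid in ids}
    for s, t in chosen:
        lag = rng.uniform(*spec.lag_ms_range)
        rel = rng.uniform(*spec.reliability_range)
        src = base[s]
        copied = src[rng.random(src.size) < rel] + lag / 1000.0
        induced[t].append(copied[copied < spec.duration_s])
        edges.append({"source": s, "target": t, "lag_ms": lag, "reliability": rel})

    spikes = {
        nid: np.sort(np.concatenate([base[nid]] + induced[nid])) for nid in ids
    }
    rec = Recording(spikes, duration=spec.duration_s, label=f"net_seed{spec.seed}")
    return rec, pd.DataFrame(edges, columns=["source", "target", "lag_ms", "reliability"])


def sample_from_table(joint: JointTable, n: int, seed: int) -> tuple[np.ndarray, ...]:
    """Draw ``n`` i.i.d. joint samples; returns one aligned state sequence
    per variable, using the table's state labels."""
    rng = np.random.default_rng(seed)
    flat = joint.probs.ravel()
    draws = rng.choice(flat.size, size=n, p=flat)
    coords = np.unravel_index(draws, joint.probs.shape)
    return tuple(
        np.asarray(alphabet)[c] for alphabet, c in zip(joint.alphabets, coords)
    )


def planted_regime_population(
    n_networks: int,
    triads_per_network: int,
    exponent: float,
    noise_sd: float,
    seed: int,
    mi_range: tuple[float, float] = (1e-3, 1.0),
    peak_mi: float | None = None,
    curvature: float = 1.0,
) -> list[pd.DataFrame]:
    """Synthetic triad tables with a planted MI-synergy relationship.

    Per triad, ``mi_norm`` is log-uniform over ``mi_range`` and synergy
    follows a power law ``mi^exponent`` times multiplicative lognormal
    noise (``noise_sd`` in log10 units). With ``peak_mi`` set, synergy
    instead follows a log-quadratic curve peaking at that MI (width set by
    ``curvature``), emulating a saturating synergy-correlation profile.
    Redundancy and mvTE are constructed to satisfy the accounting identity
    with nonnegative unique terms.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    root = np.random.default_rng(seed)
    lo, hi = np.log10(mi_range[0]), np.log10(mi_range[1])
    tables = []
    for _ in range(n_networks):
        rng = np.random.default_rng(root.integers(2**31))
        log_mi = rng.uniform(lo, hi, size=triads_per_network)
        mi = 10.0**log_mi
        noise = rng.normal(0.0, noise_sd, size=triads_per_network)
        if peak_mi is None:
            log_syn = exponent * log_mi + noise
        else:
            log_syn = -curvature * (log_mi - np.log10(peak_mi)) ** 2 + noise
        synergy = 10.0**log_syn
        redundancy = 0.3 * mi * 10.0 ** rng.normal(0.0, noise_sd, size=triads_per_network)
        unique_j = 0.1 * synergy * rng.random(triads_per_network)
        unique_k = 0.1 * synergy * rng.random(triads_per_network)
        mvte = synergy + redundancy + unique_j + unique_k
        tables.append(
            pd.DataFrame(
                {
                    "mi_norm": mi,
                    "synergy": synergy,
                    "redundancy": redundancy,
                    "unique_j": unique_j,
                    "unique_k": unique_k,
                    "mvte": mvte,
                }
            )
        )
    return tables
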