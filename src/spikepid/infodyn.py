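"""Core discrete information theory for spike rasters.

All quantities are plug-in (maximum-likelihood) estimates in bits from
binary state sequences, or exact values when computed from an explicit
joint probability table.

The quantities implemented:

* normalized mutual information ``MI(X;Y) / min(H(X), H(Y))`` between two
  simultaneous sequences (the sender-correlation measure, ``pMI^max``);
* delayed apparent transfer entropy ``TE_d(J -> I)`` with an order-1
  receiver history (the single bin preceding the predicted bin);
* multivariate transfer entropy ``TE({J,K} -> I)`` from two sources jointly;
* the two-source partial information decomposition of mvTE into redundancy,
  synergy and unique terms, using the Williams-Beer ``I_min`` redundancy
  (expected minimum specific information across sources, conditioned on the
  receiver's past), or a parameter-free lower-bound redundancy
  ``max(0, TE_J + TE_K - mvTE)``;
* entropy normalization of all terms by the receiving neuron's single-bin
  entropy (``pH^rec``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .discretize import TimescaleSpec
from .errors import ConsistencyError, ValidationError

__all__ = [
    "JointTable",
    "PIDResult",
    "entropy",
    "mutual_information_norm",
    "transfer_entropy",
    "timescale_te",
    "multivariate_te",
    "pid_decompose",
    "pid_decompose_table",
    "normalize_result",
    "pearson_similarity",
]

_LOG2 = np.log(2.0)
_TOL = 1e-10


def _h(p: np.ndarray) -> float:
    """Shannon entropy in bits of a probability array (any shape)."""
    p = np.asarray(p, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


@dataclass(frozen=True)
class JointTable:
    """A joint probability table over named discrete variables.

    ``probs`` has one axis per variable; ``alphabets`` holds the state
    labels along each axis. Built either from explicit probabilities or by
    plug-in (empirical frequency) estimation from aligned sequences.
    """

    probs: np.ndarray
    names: tuple[str, ...]
    alphabets: tuple[tuple, ...]

    @classmethod
    def from_probs(cls, probs, names=None, alphabets=None) -> "JointTable":
        p = np.asarray(probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError("probabilities must be >= 0 and sum to 1")
        if names is None:
            names = tuple(f"x{i}" for i in range(p.ndim))
        if alphabets is None:
            alphabets = tuple(tuple(range(k)) for k in p.shape)
        return cls(probs=p, names=tuple(names), alphabets=tuple(alphabets))

    @classmethod
    def from_sequences(cls, *seqs, names=None) -> "JointTable":
        """Plug-in joint table from equal-length aligned state sequences."""
        arrs = [np.asarray(s).ravel() for s in seqs]
        n = arrs[0].size
        if n == 0 or any(a.size != n for a in arrs):
            raise ValidationError("sequences must be nonempty and equal length")
        alphabets, codes = [], []
        for a in arrs:
            labels, inv = np.unique(a, return_inverse=True)
            alphabets.append(tuple(labels.tolist()))
            codes.append(inv)
        shape = tuple(len(a) for a in alphabets)
        flat = np.ravel_multi_index(codes, shape)
        counts = np.bincount(flat, minlength=int(np.prod(shape)))
        return cls.from_probs(counts.reshape(shape) / n, names=names, alphabets=tuple(alphabets))

    def marginal(self, axes: tuple[int, ...]) -> "JointTable":
        axes = tuple(axes)
        drop = tuple(i for i in range(self.probs.ndim) if i not in axes)
        p = self.probs.sum(axis=drop)
        keep = sorted(axes)
        if p.ndim > 1:
            p = np.transpose(p, [keep.index(a) for a in axes])
        return JointTable(
            probs=p,
            names=tuple(self.names[i] for i in axes),
            alphabets=tuple(self.alphabets[i] for i in axes),
        )

    def entropy(self) -> float:
        return _h(self.probs)


def entropy(dist) -> float:
    """Entropy in bits, ``-sum p log2 p`` with ``0 log 0 = 0``.

    Accepts a probability array or a :class:`JointTable`.
    """
    if isinstance(dist, JointTable):
        return dist.entropy()
    p = np.asarray(dist, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("probabilities must be >= 0 and sum to 1")
    return _h(p)


def mutual_information_norm(x, y) -> float:
    """Normalized mutual information ``MI(X;Y) / min(H(X), H(Y))``.

    Computed at zero lag on simultaneous sequences; the denominator is the
    maximum MI the pair could attain, so the value is a proportion in
    [0, 1]. Returns NaN when either marginal entropy is zero (undefined).
    """
    table = JointTable.from_sequences(x, y)
    return mutual_information_norm_table(table)


def mutual_information_norm_table(table: JointTable) -> float:
    if table.probs.ndim != 2:
        raise ValidationError("expected a two-variable joint table")
    p = table.probs
    hx, hy = _h(p.sum(axis=1)), _h(p.sum(axis=0))
    hmin = min(hx, hy)
    if hmin <= 0:
        return float("nan")
    mi = hx + hy - _h(p)
    return mi / hmin


def _check_binary(*seqs) -> list[np.ndarray]:
    out = []
    n = None
    for s in seqs:
        a = np.ascontiguousarray(s, dtype=np.uint8).ravel()
        if n is None:
            n = a.size
        elif a.size != n:
            raise ValidationError("sequences must have equal length")
        if a.size and a.max() > 1:
            raise ValidationError("state sequences must be binary (0/1)")
        out.append(a)
    return out


def _lagged_counts(arrs: list[np.ndarray], lags: list[int]) -> np.ndarray:
    """Joint counts over ``(a[t - lag] for a, lag in zip(arrs, lags))`` for
    all valid t; returns a ``(2,)*len(arrs)`` array."""
    m = max(lags)
    n = arrs[0].size
    if n - m < 2:
        raise ValidationError("sequence too short for requested lags")
    idx = np.zeros(n - m, dtype=np.int64)
    for a, lag in zip(arrs, lags):
        idx <<= 1
        idx |= a[m - lag : n - lag]
    counts = np.bincount(idx, minlength=2 ** len(arrs))
    return counts.reshape((2,) * len(arrs))


def _te_from_probs(p: np.ndarray) -> float:
    # p axes: (i_t, i_prev, j). TE = H(i_t,i_p) + H(i_p,j) - H(i_p) - H(all)
    return _h(p.sum(axis=2)) + _h(p.sum(axis=0)) - _h(p.sum(axis=(0, 2))) - _h(p)


def transfer_entropy(source, target, delay_bins: int) -> float:
    """Apparent transfer entropy ``TE_d(J -> I)`` in bits.

    ``sum p(i_t, i_{t-1}, j_{t-d}) log2 [ p(i_t | i_{t-1}, j_{t-d}) /
    p(i_t | i_{t-1}) ]`` with an order-1 receiver history, plug-in
    estimated over all bins where every lagged value exists.
    """
    if delay_bins < 1:
        raise ValidationError("delay must be a positive number of bins")
    src, tgt = _check_binary(source, target)
    if tgt.size <= delay_bins + 1:
        raise ValidationError("sequences too short for this delay")
    counts = _lagged_counts([tgt, tgt, src], [0, 1, delay_bins])
    return _te_from_probs(counts / counts.sum())


def _te_fast(src: np.ndarray, tgt: np.ndarray, d: int) -> float:
    """Unchecked TE for inner loops (binary uint8 inputs)."""
    m = max(1, d)
    n = tgt.size
    idx = (tgt[m:].astype(np.int64) << 2) | (tgt[m - 1 : n - 1] << 1) | src[m - d : n - d]
    counts = np.bincount(idx, minlength=8).reshape(2, 2, 2)
    return _te_from_probs(counts / (n - m))


def timescale_te(source, target, spec: TimescaleSpec) -> tuple[float, int]:
    """Maximum TE over the timescale's delay set and the delay attaining it.

    Ties are broken toward the smallest delay. Inputs are rasters at
    ``spec.bin_width_ms``.
    """
    src, tgt = _check_binary(source, target)
    if tgt.size <= spec.delays[-1] + 1:
        raise ValidationError("sequences too short for this timescale")
    best, best_d = -np.inf, spec.delays[0]
    for d in spec.delays:
        te = _te_fast(src, tgt, d)
        if te > best:
            best, best_d = te, d
    return best, best_d


def multivariate_te(source_j, source_k, target, delay_j: int, delay_k: int) -> float:
    """Multivariate transfer entropy ``TE({J,K} -> I)`` in bits, each sender
    taken at its own delay."""
    if min(delay_j, delay_k) < 1:
        raise ValidationError("delays must be positive")
    sj, sk, tgt = _check_binary(source_j, source_k, target)
    counts = _lagged_counts([tgt, tgt, sj, sk], [0, 1, delay_j, delay_k])
    p = counts / counts.sum()
    # CMI(i_t; (j,k) | i_p)
    return _h(p.sum(axis=(2, 3))) + _h(p.sum(axis=0)) - _h(p.sum(axis=(0, 2, 3))) - _h(p)


@dataclass(frozen=True)
class PIDResult:
    """Two-source PID of multivariate transfer entropy (all terms in bits,
    or in proportions of receiver entropy when ``normalized``)."""

    te_j: float
    te_k: float
    mvte: float
    redundancy: float
    synergy: float
    unique_j: float
    unique_k: float
    receiver_entropy: float
    normalized: bool = False

    def terms(self) -> dict[str, float]:
        return {
            "te_j": self.te_j,
            "te_k": self.te_k,
            "mvte": self.mvte,
            "redundancy": self.redundancy,
            "synergy": self.synergy,
            "unique_j": self.unique_j,
            "unique_k": self.unique_k,
        }


def _specific_information(q: np.ndarray) -> np.ndarray:
    """Specific information of each receiver transition about source S.

    ``q`` is the joint ``p(i_t, i_prev, s)``. Returns the array
    ``Ispec[i_t, i_prev] = sum_s p(s | i_t, i_prev)
    [log2 p(i_t | s, i_prev) - log2 p(i_t | i_prev)]``, which by Bayes'
    rule equals ``KL( p(s | i_t, i_prev) || p(s | i_prev) )`` and is
    therefore nonnegative.
    """
    p_itip = q.sum(axis=2)  # (i_t, i_p)
    p_ip_s = q.sum(axis=0)  # (i_p, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_given_itip = q / p_itip[:, :, None]
        s_given_ip = p_ip_s / p_ip_s.sum(axis=1, keepdims=True)
        ratio = s_given_itip / s_given_ip[None, :, :]
        terms = np.where(q > 0, s_given_itip * np.log2(ratio), 0.0)
    return terms.sum(axis=2)


def pid_decompose_table(table, mode: str = "imin") -> PIDResult:
    """PID of mvTE from an explicit joint table over
    ``(i_t, i_prev, j, k)`` (receiver future, receiver past, the two
    sender states at their delays).

    ``mode='imin'`` uses the Williams-Beer redundancy: the expectation over
    receiver transitions of the minimum specific information across the two
    senders. ``mode='lower_bound'`` uses the minimal redundancy consistent
    with nonnegative unique terms, ``max(0, TE_J + TE_K - mvTE)``, under
    which synergy is ``max(0, mvTE - TE_J - TE_K)``.
    """
    p = table.probs if isinstance(table, JointTable) else np.asarray(table, dtype=float)
    if p.ndim != 4:
        raise ValidationError("expected a four-variable joint table (i_t, i_prev, j, k)")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
        raise ValidationError("probabilities must be >= 0 and sum to 1")

    p_j = p.sum(axis=3)  # (i_t, i_p, j)
    p_k = p.sum(axis=2)  # (i_t, i_p, k)
    te_j = _te_from_probs(p_j)
    te_k = _te_from_probs(p_k)
    mvte = (
        _h(p.sum(axis=(2, 3))) + _h(p.sum(axis=0)) - _h(p.sum(axis=(0, 2, 3))) - _h(p)
    )

    if mode == "imin":
        ispec_j = _specific_information(p_j)
        ispec_k = _specific_information(p_k)
        p_itip = p.sum(axis=(2, 3))
        redundancy = float(np.sum(p_itip * np.minimum(ispec_j, ispec_k)))
        synergy = mvte - te_j - te_k + redundancy
    elif mode == "lower_bound":
        redundancy = max(0.0, te_j + te_k - mvte)
        synergy = max(0.0, mvte - te_j - te_k)
    else:
        raise ValidationError(f"unknown PID mode {mode!r}")

    result = PIDResult(
        te_j=te_j,
        te_k=te_k,
        mvte=mvte,
        redundancy=redundancy,
        synergy=synergy,
        unique_j=te_j - redundancy,
        unique_k=te_k - redundancy,
        receiver_entropy=_h(p.sum(axis=(1, 2, 3))),
    )
    for name, value in result.terms().items():
        if value < -_TOL:
            raise ConsistencyError(f"PID term {name} = {value} below -{_TOL}")
    resid = result.unique_j + result.unique_k + result.redundancy + result.synergy - result.mvte
    if abs(resid) > _TOL:
        raise ConsistencyError(f"PID accounting identity violated by {resid}")
    return result


def pid_decompose(source_j, source_k, target, delay_j: int, delay_k: int, mode: str = "imin") -> PIDResult:
    """Plug-in PID from binary sequences; each sender at its own delay.

    All four component terms (TE_J, TE_K, mvTE, redundancy) are computed
    from the same aligned joint table so the accounting identity
    ``unique_j + unique_k + redundancy + synergy = mvTE`` holds exactly.
    """
    if min(delay_j, delay_k) < 1:
        raise ValidationError("delays must be positive")
    sj, sk, tgt = _check_binary(source_j, source_k, target)
    counts = _lagged_counts([tgt, tgt, sj, sk], [0, 1, delay_j, delay_k])
    return pid_decompose_table(counts / counts.sum(), mode=mode)


def normalize_result(result: PIDResult, receiver_raster) -> PIDResult:
    """Divide every information term by the receiver's single-bin entropy.

    The receiver entropy is the plug-in entropy of the receiver's binary
    state over the full raster. Normalizing twice is an error; a
    zero-entropy receiver yields NaN terms (flagged missing).
    """
    if result.normalized:
        raise ValidationError("result is already normalized")
    states = np.asarray(receiver_raster).ravel()
    p1 = states.mean()
    h_rec = _h(np.array([1.0 - p1, p1]))
    if h_rec <= 0:
        nan = float("nan")
        return replace(
            result,
            te_j=nan, te_k=nan, mvte=nan, redundancy=nan, synergy=nan,
            unique_j=nan, unique_k=nan, receiver_entropy=0.0, normalized=True,
        )
    return PIDResult(
        te_j=result.te_j / h_rec,
        te_k=result.te_k / h_rec,
        mvte=result.mvte / h_rec,
        redundancy=result.redundancy / h_rec,
        synergy=result.synergy / h_rec,
        unique_j=result.unique_j / h_rec,
        unique_k=result.unique_k / h_rec,
        receiver_entropy=h_rec,
        normalized=True,
    )


def pearson_similarity(x, y) -> float:
    """Sample Pearson correlation of two equal-length binned sequences;
    NaN when either has zero variance."""
    a = np.asarray(x, dtype=float).ravel()
    b = np.asarray(y, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValidationError("sequences must be equal length, size >= 2")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
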