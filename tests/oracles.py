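"""Independent brute-force oracles used to check the vectorized paths.

Everything here is written as plain nested loops over explicit joint
tables so that it shares no code with the implementation under test.
"""

import itertools
import math

import numpy as np


def entropy_brute(probs) -> float:
    h = 0.0
    for p in np.asarray(probs, dtype=float).ravel():
        if p > 0:
            h -= p * math.log2(p)
    return h


def mi_norm_brute(p2) -> float:
    p2 = np.asarray(p2, dtype=float)
    px = [sum(p2[i, j] for j in range(p2.shape[1])) for i in range(p2.shape[0])]
    py = [sum(p2[i, j] for i in range(p2.shape[0])) for j in range(p2.shape[1])]
    mi = 0.0
    for i in range(p2.shape[0]):
        for j in range(p2.shape[1]):
            if p2[i, j] > 0:
                mi += p2[i, j] * math.log2(p2[i, j] / (px[i] * py[j]))
    hmin = min(entropy_brute(px), entropy_brute(py))
    return mi / hmin if hmin > 0 else float("nan")


def te_brute(p3) -> float:
    """TE from an explicit p(i_t, i_prev, j) table: direct summation of
    p * log2[ p(i_t | i_prev, j) / p(i_t | i_prev) ]."""
    p3 = np.asarray(p3, dtype=float)
    te = 0.0
    for it, ip, j in itertools.product(*(range(s) for s in p3.shape)):
        p = p3[it, ip, j]
        if p <= 0:
            continue
        p_ip_j = p3[:, ip, j].sum()
        p_it_ip = p3[it, ip, :].sum()
        p_ip = p3[:, ip, :].sum()
        te += p * math.log2((p / p_ip_j) / (p_it_ip / p_ip))
    return te


def mvte_brute(p4) -> float:
    p4 = np.asarray(p4, dtype=float)
    te = 0.0
    for it, ip, j, k in itertools.product(*(range(s) for s in p4.shape)):
        p = p4[it, ip, j, k]
        if p <= 0:
            continue
        p_ip_jk = p4[:, ip, j, k].sum()
        p_it_ip = p4[it, ip, :, :].sum()
        p_ip = p4[:, ip, :, :].sum()
        te += p * math.log2((p / p_ip_jk) / (p_it_ip / p_ip))
    return te


def _ispec_brute(p3, it, ip) -> float:
    """Specific information of the transition (it, ip) about the source in
    p(i_t, i_prev, s): sum_s p(s | it, ip) [log2 p(it | s, ip) - log2 p(it | ip)]."""
    p3 = np.asarray(p3, dtype=float)
    p_itip = p3[it, ip, :].sum()
    p_ip = p3[:, ip, :].sum()
    if p_itip <= 0:
        return 0.0
    total = 0.0
    for s in range(p3.shape[2]):
        p_s_given = p3[it, ip, s] / p_itip
        if p_s_given <= 0:
            continue
        p_it_given_s_ip = p3[it, ip, s] / p3[:, ip, s].sum()
        p_it_given_ip = p_itip / p_ip
        total += p_s_given * (math.log2(p_it_given_s_ip) - math.log2(p_it_given_ip))
    return total


def pid_brute(p4, mode="imin") -> dict:
    """Williams-Beer PID of mvTE from an explicit 4-variable table."""
    p4 = np.asarray(p4, dtype=float)
    p_j = p4.sum(axis=3)
    p_k = p4.sum(axis=2)
    te_j, te_k, mvte = te_brute(p_j), te_brute(p_k), mvte_brute(p4)
    if mode == "imin":
        red = 0.0
        for it in range(p4.shape[0]):
            for ip in range(p4.shape[1]):
                w = p4[it, ip, :, :].sum()
                if w > 0:
                    red += w * min(_ispec_brute(p_j, it, ip), _ispec_brute(p_k, it, ip))
        syn = mvte - te_j - te_k + red
    else:
        red = max(0.0, te_j + te_k - mvte)
        syn = max(0.0, mvte - te_j - te_k)
    return {
        "te_j": te_j,
        "te_k": te_k,
        "mvte": mvte,
        "redundancy": red,
        "synergy": syn,
        "unique_j": te_j - red,
        "unique_k": te_k - red,
    }


def empirical_lagged_table(seqs, lags) -> np.ndarray:
    """Plug-in joint table over (seq[t - lag]) for all valid t, by loop."""
    m = max(lags)
    n = len(seqs[0])
    counts = np.zeros((2,) * len(seqs))
    for t in range(m, n):
        idx = tuple(int(s[t - lag]) for s, lag in zip(seqs, lags))
        counts[idx] += 1
    return counts / counts.sum()


def rank_average_ties(values):
    v = list(values)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def spearman_brute(x, y) -> float:
    rx, ry = rank_average_ties(x), rank_average_ties(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
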