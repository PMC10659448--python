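"""Independent straight-line oracles used by the test suite.

Everything here is deliberately naive — textbook sum formulas, explicit
Python loops over nodes and ordered pairs, full sorts — and shares no
code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def pearson_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r via raw sum formulas."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return num / den


def cluster_weights_direct(theta1, theta2, bias, roi: int):
    """Node weight matrix evaluated as printed: rectified matrix product
    of the assignment parameters with the one-hot encoding, applied to
    the stacked bases."""
    n0 = theta1.shape[1]
    r = np.zeros(n0)
    r[roi] = 1.0
    alpha = np.maximum(theta1 @ r, 0.0)
    w = np.zeros_like(bias)
    for u in range(theta2.shape[0]):
        w = w + alpha[u] * theta2[u]
    return w + bias


def dense_rgin_oracle(adj, roi_index, h, theta1, theta2, bias, eps, aggregation):
    """Dense brute-force RGIN update (identity MLP): explicit loop over
    every ordered node pair."""
    n = h.shape[0]
    d_out = theta2.shape[1]
    out = np.zeros((n, d_out))
    for i in range(n):
        w_i = cluster_weights_direct(theta1, theta2, bias, roi_index[i])
        acc = np.zeros(d_out)
        count = 0
        for j in range(n):
            if j == i or adj[i, j] == 0.0:
                continue
            w_j = cluster_weights_direct(theta1, theta2, bias, roi_index[j])
            acc = acc + w_j @ (adj[i, j] * h[j])
            count += 1
        if aggregation == "mean" and count > 0:
            acc = acc / count
        out[i] = (1.0 + eps) * (w_i @ h[i]) + acc
    return out


def standardize_oracle(s: np.ndarray) -> np.ndarray:
    """Plain (x - mean) / population-std, no guard."""
    return (s - s.mean()) / s.std()


def topk_sort_oracle(scores: np.ndarray, k: int) -> list[int]:
    """Sort all (score, index) pairs by descending score then ascending
    index; take the first k indices."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return order[:k]


def garo_oracle(h_dn: np.ndarray, w_key: np.ndarray, w_query: np.ndarray) -> np.ndarray:
    """Key-query readout evaluated step by step in D x N orientation."""
    d, n = h_dn.shape
    keys = w_key @ h_dn
    q = w_query @ (h_dn.mean(axis=1))
    z = 1.0 / (1.0 + np.exp(-(q @ keys) / np.sqrt(d)))
    return h_dn @ z


def sero_oracle(h_dn: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Squeeze-excitation readout evaluated step by step (D x N)."""
    z = h_dn.mean(axis=1)
    hidden = np.maximum(w1 @ z, 0.0)
    z_space = 1.0 / (1.0 + np.exp(-(w2 @ hidden)))
    return h_dn @ z_space


def meanmax_oracle(h_nd: np.ndarray) -> np.ndarray:
    """Elementwise mean and max over nodes via explicit loops."""
    n, d = h_nd.shape
    mean = np.zeros(d)
    mx = np.full(d, -np.inf)
    for i in range(n):
        for c in range(d):
            mean[c] += h_nd[i, c] / n
            mx[c] = max(mx[c], h_nd[i, c])
    return np.concatenate([mean, mx])


def tpk_hand(sorted_scores: np.ndarray, k: int) -> float:
    """Hand evaluation of the selected/unselected cross-entropy."""
    n = len(sorted_scores)
    total = 0.0
    for i in range(k):
        total += np.log(sorted_scores[i])
    for i in range(n - k):
        total += np.log(1.0 - sorted_scores[i + k])
    return -total / n
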