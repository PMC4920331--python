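"""Numba kernel for Felsenstein pruning under the Lewis-Mk model."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def prune_loglik(
    left: np.ndarray,
    right: np.ndarray,
    tip_masks: np.ndarray,  # (n_nodes, n_chars) int32 bitmask; valid at tips
    blen: np.ndarray,  # (n_nodes,) branch length above node, expected changes
    k: int,
) -> np.ndarray:
    """Per-character log-likelihood for one rate category.

    Nodes are in postorder (root last).  The Mk transition probability on
    a branch of length ``b`` (in expected changes per site at
    stationarity) is P_same = 1/k + (k-1)/k * exp(-k/(k-1) * b) and
    P_diff = (1 - exp(-k/(k-1) * b))/k.  Root state frequencies are
    uniform 1/k.  A tip bitmask marks the states compatible with the
    observation (all ones for missing data).
    """
    n_nodes = left.shape[0]
    n_chars = tip_masks.shape[1]
    partial = np.empty((n_nodes, n_chars, k))
    logscale = np.zeros(n_chars)
    kk = k / (k - 1.0)
    for i in range(n_nodes):
        if left[i] < 0:
            for c in range(n_chars):
                m = tip_masks[i, c]
                for s in range(k):
                    partial[i, c, s] = float((m >> s) & 1)
        else:
            for c in range(n_chars):
                for s in range(k):
                    partial[i, c, s] = 1.0
            for child in (left[i], right[i]):
                e = np.exp(-kk * blen[child])
                pii = 1.0 / k + (k - 1.0) / k * e
                pij = (1.0 - e) / k
                for c in range(n_chars):
                    tot = 0.0
                    for s in range(k):
                        tot += partial[child, c, s]
                    for s in range(k):
                        ps = partial[child, c, s]
                        partial[i, c, s] *= pij * (tot - ps) + pii * ps
            # rescale to guard underflow on deep trees
            for c in range(n_chars):
                m = partial[i, c, 0]
                for s in range(1, k):
                    if partial[i, c, s] > m:
                        m = partial[i, c, s]
                if m < 1e-100 and m > 0.0:
                    for s in range(k):
                        partial[i, c, s] /= m
                    logscale[c] += np.log(m)
    root = n_nodes - 1
    out = np.empty(n_chars)
    for c in range(n_chars):
        tot = 0.0
        for s in range(k):
            tot += partial[root, c, s]
        if tot <= 0.0:
            out[c] = -np.inf
        else:
            out[c] = np.log(tot / k) + logscale[c]
    return out
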