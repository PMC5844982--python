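"""Independent brute-force oracles, written as literal loops on purpose.

Nothing here shares code with the package's production kernels: matches
are counted by explicit double loops, embeddings are built element by
element, and BH adjustment is applied by hand.  These exist solely to
pin the fast implementations down.
"""

import math

import numpy as np


def brute_embed(channels, lag):
    """Element-wise construction of the 6- and 9-dim delay embeddings."""
    ap, ml, v = channels
    n = len(ap)
    t = n - 2 * lag
    X, Y = [], []
    for j in range(t):
        row9 = [ap[j], ml[j], v[j],
                ap[j + lag], ml[j + lag], v[j + lag],
                ap[j + 2 * lag], ml[j + 2 * lag], v[j + 2 * lag]]
        Y.append(row9)
        X.append(row9[:6])
    return np.array(X), np.array(Y)


def brute_match_fractions(X, Y, index_set, r, theiler=0):
    """Literal O(m^2) double loop over ordered pairs, max-norm distance."""
    idx = list(index_set)
    n_pairs = 0
    cx = 0
    cy = 0
    for a in range(len(idx)):
        for b in range(len(idx)):
            i, j = idx[a], idx[b]
            if abs(i - j) <= theiler:
                continue
            n_pairs += 1
            dx = max(abs(X[i][c] - X[j][c]) for c in range(X.shape[1]))
            dy = max(abs(Y[i][c] - Y[j][c]) for c in range(Y.shape[1]))
            if dx <= r:
                cx += 1
            if dy <= r:
                cy += 1
    return cx / n_pairs, cy / n_pairs, n_pairs


def brute_sample_entropy(channels, lag, r, index_set=None, theiler=0):
    """Conventional sample entropy ln(n_x / n_y) on the nested embeddings."""
    X, Y = brute_embed(channels, lag)
    if index_set is None:
        index_set = range(len(X))
    nx, ny, _ = brute_match_fractions(X, Y, index_set, r, theiler)
    if ny == 0:
        return math.nan
    return math.log(nx / ny)


def brute_bh_adjust(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, applied by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj


def brute_mi_nats(x, y, bins):
    """Plug-in mutual information from a 2-D histogram, explicit loops."""
    h, _, _ = np.histogram2d(x, y, bins=bins)
    total = h.sum()
    px = h.sum(axis=1) / total
    py = h.sum(axis=0) / total
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            p = h[i, j] / total
            if p > 0:
                mi += p * math.log(p / (px[i] * py[j]))
    return mi
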