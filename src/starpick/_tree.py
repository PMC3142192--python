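"""Numba kernels for the depth-limited information-gain decision tree."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _entropy2(n_pos: float, n: float) -> float:
    if n <= 0.0:
        return 0.0
    p = n_pos / n
    h = 0.0
    if p > 0.0:
        h -= p * np.log2(p)
    if p < 1.0:
        h -= (1.0 - p) * np.log2(1.0 - p)
    return h


@njit(cache=False)
def fit_tree(X: np.ndarray, y: np.ndarray, max_depth: int, min_leaf: int):
    """Grow the tree with an explicit stack; returns flat node arrays.

    feature[k] < 0 marks a leaf predicting value[k].  Split ties break to
    the smaller feature index, then the smaller threshold; leaf ties
    predict the negative class.
    """
    n, k = X.shape
    max_nodes = 2 ** (max_depth + 2)
    feature = np.full(max_nodes, -1, dtype=np.int64)
    threshold = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, dtype=np.int64)
    right = np.full(max_nodes, -1, dtype=np.int64)
    value = np.zeros(max_nodes, dtype=np.int8)
    n_nodes = 0

    # stack of (node, depth, sample-range) over an index workspace
    idx = np.arange(n)
    work = np.empty(n, dtype=np.int64)
    stack_node = np.empty(max_nodes, dtype=np.int64)
    stack_depth = np.empty(max_nodes, dtype=np.int64)
    stack_lo = np.empty(max_nodes, dtype=np.int64)
    stack_hi = np.empty(max_nodes, dtype=np.int64)

    root = n_nodes
    n_nodes += 1
    top = 0
    stack_node[top] = root
    stack_depth[top] = 0
    stack_lo[top] = 0
    stack_hi[top] = n
    top += 1

    while top > 0:
        top -= 1
        node = stack_node[top]
        depth = stack_depth[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        m = hi - lo
        n_pos = 0
        for t in range(lo, hi):
            n_pos += y[idx[t]]
        value[node] = 1 if 2 * n_pos > m else 0
        if depth >= max_depth or n_pos == 0 or n_pos == m or m < 2:
            continue
        parent_h = _entropy2(n_pos, m)
        best_gain = 1e-12
        best_f = -1
        best_thr = 0.0
        for f in range(k):
            col = np.empty(m)
            for t in range(m):
                col[t] = X[idx[lo + t], f]
            order = np.argsort(col, kind="mergesort")
            pl = 0
            for t in range(m - 1):
                pl += y[idx[lo + order[t]]]
                if col[order[t + 1]] <= col[order[t]]:
                    continue
                nl = t + 1
                nr = m - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                pr = n_pos - pl
                gain = parent_h - (
                    nl * _entropy2(pl, nl) + nr * _entropy2(pr, nr)
                ) / m
                if gain > best_gain + 1e-12:
                    best_gain = gain
                    best_f = f
                    best_thr = (col[order[t]] + col[order[t + 1]]) / 2.0
        if best_f < 0:
            continue
        # partition idx[lo:hi] stably on the chosen split
        a = lo
        b = 0
        for t in range(lo, hi):
            i = idx[t]
            if X[i, best_f] <= best_thr:
                idx[a] = i  # safe: a <= t
                a += 1
            else:
                work[b] = i
                b += 1
        for t in range(b):
            idx[a + t] = work[t]
        mid = a
        feature[node] = best_f
        threshold[node] = best_thr
        lchild = n_nodes
        n_nodes += 1
        rchild = n_nodes
        n_nodes += 1
        left[node] = lchild
        right[node] = rchild
        stack_node[top] = lchild
        stack_depth[top] = depth + 1
        stack_lo[top] = lo
        stack_hi[top] = mid
        top += 1
        stack_node[top] = rchild
        stack_depth[top] = depth + 1
        stack_lo[top] = mid
        stack_hi[top] = hi
        top += 1

    return (
        feature[:n_nodes],
        threshold[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        value[:n_nodes],
    )


@njit(cache=False)
def predict_tree(
    X: np.ndarray,
    feature: np.ndarray,
    threshold: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    value: np.ndarray,
) -> np.ndarray:
    n = X.shape[0]
    out = np.empty(n, dtype=np.int8)
    for r in range(n):
        node = 0
        while feature[node] >= 0:
            if X[r, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[r] = value[node]
    return out
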