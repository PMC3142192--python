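"""Numba kernels for the self-contained toy folding model.

The toy model assigns fixed stacking-free pair energies (G-C -3, A-U -2,
G-U -1 kcal/mol), no loop terms, and a minimum hairpin loop of three
unpaired bases.  Under this model the minimum free energy and the exact
partition function are computed by standard interval dynamic programming.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e18


@njit(cache=False)
def nussinov_fill(W: np.ndarray, must_pair: np.ndarray) -> np.ndarray:
    """Minimum-energy fill.  W[i, j] is the pair energy (<= 0) or +INF if
    the pair (i, j) is disallowed; ``must_pair[i]`` forbids leaving i
    unpaired (used for constraint-enforced seed positions)."""
    n = W.shape[0]
    # M[i][j+1] = min energy of segment i..j inclusive (0-based); empty -> 0
    M = np.zeros((n + 2, n + 2))
    for length in range(1, n + 1):
        for i in range(0, n - length + 1):
            j = i + length - 1
            best = INF
            if not must_pair[i]:
                best = M[i + 1][j + 1] if i + 1 <= j else 0.0
                # M indexing: store at [i][j] shifted by nothing; see below
            # pair i with k
            for k in range(i + 1, j + 1):
                w = W[i, k]
                if w < INF / 2:
                    inner = M[i + 1][k - 1 + 1] if i + 1 <= k - 1 else 0.0
                    outer = M[k + 1][j + 1] if k + 1 <= j else 0.0
                    cand = w + inner + outer
                    if cand < best:
                        best = cand
            M[i][j + 1] = best
    return M


@njit(cache=False)
def _seg(M: np.ndarray, i: int, j: int) -> float:
    if i > j:
        return 0.0
    return M[i][j + 1]


@njit(cache=False)
def nussinov_traceback(
    M: np.ndarray, W: np.ndarray, must_pair: np.ndarray
) -> np.ndarray:
    """Recover one optimal pairing (leftmost-pairing, smallest-partner
    tie-break, hence deterministic)."""
    n = W.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    stack_i = np.empty(2 * n + 2, dtype=np.int64)
    stack_j = np.empty(2 * n + 2, dtype=np.int64)
    top = 0
    stack_i[top] = 0
    stack_j[top] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        if i > j:
            continue
        e = _seg(M, i, j)
        if e >= INF / 2:
            continue
        if not must_pair[i] and abs(e - _seg(M, i + 1, j)) < 1e-9:
            stack_i[top] = i + 1
            stack_j[top] = j
            top += 1
            continue
        for k in range(i + 1, j + 1):
            w = W[i, k]
            if w < INF / 2 and abs(e - (w + _seg(M, i + 1, k - 1) + _seg(M, k + 1, j))) < 1e-9:
                partner[i] = k
                partner[k] = i
                stack_i[top] = i + 1
                stack_j[top] = k - 1
                top += 1
                stack_i[top] = k + 1
                stack_j[top] = j
                top += 1
                break
    return partner


@njit(cache=False)
def partition_logz(Wb: np.ndarray, log_c: float) -> float:
    """Exact log partition function with per-nucleotide rescaling.

    ``Wb[i, j]`` is the Boltzmann weight exp(-E(i,j)/RT) of an allowed
    pair, 0 if disallowed.  ``log_c`` is the per-base scale (typically the
    MFE spread per base) keeping intermediate sums inside double range.
    Returns ln Z of the unscaled ensemble (open chain contributes 1).
    """
    n = Wb.shape[0]
    c = np.exp(log_c)
    Zs = np.ones((n + 2, n + 2))  # scaled Z over [i, j] inclusive; empty = 1
    for length in range(1, n + 1):
        for i in range(0, n - length + 1):
            j = i + length - 1
            # i unpaired
            left = Zs[i + 1][j + 1] if i + 1 <= j else 1.0
            total = left / c
            for k in range(i + 1, j + 1):
                w = Wb[i, k]
                if w > 0.0:
                    inner = Zs[i + 1][k] if i + 1 <= k - 1 else 1.0
                    outer = Zs[k + 1][j + 1] if k + 1 <= j else 1.0
                    total += (w / (c * c)) * inner * outer
            Zs[i][j + 1] = total
    z = Zs[0][n]
    if not np.isfinite(z) or z <= 0.0:
        return np.nan
    return np.log(z) + n * log_c
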