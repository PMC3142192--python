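"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written as naive enumeration or direct
scanning, sharing no code path with the package internals it checks.
"""

from __future__ import annotations

import math
from functools import lru_cache

# toy model constants, restated independently
PAIR_E = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}
RT = 0.0019872041 * 310.15
MIN_LOOP = 3


def duplex_mfe_enumeration(a: str, b: str):
    """Minimum toy energy over ALL antiparallel non-crossing inter-molecular
    pairings, by explicit recursion over (a position, b limit).  Returns
    None when no pair can form."""
    n, m = len(a), len(b)

    best = [None]

    def rec(i: int, limit: int, acc: float, npairs: int):
        if i == n:
            if npairs and (best[0] is None or acc < best[0]):
                best[0] = acc
            return
        rec(i + 1, limit, acc, npairs)  # a[i] unpaired
        for l in range(limit - 1, -1, -1):
            e = PAIR_E.get((a[i], b[l]))
            if e is not None:
                rec(i + 1, l, acc + e, npairs + 1)

    rec(0, m, 0.0, 0)
    return best[0]


def enumerate_structures(res: str, cut: int | None = None):
    """All intra-interval secondary structures as tuples of 0-based pairs.

    Minimum hairpin loop of MIN_LOOP unpaired bases, waived for pairs
    spanning ``cut`` (two concatenated molecules).
    """
    n = len(res)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if i >= j:
            return [()]
        out = list(rec(i + 1, j))
        for k in range(i + 1, j + 1):
            spans = cut is not None and i < cut <= k
            if not spans and k - i - 1 < MIN_LOOP:
                continue
            if (res[i], res[k]) not in PAIR_E:
                continue
            for inner in rec(i + 1, k - 1):
                for outer in rec(k + 1, j):
                    out.append(((i, k),) + inner + outer)
        return out

    result = rec(0, n - 1)
    rec.cache_clear()
    return result


def structure_energy(res: str, pairs) -> float:
    return sum(PAIR_E[(res[i], res[j])] for i, j in pairs)


def ensemble_free_energy_enumeration(
    res: str, unpaired_region: tuple[int, int] | None = None
) -> float:
    """-RT ln sum over structures of exp(-E/RT); region is 1-based."""
    z = 0.0
    blocked = set()
    if unpaired_region:
        blocked = set(range(unpaired_region[0] - 1, unpaired_region[1]))
    for s in enumerate_structures(res):
        if blocked and any(i in blocked or j in blocked for i, j in s):
            continue
        z += math.exp(-structure_energy(res, s) / RT)
    return -RT * math.log(z)


def cofold_mfe_enumeration(a: str, b: str, forced: list[tuple[int, int]]):
    """(energy, pairs) of the constrained joint MFE by full enumeration.

    ``forced`` holds 1-based (i on a, j on b) pairs that must be present.
    Returns None when no structure satisfies the constraints.
    """
    n1 = len(a)
    res = a + b
    want = {(i - 1, n1 + j - 1) for i, j in forced}
    best = None
    for s in enumerate_structures(res, cut=n1):
        if not want <= set(s):
            continue
        e = structure_energy(res, s)
        if best is None or e < best[0]:
            best = (e, s)
    return best


def seed_scan_bruteforce(srna: str, target: str, min_len: int = 5):
    """All maximal antiparallel complementary runs, G-U trimmed, >= min_len,
    found by checking every possible start pair and extending."""
    GU = {("G", "U"), ("U", "G")}
    n, m = len(srna), len(target)

    def comp(i, j):
        return 0 <= i < n and 0 <= j < m and (srna[i], target[j]) in PAIR_E

    out = []
    for i in range(n):
        for j in range(m):
            if not comp(i, j) or comp(i - 1, j + 1):
                continue  # not a maximal-run start
            length = 0
            while comp(i + length, j - length):
                length += 1
            s, ln = i, length
            while ln > 0 and (srna[s], target[j - (s - i)]) in GU:
                s += 1
                ln -= 1
            while ln > 0 and (srna[s + ln - 1], target[j - (s - i) - ln + 1]) in GU:
                ln -= 1
            if ln >= min_len:
                t_hi = j - (s - i)  # 0-based target end of trimmed run
                out.append(((s + 1, s + ln), (t_hi - ln + 2, t_hi + 1)))
    return sorted(out)
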