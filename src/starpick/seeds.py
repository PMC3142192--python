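"""Seed selection: candidate perfectly paired helices and their screening.

A seed is a maximal antiparallel run of consecutive complementary base
pairs (Watson-Crick plus G-U) between the sRNA and the target window,
trimmed of terminal G-U pairs.  Seeds shorter than five pairs are
discarded, the remaining ones must satisfy length-dependent composition
rules, and finally their accessibility-corrected hybridization energy
(ddG) must fall below a stability threshold (-2 kcal/mol by default,
strict inequality).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

from starpick.energy import EnergyEngine, bundle, can_pair, open_energy
from starpick.io_formats import RnaSequence

DEFAULT_SEED_DDG_THRESHOLD = -2.0
MIN_SEED_LENGTH = 5

_GU = {("G", "U"), ("U", "G")}
_GC = {("G", "C"), ("C", "G")}


@dataclasses.dataclass
class SeedMatch:
    """A consecutive-base-pair helix candidate.

    Intervals are 1-based inclusive; the pairing is antiparallel, so sRNA
    position ``srna_interval[0] + k`` pairs target position
    ``target_interval[1] - k``.
    """

    srna_interval: tuple[int, int]
    target_interval: tuple[int, int]
    length: int
    n_gc: int
    n_gu: int
    n_au: int
    max_consecutive_gc: int
    dg_hybrid_seed: Optional[float] = None
    ddg_seed: Optional[float] = None

    def pairs(self) -> list[tuple[int, int]]:
        """(sRNA position, target position) pairs, 1-based."""
        s0 = self.srna_interval[0]
        t1 = self.target_interval[1]
        return [(s0 + k, t1 - k) for k in range(self.length)]

    @property
    def scored(self) -> bool:
        return self.ddg_seed is not None


def _classify(x: str, y: str) -> str:
    if (x, y) in _GU:
        return "gu"
    if (x, y) in _GC:
        return "gc"
    return "au"


def _make_seed(srna: str, target: str, s0: int, t1: int, length: int) -> SeedMatch:
    """Build a SeedMatch from 0-based run anchors: sRNA run starts at s0,
    target run ends at t1 (pairing (s0 + k, t1 - k))."""
    kinds = [_classify(srna[s0 + k], target[t1 - k]) for k in range(length)]
    n_gc = kinds.count("gc")
    n_gu = kinds.count("gu")
    n_au = kinds.count("au")
    best = run = 0
    for k in kinds:
        run = run + 1 if k == "gc" else 0
        best = max(best, run)
    return SeedMatch(
        srna_interval=(s0 + 1, s0 + length),
        target_interval=(t1 - length + 2, t1 + 1),
        length=length,
        n_gc=n_gc,
        n_gu=n_gu,
        n_au=n_au,
        max_consecutive_gc=best,
    )


def enumerate_helices(
    srna: RnaSequence | str,
    target: RnaSequence | str,
    min_len: int = MIN_SEED_LENGTH,
) -> list[SeedMatch]:
    """All maximal antiparallel complementary runs, G-U-trimmed, >= min_len.

    Runs live on anti-diagonals of the complementarity matrix: a pair
    (i, j) stacks on (i+1, j-1).  Each maximal run is trimmed of terminal
    G-U pairs from both ends (sub-runs are not emitted separately).
    Output is ordered by sRNA start, then target end.
    """
    rs = srna.residues if isinstance(srna, RnaSequence) else srna
    rt = target.residues if isinstance(target, RnaSequence) else target
    n, m = len(rs), len(rt)
    out: list[SeedMatch] = []
    # anti-diagonal d = i + j, i on sRNA ascending
    for d in range(n + m - 1):
        i_lo = max(0, d - m + 1)
        i_hi = min(n - 1, d)
        i = i_lo
        while i <= i_hi:
            if can_pair(rs[i], rt[d - i]):
                start = i
                while i <= i_hi and can_pair(rs[i], rt[d - i]):
                    i += 1
                s0, length = _trim_gu(rs, rt, start, d, i - start)
                if length >= min_len:
                    out.append(_make_seed(rs, rt, s0, d - s0, length))
            else:
                i += 1
    out.sort(key=lambda s: (s.srna_interval, s.target_interval))
    return out


def _trim_gu(rs: str, rt: str, s0: int, d: int, length: int) -> tuple[int, int]:
    """Trim terminal G-U pairs from both ends of the run (idempotent)."""
    while length > 0 and (rs[s0], rt[d - s0]) in _GU:
        s0 += 1
        length -= 1
    while length > 0 and (rs[s0 + length - 1], rt[d - s0 - length + 1]) in _GU:
        length -= 1
    return s0, length


def passes_composition_rules(seed: SeedMatch) -> bool:
    """Length-dependent base-pair composition screen.

    length 5: no G-U, and >= 4 G-C or 3 consecutive G-C;
    length 6-7: <= 1 G-U and >= 3 G-C;
    length 8-9: <= 1 G-U and >= 2 G-C;
    length >= 10: <= 4 G-U and >= 2 G-C.
    """
    ln = seed.length
    if ln < MIN_SEED_LENGTH:
        raise ValueError(f"seed length {ln} below minimum {MIN_SEED_LENGTH}")
    if ln == 5:
        return seed.n_gu == 0 and (seed.n_gc >= 4 or seed.max_consecutive_gc >= 3)
    if ln <= 7:
        return seed.n_gu <= 1 and seed.n_gc >= 3
    if ln <= 9:
        return seed.n_gu <= 1 and seed.n_gc >= 2
    return seed.n_gu <= 4 and seed.n_gc >= 2


def score_seed(
    seed: SeedMatch,
    srna: RnaSequence,
    target: RnaSequence,
    engine: EnergyEngine,
    target_offset: int = 0,
) -> SeedMatch:
    """Fill dG_hybrid and ddG for the seed.

    The sRNA opening energy folds the full-length sRNA; the target opening
    energy folds the seed region plus up to 100 nt of flank within
    ``target``.  ``target_offset`` shifts seed target coordinates into
    ``target`` coordinates when the seed was enumerated on a sub-window of
    a longer accessibility context.
    """
    s_lo, s_hi = seed.srna_interval
    t_lo, t_hi = seed.target_interval
    t_lo += target_offset
    t_hi += target_offset
    dup = engine.duplex_energy(
        srna.subsequence(s_lo, s_hi), target.subsequence(t_lo, t_hi)
    )
    if not dup.interacting:  # cannot happen for a complementary run, but be safe
        seed.dg_hybrid_seed = None
        seed.ddg_seed = None
        return seed
    open_s = open_energy(engine, srna, (s_lo, s_hi), "full_length")
    open_t = open_energy(engine, target, (t_lo, t_hi), "flank_100")
    b = bundle(dup.energy, open_s, open_t)
    seed.dg_hybrid_seed = b.dg_hybrid
    seed.ddg_seed = b.ddg
    return seed


def select_seeds(
    seeds: Sequence[SeedMatch],
    ddg_threshold: float = DEFAULT_SEED_DDG_THRESHOLD,
) -> list[SeedMatch]:
    """Keep scored seeds passing composition rules with ddG strictly below
    the threshold; order-preserving."""
    kept = []
    for s in seeds:
        if not s.scored:
            raise ValueError("select_seeds requires scored seeds")
        if passes_composition_rules(s) and s.ddg_seed < ddg_threshold:
            kept.append(s)
    return kept
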