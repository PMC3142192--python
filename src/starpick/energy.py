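"""Hybridization and accessibility energetics.

Three quantities drive the predictor, all in kcal/mol at 37 degC:

* ``dG_hybrid`` -- minimum free energy of the purely inter-molecular
  duplex between two regions (RNAduplex-style).
* ``dG_open``  -- cost of freeing a region from intra-molecular structure,
  computed as the difference between the constrained (region forced
  single-stranded) and unconstrained ensemble free energies.  It is
  non-negative by construction.
* ``ddG``      -- dG_hybrid + dG_open(sRNA region) + dG_open(target
  region): the accessibility-corrected interaction energy.

Two engines implement the same contract: :class:`ViennaEngine` adapts the
ViennaRNA nearest-neighbor programs (the production path) and
:class:`ToyEngine` is a self-contained stacking-free model (pair energies
G-C -3, A-U -2, G-U -1; no loop terms; minimum hairpin loop 3) whose MFE
and partition function are exact, so the entire test suite runs without
external parameter tables.
"""

from __future__ import annotations

import abc
import dataclasses
import math
from typing import Optional, Sequence, Union

import numpy as np

from starpick import _toyfold
from starpick.io_formats import RnaSequence, StructureTable, dotbracket_to_table

GAS_CONSTANT = 0.0019872041  # kcal / (mol K)
TEMPERATURE_C = 37.0
RT = GAS_CONSTANT * (TEMPERATURE_C + 273.15)

TOY_PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

MIN_HAIRPIN_LOOP = 3

SeqLike = Union[RnaSequence, str]


def _residues(seq: SeqLike) -> str:
    return seq.residues if isinstance(seq, RnaSequence) else seq


def pair_energy(x: str, y: str) -> Optional[float]:
    """Toy-model energy of pairing bases x and y, None if they cannot pair."""
    return TOY_PAIR_ENERGY.get((x, y))


def can_pair(x: str, y: str) -> bool:
    return (x, y) in TOY_PAIR_ENERGY


class ConstraintError(RuntimeError):
    """The engine could not satisfy the requested base-pair constraints."""


@dataclasses.dataclass(frozen=True)
class DuplexResult:
    """Inter-molecular MFE duplex.  ``energy`` is None when no pair can
    form (the no-interaction sentinel); ``pairs`` are 1-based (i on the
    first molecule, j on the second)."""

    energy: Optional[float]
    pairs: tuple[tuple[int, int], ...] = ()

    @property
    def interacting(self) -> bool:
        return self.energy is not None


@dataclasses.dataclass(frozen=True)
class EnergyBundle:
    dg_hybrid: Optional[float]
    dg_open_srna: float
    dg_open_target: float

    @property
    def interacting(self) -> bool:
        return self.dg_hybrid is not None

    @property
    def ddg(self) -> Optional[float]:
        if not self.interacting:
            return None
        return self.dg_hybrid + self.dg_open_srna + self.dg_open_target


def bundle(
    dg_hybrid: Optional[float], open_srna: float, open_target: float
) -> EnergyBundle:
    """Assemble an :class:`EnergyBundle`; ddG = dG_hybrid + dG_open terms."""
    for v in (open_srna, open_target):
        if not math.isfinite(v):
            raise ValueError("opening energies must be finite")
    if dg_hybrid is not None and not math.isfinite(dg_hybrid):
        raise ValueError("dg_hybrid must be finite or None (no interaction)")
    return EnergyBundle(dg_hybrid, open_srna, open_target)


class EnergyEngine(abc.ABC):
    """Deterministic folding-engine contract (energies in kcal/mol, 37 degC)."""

    engine_id: str = "abstract"
    temperature: float = TEMPERATURE_C

    @abc.abstractmethod
    def duplex_energy(self, a: SeqLike, b: SeqLike) -> DuplexResult:
        """MFE over structures containing only inter-molecular pairs
        (Watson-Crick plus G-U)."""

    @abc.abstractmethod
    def ensemble_energy(
        self, seq: SeqLike, unpaired_region: Optional[tuple[int, int]] = None
    ) -> float:
        """Equilibrium ensemble free energy -RT ln Z over intra-molecular
        structures; with ``unpaired_region`` (1-based inclusive) the sum
        runs only over structures leaving every region base unpaired."""

    @abc.abstractmethod
    def cofold(
        self,
        a: SeqLike,
        b: SeqLike,
        forced_pairs: Sequence[tuple[int, int]] = (),
    ) -> tuple[StructureTable, float]:
        """Joint MFE structure of the two concatenated molecules with every
        ``forced_pairs`` entry (i on a, j on b, both 1-based) enforced."""

    def metadata(self) -> dict:
        return {"engine_id": self.engine_id, "temperature": self.temperature}


# ---------------------------------------------------------------------------
# toy engine


class ToyEngine(EnergyEngine):
    """Stacking-free reference engine, exact by dynamic programming."""

    engine_id = "toy-nn0"

    def duplex_energy(self, a: SeqLike, b: SeqLike) -> DuplexResult:
        ra, rb = _residues(a), _residues(b)
        if not ra or not rb:
            raise ValueError("duplex_energy requires nonempty sequences")
        n, m = len(ra), len(rb)
        rbrev = rb[::-1]
        # antiparallel duplex: pairs (i, j) with i ascending on a and j
        # descending on b form a common-subsequence chain of a vs reversed b
        D = np.zeros((n + 1, m + 1))
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                best = max(D[i - 1][j], D[i][j - 1])
                e = pair_energy(ra[i - 1], rbrev[j - 1])
                if e is not None:
                    cand = D[i - 1][j - 1] - e
                    if cand > best:
                        best = cand
                D[i][j] = best
        if D[n][m] <= 0.0:
            return DuplexResult(None)
        pairs = []
        i, j = n, m
        while i > 0 and j > 0:
            if D[i][j] == D[i - 1][j]:
                i -= 1
            elif D[i][j] == D[i][j - 1]:
                j -= 1
            else:
                pairs.append((i, m - j + 1))  # back to original b coordinate
                i -= 1
                j -= 1
        pairs.reverse()
        return DuplexResult(-float(D[n][m]), tuple(pairs))

    def _pair_matrix(
        self,
        res: str,
        blocked: Optional[set[int]] = None,
        cut: Optional[int] = None,
    ) -> np.ndarray:
        """Energy matrix, +INF where the pair (i, j) is disallowed (0-based)."""
        n = len(res)
        W = np.full((n, n), _toyfold.INF)
        blocked = blocked or set()
        for i in range(n):
            if i in blocked:
                continue
            for j in range(i + 1, n):
                if j in blocked:
                    continue
                spans_cut = cut is not None and i < cut <= j
                if not spans_cut and j - i - 1 < MIN_HAIRPIN_LOOP:
                    continue
                e = pair_energy(res[i], res[j])
                if e is not None:
                    W[i, j] = e
        return W

    def ensemble_energy(
        self, seq: SeqLike, unpaired_region: Optional[tuple[int, int]] = None
    ) -> float:
        res = _residues(seq)
        n = len(res)
        blocked: Optional[set[int]] = None
        if unpaired_region is not None:
            s, e = unpaired_region
            if not (1 <= s <= e <= n):
                raise ValueError(
                    f"unpaired_region [{s},{e}] outside sequence of length {n}"
                )
            blocked = set(range(s - 1, e))
        W = self._pair_matrix(res, blocked)
        if not np.any(W < _toyfold.INF / 2):
            return 0.0  # only the open chain exists
        # per-base scale from the (unconstrained) MFE keeps Z in double range
        Wfree = self._pair_matrix(res) if blocked else W
        must = np.zeros(n, dtype=np.bool_)
        mfe = float(_toyfold.nussinov_fill(Wfree, must)[0][n])
        log_c = max(0.0, -mfe / (RT * n))
        Wb = np.where(W < _toyfold.INF / 2, np.exp(-W / RT), 0.0)
        logz = _toyfold.partition_logz(Wb, log_c)
        if math.isnan(logz):
            raise OverflowError("partition function out of double range")
        return -RT * logz

    def cofold(
        self,
        a: SeqLike,
        b: SeqLike,
        forced_pairs: Sequence[tuple[int, int]] = (),
    ) -> tuple[StructureTable, float]:
        ra, rb = _residues(a), _residues(b)
        n1 = len(ra)
        res = ra + rb
        n = len(res)
        W = self._pair_matrix(res, cut=n1)
        must = np.zeros(n, dtype=np.bool_)
        forced = {}
        for i, j in forced_pairs:
            gi, gj = i - 1, n1 + j - 1
            if not (0 <= gi < n1 and n1 <= gj < n):
                raise ValueError(f"forced pair ({i},{j}) out of range")
            forced[gi] = gj
            forced[gj] = gi
        for i, j in forced.items():
            if i < j and W[i, j] >= _toyfold.INF / 2:
                raise ConstraintError(f"forced pair {i + 1}-{j + 1} cannot form")
        for i in range(n):
            if i in forced:
                must[i] = True
                p = forced[i]
                W[i, :] = _toyfold.INF
                W[:, i] = _toyfold.INF
                lo, hi = min(i, p), max(i, p)
                W[lo, hi] = pair_energy(res[lo], res[hi])
        M = _toyfold.nussinov_fill(W, must)
        energy = float(M[0][n])
        if energy >= _toyfold.INF / 2:
            raise ConstraintError("constraints admit no valid joint structure")
        partner = _toyfold.nussinov_traceback(M, W, must)
        return StructureTable(partner, cut_point=n1), energy


# ---------------------------------------------------------------------------
# ViennaRNA adapter


class ViennaEngine(EnergyEngine):
    """Adapter to the ViennaRNA nearest-neighbor programs.

    Uses RNAduplex-style duplex folding for dG_hybrid, the constrained
    partition function for opening energies, and two-strand MFE folding
    with enforced seed pairs, lonely pairs disallowed and G-U forbidden at
    helix ends for binding-site extension.  Dangling-end and terminal-AU
    options are left at the library defaults.
    """

    def __init__(self):
        import RNA  # deferred so the toy engine works without the bindings

        self._RNA = RNA
        self.engine_id = f"vienna-{RNA.__version__}"

    def duplex_energy(self, a: SeqLike, b: SeqLike) -> DuplexResult:
        ra, rb = _residues(a), _residues(b)
        if not ra or not rb:
            raise ValueError("duplex_energy requires nonempty sequences")
        d = self._RNA.duplexfold(ra, rb)
        part1, part2 = d.structure.split("&")
        if "(" not in part1:
            return DuplexResult(None)
        start1 = d.i - len(part1) + 1
        start2 = d.j
        opens = [start1 + k for k, c in enumerate(part1) if c == "("]
        closes = [start2 + k for k, c in enumerate(part2) if c == ")"]
        pairs = tuple(zip(opens, closes[::-1]))
        return DuplexResult(float(d.energy), pairs)

    def ensemble_energy(
        self, seq: SeqLike, unpaired_region: Optional[tuple[int, int]] = None
    ) -> float:
        res = _residues(seq)
        fc = self._RNA.fold_compound(res)
        if unpaired_region is not None:
            s, e = unpaired_region
            if not (1 <= s <= e <= len(res)):
                raise ValueError(
                    f"unpaired_region [{s},{e}] outside sequence of length {len(res)}"
                )
            for p in range(s, e + 1):
                fc.hc_add_up(p)
        _, energy = fc.pf()
        return float(energy)

    def cofold(
        self,
        a: SeqLike,
        b: SeqLike,
        forced_pairs: Sequence[tuple[int, int]] = (),
    ) -> tuple[StructureTable, float]:
        RNA = self._RNA
        ra, rb = _residues(a), _residues(b)
        n1, n2 = len(ra), len(rb)
        md = RNA.md()
        md.noLP = 1
        md.noGUclosure = 1
        fc = RNA.fold_compound(f"{ra}&{rb}", md)
        if forced_pairs:
            cons = ["."] * (n1 + n2)
            for i, j in forced_pairs:
                if not (1 <= i <= n1 and 1 <= j <= n2):
                    raise ValueError(f"forced pair ({i},{j}) out of range")
                cons[i - 1] = "("
                cons[n1 + j - 1] = ")"
            fc.hc_add_from_db(
                "".join(cons),
                RNA.CONSTRAINT_DB_DEFAULT | RNA.CONSTRAINT_DB_ENFORCE_BP,
            )
        structure, energy = fc.mfe()
        if not math.isfinite(energy) or energy > 1e5:
            raise ConstraintError("constraints admit no valid joint structure")
        table = dotbracket_to_table(structure, cut_point=n1)
        for i, j in forced_pairs:
            if table.partner[i - 1] != n1 + j - 1:
                raise ConstraintError(
                    f"engine dropped forced pair ({i},{j}) from the MFE structure"
                )
        return table, float(energy)


def get_engine(name: str) -> EnergyEngine:
    if name == "toy":
        return ToyEngine()
    if name == "vienna":
        return ViennaEngine()
    raise ValueError(f"unknown engine {name!r} (expected 'toy' or 'vienna')")


def open_energy(
    engine: EnergyEngine,
    seq: SeqLike,
    region: tuple[int, int],
    flank_policy: str = "full_length",
    flank: int = 100,
) -> float:
    """dG_open = dG_unpaired - dG_paired for ``region`` (1-based inclusive).

    ``full_length`` folds the whole molecule (used for sRNAs);
    ``flank_100`` folds the region plus up to ``flank`` nt on each side,
    truncated at the molecule ends (used for mRNA target regions).
    Always >= 0 up to engine rounding, which is clamped.
    """
    res = _residues(seq)
    n = len(res)
    s, e = region
    if not (1 <= s <= e <= n):
        raise ValueError(f"region [{s},{e}] outside sequence of length {n}")
    if flank_policy == "full_length":
        sub, rs, re_ = res, s, e
    elif flank_policy == "flank_100":
        lo = max(1, s - flank)
        hi = min(n, e + flank)
        sub = res[lo - 1 : hi]
        rs, re_ = s - lo + 1, e - lo + 1
    else:
        raise ValueError(f"unknown flank_policy {flank_policy!r}")
    dg_paired = engine.ensemble_energy(sub)
    dg_unpaired = engine.ensemble_energy(sub, (rs, re_))
    diff = dg_unpaired - dg_paired
    if diff < -0.05:
        raise RuntimeError(
            f"negative opening energy {diff:.3f} kcal/mol; engine inconsistency"
        )
    return max(0.0, diff)
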