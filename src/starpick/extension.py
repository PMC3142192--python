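"""Binding-site extension: elongate a selected seed into the full duplex.

The sRNA is co-folded with the target seed region plus up to 100 nt of
window context on each side, with every seed pair enforced.  From each
seed boundary the joint structure is scanned outward over positions that
are inter-molecularly paired or unpaired; the first position caught in an
intra-molecular pair halts that side.  The site is then clipped to the
outermost inter-molecular pair on each side, so interior loops and bulges
belong to the site but dangling single-stranded tails do not.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

from starpick.energy import (
    ConstraintError,
    EnergyEngine,
    bundle,
    open_energy,
)
from starpick.io_formats import RnaSequence, StructureTable
from starpick.seeds import SeedMatch

logger = logging.getLogger(__name__)

CONTEXT_FLANK = 100

_GU = {("G", "U"), ("U", "G")}


@dataclasses.dataclass
class JointStructure:
    """Co-folded sRNA + target-context structure.

    ``table`` spans the concatenation (sRNA first, cut at ``srna_len``);
    ``context_interval`` locates the folded context on the target window
    (1-based inclusive).
    """

    table: StructureTable
    srna_len: int
    context_interval: tuple[int, int]
    energy: float

    def target_pos(self, joint_pos: int) -> int:
        """Map a 1-based joint position in the context to a window position."""
        return joint_pos - self.srna_len + self.context_interval[0] - 1


@dataclasses.dataclass
class BindingSite:
    """The extended inter-molecular duplex grown from one seed."""

    seed: SeedMatch
    srna_site: tuple[int, int]
    target_site: tuple[int, int]
    hybrid_pairs: tuple[tuple[int, int], ...]  # (sRNA pos, window pos), 1-based
    dg_binding: Optional[float] = None
    ddg_binding: Optional[float] = None

    @property
    def scored(self) -> bool:
        return self.ddg_binding is not None


def cofold_with_seed(
    srna: RnaSequence,
    window: RnaSequence,
    seed: SeedMatch,
    engine: EnergyEngine,
    context_flank: int = CONTEXT_FLANK,
    enforce_helix_rules: bool = True,
) -> JointStructure:
    """Joint MFE structure with the seed pairing enforced.

    The target context is the seed region plus up to ``context_flank`` nt
    each side of the window (truncated at window edges).  When
    ``enforce_helix_rules`` is set, lonely (isolated) pairs and G-U pairs
    closing a helix are pruned from the returned structure (seed pairs are
    exempt); the production engine already forbids them, so pruning only
    matters for engines without native support.
    """
    t_lo, t_hi = seed.target_interval
    c_lo = max(1, t_lo - context_flank)
    c_hi = min(len(window), t_hi + context_flank)
    context = window.subsequence(c_lo, c_hi)
    forced = [(i, j - c_lo + 1) for i, j in seed.pairs()]
    table, energy = engine.cofold(srna, context, forced)
    if enforce_helix_rules:
        forced_set = {(i, len(srna) + j) for i, j in forced}
        _prune_helix_rule_violations(table, srna.residues + context.residues, forced_set)
    return JointStructure(table, len(srna), (c_lo, c_hi), energy)


def _prune_helix_rule_violations(
    table: StructureTable, residues: str, exempt: set[tuple[int, int]]
) -> None:
    """Iteratively drop lonely pairs and helix-terminal G-U pairs in place.

    A pair (i, j) is lonely when neither (i+1, j-1) nor (i-1, j+1) pairs;
    a G-U pair closes a helix when it terminates a stack run.  Removal can
    expose new violations, so iterate to a fixed point.
    """
    partner = table.partner
    n = len(partner)

    def paired(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and partner[i] == j

    changed = True
    while changed:
        changed = False
        for i in range(n):
            j = partner[i]
            if j <= i or (i + 1, j + 1) in exempt:
                continue
            inner = paired(i + 1, j - 1)
            outer = paired(i - 1, j + 1)
            lonely = not inner and not outer
            gu_terminal = (residues[i], residues[j]) in _GU and (
                not inner or not outer
            )
            if lonely or gu_terminal:
                partner[i] = -1
                partner[j] = -1
                changed = True


def scan_outward(joint: JointStructure, seed: SeedMatch) -> BindingSite:
    """Grow the site from the seed boundaries until an intra-molecular
    pair halts each side, then clip to the outermost inter-molecular pair."""
    table = joint.table
    n1 = joint.srna_len
    n = len(table)
    s_lo, s_hi = seed.srna_interval
    # seed target interval in joint coordinates
    t_lo_w, t_hi_w = seed.target_interval
    c_lo = joint.context_interval[0]
    jt_lo = n1 + (t_lo_w - c_lo) + 1
    jt_hi = n1 + (t_hi_w - c_lo) + 1

    def sweep(start: int, stop: int, step: int) -> int:
        """Last admissible joint position walking from start towards stop."""
        last = start
        p = start + step
        while (p - stop) * step <= 0:
            if table.is_intramolecular(p):
                break
            last = p
            p += step
        return last

    lo_s = sweep(s_lo, 1, -1)
    hi_s = sweep(s_hi, n1, +1)
    lo_t = sweep(jt_lo, n1 + 1, -1)
    hi_t = sweep(jt_hi, n, +1)

    inter = [
        (i + 1, int(p) + 1)
        for i, p in enumerate(table.partner)
        if p >= 0 and i < n1 <= p
    ]
    kept = [
        (i, j)
        for i, j in inter
        if lo_s <= i <= hi_s and lo_t <= j <= hi_t
    ]
    # the seed pairs are always present and inside the swept ranges
    lo_s = min(i for i, _ in kept)
    hi_s = max(i for i, _ in kept)
    lo_t = min(j for _, j in kept)
    hi_t = max(j for _, j in kept)
    hybrid = tuple(
        sorted((i, joint.target_pos(j)) for i, j in kept)
    )
    return BindingSite(
        seed=seed,
        srna_site=(lo_s, hi_s),
        target_site=(joint.target_pos(lo_t), joint.target_pos(hi_t)),
        hybrid_pairs=hybrid,
    )


def score_binding_site(
    site: BindingSite,
    srna: RnaSequence,
    target: RnaSequence,
    engine: EnergyEngine,
    target_offset: int = 0,
) -> BindingSite:
    """Fill dG_binding (duplex MFE of the two site subsequences) and
    ddG_binding (plus opening energies, full-length sRNA / 100-nt-flanked
    target).  ``target_offset`` maps window coordinates into ``target``."""
    s_lo, s_hi = site.srna_site
    t_lo = site.target_site[0] + target_offset
    t_hi = site.target_site[1] + target_offset
    dup = engine.duplex_energy(
        srna.subsequence(s_lo, s_hi), target.subsequence(t_lo, t_hi)
    )
    if not dup.interacting:
        site.dg_binding = None
        site.ddg_binding = None
        return site
    open_s = open_energy(engine, srna, (s_lo, s_hi), "full_length")
    open_t = open_energy(engine, target, (t_lo, t_hi), "flank_100")
    b = bundle(dup.energy, open_s, open_t)
    site.dg_binding = b.dg_hybrid
    site.ddg_binding = b.ddg
    return site


def extend_seed(
    srna: RnaSequence,
    window: RnaSequence,
    seed: SeedMatch,
    engine: EnergyEngine,
    context_flank: int = CONTEXT_FLANK,
) -> Optional[BindingSite]:
    """cofold + scan convenience; None when constraints are unsatisfiable."""
    try:
        joint = cofold_with_seed(srna, window, seed, engine, context_flank)
    except ConstraintError as exc:
        logger.warning("extension aborted for seed %s: %s", seed.srna_interval, exc)
        return None
    return scan_outward(joint, seed)
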