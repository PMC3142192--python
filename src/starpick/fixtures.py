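"""Synthetic, label-known inputs for every stage of the pipeline.

The generators plant exact complementary helices of controlled length and
composition into random-background sRNA/target pairs, build labeled
feature tables with a known informative-feature structure, and assemble
small annotated genomes with planted target genes, so energies, seed
screening, extension, training and the genome-wide mode are all testable
without any external data.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd


from starpick.io_formats import GeneRecord, RnaSequence
from starpick.seeds import SeedMatch, enumerate_helices, passes_composition_rules
from starpick.ensemble import NEGATIVE, POSITIVE, TrainingTable

#: default background composition; the A/U-rich alternative sharpens tests
#: by making accidental rule-passing seeds rare
UNIFORM = {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25}
AU_RICH = {"A": 0.4, "C": 0.1, "G": 0.1, "U": 0.4}

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _random_background(rng: np.random.Generator, n: int, comp: dict) -> str:
    bases = list(comp)
    return "".join(rng.choice(bases, size=n, p=[comp[b] for b in bases]))


def _revcomp_rna(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


@dataclasses.dataclass(frozen=True)
class PlantSpec:
    """A planted complementary helix: length, composition and context."""

    seed_len: int = 8
    n_gc: int = 6
    n_gu: int = 0
    srna_pos: int = 20  # 1-based position of the helix start on the sRNA
    target_pos: int = 100  # 1-based position of the helix start on the target
    context: str = "open"  # "open" (A/U background) or "occluded" (hairpin stem)
    srna_len: int = 60
    target_len: int = 250
    background: Optional[dict] = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_gc + self.n_gu > self.seed_len:
            raise ValueError("n_gc + n_gu exceeds seed length")
        if self.context not in ("open", "occluded"):
            raise ValueError("context must be 'open' or 'occluded'")
        if self.srna_pos + self.seed_len - 1 > self.srna_len:
            raise ValueError("planted helix overruns the sRNA")
        if self.target_pos + self.seed_len - 1 > self.target_len:
            raise ValueError("planted helix overruns the target")


def _seed_pair_sequences(spec: PlantSpec, rng: np.random.Generator) -> tuple[str, str]:
    """sRNA-side helix sequence and the target-side pairing partner.

    Terminal pairs are never G-U (they would be trimmed away), achieved by
    placing G-U pairs at interior slots only.
    """
    n_au = spec.seed_len - spec.n_gc - spec.n_gu
    kinds = ["gc"] * spec.n_gc + ["au"] * n_au
    rng.shuffle(kinds)
    if spec.n_gu:
        if spec.seed_len - 2 < spec.n_gu:
            raise ValueError("not enough interior slots for G-U pairs")
        gu_slots = rng.choice(
            np.arange(1, spec.seed_len - 1), size=spec.n_gu, replace=False
        )
        others = iter(kinds)
        kinds = [
            "gu" if k in gu_slots else next(others) for k in range(spec.seed_len)
        ]
    srna_side = []
    target_side = []  # written 5'->3' along the target
    for kind in kinds:
        if kind == "gc":
            s = rng.choice(["G", "C"])
            t = _RC[s]
        elif kind == "au":
            s = rng.choice(["A", "U"])
            t = _RC[s]
        else:
            s = rng.choice(["G", "U"])
            t = "U" if s == "G" else "G"
        srna_side.append(s)
        target_side.append(t)
    return "".join(srna_side), "".join(reversed(target_side))


def generate_pair(spec: PlantSpec) -> tuple[RnaSequence, RnaSequence, SeedMatch]:
    """Random-background pair with one exact planted helix and its truth.

    The ``occluded`` context wraps the planted target stretch in a perfect
    hairpin stem so that its opening energy is large.
    """
    rng = np.random.default_rng(spec.rng_seed)
    comp = spec.background or AU_RICH
    srna_res = list(_random_background(rng, spec.srna_len, comp))
    target_res = list(_random_background(rng, spec.target_len, comp))
    s_side, t_side = _seed_pair_sequences(spec, rng)
    s0 = spec.srna_pos - 1
    t0 = spec.target_pos - 1
    srna_res[s0 : s0 + spec.seed_len] = s_side
    target_res[t0 : t0 + spec.seed_len] = t_side
    # pin the bases stacking onto either end of the helix to A.A (cannot
    # pair), so the planted run is exactly maximal
    if s0 > 0:
        srna_res[s0 - 1] = "A"
    if t0 + spec.seed_len < spec.target_len:
        target_res[t0 + spec.seed_len] = "A"
    if s0 + spec.seed_len < spec.srna_len:
        srna_res[s0 + spec.seed_len] = "A"
    if t0 > 0:
        target_res[t0 - 1] = "A"
    if spec.context == "occluded":
        # complement of the planted stretch downstream, 4-nt loop between,
        # so the target helix sits inside a perfect stem
        stem_rc = _revcomp_rna("".join(t_side))
        loop_end = t0 + spec.seed_len + 4
        if loop_end + spec.seed_len > spec.target_len:
            raise ValueError("no room for the occluding stem")
        target_res[loop_end : loop_end + spec.seed_len] = stem_rc
    srna = RnaSequence("srna_planted", "".join(srna_res), "synthetic")
    target = RnaSequence("target_planted", "".join(target_res), "synthetic")
    truth_kinds = [
        _pair_kind(srna.residues[s0 + k], target.residues[t0 + spec.seed_len - 1 - k])
        for k in range(spec.seed_len)
    ]
    truth = SeedMatch(
        srna_interval=(spec.srna_pos, spec.srna_pos + spec.seed_len - 1),
        target_interval=(spec.target_pos, spec.target_pos + spec.seed_len - 1),
        length=spec.seed_len,
        n_gc=truth_kinds.count("gc"),
        n_gu=truth_kinds.count("gu"),
        n_au=truth_kinds.count("au"),
        max_consecutive_gc=_max_run(truth_kinds, "gc"),
    )
    return srna, target, truth


def _pair_kind(x: str, y: str) -> str:
    if {x, y} == {"G", "U"}:
        return "gu"
    if {x, y} == {"G", "C"}:
        return "gc"
    return "au"


def _max_run(kinds: list[str], kind: str) -> int:
    best = run = 0
    for k in kinds:
        run = run + 1 if k == kind else 0
        best = max(best, run)
    return best


def audit_accidental_seeds(
    srna: RnaSequence, target: RnaSequence, truth: SeedMatch
) -> list[SeedMatch]:
    """Unplanned rule-passing helices in a generated pair (self-check)."""
    return [
        s
        for s in enumerate_helices(srna, target)
        if passes_composition_rules(s)
        and (s.srna_interval, s.target_interval)
        != (truth.srna_interval, truth.target_interval)
    ]


# ---------------------------------------------------------------------------
# labeled feature tables

#: class-conditional separation applied to the ddG of the binding region
#: (f19, in SD units, positives lower) and the seed length (f22, in nt,
#: positives longer by round(effect)).  A true interaction must clear
#: BOTH screens of the two-step model -- an accessible, stable binding
#: region AND a long seed -- so the negative class contains the two
#: corresponding decoy populations (stable-but-short pseudo-seeds and
#: long-but-inaccessible seeds).  Each feature alone misclassifies one
#: decoy population; only the pair excludes both, which is what makes
#: the planted subset uniquely informative rather than a one-feature
#: shortcut.  effect = 0 degenerates to a pure label-independent null.
DEFAULT_EFFECT = 2.0

#: fraction of negatives in each decoy population (rest are background)
DECOY_FRACTION = 0.2

_F19_SD = 2.0


def _truncated_normal(rng, mean, sd, upper=None, lower=None, size=None):
    out = rng.normal(mean, sd, size)
    scalar = size is None
    vals = np.atleast_1d(out)
    for i in range(vals.size):
        while (upper is not None and vals[i] >= upper) or (
            lower is not None and vals[i] < lower
        ):
            vals[i] = rng.normal(mean, sd)
    return float(vals[0]) if scalar else vals


def generate_training_table(
    n_pos: int = 31,
    n_neg: int = 102,
    effect: float = DEFAULT_EFFECT,
    rng_seed: int = 0,
) -> TrainingTable:
    """Labeled 22-feature table with signal planted only on f19 and f22.

    The default 31:102 class ratio reproduces the imbalanced training
    conditions the predictor is built for.  All other features are drawn
    iid from class-independent distributions on their natural scales.
    """
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least two rows per class")
    rng = np.random.default_rng(rng_seed)
    n = n_pos + n_neg
    labels = np.array([POSITIVE] * n_pos + [NEGATIVE] * n_neg)

    comp = rng.dirichlet([4, 4, 4, 4], size=n) * 100.0  # f1..f4 percentages
    f8 = rng.uniform(40, 95, n)
    f17 = 100.0 - f8
    f12 = rng.poisson(1.0, n).astype(float)
    f13 = rng.poisson(1.0, n).astype(float)
    interior_share = rng.uniform(0.2, 0.8, n)
    f15 = f17 * interior_share
    f16 = f17 - f15
    n_bp = rng.integers(8, 25, n).astype(float)
    f10 = rng.uniform(0.6, 1.0, n)
    f11 = np.minimum(rng.integers(3, 12, n).astype(float), n_bp)
    f9 = f8 * f10
    f18 = rng.normal(-14, 3, n)
    f20 = rng.normal(-10, 2, n)
    f21 = rng.normal(-4, 1.5, n)

    f19 = rng.normal(-4.0, _F19_SD, n)
    f22 = 5.0 + rng.binomial(6, 0.25, n).astype(float)
    if effect > 0:
        shift_nt = max(1, int(round(effect)))
        # energy screen: the ddG bound positives always clear and
        # background negatives mostly fail
        bound = -4.0 - (effect - 1.0) * _F19_SD
        # decoy stability shift capped: a pseudo-seed can be as stable as
        # a typical true seed but not arbitrarily so, which also keeps
        # f19 fully separating in the effect -> infinity limit
        decoy_shift = min(effect, 3.0) * _F19_SD
        f19[:n_pos] = _truncated_normal(
            rng, -4.0 - effect * _F19_SD, _F19_SD, upper=bound, size=n_pos
        )
        f22[:n_pos] += shift_nt
        kind = rng.choice(3, size=n_neg, p=[1 - 2 * DECOY_FRACTION,
                                            DECOY_FRACTION, DECOY_FRACTION])
        for j, k in enumerate(kind):
            i = n_pos + j
            if k == 1:  # stable but short: passes the energy screen only
                f19[i] = rng.normal(-4.0 - decoy_shift, _F19_SD)
                f22[i] = 5.0 + min(int(rng.binomial(6, 0.25)), shift_nt - 1)
            elif k == 2:  # long but inaccessible: passes the length screen only
                f19[i] = _truncated_normal(rng, -4.0, _F19_SD, lower=bound)
                f22[i] += shift_nt

    data = {
        "f1": comp[:, 0],
        "f2": comp[:, 1],
        "f3": comp[:, 2],
        "f4": comp[:, 3],
        "f5": comp[:, 2] + comp[:, 1],
        "f6": comp[:, 0] + comp[:, 3],
        "f7": comp[:, 0] + comp[:, 1],
        "f8": f8,
        "f9": f9,
        "f10": f10,
        "f11": f11,
        "f12": f12,
        "f13": f13,
        "f14": f12 + f13,
        "f15": f15,
        "f16": f16,
        "f17": f17,
        "f18": f18,
        "f19": f19,
        "f20": f20,
        "f21": f21,
        "f22": f22,
        "label": labels,
    }
    frame = pd.DataFrame(data)
    frame["pair_id"] = [f"pair{i}" for i in range(n)]
    frame["seed_id"] = ["s0"] * n
    # shuffle rows so class blocks do not align with split order
    frame = frame.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    return TrainingTable(frame)


# ---------------------------------------------------------------------------
# synthetic genomes


def generate_genome(
    n_genes: int = 20,
    n_planted_targets: int = 2,
    srna: Optional[RnaSequence] = None,
    rng_seed: int = 0,
    plant: Optional[PlantSpec] = None,
) -> tuple[RnaSequence, list[GeneRecord], list[str], RnaSequence]:
    """Synthetic contig + annotation with planted sRNA targets.

    Genes are non-overlapping CDSs alternating between strands; each
    planted target carries an open, rule-passing complement of the sRNA
    helix inside its [-150, +100] start-codon window.  Returns (contig as
    a DNA-alphabet sequence is not needed -- the contig is returned in
    RNA alphabet and transliterated on write), gene records, the ids of
    the planted targets, and the sRNA used.
    """
    if n_planted_targets > n_genes:
        raise ValueError("cannot plant more targets than genes")
    rng = np.random.default_rng(rng_seed)
    plant = plant or PlantSpec(seed_len=9, n_gc=7, n_gu=0, rng_seed=rng_seed)
    if srna is None:
        srna_res = list(_random_background(rng, plant.srna_len, AU_RICH))
        s_side, t_side = _seed_pair_sequences(plant, rng)
        # purine-only helix on the sRNA side, so the planted complement is
        # C/U-only and cannot base-pair with the C buffers around it
        s_side = s_side.replace("C", "G").replace("U", "A")
        t_side = _revcomp_rna(s_side)
        s0 = plant.srna_pos - 1
        srna_res[s0 : s0 + plant.seed_len] = s_side
        if s0 > 0:
            srna_res[s0 - 1] = "A"
        if s0 + plant.seed_len < plant.srna_len:
            srna_res[s0 + plant.seed_len] = "A"
        srna = RnaSequence("srna_synth", "".join(srna_res), "synthetic")
        helix_target_side = t_side
    else:
        s0 = plant.srna_pos - 1
        helix = srna.residues[s0 : s0 + plant.seed_len]
        helix_target_side = _revcomp_rna(helix)

    spacing = 700  # window (250) + flanks + CDS, no overlap between windows
    contig_len = spacing * n_genes + 400
    contig = list(_random_background(rng, contig_len, AU_RICH))
    genes: list[GeneRecord] = []
    planted_ids: list[str] = []
    # strand-balanced planting: alternate picks from plus-strand (even
    # index) and minus-strand (odd index) genes
    evens = list(rng.permutation(np.arange(0, n_genes, 2)))
    odds = list(rng.permutation(np.arange(1, n_genes, 2)))
    planted_idx = set()
    for k in range(n_planted_targets):
        pool = evens if (k % 2 == 0 and evens) or not odds else odds
        planted_idx.add(int(pool.pop()))
    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        anchor = 300 + g * spacing  # forward-strand pos of start-codon first base
        gene_id = f"gene{g:03d}"
        if g in planted_idx:
            # The planted cassette (mRNA sense, complement ending at
            # window position -20):
            #   fence | C-buffer | complement | C-buffer | fence
            # C-only buffers are nearly unpairable against the A/U-rich
            # sRNA, so the loop-penalty-free toy model cannot sprawl the
            # extended site into long gappy A-U tails; each fence is a
            # self-pairing hairpin whose intra-molecular stem always
            # forms in the MFE and halts the outward scan, and whose C
            # arm keeps the complement's remote G partners fungible so
            # the site stays cheap to open.
            rel = -20
            L = len(helix_target_side)
            fence = "GGGGG" + "AAAA" + "CCCCC"
            buf = 15
            cassette = fence + "C" * buf + helix_target_side + "C" * buf + fence
            # window index (1-based) of the cassette start; window index
            # w maps to rel = w - 151 for the untruncated window
            idx0 = (151 + rel) - L + 1 - buf - len(fence)
            if strand == "+":
                fwd_start = anchor - 151 + idx0
                contig[fwd_start - 1 : fwd_start - 1 + len(cassette)] = cassette
            else:
                fwd_start = anchor + 151 - (idx0 + len(cassette) - 1)
                seg = _revcomp_rna(cassette)
                contig[fwd_start - 1 : fwd_start - 1 + len(seg)] = seg
            planted_ids.append(gene_id)
        # start codon written after planting so buffers never erase it
        if strand == "+":
            contig[anchor - 1 : anchor + 2] = "AUG"
        else:
            contig[anchor - 3 : anchor] = "CAU"  # AUG on the minus strand
        genes.append(GeneRecord(gene_id, "synth_contig", strand, anchor))
    contig_seq = RnaSequence("synth_contig", "".join(contig), "synthetic")
    return contig_seq, genes, planted_ids, srna


def write_genome_files(
    contig: RnaSequence, genes: list[GeneRecord], fasta_path, gff3_path
) -> None:
    """Emit the synthetic genome as FASTA (DNA alphabet) + GFF3."""
    dna = contig.residues.replace("U", "T")
    with open(fasta_path, "w") as fh:
        fh.write(f">{contig.id}\n")
        for i in range(0, len(dna), 70):
            fh.write(dna[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {contig.id} 1 {len(dna)}\n")
        for g in genes:
            if g.strand == "+":
                start, end = g.start_codon_pos, min(g.start_codon_pos + 299, len(dna))
            else:
                start, end = max(1, g.start_codon_pos - 299), g.start_codon_pos
            fh.write(
                f"{contig.id}\tstarpick_synth\tCDS\t{start}\t{end}\t.\t{g.strand}"
                f"\t0\tID={g.gene_id}\n"
            )
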