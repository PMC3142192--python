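"""The 22 descriptors of a binding-site hybrid.

The hybrid is the concatenation of the sRNA site and target site
nucleotides together with its inter-molecular pairs.  Percentages use the
total nucleotide count of both strands as denominator, so the
paired/unpaired split satisfies f8 + f17 = 100 exactly.  Interior loops
(unpaired stretch on both strands between two pairs) and bulges (stretch
on exactly one strand) are counted from consecutive pairs of the duplex.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from starpick.extension import BindingSite
from starpick.io_formats import RnaSequence
from starpick.seeds import SeedMatch

FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 23))

#: the feature subset used by the final classifier: %A, %U, dG and ddG of
#: the binding region, and the seed length
FINAL_SUBSET = (1, 4, 18, 19, 22)


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    f1: float  # % A
    f2: float  # % C
    f3: float  # % G
    f4: float  # % U
    f5: float  # % G+C
    f6: float  # % A+U
    f7: float  # % A+C
    f8: float  # % paired nucleotides
    f9: float  # % nucleotides paired within duplexes >= 3 bp
    f10: float  # base pairs in duplexes >= 3 bp / all base pairs
    f11: float  # maximum consecutive base pairs
    f12: float  # number of interior loops
    f13: float  # number of bulges
    f14: float  # interior loops + bulges
    f15: float  # % nucleotides in interior loops
    f16: float  # % nucleotides in bulges
    f17: float  # % unpaired nucleotides
    f18: float  # dG of the binding region (kcal/mol)
    f19: float  # ddG of the binding region (kcal/mol)
    f20: float  # dG of the seed region (kcal/mol)
    f21: float  # ddG of the seed region (kcal/mol)
    f22: float  # seed length (nt)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def __getitem__(self, idx: int) -> float:
        return getattr(self, f"f{idx}")


def extract_features(
    site: BindingSite,
    seed: SeedMatch,
    srna: RnaSequence,
    window: RnaSequence,
) -> FeatureVector:
    """Compute all 22 descriptors for a scored binding site."""
    if not site.scored or not seed.scored:
        raise ValueError("extract_features requires scored seed and site")
    s_lo, s_hi = site.srna_site
    t_lo, t_hi = site.target_site
    if s_lo > s_hi or t_lo > t_hi:
        raise ValueError("empty binding site")
    seq = (
        srna.residues[s_lo - 1 : s_hi] + window.residues[t_lo - 1 : t_hi]
    )
    n_total = len(seq)
    counts = {b: seq.count(b) for b in "ACGU"}
    pct = {b: 100.0 * counts[b] / n_total for b in "ACGU"}

    pairs = sorted(site.hybrid_pairs)  # ascending sRNA position
    n_pairs = len(pairs)
    # duplex runs: (s, t) stacks on (s+1, t-1)
    runs: list[int] = []
    run = 1
    for (s0, t0), (s1, t1) in zip(pairs, pairs[1:]):
        if s1 == s0 + 1 and t1 == t0 - 1:
            run += 1
        else:
            runs.append(run)
            run = 1
    runs.append(run)

    bp_in_long = sum(r for r in runs if r >= 3)
    f8 = 100.0 * 2 * n_pairs / n_total
    f9 = 100.0 * 2 * bp_in_long / n_total
    f10 = bp_in_long / n_pairs
    f11 = max(runs)

    n_interior = n_bulge = 0
    nt_interior = nt_bulge = 0
    for (s0, t0), (s1, t1) in zip(pairs, pairs[1:]):
        gap_s = s1 - s0 - 1
        gap_t = t0 - t1 - 1
        if gap_s > 0 and gap_t > 0:
            n_interior += 1
            nt_interior += gap_s + gap_t
        elif gap_s > 0 or gap_t > 0:
            n_bulge += 1
            nt_bulge += gap_s + gap_t

    return FeatureVector(
        f1=pct["A"],
        f2=pct["C"],
        f3=pct["G"],
        f4=pct["U"],
        f5=pct["G"] + pct["C"],
        f6=pct["A"] + pct["U"],
        f7=pct["A"] + pct["C"],
        f8=f8,
        f9=f9,
        f10=f10,
        f11=float(f11),
        f12=float(n_interior),
        f13=float(n_bulge),
        f14=float(n_interior + n_bulge),
        f15=100.0 * nt_interior / n_total,
        f16=100.0 * nt_bulge / n_total,
        f17=100.0 - f8,
        f18=site.dg_binding,
        f19=site.ddg_binding,
        f20=seed.dg_hybrid_seed,
        f21=seed.ddg_seed,
        f22=float(seed.length),
    )


def project_final_subset(v: FeatureVector) -> np.ndarray:
    """The ordered 5-vector (f1, f4, f18, f19, f22); no transformation."""
    return np.array([v[i] for i in FINAL_SUBSET], dtype=float)


def feature_frame(
    rows: list[tuple[FeatureVector, str]],
    provenance: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Labeled feature table (columns f1..f22, label, pair_id, seed_id)."""
    data = {
        name: [r[0][i + 1] for r in rows] for i, name in enumerate(FEATURE_NAMES)
    }
    data["label"] = [r[1] for r in rows]
    if provenance is not None:
        data["pair_id"] = [p[0] for p in provenance]
        data["seed_id"] = [p[1] for p in provenance]
    return pd.DataFrame(data)


def write_feature_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
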