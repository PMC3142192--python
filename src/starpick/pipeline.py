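"""End-to-end prediction: window extraction, candidate cascade, ranking.

Target windows span -150 to +100 nt around the annotated start codon (150
bases upstream plus 100 bases beginning at the start-codon first base;
there is no position 0), with up to 100 nt of genomic flank on each side
retained as accessibility context.  For every window the cascade runs:
enumerate and screen seeds, extend each surviving seed by constrained
co-folding, score and characterize the resulting binding sites, and vote
with the ensemble.  Results order by probability (descending), then ddG
of the binding region, then ddG of the seed (both ascending).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Union

from starpick.energy import EnergyEngine
from starpick.ensemble import EnsembleModel
from starpick.extension import extend_seed, score_binding_site
from starpick.features import extract_features
from starpick.io_formats import GeneRecord, RnaSequence
from starpick.seeds import (
    passes_composition_rules,
    DEFAULT_SEED_DDG_THRESHOLD,
    enumerate_helices,
    score_seed,
    select_seeds,
)

logger = logging.getLogger(__name__)

WINDOW_UPSTREAM = 150
WINDOW_DOWNSTREAM = 100
GENOMIC_FLANK = 100

_RC_RNA = str.maketrans("ACGU", "UGCA")
_TO_RNA = str.maketrans("acgutT", "ACGUUU")


def _revcomp(res: str) -> str:
    return res.translate(_RC_RNA)[::-1]


@dataclasses.dataclass
class TargetWindow:
    """The putative binding region of one gene, in mRNA sense.

    ``rel_start`` is the start-codon-relative coordinate of the first
    window base (-150 normally, closer to -1 when truncated by a contig
    edge); None marks a direct-sequence target whose coordinates are
    reported 1-based as given.  Flanks are accessibility context only --
    seeds and binding sites are confined to the window itself.
    """

    residues: str
    gene: Optional[GeneRecord] = None
    rel_start: Optional[int] = -WINDOW_UPSTREAM
    flank_left: str = ""
    flank_right: str = ""
    target_id: str = ""

    def __post_init__(self):
        if len(self.residues) > WINDOW_UPSTREAM + WINDOW_DOWNSTREAM:
            raise ValueError("window longer than 250 nt")
        if not self.target_id:
            self.target_id = self.gene.gene_id if self.gene else "target"

    @classmethod
    def from_sequence(cls, seq: RnaSequence) -> "TargetWindow":
        res = seq.residues
        if len(res) > WINDOW_UPSTREAM + WINDOW_DOWNSTREAM:
            raise ValueError(
                "direct target longer than the 250-nt putative binding region"
            )
        return cls(residues=res, rel_start=None, target_id=seq.id)

    @property
    def n_upstream(self) -> int:
        return -self.rel_start if self.rel_start is not None else 0

    def to_relative(self, pos: int) -> int:
        """Window position (1-based) -> start-codon-relative coordinate."""
        if self.rel_start is None:
            return pos
        up = self.n_upstream
        return self.rel_start + pos - 1 if pos <= up else pos - up

    def context(self) -> tuple[RnaSequence, int]:
        """(full accessibility context, offset of window within it)."""
        full = self.flank_left + self.residues + self.flank_right
        return (
            RnaSequence(self.target_id + "_ctx", full),
            len(self.flank_left),
        )


def extract_target_window(
    contig: Union[str, RnaSequence], gene: GeneRecord
) -> TargetWindow:
    """Window [-150, +100] around the start codon plus genomic flanks.

    ``contig`` is the forward-strand sequence (DNA or RNA alphabet);
    minus-strand windows are reverse-complemented into mRNA sense.
    Windows and flanks are truncated silently at contig ends.
    """
    res = (contig.residues if isinstance(contig, RnaSequence) else contig).translate(
        _TO_RNA
    )
    n = len(res)
    p = gene.start_codon_pos
    if not (1 <= p <= n):
        raise ValueError(
            f"gene {gene.gene_id}: start codon position {p} outside contig"
        )

    def fwd(lo: int, hi: int) -> str:
        lo, hi = max(1, lo), min(n, hi)
        return res[lo - 1 : hi] if lo <= hi else ""

    if gene.strand == "+":
        window = fwd(p - WINDOW_UPSTREAM, p + WINDOW_DOWNSTREAM - 1)
        up = p - max(1, p - WINDOW_UPSTREAM)
        flank_left = fwd(p - WINDOW_UPSTREAM - GENOMIC_FLANK, p - WINDOW_UPSTREAM - 1)
        flank_right = fwd(p + WINDOW_DOWNSTREAM, p + WINDOW_DOWNSTREAM + GENOMIC_FLANK - 1)
    else:
        window = _revcomp(fwd(p - WINDOW_DOWNSTREAM + 1, p + WINDOW_UPSTREAM))
        up = min(n, p + WINDOW_UPSTREAM) - p
        flank_left = _revcomp(
            fwd(p + WINDOW_UPSTREAM + 1, p + WINDOW_UPSTREAM + GENOMIC_FLANK)
        )
        flank_right = _revcomp(
            fwd(p - WINDOW_DOWNSTREAM - GENOMIC_FLANK + 1, p - WINDOW_DOWNSTREAM)
        )
    return TargetWindow(
        residues=window,
        gene=gene,
        rel_start=-up,
        flank_left=flank_left,
        flank_right=flank_right,
    )


@dataclasses.dataclass
class PredictionRecord:
    """One candidate interaction of an sRNA-gene pair."""

    srna_id: str
    gene_id: str
    probability: float
    ddg_binding: float
    ddg_seed: float
    srna_site: tuple[int, int]
    target_site: tuple[int, int]  # start-codon-relative (or 1-based if direct)
    structure: str
    rank: Optional[int] = None


@dataclasses.dataclass(frozen=True)
class MutationSpec:
    """Point substitutions: (1-based position, reference base, alternate)."""

    substitutions: tuple[tuple[int, str, str], ...]

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse e.g. ``"12:G>C,15:A>U"``; empty string means no mutations."""
        subs = []
        for item in filter(None, (t.strip() for t in text.split(","))):
            pos_part, change = item.split(":")
            ref, alt = change.split(">")
            subs.append((int(pos_part), ref.strip(), alt.strip()))
        return cls(tuple(subs))


def apply_mutations(seq: RnaSequence, spec: MutationSpec) -> RnaSequence:
    """Apply substitutions; every reference base must match the sequence."""
    res = list(seq.residues)
    for pos, ref, alt in spec.substitutions:
        ref_r = ref.translate(_TO_RNA)
        alt_r = alt.translate(_TO_RNA)
        if not (1 <= pos <= len(res)):
            raise ValueError(f"mutation position {pos} outside sequence {seq.id}")
        if res[pos - 1] != ref_r:
            raise ValueError(
                f"reference mismatch at position {pos}: sequence has "
                f"{res[pos - 1]}, mutation expects {ref_r}"
            )
        res[pos - 1] = alt_r
    return RnaSequence(seq.id, "".join(res), seq.source_note)


def _hybrid_structure(site, window_len: int) -> str:
    """Dot-bracket of the hybrid over the two site intervals, '&'-separated."""
    s_lo, s_hi = site.srna_site
    t_lo, t_hi = site.target_site
    paired_s = {i for i, _ in site.hybrid_pairs}
    paired_t = {j for _, j in site.hybrid_pairs}
    left = "".join("(" if p in paired_s else "." for p in range(s_lo, s_hi + 1))
    right = "".join(")" if p in paired_t else "." for p in range(t_lo, t_hi + 1))
    return left + "&" + right


def predict_pair(
    srna: RnaSequence,
    window: Union[TargetWindow, RnaSequence],
    model: EnsembleModel,
    engine: EnergyEngine,
    seed_ddg_threshold: float = DEFAULT_SEED_DDG_THRESHOLD,
) -> list[PredictionRecord]:
    """Full cascade for one sRNA-target pair; all candidates returned.

    An empty list means the pair is non-interacting by construction (no
    stable accessible seed of five or more pairs).
    """
    if isinstance(window, RnaSequence):
        window = TargetWindow.from_sequence(window)
    if model.engine_metadata and model.engine_metadata.get("engine_id") not in (
        None,
        engine.engine_id,
    ):
        logger.warning(
            "model was trained with engine %s but %s is in use",
            model.engine_metadata.get("engine_id"),
            engine.engine_id,
        )
    window_seq = RnaSequence(window.target_id, window.residues)
    context, offset = window.context()
    seeds = enumerate_helices(srna, window_seq)
    # composition rules are applied before the (expensive) energy screen,
    # mirroring the two-stage seed selection: ddG is only computed for
    # helices that already satisfy the length/composition conditions
    passing = [s for s in seeds if passes_composition_rules(s)]
    for seed in passing:
        score_seed(seed, srna, context, engine, target_offset=offset)
    selected = select_seeds(
        [s for s in passing if s.scored], ddg_threshold=seed_ddg_threshold
    )
    sites = []
    for seed in selected:
        site = extend_seed(srna, window_seq, seed, engine)
        if site is None:
            continue
        score_binding_site(site, srna, context, engine, target_offset=offset)
        if site.scored:
            sites.append(site)
    # identical extended sites from different seeds: keep smallest seed ddG
    dedup: dict[tuple, object] = {}
    for site in sites:
        key = (site.srna_site, site.target_site)
        if key not in dedup or site.seed.ddg_seed < dedup[key].seed.ddg_seed:
            dedup[key] = site
    records = []
    gene_id = window.gene.gene_id if window.gene else window.target_id
    for site in dedup.values():
        fv = extract_features(site, site.seed, srna, window_seq)
        prob = model.predict_probability(fv)
        records.append(
            PredictionRecord(
                srna_id=srna.id,
                gene_id=gene_id,
                probability=prob,
                ddg_binding=site.ddg_binding,
                ddg_seed=site.seed.ddg_seed,
                srna_site=site.srna_site,
                target_site=(
                    window.to_relative(site.target_site[0]),
                    window.to_relative(site.target_site[1]),
                ),
                structure=_hybrid_structure(site, len(window_seq)),
            )
        )
    return records


def rank_predictions(records: Sequence[PredictionRecord]) -> list[PredictionRecord]:
    """Three-key total order: probability desc, ddG_binding asc, ddG_seed
    asc; residual ties break on gene id then sRNA id for determinism."""
    ranked = sorted(
        records,
        key=lambda r: (-r.probability, r.ddg_binding, r.ddg_seed, r.gene_id, r.srna_id),
    )
    out = []
    for i, r in enumerate(ranked, start=1):
        out.append(dataclasses.replace(r, rank=i))
    return out


def best_per_pair(records: Sequence[PredictionRecord]) -> list[PredictionRecord]:
    """Per sRNA-gene pair, keep only the smallest-rank candidate site."""
    seen = set()
    out = []
    for r in rank_predictions(records):
        key = (r.srna_id, r.gene_id)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def predict_genome(
    contigs: dict[str, Union[str, RnaSequence]],
    genes: Sequence[GeneRecord],
    srna: RnaSequence,
    model: EnsembleModel,
    engine: EnergyEngine,
    threshold: float = 0.5,
    seed_ddg_threshold: float = DEFAULT_SEED_DDG_THRESHOLD,
    return_all: bool = False,
) -> list[PredictionRecord]:
    """Run the cascade over every annotated gene's window.

    Returns the ranked records with probability strictly above
    ``threshold`` (all candidate interactions of each reported pair), or
    every record when ``return_all`` is set.  Per-gene failures are
    logged and skipped, never fatal.
    """
    all_records: list[PredictionRecord] = []
    for gene in genes:
        if gene.contig_id not in contigs:
            logger.warning("gene %s: contig %s not provided", gene.gene_id, gene.contig_id)
            continue
        try:
            window = extract_target_window(contigs[gene.contig_id], gene)
            all_records.extend(
                predict_pair(srna, window, model, engine, seed_ddg_threshold)
            )
        except Exception:
            logger.exception("gene %s: prediction failed, skipping", gene.gene_id)
    ranked = rank_predictions(all_records)
    if return_all:
        return ranked
    return [r for r in ranked if r.probability > threshold]
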