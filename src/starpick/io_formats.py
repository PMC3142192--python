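"""External representations: sequences, annotations, structures, result tables.

Coordinates in files are 1-based inclusive (GenBank convention).  DNA input
is accepted everywhere and transliterated to RNA; lowercase is uppercased.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGU")
_TRANS = str.maketrans("acgutT", "ACGUUU")

COMPLEMENT_DNA = str.maketrans("ACGTUacgtu", "TGCAATGCAA")


class ParseError(ValueError):
    """Malformed input file."""


@dataclasses.dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence over {A,C,G,U}.  T is transliterated to U on ingest."""

    id: str
    residues: str
    source_note: str = ""

    def __post_init__(self):
        res = self.residues.translate(_TRANS)
        if not res:
            raise ValueError(f"sequence {self.id!r}: empty residues")
        bad = set(res) - _VALID
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal residue(s) {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, start: int, end: int, id_suffix: str = "") -> "RnaSequence":
        """1-based inclusive slice."""
        if not (1 <= start <= end <= len(self)):
            raise ValueError(f"interval [{start},{end}] outside 1..{len(self)}")
        return RnaSequence(self.id + id_suffix, self.residues[start - 1 : end])


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene anchored by the first base of its start codon.

    ``start_codon_pos`` is always a forward-strand 1-based coordinate; for
    minus-strand genes it is the CDS end coordinate on the forward strand.
    """

    gene_id: str
    contig_id: str
    strand: str  # '+' or '-'
    start_codon_pos: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.start_codon_pos < 1:
            raise ValueError(f"gene {self.gene_id!r}: start_codon_pos must be >= 1")


class StructureTable:
    """Per-position pairing table (CT-style), 0 = unpaired externally.

    Internally ``partner`` is a 0-based numpy array with -1 for unpaired.
    For co-folded duplexes ``cut_point`` is the length of the first
    molecule; ``molecule`` flags each position 0 (first) or 1 (second).
    """

    def __init__(self, partner: np.ndarray, cut_point: Optional[int] = None):
        partner = np.asarray(partner, dtype=np.int64)
        n = partner.size
        for i, p in enumerate(partner):
            if p >= 0:
                if p == i:
                    raise ValueError(f"position {i + 1} pairs with itself")
                if p >= n or partner[p] != i:
                    raise ValueError("pairing table is not an involution")
        if cut_point is not None and not (0 < cut_point < n):
            raise ValueError("cut_point must split the table into two nonempty parts")
        self.partner = partner
        self.cut_point = cut_point
        self.molecule = (
            (np.arange(n) >= cut_point).astype(np.int8)
            if cut_point is not None
            else np.zeros(n, dtype=np.int8)
        )

    def __len__(self) -> int:
        return self.partner.size

    def pairs(self) -> list[tuple[int, int]]:
        """Sorted (i, j) pairs, 1-based, i < j."""
        return [
            (i + 1, int(p) + 1)
            for i, p in enumerate(self.partner)
            if p > i
        ]

    def is_paired(self, i: int) -> bool:
        """1-based query."""
        return self.partner[i - 1] >= 0

    def is_intramolecular(self, i: int) -> bool:
        """1-based: does position i pair within its own molecule?"""
        p = self.partner[i - 1]
        return p >= 0 and self.molecule[p] == self.molecule[i - 1]

    def is_intermolecular(self, i: int) -> bool:
        p = self.partner[i - 1]
        return p >= 0 and self.molecule[p] != self.molecule[i - 1]

    def copy(self) -> "StructureTable":
        new = StructureTable.__new__(StructureTable)
        new.partner = self.partner.copy()
        new.cut_point = self.cut_point
        new.molecule = self.molecule.copy()
        return new

    def to_dotbracket(self) -> str:
        chars = ["."] * len(self)
        for i, j in self.pairs():
            chars[i - 1] = "("
            chars[j - 1] = ")"
        s = "".join(chars)
        if self.cut_point is not None:
            s = s[: self.cut_point] + "&" + s[self.cut_point :]
        return s


def read_fasta(path) -> list[RnaSequence]:
    """Read a FASTA file into RnaSequence records (DNA transliterated).

    Ids are taken from the header up to the first whitespace.  Illegal
    residues and malformed headers raise :class:`ParseError` naming the
    offending line.
    """
    path = Path(path)
    _validate_fasta_lines(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(RnaSequence(rec.id, str(rec.seq), source_note=str(path)))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def _validate_fasta_lines(path: Path) -> None:
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                in_record = True
                continue
            if not in_record:
                raise ParseError(f"{path}:{lineno}: sequence before any header")
            bad = set(line) - set("ACGUTacgut")
            if bad:
                raise ParseError(
                    f"{path}:{lineno}: illegal residue(s) {sorted(bad)}"
                )


def write_fasta(records: Iterable[RnaSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_annotation(
    path, dialect: str = "genbank", fasta_path=None
) -> tuple[list[GeneRecord], dict[str, str]]:
    """Read gene annotations plus contig sequences.

    ``dialect`` is ``"genbank"`` (sequence embedded) or ``"gff3"`` (requires
    a companion FASTA via ``fasta_path``).  Every CDS with an unambiguous
    strand and start becomes a :class:`GeneRecord`; partial/defective CDS
    records are skipped with a logged warning.  Contig sequences are
    returned as uppercase DNA strings keyed by contig id.
    """
    if dialect == "genbank":
        return _read_genbank(path)
    if dialect == "gff3":
        if fasta_path is None:
            raise ValueError("gff3 dialect requires a companion FASTA")
        return _read_gff3(path, fasta_path)
    raise ValueError(f"unrecognized annotation dialect {dialect!r}")


def _read_genbank(path) -> tuple[list[GeneRecord], dict[str, str]]:
    genes: list[GeneRecord] = []
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        contigs[rec.id] = str(rec.seq).upper()
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            loc = feat.location
            if loc is None or loc.strand not in (1, -1):
                logger.warning("skipping CDS without strand in %s", rec.id)
                continue
            start, end = int(loc.start) + 1, int(loc.end)  # to 1-based inclusive
            if "<" in str(loc) or ">" in str(loc):
                logger.warning("skipping partial CDS %s", loc)
                continue
            gene_id = _first_qualifier(feat, ("locus_tag", "gene", "protein_id"))
            if gene_id is None:
                gene_id = f"{rec.id}_{start}_{end}"
            pos = start if loc.strand == 1 else end
            strand = "+" if loc.strand == 1 else "-"
            genes.append(GeneRecord(gene_id, rec.id, strand, pos))
    return genes, contigs


def _first_qualifier(feat, keys) -> Optional[str]:
    for k in keys:
        if k in feat.qualifiers:
            return feat.qualifiers[k][0]
    return None


def _read_gff3(path, fasta_path) -> tuple[list[GeneRecord], dict[str, str]]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("CDS"):
        if feat.strand not in ("+", "-"):
            logger.warning("skipping CDS %s without strand", feat.id)
            continue
        if feat.frame not in (".", "0", None):
            logger.warning("skipping CDS %s with nonzero phase (partial)", feat.id)
            continue
        gene_id = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("locus_tag", [None])[0]
            or feat.attributes.get("Parent", [None])[0]
            or f"{feat.seqid}_{feat.start}_{feat.end}"
        )
        pos = feat.start if feat.strand == "+" else feat.end
        genes.append(GeneRecord(gene_id, feat.seqid, feat.strand, pos))
    return genes, contigs


_OPENERS = "([{<"
_CLOSERS = ")]}>"


def dotbracket_to_table(
    structure: str, cut_point: Optional[int] = None
) -> StructureTable:
    """Convert dot-bracket notation to a CT-style pairing table.

    An ``&`` in the string marks the junction of two co-folded molecules
    and overrides ``cut_point``.  Unbalanced brackets raise
    :class:`ParseError`.
    """
    if "&" in structure:
        cut_point = structure.index("&")
        structure = structure.replace("&", "")
    n = len(structure)
    partner = np.full(n, -1, dtype=np.int64)
    stacks: dict[str, list[int]] = {c: [] for c in _OPENERS}
    for i, c in enumerate(structure):
        if c in _OPENERS:
            stacks[c].append(i)
        elif c in _CLOSERS:
            opener = _OPENERS[_CLOSERS.index(c)]
            if not stacks[opener]:
                raise ParseError(f"unbalanced bracket {c!r} at position {i + 1}")
            j = stacks[opener].pop()
            partner[i], partner[j] = j, i
        elif c not in ".,:_-":
            raise ParseError(f"unrecognized structure character {c!r} at {i + 1}")
    for opener, stack in stacks.items():
        if stack:
            raise ParseError(
                f"unbalanced bracket {opener!r} at position {stack[-1] + 1}"
            )
    return StructureTable(partner, cut_point=cut_point)


PREDICTION_COLUMNS = (
    "srna_id",
    "gene_id",
    "probability",
    "ddg_binding",
    "ddg_seed",
    "srna_site_interval",
    "target_site_interval",
    "structure",
)


def write_predictions(records: Sequence, path) -> None:
    """Write ranked prediction records as a TSV table.

    One row per candidate interaction; a pair with several binding sites
    contributes one row per site.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.srna_id,
                        r.gene_id,
                        f"{r.probability:.3f}",
                        f"{r.ddg_binding:.2f}",
                        f"{r.ddg_seed:.2f}",
                        f"{r.srna_site[0]}..{r.srna_site[1]}",
                        f"{r.target_site[0]}..{r.target_site[1]}",
                        r.structure,
                    ]
                )
                + "\n"
            )


def save_model(model, path) -> None:
    """Serialize a trained ensemble model to a versioned JSON container."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path):
    from starpick.ensemble import EnsembleModel

    with open(path) as fh:
        return EnsembleModel.from_dict(json.load(fh))
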