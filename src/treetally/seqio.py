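"""Sequence and taxon-metadata I/O, segment extraction, and taxon naming codes.

Multidomain photoreceptor proteins (canonical phytochromes among them) carry an
N-terminal photosensory segment and a C-terminal output segment whose
evolutionary histories can differ.  This module reads ungapped protein
sequences plus a taxon table giving, per protein, the 1-based inclusive residue
coordinates of the two segments, and slices each protein into "seg1"
(N-terminal) and "seg2" (C-terminal) sequence sets for independent phylogenetic
analysis.

All residue coordinates are 1-based and inclusive at both ends, the convention
used for protein residues throughout the package.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: symbols accepted in ungapped sequences; ambiguity codes collapse to X at read time
_AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "O": "X", "J": "X"}
_VALID = set(AMINO_ACIDS) | {"X"}

PHY_CLASSES = ("Phy", "Fph", "CphA", "CphB", "BphP", "other")

TAXON_TABLE_COLUMNS = (
    "code",
    "species",
    "strain",
    "group",
    "phy_class",
    "seg1_start",
    "seg1_end",
    "seg2_start",
    "seg2_end",
)


def _clean_residues(seq: str, *, where: str) -> str:
    """Uppercase, strip gaps, and collapse ambiguity codes to X."""
    out = []
    for ch in seq.upper():
        if ch in ("-", ".", " "):
            continue
        ch = _AMBIGUOUS.get(ch, ch)
        if ch == "*":  # trailing stop from translated ORFs
            continue
        if ch not in _VALID:
            raise DataError(f"invalid residue {ch!r} in {where}")
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class TaxonRecord:
    """One protein: naming code, provenance, and segment coordinates.

    ``seg1_range``/``seg2_range`` are 1-based inclusive residue intervals; the
    N-terminal segment must end strictly before the C-terminal segment starts.
    """

    code: str
    species: str
    group: str
    phy_class: str
    seg1_range: tuple[int, int]
    seg2_range: tuple[int, int]
    strain: str = ""

    def __post_init__(self) -> None:
        if self.phy_class not in PHY_CLASSES:
            raise DataError(
                f"unknown phy_class {self.phy_class!r} for {self.code}; "
                f"expected one of {PHY_CLASSES}"
            )
        for name, (a, b) in (("seg1", self.seg1_range), ("seg2", self.seg2_range)):
            if a < 1 or b < a:
                raise DataError(f"{self.code}: invalid {name} range [{a}, {b}]")
        if self.seg1_range[1] >= self.seg2_range[0]:
            raise DataError(
                f"{self.code}: segments overlap or are inverted "
                f"(seg1 ends at {self.seg1_range[1]}, seg2 starts at {self.seg2_range[0]})"
            )


class SequenceSet:
    """Ordered map from taxon code to ungapped amino-acid string."""

    def __init__(self, records: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        self.records: "OrderedDict[str, str]" = OrderedDict()
        items = records.items() if isinstance(records, Mapping) else records
        for code, seq in items:
            self.add(code, seq)

    def add(self, code: str, seq: str) -> None:
        if code in self.records:
            raise DataError(f"duplicate sequence code {code!r}")
        seq = _clean_residues(seq, where=code)
        if not seq:
            raise DataError(f"empty sequence for code {code!r}")
        self.records[code] = seq

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, code: str) -> bool:
        return code in self.records

    def __getitem__(self, code: str) -> str:
        return self.records[code]

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, SequenceSet) and self.records == other.records

    def codes(self) -> list[str]:
        return list(self.records)


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a protein FASTA file into a :class:`SequenceSet`.

    The code is the header token before the first whitespace.  Sequences are
    uppercased, gap characters stripped, and ambiguity codes mapped to X.
    Duplicate codes and empty files are errors.
    """
    path = Path(path)
    seqs = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs.add(rec.id, str(rec.seq))
    if len(seqs) == 0:
        raise DataError(f"no FASTA records found in {path}")
    return seqs


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    """Write a :class:`SequenceSet` as FASTA wrapped at 60 columns."""
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in seqs.records.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_taxon_table(path: str | Path) -> list[TaxonRecord]:
    """Read the 9-column tab-separated taxon table.

    Header must be exactly ``code species strain group phy_class seg1_start
    seg1_end seg2_start seg2_end``.  Coordinate invariants (1-based, seg1
    strictly before seg2) are enforced per row.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise DataError(f"empty taxon table {path}")
    header = tuple(lines[0].split("\t"))
    if header != TAXON_TABLE_COLUMNS:
        raise DataError(
            f"{path}: bad taxon-table header {header!r}; expected {TAXON_TABLE_COLUMNS}"
        )
    records: list[TaxonRecord] = []
    seen: set[str] = set()
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != len(TAXON_TABLE_COLUMNS):
            raise DataError(f"{path}:{i}: expected {len(TAXON_TABLE_COLUMNS)} columns")
        code, species, strain, group, phy_class = parts[:5]
        try:
            s1a, s1b, s2a, s2b = (int(x) for x in parts[5:])
        except ValueError as exc:
            raise DataError(f"{path}:{i}: non-integer coordinate ({exc})") from None
        if code in seen:
            raise DataError(f"{path}:{i}: duplicate code {code!r}")
        seen.add(code)
        records.append(
            TaxonRecord(
                code=code,
                species=species,
                strain=strain,
                group=group,
                phy_class=phy_class,
                seg1_range=(s1a, s1b),
                seg2_range=(s2a, s2b),
            )
        )
    return records


def write_taxon_table(records: Iterable[TaxonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TAXON_TABLE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.code,
                        r.species,
                        r.strain,
                        r.group,
                        r.phy_class,
                        str(r.seg1_range[0]),
                        str(r.seg1_range[1]),
                        str(r.seg2_range[0]),
                        str(r.seg2_range[1]),
                    ]
                )
                + "\n"
            )


def validate_against(records: Iterable[TaxonRecord], seqs: SequenceSet) -> None:
    """Check every record's code exists and its ranges fit its sequence."""
    for r in records:
        if r.code not in seqs:
            raise DataError(f"taxon {r.code!r} has no sequence")
        n = len(seqs[r.code])
        if r.seg2_range[1] > n:
            raise DataError(
                f"{r.code}: seg2 ends at {r.seg2_range[1]} but sequence has {n} residues"
            )


def extract_segment(
    seqs: SequenceSet, records: Iterable[TaxonRecord], which: str
) -> SequenceSet:
    """Slice out segment ``which`` ("seg1" or "seg2") of every record.

    Coordinates are 1-based inclusive, so seg1 = [1, 500] yields 500 residues.
    """
    if which not in ("seg1", "seg2"):
        raise ValueError(f"which must be 'seg1' or 'seg2', got {which!r}")
    out = SequenceSet()
    for r in records:
        if r.code not in seqs:
            raise DataError(f"taxon {r.code!r} has no sequence")
        seq = seqs[r.code]
        a, b = r.seg1_range if which == "seg1" else r.seg2_range
        if b > len(seq):
            raise DataError(
                f"{r.code}: {which} range [{a}, {b}] outside sequence of length {len(seq)}"
            )
        out.add(r.code, seq[a - 1 : b])
    return out


def make_taxon_code(
    species: str, strain_index: int, protein: str, disambiguator: str = ""
) -> str:
    """Build the 5-letter species code plus protein abbreviation.

    The code takes the first three letters of the genus (capitalized) and the
    first two letters of the epithet (first letter capitalized), e.g.
    *Agrobacterium tumefaciens* + "Agp1" -> "AgrTuAgp1".  A second strain of
    the same species must carry an extra letter or digit supplied by the
    caller ("AgrTuFAgp1"); how that character is chosen is up to the dataset
    curator.
    """
    parts = species.split()
    if len(parts) < 2:
        raise DataError(f"species name {species!r} needs genus and epithet")
    if strain_index < 1:
        raise ValueError("strain_index must be >= 1")
    if strain_index > 1 and not disambiguator:
        raise DataError(
            f"strain_index {strain_index} > 1 requires a disambiguator letter/digit"
        )
    genus, epithet = parts[0], parts[1]
    prefix = genus[:3].capitalize() + epithet[:2].capitalize()
    extra = disambiguator if strain_index > 1 else ""
    return prefix + extra + protein
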