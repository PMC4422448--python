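"""Alignment editing and statistics: gap-column filtering, parsimony-informative
site fraction, short-overlap row removal, and bootstrap column resampling.

The editing rule is the one used throughout deep-divergence protein
phylogenetics: drop every column in which strictly more than a given fraction
of rows carry a gap (default 50%), which concentrates the alignment on
positions most rows actually share and raises the fraction of
parsimony-informative sites.  Rows whose remaining non-gap overlap is too
short to place reliably are removed before tree building.

Gap character is ``-``; ``.`` is converted on input.  ``X`` (unknown residue)
is treated as missing data wherever states are counted.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .seqio import AMINO_ACIDS, SequenceSet

GAP = "-"
_ALPHABET = set(AMINO_ACIDS) | {"X", GAP}
#: symbols that carry no state information in a column
MISSING = {GAP, "X"}


class SegmentAlignment:
    """Gapped, equal-length rows for one protein segment.

    ``column_keep_map`` maps each current column index to its index in the
    original (pre-filtering) alignment, so filtered coordinates stay
    traceable.
    """

    def __init__(
        self,
        rows: Mapping[str, str] | Iterable[tuple[str, str]],
        column_keep_map: Sequence[int] | None = None,
    ):
        items = rows.items() if isinstance(rows, Mapping) else list(rows)
        self.rows: "OrderedDict[str, str]" = OrderedDict()
        n_cols = None
        for code, row in items:
            row = row.upper().replace(".", GAP)
            if code in self.rows:
                raise DataError(f"duplicate alignment row {code!r}")
            bad = set(row) - _ALPHABET
            if bad:
                raise DataError(f"row {code!r} contains invalid symbols {sorted(bad)}")
            if n_cols is None:
                n_cols = len(row)
            elif len(row) != n_cols:
                raise DataError(
                    f"row {code!r} has length {len(row)}, expected {n_cols}"
                )
            self.rows[code] = row
        if len(self.rows) < 2:
            raise DataError("alignment needs at least 2 rows")
        self.n_cols: int = int(n_cols or 0)
        if column_keep_map is not None and len(column_keep_map) != self.n_cols:
            raise DataError("column_keep_map length must equal n_cols")
        self.column_keep_map = list(column_keep_map) if column_keep_map is not None else None

    # -- container basics -------------------------------------------------
    @property
    def codes(self) -> list[str]:
        return list(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, SegmentAlignment) and self.rows == other.rows

    def to_array(self) -> np.ndarray:
        """Rows as a (n_rows, n_cols) array of single-byte codes."""
        return np.frombuffer(
            "".join(self.rows.values()).encode("ascii"), dtype="S1"
        ).reshape(len(self.rows), self.n_cols)

    def take_columns(self, idx: Sequence[int]) -> "SegmentAlignment":
        """New alignment from the given original-order column indices."""
        idx = list(idx)
        rows = OrderedDict(
            (code, "".join(row[i] for i in idx)) for code, row in self.rows.items()
        )
        if self.column_keep_map is not None:
            keep = [self.column_keep_map[i] for i in idx]
        else:
            keep = idx
        return SegmentAlignment(rows, column_keep_map=keep)

    def ungapped(self) -> SequenceSet:
        return SequenceSet((c, r.replace(GAP, "")) for c, r in self.rows.items())


@dataclass
class AlignmentStats:
    """Before/after filtering statistics for one segment alignment."""

    n_cols_before: int
    n_cols_after: int
    informative_fraction: float
    per_row_coverage: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tkey\tvalue\n")
            fh.write(f"n_cols_before\t-\t{self.n_cols_before}\n")
            fh.write(f"n_cols_after\t-\t{self.n_cols_after}\n")
            fh.write(f"informative_fraction\t-\t{self.informative_fraction:.6f}\n")
            for code, cov in self.per_row_coverage.items():
                fh.write(f"coverage\t{code}\t{cov}\n")


def read_alignment(path: str | Path) -> SegmentAlignment:
    """Read an aligned FASTA file (equal-length gapped rows)."""
    rows = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise DataError(f"duplicate alignment row {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq)
    if not rows:
        raise DataError(f"no FASTA records found in {path}")
    return SegmentAlignment(rows)


def write_alignment(aln: SegmentAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(r), id=c, description="") for c, r in aln.rows.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def filter_gap_columns(aln: SegmentAlignment, threshold: float = 0.5) -> SegmentAlignment:
    """Remove columns whose gap fraction is strictly greater than ``threshold``.

    A column with exactly ``threshold`` gaps (e.g. 50% at the default) is
    kept.  The surviving columns' original indices are recorded in
    ``column_keep_map``.  Raises if nothing survives.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    arr = aln.to_array()
    gap_frac = (arr == GAP.encode()).mean(axis=0)
    keep = [i for i in range(aln.n_cols) if gap_frac[i] <= threshold]
    if not keep:
        raise DataError(
            "gap filtering removed every column; raise the gap threshold"
        )
    return aln.take_columns(keep)


def _column_informative(column: Iterable[str]) -> bool:
    counts: dict[str, int] = {}
    for ch in column:
        if ch in MISSING:
            continue
        counts[ch] = counts.get(ch, 0) + 1
    return sum(1 for v in counts.values() if v >= 2) >= 2


def informative_site_fraction(aln: SegmentAlignment) -> float:
    """Fraction of columns that are parsimony-informative.

    A column is informative when at least two distinct residues each occur in
    at least two rows; gaps and X are missing data.  Needs >= 4 rows.
    """
    if len(aln) < 4:
        raise DataError("informative-site fraction undefined for < 4 rows")
    rows = list(aln.rows.values())
    n_inf = sum(
        _column_informative(row[i] for row in rows) for i in range(aln.n_cols)
    )
    return n_inf / aln.n_cols if aln.n_cols else 0.0


def overlap_filter(
    aln: SegmentAlignment, min_overlap: int
) -> tuple[SegmentAlignment, list[str]]:
    """Drop rows with fewer than ``min_overlap`` non-gap columns.

    Returns the retained alignment and the removed codes.  Deep alignments of
    partial sequences routinely contain rows whose usable overlap with the
    rest is too short to place; those rows only add noise to distance and
    parsimony estimates.
    """
    removed = [
        code
        for code, row in aln.rows.items()
        if sum(ch != GAP for ch in row) < min_overlap
    ]
    if len(removed) == len(aln):
        raise DataError("overlap filter removed every row; lower min_overlap")
    if len(aln) - len(removed) < 2:
        raise DataError("overlap filter left fewer than 2 rows; lower min_overlap")
    kept = OrderedDict(
        (code, row) for code, row in aln.rows.items() if code not in removed
    )
    return SegmentAlignment(kept, column_keep_map=aln.column_keep_map), removed


def bootstrap_indices(
    n_cols: int, n_replicates: int, seed: int
) -> list[np.ndarray]:
    """Column index draws for bootstrap replicates.

    Replicate ``r`` uses ``numpy.random.default_rng([seed, r])`` — a
    documented deterministic substream of the master seed — so any replicate
    can be regenerated in isolation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_cols < 1:
        raise DataError("cannot bootstrap an alignment with 0 columns")
    out = []
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        out.append(rng.integers(0, n_cols, size=n_cols))
    return out


def bootstrap_resample(
    aln: SegmentAlignment, n_replicates: int, seed: int
) -> list[SegmentAlignment]:
    """Draw ``n_replicates`` bootstrap alignments (columns with replacement).

    Fully reproducible: the same seed yields byte-identical replicates.
    """
    reps = []
    for idx in bootstrap_indices(aln.n_cols, n_replicates, seed):
        arr = aln.to_array()[:, idx]
        rows = OrderedDict(
            (code, arr[i].tobytes().decode("ascii"))
            for i, code in enumerate(aln.codes)
        )
        reps.append(SegmentAlignment(rows))
    return reps


def alignment_stats(before: SegmentAlignment, after: SegmentAlignment) -> AlignmentStats:
    """Summarize a filtering step (column counts, informativeness, coverage)."""
    frac = informative_site_fraction(after) if len(after) >= 4 else float("nan")
    coverage = {
        code: sum(ch != GAP for ch in row) for code, row in after.rows.items()
    }
    return AlignmentStats(
        n_cols_before=before.n_cols,
        n_cols_after=after.n_cols,
        informative_fraction=frac,
        per_row_coverage=coverage,
    )
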