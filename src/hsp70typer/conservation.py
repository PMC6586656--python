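"""Pairwise identity, per-column conservation, consensus and group masks.

Operates on protein alignments (the module computes on alignments, it does
not build them). Identity convention: computed over aligned columns
excluding terminal gap overhangs; internal gaps count as mismatches.
Consensus ties break alphabetically and are flagged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .motif_typing import make_aligner

GAP = "-"


class AlignmentError(ValueError):
    """Raised when alignment rows violate the alignment contract."""


@dataclass
class Alignment:
    """An ordered list of (id, gapped sequence) rows of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise AlignmentError("alignment needs at least 2 rows")
        length = len(self.rows[0][1])
        if any(len(seq) != length for _, seq in self.rows):
            raise AlignmentError("alignment rows must have equal length")
        self.rows = [(rid, seq.upper()) for rid, seq in self.rows]
        for col in range(length):
            if all(seq[col] == GAP for _, seq in self.rows):
                raise AlignmentError(f"all-gap column at position {col + 1}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    def column(self, i: int) -> list[str]:
        """Residues of 0-based column ``i``."""
        return [seq[i] for _, seq in self.rows]


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file."""
    rows = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return Alignment(rows)


@dataclass(frozen=True)
class ColumnStats:
    """Consensus call for one alignment column (1-based)."""

    column: int
    consensus: str
    conservation: float
    is_gap_majority: bool
    tie: bool


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity between two protein sequences, to one decimal.

    Equal-length inputs are compared position by position. Unequal-length
    inputs are globally aligned first; identity is then computed over
    aligned columns excluding terminal gaps, with internal gaps counted as
    mismatches.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        return round(100.0 * matches / len(a), 1)

    alignment = make_aligner().align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    # trim terminal gap overhangs (columns where either row has an end gap)
    start = 0
    while ga[start] == GAP or gb[start] == GAP:
        start += 1
    end = len(ga)
    while ga[end - 1] == GAP or gb[end - 1] == GAP:
        end -= 1
    compared = end - start
    matches = sum(ga[i] == gb[i] for i in range(start, end))
    return round(100.0 * matches / compared, 1)


def mean_and_min_identity(seqs: list[str]) -> tuple[float, float]:
    """Mean and minimum pairwise identity over all sequence pairs."""
    vals = [
        pairwise_identity(seqs[i], seqs[j])
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    ]
    if not vals:
        raise ValueError("need at least two sequences")
    return round(sum(vals) / len(vals), 1), min(vals)


def column_profile(aln: Alignment) -> list[ColumnStats]:
    """Per-column modal residue and conservation percent.

    Conservation is 100 × (count of the modal non-gap residue) / (non-gap
    count). Ties break alphabetically and set the tie flag. A column with
    more gaps than residues is flagged gap-majority.
    """
    profile = []
    for i in range(aln.length):
        col = aln.column(i)
        residues = [c for c in col if c != GAP]
        n_gaps = len(col) - len(residues)
        counts = Counter(residues)
        top = max(counts.values())
        modal = sorted(r for r, c in counts.items() if c == top)
        profile.append(
            ColumnStats(
                column=i + 1,
                consensus=modal[0],
                conservation=100.0 * top / len(residues),
                is_gap_majority=n_gaps > len(residues),
                tie=len(modal) > 1,
            )
        )
    return profile


def consensus(aln: Alignment) -> str:
    """Majority-rule consensus; gap-majority columns are omitted."""
    return "".join(
        c.consensus for c in column_profile(aln) if not c.is_gap_majority
    )


def group_differences(consensus_a: str, consensus_b: str) -> list[int]:
    """Sorted 1-based positions where two consensus sequences differ.

    Equal-length inputs are compared directly; unequal-length inputs are
    globally aligned first and positions refer to alignment columns (a gap
    opposite a residue counts as a difference).
    """
    a, b = consensus_a.upper(), consensus_b.upper()
    if len(a) != len(b):
        alignment = make_aligner().align(a, b)[0]
        a, b = str(alignment[0]), str(alignment[1])
    return [i + 1 for i in range(len(a)) if a[i] != b[i]]


def write_column_profile(profile: list[ColumnStats], path: str | Path) -> None:
    """TSV export: column, consensus, conservation, gap_majority, tie."""
    with open(path, "w") as fh:
        fh.write("column\tconsensus\tconservation\tgap_majority\ttie\n")
        for c in profile:
            fh.write(
                f"{c.column}\t{c.consensus}\t{c.conservation:.4f}\t"
                f"{int(c.is_gap_majority)}\t{int(c.tie)}\n"
            )
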