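"""Sequence I/O, ORF finding and translation.

All coordinates in this package are 1-based and inclusive on the forward
strand. Reverse-strand features report the forward-strand interval they span.
DNA records use the alphabet ACGTN; protein records use the 20 standard amino
acids plus X. Codons containing N translate to X and are never accepted as
start or stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Moltype = Literal["dna", "protein"]


class FastaFormatError(ValueError):
    """Raised when a FASTA file or a sequence violates the format contract."""


class TranslationError(ValueError):
    """Raised when a nucleotide sequence cannot be translated as an ORF."""


def _alphabet_for(moltype: Moltype) -> frozenset:
    if moltype == "dna":
        return DNA_ALPHABET
    if moltype == "protein":
        return PROTEIN_ALPHABET
    raise ValueError(f"unknown moltype: {moltype!r}")


@dataclass
class SeqRecord:
    """An identified DNA or protein sequence.

    Sequences are stored upper-case and validated against the declared
    alphabet on construction.
    """

    id: str
    sequence: str
    moltype: Moltype = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        alphabet = _alphabet_for(self.moltype)
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in alphabet:
                raise FastaFormatError(
                    f"record {self.id!r}: illegal {self.moltype} character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Orf:
    """A complete open reading frame, ATG through stop codon.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates of the
    spanned interval; ``nt_sequence`` includes the stop codon, which is not
    translated into ``aa_sequence``.
    """

    parent_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    nt_sequence: str
    aa_sequence: str = field(default="")

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            self.aa_sequence = translate(self.nt_sequence)
        n = len(self.nt_sequence)
        if n % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if self.end - self.start + 1 != n:
            raise ValueError("ORF coordinates inconsistent with sequence length")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, moltype: Moltype) -> list[SeqRecord]:
    """Read a FASTA file into validated :class:`SeqRecord` objects.

    One record per header, multi-line sequences concatenated, file order
    preserved. Raises :class:`FastaFormatError` on a malformed header, an
    illegal character (naming the record and position) or a duplicate id.
    """
    path = Path(path)
    with open(path) as fh:
        first = next((line for line in fh if line.strip()), None)
    if first is None:
        raise FastaFormatError(f"{path}: empty file")
    if not first.startswith(">"):
        raise FastaFormatError(f"{path}: does not start with a FASTA header")

    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: malformed header (missing id)")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SeqRecord(
                id=rec.id,
                sequence=str(rec.seq),
                moltype=moltype,
                description=rec.description,
            )
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    bio = [
        BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def translate(nt: str | Orf) -> str:
    """Translate a complete ORF (standard genetic code), excluding the stop.

    Accepts an :class:`Orf` or a raw nucleotide string that must be divisible
    by 3 and end in a stop codon. Codons containing N yield X. An internal
    stop codon raises :class:`TranslationError` naming the codon index.
    """
    seq = nt.nt_sequence if isinstance(nt, Orf) else str(nt).upper()
    if len(seq) % 3 != 0:
        raise TranslationError(
            f"sequence length {len(seq)} is not divisible by 3"
        )
    if len(seq) < 6:
        raise TranslationError("ORF must contain at least a start and a stop codon")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] not in STOP_CODONS:
        raise TranslationError(f"terminal codon {codons[-1]!r} is not a stop codon")
    aa: list[str] = []
    for idx, codon in enumerate(codons[:-1], start=1):
        if codon in STOP_CODONS:
            raise TranslationError(f"internal stop codon at codon index {idx}")
        aa.append(_CODON_MAP.get(codon, "X"))
    return "".join(aa)


def find_orfs(record: SeqRecord, min_aa: int) -> list[Orf]:
    """Find all complete ORFs (ATG→stop) in all six reading frames.

    Every ATG is paired with its nearest in-frame downstream stop, so nested
    ORFs sharing a stop are all reported. Codons containing N are neither
    starts nor stops. Results are sorted by descending amino-acid length
    (ties by forward-strand start, then strand).
    """
    if record.moltype != "dna":
        raise ValueError("find_orfs requires a DNA record")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")

    seq = record.sequence
    length = len(seq)
    orfs: list[Orf] = []

    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            open_starts: list[int] = []  # 0-based codon start offsets on s
            for i in range(frame, length - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    for a in open_starts:
                        nt_seq = s[a : i + 3]
                        aa = translate(nt_seq)
                        if len(aa) >= min_aa:
                            if strand == "+":
                                start, end = a + 1, i + 3
                            else:
                                start, end = length - (i + 3) + 1, length - a
                            orfs.append(
                                Orf(
                                    parent_id=record.id,
                                    start=start,
                                    end=end,
                                    strand=strand,
                                    nt_sequence=nt_seq,
                                    aa_sequence=aa,
                                )
                            )
                    open_starts.clear()
                elif codon == START_CODON:
                    open_starts.append(i)

    orfs.sort(key=lambda o: (-len(o.aa_sequence), o.start, o.strand))
    return orfs
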