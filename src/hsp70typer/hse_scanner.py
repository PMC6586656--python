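"""Heat-shock-element detection in promoter DNA.

A heat shock element (HSE) is a run of alternating NTTCN / NGAAN
pentanucleotides bound by heat shock factor trimers; the canonical element
has at least three contiguous units. Only the central trinucleotide of each
pentamer (TTC or GAA) is constrained — the flanking N positions are free.

Because the reverse complement of NGAAN is NTTCN, an alternating run is the
same element on both strands. Each run is therefore reported once, with its
strand defined by the 5'-most unit on the forward strand: a run leading with
NGAAN is ``+``, one leading with NTTCN is ``-``. Under reverse complement
the multiset of (units, class) per sequence is invariant and the strand
label flips for odd-unit runs (an even alternating run reverse-complements
to one leading with the same unit class).

Classification: ``canonical`` = at least ``min_units`` units with no core
mismatch; ``hse_like`` = such a run carrying exactly one core mismatch
(equivalently, a perfect two-unit run extended by a single one-mismatch
unit). Runs are maximal: a reported run cannot be extended by another
in-phase unit without breaking alternation, unit validity or the one-
mismatch budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .core_seq import SeqRecord

UnitClass = Literal["NTTCN", "NGAAN", "none"]

_CORES = {"NTTCN": "TTC", "NGAAN": "GAA"}


class HseInputError(ValueError):
    """Raised on invalid pentamer or coordinate input."""


@dataclass(frozen=True)
class PentamerCall:
    """Classification of one pentamer (offset is 1-based on its sequence)."""

    offset: int
    unit_class: UnitClass
    mismatches: int


@dataclass(frozen=True)
class HseHit:
    """A maximal alternating pentamer run in forward-strand coordinates."""

    sequence_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    units: tuple[str, ...]
    n_units: int
    total_mismatches: int
    hse_class: Literal["canonical", "hse_like"]
    upstream_distance: int | None = None


def classify_pentamer(
    pentamer: str, allow_mismatch: bool = False, offset: int = 1
) -> PentamerCall:
    """Classify a 5-base window as NTTCN, NGAAN or neither.

    The core (bases 2–4) is compared against TTC and GAA; with
    ``allow_mismatch`` one core substitution is tolerated and recorded.
    The two cores differ at all three positions, so a call within one
    mismatch is always unambiguous.
    """
    p = pentamer.upper()
    if len(p) != 5 or any(c not in "ACGT" for c in p):
        raise HseInputError(f"pentamer must be 5 ACGT bases, got {pentamer!r}")
    core = p[1:4]
    best_class: UnitClass = "none"
    best_mm = 3
    for unit, ref_core in _CORES.items():
        mm = sum(a != b for a, b in zip(core, ref_core))
        if mm < best_mm:
            best_mm = mm
            best_class = unit  # type: ignore[assignment]
    budget = 1 if allow_mismatch else 0
    if best_mm > budget:
        return PentamerCall(offset=offset, unit_class="none", mismatches=best_mm)
    return PentamerCall(offset=offset, unit_class=best_class, mismatches=best_mm)


def _phase_calls(seq: str, phase: int) -> list[PentamerCall]:
    calls = []
    for i in range(phase, len(seq) - 4, 5):
        window = seq[i : i + 5]
        if any(c not in "ACGT" for c in window):
            calls.append(PentamerCall(offset=i + 1, unit_class="none", mismatches=3))
        else:
            calls.append(classify_pentamer(window, allow_mismatch=True, offset=i + 1))
    return calls


def find_hse(
    record: SeqRecord,
    min_units: int = 3,
    scan_both_strands: bool = True,
    max_total_mismatches: int = 1,
) -> list[HseHit]:
    """All maximal alternating NTTCN/NGAAN runs in a DNA record.

    All five pentamer phases are scanned; overlapping runs in different
    phases are all reported, while within one phase only maximal runs
    survive. With ``scan_both_strands=False`` only runs leading with NGAAN
    (strand ``+``) are reported.
    """
    if record.moltype != "dna":
        raise ValueError("find_hse requires a DNA record")
    seq = record.sequence
    hits: list[HseHit] = []

    for phase in range(5):
        calls = _phase_calls(seq, phase)
        n = len(calls)
        a = 0
        while a < n:
            if calls[a].unit_class == "none":
                a += 1
                continue
            # extend right while valid, alternating, within budget
            b = a
            mm = calls[a].mismatches
            while b + 1 < n:
                nxt = calls[b + 1]
                if (
                    nxt.unit_class == "none"
                    or nxt.unit_class == calls[b].unit_class
                    or mm + nxt.mismatches > max_total_mismatches
                ):
                    break
                b += 1
                mm += nxt.mismatches
            # left-maximality under the same constraints
            left_ok = (
                a > 0
                and calls[a - 1].unit_class != "none"
                and calls[a - 1].unit_class != calls[a].unit_class
                and mm + calls[a - 1].mismatches <= max_total_mismatches
            )
            if not left_ok and b - a + 1 >= min_units:
                units = tuple(c.unit_class for c in calls[a : b + 1])
                hits.append(
                    HseHit(
                        sequence_id=record.id,
                        start=calls[a].offset,
                        end=calls[b].offset + 4,
                        strand="+" if units[0] == "NGAAN" else "-",
                        units=units,
                        n_units=len(units),
                        total_mismatches=mm,
                        hse_class="canonical" if mm == 0 else "hse_like",
                    )
                )
            a += 1

    if not scan_both_strands:
        hits = [h for h in hits if h.strand == "+"]
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def upstream_distance(hit: HseHit, orf_start: int) -> int:
    """Bases strictly between the element and the A of the ATG start codon.

    Errors if the element overlaps or lies downstream of the start.
    """
    if hit.end >= orf_start:
        raise HseInputError(
            f"HSE at {hit.start}-{hit.end} is not upstream of ORF start {orf_start}"
        )
    return orf_start - hit.end - 1
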