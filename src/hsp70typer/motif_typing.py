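"""Degenerate signature grammar, scanner and the Hsp70 type classifier.

The Hsp/Hsc70 chaperone family carries a small set of near-invariant amino
acid signatures (family motifs such as IDLGTTYS or the phosphate-binding
site), plus a handful of motifs that discriminate the heat-inducible
paralog from the constitutively expressed cognate form in amphipods: the
ATP/GTP-binding site S(A)EAYLGK(G)E(A) versus ADAYLGTN, the N-terminal
hexamer MRAKST versus MSKATA, and the RARFEEM/RARFEEL pair. The classifier
combines presence/absence of these signatures into a family / localization /
inducibility verdict with an explicit evidence trail.

Motif notation: plain amino-acid letters are fixed positions, ``X`` is a
wildcard, and a single parenthesized letter is an alternative for the
immediately preceding position — so ``S(A)EAYLGK(G)E(A)`` is 8 positions
with {S,A}, {K,G} and {E,A} sets at positions 1, 7 and 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .core_seq import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

Anchor = Literal["anywhere", "n_terminus", "c_terminus"]


class MotifParseError(ValueError):
    """Raised when a degenerate motif notation cannot be parsed."""


class CoordinateError(ValueError):
    """Raised on invalid reference coordinates."""


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate protein signature as an ordered list of residue sets."""

    name: str
    positions: tuple[frozenset, ...]
    max_mismatches: int = 0
    anchor: Anchor = "anywhere"

    def __post_init__(self) -> None:
        if not self.positions:
            raise MotifParseError("pattern must have at least one position")
        if any(not p for p in self.positions):
            raise MotifParseError("every position set must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    def __len__(self) -> int:
        return len(self.positions)

    def is_wildcard(self, i: int) -> bool:
        return len(self.positions[i]) == len(_AA_SET)


@dataclass(frozen=True)
class MotifHit:
    """A located occurrence of a pattern (1-based inclusive coordinates)."""

    pattern_name: str
    start: int
    end: int
    matched: str
    mismatches: int


def parse_motif(
    notation: str,
    max_mismatches: int = 0,
    anchor: Anchor = "anywhere",
    name: str | None = None,
) -> MotifPattern:
    """Parse degenerate motif notation into a :class:`MotifPattern`.

    ``X`` expands to the full 20-letter alphabet (a wildcard); ``(Y)`` merges
    Y into the preceding position's set. A leading, empty or multi-letter
    parenthesis is a parse error.
    """
    if not notation:
        raise MotifParseError("empty motif notation")
    positions: list[set] = []
    i = 0
    while i < len(notation):
        ch = notation[i]
        if ch == "(":
            j = notation.find(")", i)
            if j == -1:
                raise MotifParseError(f"unbalanced parenthesis in {notation!r}")
            inner = notation[i + 1 : j]
            if len(inner) != 1 or inner not in _AA_SET:
                raise MotifParseError(
                    f"parenthesis must contain exactly one amino acid, got {inner!r}"
                )
            if not positions:
                raise MotifParseError("alternative before any position")
            positions[-1].add(inner)
            i = j + 1
        elif ch == "X":
            positions.append(set(_AA_SET))
            i += 1
        elif ch in _AA_SET:
            positions.append({ch})
            i += 1
        else:
            raise MotifParseError(f"illegal character {ch!r} in motif {notation!r}")
    return MotifPattern(
        name=name if name is not None else notation,
        positions=tuple(frozenset(p) for p in positions),
        max_mismatches=max_mismatches,
        anchor=anchor,
    )


def scan_motif(protein: SeqRecord, pattern: MotifPattern) -> list[MotifHit]:
    """All occurrences of ``pattern`` in ``protein`` within the mismatch budget.

    Wildcard positions match anything (including X) and never count as
    mismatches. Anchored patterns are evaluated only at the first / last
    admissible start. Hits are sorted by start; a pattern longer than the
    sequence yields an empty list.
    """
    if protein.moltype != "protein":
        raise ValueError("scan_motif requires a protein record")
    seq = protein.sequence
    plen = len(pattern)
    if plen > len(seq):
        return []

    if pattern.anchor == "n_terminus":
        starts: Sequence[int] = (0,)
    elif pattern.anchor == "c_terminus":
        starts = (len(seq) - plen,)
    else:
        starts = range(len(seq) - plen + 1)

    hits: list[MotifHit] = []
    for s in starts:
        mm = 0
        for i in range(plen):
            if pattern.is_wildcard(i):
                continue
            if seq[s + i] not in pattern.positions[i]:
                mm += 1
                if mm > pattern.max_mismatches:
                    break
        else:
            hits.append(
                MotifHit(
                    pattern_name=pattern.name,
                    start=s + 1,
                    end=s + plen,
                    matched=seq[s : s + plen],
                    mismatches=mm,
                )
            )
    return hits


#: The built-in signature set: (notation, anchor).
BUILTIN_SIGNATURES: dict[str, tuple[str, Anchor]] = {
    "IDLGTTYS": ("IDLGTTYS", "anywhere"),
    "TVPAYFND": ("TVPAYFND", "anywhere"),
    "NEPTAA": ("NEPTAA", "anywhere"),
    "phosphate_binding": ("IFDLGGGTFDVSIL", "anywhere"),
    "NLS": ("KKXXXXXXXXXRRLRT", "anywhere"),
    "RARFEEL": ("RARFEEL", "anywhere"),
    "RARFEEM": ("RARFEEM", "anywhere"),
    "GPTIEEVD": ("GPTIEEVD", "c_terminus"),
    "EEVD_tail": ("EEVD", "c_terminus"),
    "ATP_inducible": ("S(A)EAYLGK(G)E(A)", "anywhere"),
    "ATP_cognate": ("ADAYLGTN", "anywhere"),
    "Nterm_inducible": ("MRAKST", "n_terminus"),
    "Nterm_cognate": ("MSKATA", "n_terminus"),
}

#: Family-membership signatures (>= 2 required).
FAMILY_SIGNATURES = ("IDLGTTYS", "TVPAYFND", "NEPTAA", "phosphate_binding")
#: Diagnostic signatures for the heat-inducible type.
INDUCIBLE_SIGNATURES = ("ATP_inducible", "Nterm_inducible", "RARFEEM")
#: Diagnostic signatures for the cognate / cognate-inducible type.
COGNATE_SIGNATURES = ("ATP_cognate", "Nterm_cognate", "RARFEEL")


def builtin_patterns(
    mismatch_budgets: Mapping[str, int] | None = None,
) -> dict[str, MotifPattern]:
    """The built-in signatures as parsed patterns (default budget 0)."""
    budgets = mismatch_budgets or {}
    return {
        name: parse_motif(
            notation, max_mismatches=budgets.get(name, 0), anchor=anchor, name=name
        )
        for name, (notation, anchor) in BUILTIN_SIGNATURES.items()
    }


@dataclass
class SignatureProfile:
    """Per-sequence hit lists for every built-in signature."""

    sequence_id: str
    hits: dict[str, list[MotifHit]]

    def present(self, name: str) -> bool:
        return bool(self.hits[name])


def profile_signatures(
    protein: SeqRecord, mismatch_budgets: Mapping[str, int] | None = None
) -> SignatureProfile:
    """Scan a protein with every built-in signature.

    N-terminal hexamers are anchored at residue 1; GPTIEEVD and the EEVD
    tail are anchored at the C-terminus. Per-signature mismatch budgets can
    be raised for relaxed searches; the default is 0 everywhere.
    """
    patterns = builtin_patterns(mismatch_budgets)
    return SignatureProfile(
        sequence_id=protein.id,
        hits={name: scan_motif(protein, pat) for name, pat in patterns.items()},
    )


@dataclass
class Hsp70Classification:
    """Family / localization / inducibility verdict with evidence trail."""

    sequence_id: str
    is_family_member: bool
    localization: Literal["cytosolic", "non_cytosolic", "undetermined"]
    inducibility: Literal["heat_inducible", "cognate_like", "undetermined"]
    evidence: list[tuple[str, bool, tuple[int, ...]]] = field(default_factory=list)
    score: int = 0


def classify(profile: SignatureProfile) -> Hsp70Classification:
    """Apply the ordered decision rules to a signature profile.

    1. Family membership: at least two of the four family signatures.
    2. Localization: EEVD tail present → cytosolic; family member without an
       EEVD tail → non-cytosolic (suggesting an organellar paralog).
    3. Inducibility (family members only): inducible diagnostics without
       ADAYLGTN → heat-inducible; cognate diagnostics without the inducible
       ATP site → cognate-like; contradictory evidence → undetermined.

    The score counts type-concordant diagnostic signatures (max 3).
    """
    ev: list[tuple[str, bool, tuple[int, ...]]] = []

    def note(name: str) -> bool:
        hits = profile.hits[name]
        ev.append((name, bool(hits), tuple(h.start for h in hits)))
        return bool(hits)

    family_present = sum(note(n) for n in FAMILY_SIGNATURES)
    is_family = family_present >= 2

    eevd = note("EEVD_tail")
    note("GPTIEEVD")  # supporting evidence for cytosolic localization
    if eevd:
        localization = "cytosolic"
    elif is_family:
        localization = "non_cytosolic"
    else:
        localization = "undetermined"

    ind_present = {n: note(n) for n in INDUCIBLE_SIGNATURES}
    cog_present = {n: note(n) for n in COGNATE_SIGNATURES}
    note("NLS")

    inducibility: str = "undetermined"
    score = 0
    if is_family:
        inducible_rule = any(ind_present.values()) and not cog_present["ATP_cognate"]
        cognate_rule = any(cog_present.values()) and not ind_present["ATP_inducible"]
        if inducible_rule and not cognate_rule:
            inducibility = "heat_inducible"
            score = sum(ind_present.values())
        elif cognate_rule and not inducible_rule:
            inducibility = "cognate_like"
            score = sum(cog_present.values())
        # both rules firing, or neither, leaves the verdict undetermined

    return Hsp70Classification(
        sequence_id=profile.sequence_id,
        is_family_member=is_family,
        localization=localization,
        inducibility=inducibility,
        evidence=ev,
        score=score,
    )


# --- reference-based domain / region operations ----------------------------


@dataclass(frozen=True)
class ReferenceModel:
    """A full-length Hsp70 reference with fixed domain boundaries.

    Defaults follow the amphipod gene model: nucleotide-binding domain (NBD)
    residues 1–390, substrate-binding domain (SBD) 397–560 and C-terminal
    domain (CTD) 561–641, with the 391–396 linker in no domain.
    """

    accession: str
    aa_sequence: str
    nbd: tuple[int, int] = (1, 390)
    sbd: tuple[int, int] = (397, 560)
    ctd: tuple[int, int] = (561, 641)

    def __post_init__(self) -> None:
        bounds = [*self.nbd, *self.sbd, *self.ctd]
        if sorted(bounds) != bounds or bounds[0] < 1:
            raise ValueError("domain boundaries must be ordered and positive")
        if bounds[-1] > len(self.aa_sequence):
            raise ValueError("domain boundaries exceed sequence length")

    @property
    def domains(self) -> dict[str, tuple[int, int]]:
        return {"NBD": self.nbd, "SBD": self.sbd, "CTD": self.ctd}


@dataclass
class DomainAnnotation:
    """Reference domains transferred onto a query via global alignment."""

    query_id: str
    domains: dict[str, tuple[int, int] | None]
    coverage: dict[str, float]
    identity: float
    low_identity_warning: bool


def make_aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> PairwiseAligner:
    """Global protein aligner: BLOSUM62, affine gaps, free end gaps."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    try:  # biopython >= 1.88 naming
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def _align_positions(ref: str, query: str) -> tuple[dict[int, int], float]:
    """Map 1-based reference positions to aligned 1-based query positions.

    Returns the position map (aligned columns only) and the percent identity
    over aligned columns.
    """
    alignment = make_aligner().align(ref, query)[0]
    mapping: dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (rs, re_), (qs, qe) in zip(*alignment.aligned):
        for k in range(re_ - rs):
            mapping[rs + k + 1] = qs + k + 1
            aligned_cols += 1
            if ref[rs + k] == query[qs + k]:
                matches += 1
    # identity relative to the shorter sequence, so a fragment aligning
    # perfectly scores 100 while a spuriously aligned short block does not
    return mapping, 100.0 * matches / min(len(ref), len(query))


def _nearest_mapped(mapping: dict[int, int], pos: int, lo: int, hi: int) -> int | None:
    """Query position for ``pos``, or for the nearest aligned reference
    position within [lo, hi]."""
    if pos in mapping:
        return mapping[pos]
    for offset in range(1, hi - lo + 1):
        for cand in (pos - offset, pos + offset):
            if lo <= cand <= hi and cand in mapping:
                return mapping[cand]
    return None


def map_domains(
    query: SeqRecord, reference: ReferenceModel, min_identity: float = 30.0
) -> DomainAnnotation:
    """Transfer reference domain boundaries onto a query protein.

    The query is globally aligned to the reference (BLOSUM62, affine gaps,
    free end gaps); each domain boundary moves to the nearest aligned query
    column. Coverage is the aligned fraction of each reference domain. An
    alignment identity below ``min_identity`` sets a warning flag instead of
    failing.
    """
    mapping, identity = _align_positions(reference.aa_sequence, query.sequence)
    domains: dict[str, tuple[int, int] | None] = {}
    coverage: dict[str, float] = {}
    for name, (dstart, dend) in reference.domains.items():
        aligned = [p for p in range(dstart, dend + 1) if p in mapping]
        coverage[name] = len(aligned) / (dend - dstart + 1)
        if not aligned:
            domains[name] = None
            continue
        qstart = _nearest_mapped(mapping, dstart, dstart, dend)
        qend = _nearest_mapped(mapping, dend, dstart, dend)
        assert qstart is not None and qend is not None
        domains[name] = (qstart, qend)
    return DomainAnnotation(
        query_id=query.id,
        domains=domains,
        coverage=coverage,
        identity=identity,
        low_identity_warning=identity < min_identity,
    )


def extract_region(
    protein: SeqRecord, ref_start: int, ref_end: int, reference: ReferenceModel
) -> tuple[str, int]:
    """Query residues aligned to reference columns [ref_start, ref_end].

    For a query identical to the reference this is the literal slice of
    length ``ref_end - ref_start + 1``. Otherwise the query is globally
    aligned to the reference and the contiguous query stretch spanning the
    aligned window is returned. Returns ``(subsequence, length)``.
    """
    rlen = len(reference.aa_sequence)
    if not (1 <= ref_start <= ref_end <= rlen):
        raise CoordinateError(
            f"invalid reference region {ref_start}..{ref_end} for length {rlen}"
        )
    if protein.sequence == reference.aa_sequence:
        sub = protein.sequence[ref_start - 1 : ref_end]
        return sub, len(sub)
    mapping, _ = _align_positions(reference.aa_sequence, protein.sequence)
    qpos = [mapping[p] for p in range(ref_start, ref_end + 1) if p in mapping]
    if not qpos:
        return "", 0
    sub = protein.sequence[min(qpos) - 1 : max(qpos)]
    return sub, len(sub)
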