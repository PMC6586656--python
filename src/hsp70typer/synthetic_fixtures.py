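"""Deterministic synthetic inputs mirroring the structure of the real data.

Every generator takes a seed and returns both the generated input and a
"truth" sidecar (planted coordinates / flags) sufficient to score recovery
downstream without re-derivation. Identical parameters and seed produce
identical output. Backbone composition is uniform by default; planted-motif
detectability depends on this and is documented in the methods note.

Protein fixtures place the signatures at domain-consistent positions
(N-terminal hexamer at 1–6, family signatures in the NBD, RARFEE[L/M]
mid-protein, GPTIEEVD / EEVD at the C-terminus). Promoter fixtures plant
heat-shock elements at exact distances upstream of an ORF start in a
background rejection-sampled to be free of accidental elements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import hse_scanner, motif_typing
from .core_seq import SeqRecord, write_fasta
from .expression_qpcr import CqMeasurement, ExpressionRecord
from .motif_typing import AMINO_ACIDS, profile_signatures

ProteinKind = Literal["protein_inducible", "protein_cognate", "protein_noncytosolic"]

_BASES = "ACGT"


class FixtureSpecError(ValueError):
    """Raised when requested fixture geometry is impossible."""


# --- proteins --------------------------------------------------------------

# (signature name, planted literal or None for NLS middle, 1-based start)
_COMMON_PLANTS = [
    ("IDLGTTYS", "IDLGTTYS", 9),
    ("TVPAYFND", "TVPAYFND", 40),
    ("NEPTAA", "NEPTAA", 90),
    ("phosphate_binding", "IFDLGGGTFDVSIL", 197),
    ("NLS", None, 246),  # KK + 9 random + RRLRT
]

_KIND_PLANTS: dict[str, list[tuple[str, str, int]]] = {
    "protein_inducible": [
        ("Nterm_inducible", "MRAKST", 1),
        ("ATP_inducible", "SEAYLGKE", 131),
        ("RARFEEM", "RARFEEM", 301),
    ],
    "protein_cognate": [
        ("Nterm_cognate", "MSKATA", 1),
        ("ATP_cognate", "ADAYLGTN", 131),
        ("RARFEEL", "RARFEEL", 301),
    ],
}
_KIND_PLANTS["protein_noncytosolic"] = _KIND_PLANTS["protein_inducible"]

#: Signatures expected present per kind (besides the common set + NLS).
EXPECTED_PRESENT: dict[str, set[str]] = {
    "protein_inducible": {
        "Nterm_inducible", "ATP_inducible", "RARFEEM", "GPTIEEVD", "EEVD_tail"
    },
    "protein_cognate": {
        "Nterm_cognate", "ATP_cognate", "RARFEEL", "GPTIEEVD", "EEVD_tail"
    },
    "protein_noncytosolic": {"Nterm_inducible", "ATP_inducible", "RARFEEM"},
}

EXPECTED_VERDICT: dict[str, tuple[bool, str, str]] = {
    "protein_inducible": (True, "cytosolic", "heat_inducible"),
    "protein_cognate": (True, "cytosolic", "cognate_like"),
    "protein_noncytosolic": (True, "non_cytosolic", "heat_inducible"),
}


def _plants_for(kind: ProteinKind, length: int, rng: np.random.Generator):
    plants = list(_COMMON_PLANTS) + list(_KIND_PLANTS[kind])
    if kind != "protein_noncytosolic":
        plants.append(("GPTIEEVD", "GPTIEEVD", length - 7))
    resolved = []
    for name, literal, start in plants:
        if literal is None:  # NLS: fixed flanks, free middle
            middle = "".join(rng.choice(list(AMINO_ACIDS), size=9))
            literal = "KK" + middle + "RRLRT"
        resolved.append((name, literal, start))
    resolved.sort(key=lambda t: t[2])
    for (_, lit_a, s_a), (_, _, s_b) in zip(resolved, resolved[1:]):
        if s_a + len(lit_a) > s_b:
            raise FixtureSpecError("planted signatures overlap")
    if resolved[-1][2] + len(resolved[-1][1]) - 1 > length:
        raise FixtureSpecError(f"length {length} too short for planted layout")
    return resolved


def gen_protein(
    kind: ProteinKind,
    seed: int,
    length: int = 641,
    n_mutations: int = 0,
) -> tuple[SeqRecord, dict]:
    """A random protein with type-appropriate signatures planted.

    ``n_mutations`` point substitutions are applied at random non-wildcard
    positions inside planted motifs (to probe classifier degradation). The
    backbone is rejection-sampled so that exactly the planted signatures are
    detectable at mismatch budget 0 before mutation.
    """
    if kind not in EXPECTED_PRESENT:
        raise FixtureSpecError(f"unknown protein fixture kind {kind!r}")
    if length < 641:
        raise FixtureSpecError("protein fixtures require length >= 641")
    rng = np.random.default_rng(seed)
    plants = _plants_for(kind, length, rng)
    expected = EXPECTED_PRESENT[kind] | {n for n, _, _ in _COMMON_PLANTS}

    for _attempt in range(50):
        seq = list(rng.choice(list(AMINO_ACIDS), size=length))
        for _, literal, start in plants:
            seq[start - 1 : start - 1 + len(literal)] = literal
        candidate = SeqRecord(
            id=f"{kind}_seed{seed}", sequence="".join(seq), moltype="protein"
        )
        profile = profile_signatures(candidate)
        found = {n for n, hits in profile.hits.items() if hits}
        singleton = all(len(profile.hits[n]) == 1 for n in expected)
        if found == expected and singleton:
            break
    else:
        raise FixtureSpecError("could not generate a clean backbone in 50 tries")

    patterns = motif_typing.builtin_patterns()
    mutable: list[tuple[int, frozenset]] = []
    for name, literal, start in plants:
        pat = patterns[name]
        for i in range(len(literal)):
            if not pat.is_wildcard(i):
                mutable.append((start - 1 + i, pat.positions[i]))
    mutated_positions: list[int] = []
    if n_mutations > 0:
        picks = rng.choice(len(mutable), size=min(n_mutations, len(mutable)), replace=False)
        seq = list(candidate.sequence)
        for k in sorted(int(p) for p in picks):
            pos, allowed = mutable[k]
            choices = [aa for aa in AMINO_ACIDS if aa not in allowed]
            seq[pos] = choices[int(rng.integers(len(choices)))]
            mutated_positions.append(pos + 1)
        candidate = SeqRecord(
            id=candidate.id, sequence="".join(seq), moltype="protein"
        )

    truth = {
        "kind": kind,
        "seed": seed,
        "planted": {
            name: [start, start + len(literal) - 1] for name, literal, start in plants
        },
        "mutated_positions": mutated_positions,
        "expected_verdict": list(EXPECTED_VERDICT[kind]),
    }
    return candidate, truth


# --- promoters -------------------------------------------------------------


@dataclass(frozen=True)
class PlantedHse:
    hse_class: Literal["canonical", "hse_like"]
    strand: Literal["+", "-"]
    distance: int
    n_units: int = 3


def _build_element(spec: PlantedHse, rng: np.random.Generator) -> str:
    first = "NGAAN" if spec.strand == "+" else "NTTCN"
    units = []
    cls = first
    for _ in range(spec.n_units):
        core = hse_scanner._CORES[cls]
        units.append(
            _BASES[rng.integers(4)] + core + _BASES[rng.integers(4)]
        )
        cls = "NTTCN" if cls == "NGAAN" else "NGAAN"
    element = list("".join(units))
    if spec.hse_class == "hse_like":
        unit_idx = int(rng.integers(spec.n_units))
        core_pos = unit_idx * 5 + 1 + int(rng.integers(3))
        alternatives = [b for b in _BASES if b != element[core_pos]]
        element[core_pos] = alternatives[int(rng.integers(3))]
    return "".join(element)


def gen_promoter(
    seed: int,
    elements: Sequence[PlantedHse] = (PlantedHse("canonical", "+", 1187),),
    orf_start: int | None = None,
    length: int | None = None,
) -> tuple[SeqRecord, dict]:
    """A promoter with HSEs planted at exact distances upstream of an ATG.

    The background is rejection-sampled to contain no accidental element and
    the planted geometry is re-verified after insertion; impossible geometry
    or exhausted retries raise :class:`FixtureSpecError` rather than
    silently degrading the guarantee.
    """
    rng = np.random.default_rng(seed)
    max_span = max((e.distance + 5 * e.n_units for e in elements), default=0)
    if orf_start is None:
        orf_start = max_span + 51
    if length is None:
        length = orf_start + 12
    if length < orf_start + 2:
        raise FixtureSpecError("sequence too short for the ORF start")

    planned = []
    for e in elements:
        end = orf_start - e.distance - 1
        start = end - 5 * e.n_units + 1
        if start < 1:
            raise FixtureSpecError(f"element at distance {e.distance} does not fit")
        planned.append((start, end, e))
    planned.sort()
    for (s1, e1, _), (s2, _, _) in zip(planned, planned[1:]):
        if e1 >= s2:
            raise FixtureSpecError("planted elements overlap")

    for _attempt in range(500):
        seq = list(rng.choice(list(_BASES), size=length))
        seq[orf_start - 1 : orf_start + 2] = "ATG"
        for start, _end, e in planned:
            element = _build_element(e, rng)
            seq[start - 1 : start - 1 + len(element)] = element
        record = SeqRecord(
            id=f"promoter_seed{seed}", sequence="".join(seq), moltype="dna"
        )
        hits = hse_scanner.find_hse(record)
        expected = {
            (start, end, e.strand, e.hse_class, e.n_units)
            for start, end, e in planned
        }
        got = {(h.start, h.end, h.strand, h.hse_class, h.n_units) for h in hits}
        if got == expected:
            truth = {
                "seed": seed,
                "orf_start": orf_start,
                "elements": [
                    {
                        "start": start,
                        "end": end,
                        "strand": e.strand,
                        "hse_class": e.hse_class,
                        "n_units": e.n_units,
                        "distance": e.distance,
                    }
                    for start, end, e in planned
                ],
            }
            return record, truth
    raise FixtureSpecError("could not generate a clean promoter in 500 tries")


# --- DE tables -------------------------------------------------------------

_FAIL_MODES = ("lfc", "padj", "tpm", "all", "padj_missing")


def gen_de_table(
    seed: int,
    n_total: int = 155,
    n_pass: int = 23,
    conditions: tuple[str, str] = ("control", "heat_shock"),
) -> tuple[list[ExpressionRecord], dict]:
    """A DE results table with exactly ``n_pass`` joint-passing rows.

    Failing rows cycle through all single-failure modes (fold change,
    adjusted p, abundance, everything, missing padj); the first fold-change
    failure sits exactly on the threshold to pin the strict inequality.
    """
    if n_pass > n_total:
        raise FixtureSpecError("n_pass cannot exceed n_total")
    rng = np.random.default_rng(seed)
    records: list[ExpressionRecord] = []
    truth_pass: list[str] = []

    def tpm_pair(lo: float, hi: float) -> dict[str, float]:
        return {c: float(rng.uniform(lo, hi)) for c in conditions}

    def good_lfc() -> float:
        return float(rng.choice([-1, 1]) * rng.uniform(1.5, 8.0))

    def good_padj() -> float:
        return float(rng.uniform(1e-12, 5e-4))

    first_lfc_fail = True
    for i in range(n_total):
        tid = f"TRINITY_DN{i:04d}_c0_g1_i1"
        if i < n_pass:
            rec = ExpressionRecord(
                tid, "heat shock protein 70", tpm_pair(250.0, 5000.0),
                good_lfc(), None, good_padj(),
            )
            rec.pvalue = rec.padj * float(rng.uniform(0.1, 1.0))
            truth_pass.append(tid)
        else:
            mode = _FAIL_MODES[(i - n_pass) % len(_FAIL_MODES)]
            lfc, padj, tpm = good_lfc(), good_padj(), tpm_pair(250.0, 5000.0)
            if mode in ("lfc", "all"):
                lfc = 1.0 if first_lfc_fail else float(
                    rng.choice([-1, 1]) * rng.uniform(0.0, 1.0)
                )
                first_lfc_fail = False
            if mode in ("padj", "all"):
                padj = float(rng.uniform(0.0011, 0.9))
            if mode in ("tpm", "all"):
                tpm = tpm_pair(0.0, 150.0)
            if mode == "padj_missing":
                padj = None
            rec = ExpressionRecord(tid, "heat shock protein 70", tpm, lfc, None, padj)
            if padj is not None:
                rec.pvalue = padj * float(rng.uniform(0.1, 1.0))
        records.append(rec)

    perm = rng.permutation(n_total)
    records = [records[int(k)] for k in perm]
    truth = {"seed": seed, "n_total": n_total, "n_pass": n_pass,
             "passing_ids": sorted(truth_pass)}
    return records, truth


# --- Cq tables -------------------------------------------------------------


def gen_cq_table(
    seed: int,
    n_per_group: int = 6,
    effect_size: float = -6.0,
    target_genes: tuple[str, ...] = ("hsp70_II",),
    reference_mean: float = 18.0,
    target_control_mean: float = 26.0,
    qc_failures: Sequence[tuple[str, str]] = (),
) -> tuple[list[CqMeasurement], dict]:
    """Two-group Cq measurements with a ΔCq shift in the heat-shock group.

    ``effect_size`` is in ΔCq units (negative = induction). ``qc_failures``
    plants reference-gene failures: ``(sample_id, "below_detection")`` sets
    gapdh Cq to 31, ``(sample_id, "contaminated")`` sets the −RT Cq to 28.
    """
    if n_per_group < 4:
        raise FixtureSpecError("need at least 4 biological replicates per group")
    rng = np.random.default_rng(seed)
    failures = dict(qc_failures)
    out: list[CqMeasurement] = []
    samples = [("control", f"C{i+1}") for i in range(n_per_group)] + [
        ("heat_shock", f"H{i+1}") for i in range(n_per_group)
    ]
    for group, sid in samples:
        ref_cq = float(rng.normal(reference_mean, 0.3))
        minus_rt = None
        if failures.get(sid) == "below_detection":
            ref_cq = 31.0
        elif failures.get(sid) == "contaminated":
            minus_rt = 28.0
        out.append(CqMeasurement(sid, group, "gapdh", ref_cq, minus_rt))
        for gene in target_genes:
            shift = effect_size if group == "heat_shock" else 0.0
            cq = float(rng.normal(target_control_mean + shift, 0.8))
            out.append(CqMeasurement(sid, group, gene, cq, None))
    truth = {
        "seed": seed,
        "n_per_group": n_per_group,
        "effect_size": effect_size,
        "qc_failures": sorted(failures.items()),
    }
    return out, truth


# --- serialization for the CLI --------------------------------------------


def write_fixture(kind: str, seed: int, out_prefix: str | Path, **params) -> dict:
    """Generate a fixture and write it plus its truth JSON sidecar.

    Returns the truth dict. File formats: FASTA for sequences, TSV for the
    DE table, CSV for the Cq table.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if kind in EXPECTED_PRESENT:
        record, truth = gen_protein(kind, seed, **params)
        write_fasta([record], f"{out_prefix}.fasta")
    elif kind == "promoter":
        record, truth = gen_promoter(seed, **params)
        write_fasta([record], f"{out_prefix}.fasta")
        with open(f"{out_prefix}.starts.tsv", "w") as fh:
            fh.write("sequence_id\torf_start\n")
            fh.write(f"{record.id}\t{truth['orf_start']}\n")
    elif kind == "de_table":
        records, truth = gen_de_table(seed, **params)
        conditions = sorted(records[0].mean_tpm)
        with open(f"{out_prefix}.tsv", "w") as fh:
            cols = ["transcript_id", "annotation"] + [f"tpm_{c}" for c in conditions]
            fh.write("\t".join(cols + ["log2fc", "pvalue", "padj"]) + "\n")
            for r in records:
                tpms = "\t".join(f"{r.mean_tpm[c]:.4f}" for c in conditions)
                pv = "" if r.pvalue is None else f"{r.pvalue:.6g}"
                pa = "" if r.padj is None else f"{r.padj:.6g}"
                fh.write(
                    f"{r.transcript_id}\t{r.annotation}\t{tpms}\t"
                    f"{r.log2fc:.4f}\t{pv}\t{pa}\n"
                )
    elif kind == "cq_table":
        measurements, truth = gen_cq_table(seed, **params)
        with open(f"{out_prefix}.csv", "w") as fh:
            fh.write("sample_id,group,gene,cq,minus_rt_cq\n")
            for m in measurements:
                cq = "" if m.cq is None else f"{m.cq:.4f}"
                rt = "" if m.minus_rt_cq is None else f"{m.minus_rt_cq:.4f}"
                fh.write(f"{m.sample_id},{m.group},{m.gene},{cq},{rt}\n")
    else:
        raise FixtureSpecError(f"unknown fixture kind {kind!r}")
    with open(f"{out_prefix}.truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
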