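"""Candidate filtering from DE tables and the qPCR ΔCq statistics pipeline.

The differential-expression filter consumes a results table produced by an
upstream quantification/DE pipeline (e.g. salmon + DESeq2) and flags
candidate transcripts by the study thresholds: |log2 fold change| > 1,
adjusted p < 0.001 (both strict), and mean abundance above 200 TPM.

The qPCR pipeline normalizes target quantification cycles (Cq) against a
reference gene (gapdh by default): ΔCq = Cq_target − Cq_reference, so lower
ΔCq means higher relative expression. Samples are quality-controlled before
analysis: a reference Cq above 30 means the sample is below detection, and
a −RT (no reverse transcriptase) reference Cq below 30 indicates genomic
DNA contamination; either discards the sample. Group comparisons use an
exact Wilcoxon–Mann–Whitney test with a step-down Holm correction across
primer pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

REFERENCE_GENE = "gapdh"


# --- differential-expression filtering -------------------------------------


@dataclass
class ExpressionRecord:
    """One row of a DE results table."""

    transcript_id: str
    annotation: str
    mean_tpm: dict[str, float]
    log2fc: float
    pvalue: float | None
    padj: float | None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.mean_tpm.values()):
            raise ValueError(f"{self.transcript_id}: negative TPM")


@dataclass(frozen=True)
class FilterConfig:
    """Candidate thresholds; defaults are the study values."""

    lfc_min: float = 1.0
    padj_max: float = 0.001
    tpm_min: float = 200.0

    def __post_init__(self) -> None:
        if min(self.lfc_min, self.padj_max, self.tpm_min) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class CandidateFlags:
    transcript_id: str
    de_significant: bool
    abundant: bool
    log2fc: float
    padj: float | None
    mean_tpm: float


def filter_de(
    records: Sequence[ExpressionRecord], cfg: FilterConfig = FilterConfig()
) -> tuple[list[CandidateFlags], list[str]]:
    """Flag DE-significant and abundant transcripts (strict inequalities).

    A missing adjusted p-value makes a row non-significant and is reported
    in the returned warning list; malformed rows are skipped with an error
    message while the remaining rows proceed.
    """
    flags: list[CandidateFlags] = []
    warnings: list[str] = []
    for rec in records:
        try:
            if rec.padj is None or (isinstance(rec.padj, float) and math.isnan(rec.padj)):
                significant = False
                warnings.append(f"{rec.transcript_id}: missing padj, not significant")
            else:
                if not (0.0 <= rec.padj <= 1.0):
                    raise ValueError(f"padj {rec.padj} outside [0, 1]")
                significant = abs(rec.log2fc) > cfg.lfc_min and rec.padj < cfg.padj_max
            mean_tpm = float(np.mean(list(rec.mean_tpm.values())))
            flags.append(
                CandidateFlags(
                    transcript_id=rec.transcript_id,
                    de_significant=significant,
                    abundant=mean_tpm > cfg.tpm_min,
                    log2fc=rec.log2fc,
                    padj=rec.padj,
                    mean_tpm=mean_tpm,
                )
            )
        except (ValueError, TypeError) as exc:
            warnings.append(f"{rec.transcript_id}: malformed row skipped ({exc})")
    return flags, warnings


def read_de_table(path) -> list[ExpressionRecord]:
    """Read a TSV with columns transcript_id, annotation, tpm_<condition>...,
    log2fc, pvalue, padj."""
    df = pd.read_csv(path, sep="\t")
    tpm_cols = [c for c in df.columns if c.startswith("tpm_")]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ExpressionRecord(
                transcript_id=str(d["transcript_id"]),
                annotation=str(d.get("annotation", "")),
                mean_tpm={c[4:]: float(d[c]) for c in tpm_cols},
                log2fc=float(d["log2fc"]),
                pvalue=None if pd.isna(d.get("pvalue")) else float(d["pvalue"]),
                padj=None if pd.isna(d.get("padj")) else float(d["padj"]),
            )
        )
    return records


# --- qPCR ------------------------------------------------------------------


@dataclass
class CqMeasurement:
    """One qPCR well: Cq and −RT control Cq (None = undetected)."""

    sample_id: str
    group: Literal["control", "heat_shock"]
    gene: str
    cq: float | None
    minus_rt_cq: float | None = None


@dataclass
class DiscardedSample:
    sample_id: str
    reason: Literal["below_detection", "contaminated", "missing_reference"]


def qc_cq(
    measurements: Sequence[CqMeasurement],
    cq_cutoff: float = 30.0,
    reference_gene: str = REFERENCE_GENE,
) -> tuple[list[CqMeasurement], list[DiscardedSample]]:
    """Discard samples failing reference-gene quality control.

    A sample is discarded when its reference-gene Cq exceeds the cutoff
    (below detection), when the reference −RT Cq is below the cutoff
    (genomic DNA contamination), or when it lacks a reference measurement.
    """
    by_sample: dict[str, list[CqMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, []).append(m)

    kept: list[CqMeasurement] = []
    discarded: list[DiscardedSample] = []
    for sample_id, ms in by_sample.items():
        refs = [m for m in ms if m.gene == reference_gene]
        if not refs:
            discarded.append(DiscardedSample(sample_id, "missing_reference"))
            continue
        ref = refs[0]
        if ref.cq is None or ref.cq > cq_cutoff:
            discarded.append(DiscardedSample(sample_id, "below_detection"))
        elif ref.minus_rt_cq is not None and ref.minus_rt_cq < cq_cutoff:
            discarded.append(DiscardedSample(sample_id, "contaminated"))
        else:
            kept.extend(ms)
    return kept, discarded


@dataclass
class DeltaCq:
    sample_id: str
    group: str
    gene: str
    value: float | None  # None = target undetected (censored)

    @property
    def censored(self) -> bool:
        return self.value is None


def delta_cq(
    measurements: Sequence[CqMeasurement],
    reference_gene: str = REFERENCE_GENE,
) -> list[DeltaCq]:
    """Per-sample ΔCq = Cq_target − Cq_reference for every target gene.

    Samples are assumed to have passed :func:`qc_cq`. Undetected targets
    yield censored values that are excluded from testing but counted in
    the detection report.
    """
    by_sample: dict[str, list[CqMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, []).append(m)

    out: list[DeltaCq] = []
    for sample_id, ms in by_sample.items():
        refs = [m for m in ms if m.gene == reference_gene]
        if not refs or refs[0].cq is None:
            raise ValueError(f"sample {sample_id!r} lacks a detected reference Cq")
        ref_cq = refs[0].cq
        for m in ms:
            if m.gene == reference_gene:
                continue
            value = None if m.cq is None else m.cq - ref_cq
            out.append(DeltaCq(sample_id, m.group, m.gene, value))
    return out


# --- rank statistics -------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: Literal["exact", "normal_approx"]
    n_a: int
    n_b: int


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_limit: int = 12,
) -> MannWhitneyResult:
    """Two-sided Wilcoxon–Mann–Whitney test.

    For n + m <= ``exact_limit`` the p-value is exact: all C(n+m, n) group
    labelings are enumerated (midranks for ties) and the two-sided p is the
    probability of a U statistic at least as far from the null mean nm/2 as
    the observed one — no tail doubling. Larger samples use the normal
    approximation with tie correction and continuity correction. The U
    reported is for ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("both groups must be non-empty")

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    mu = n * m / 2.0

    if n + m <= exact_limit:
        combos = np.array(list(combinations(range(n + m), n)))
        u_all = ranks[combos].sum(axis=1) - n * (n + 1) / 2.0
        d_obs = abs(u_obs - mu)
        p = float(np.mean(np.abs(u_all - mu) >= d_obs - 1e-9))
        return MannWhitneyResult(u=float(u_obs), p=p, method="exact", n_a=n, n_b=m)

    total = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (total * (total - 1))
    sigma2 = n * m / 12.0 * ((total + 1) - tie_term)
    if sigma2 <= 0:  # all values tied
        return MannWhitneyResult(u=float(u_obs), p=1.0, method="normal_approx", n_a=n, n_b=m)
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return MannWhitneyResult(u=float(u_obs), p=p, method="normal_approx", n_a=n, n_b=m)


def holm_adjust(ps: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment, returned in input order.

    The i-th smallest p is multiplied by (m − i + 1); running maxima enforce
    monotonicity and values are capped at 1.
    """
    ps = list(ps)
    if any(p < 0 or p > 1 or math.isnan(p) for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * ps[idx]))
        adjusted[idx] = running
    return adjusted


# --- orchestration ---------------------------------------------------------


@dataclass
class GeneComparison:
    gene: str
    n_control: int
    n_heat_shock: int
    n_censored_control: int
    n_censored_heat_shock: int
    u: float | None
    p_raw: float | None
    p_holm: float | None
    method: str | None


@dataclass
class DeltaCqResult:
    """Full qPCR analysis: QC log, per-sample ΔCq and per-gene tests."""

    delta_cq: list[DeltaCq]
    discarded: list[DiscardedSample]
    comparisons: list[GeneComparison] = field(default_factory=list)


def analyze_qpcr(
    measurements: Sequence[CqMeasurement],
    cq_cutoff: float = 30.0,
    reference_gene: str = REFERENCE_GENE,
    min_group_size: int = 4,
) -> DeltaCqResult:
    """QC, ΔCq computation and per-gene control vs heat-shock tests.

    Censored (undetected-target) ΔCq values are excluded from testing and
    reported as censoring counts. The Holm family is the set of target
    genes tested. Comparisons with fewer than ``min_group_size`` usable
    values per group are reported without a test.
    """
    kept, discarded = qc_cq(measurements, cq_cutoff, reference_gene)
    deltas = delta_cq(kept, reference_gene)

    genes = sorted({d.gene for d in deltas})
    comparisons: list[GeneComparison] = []
    raw_ps: list[float] = []
    testable: list[int] = []
    for gene in genes:
        ctrl = [d for d in deltas if d.gene == gene and d.group == "control"]
        heat = [d for d in deltas if d.gene == gene and d.group == "heat_shock"]
        ctrl_vals = [d.value for d in ctrl if not d.censored]
        heat_vals = [d.value for d in heat if not d.censored]
        comp = GeneComparison(
            gene=gene,
            n_control=len(ctrl_vals),
            n_heat_shock=len(heat_vals),
            n_censored_control=len(ctrl) - len(ctrl_vals),
            n_censored_heat_shock=len(heat) - len(heat_vals),
            u=None,
            p_raw=None,
            p_holm=None,
            method=None,
        )
        if len(ctrl_vals) >= min_group_size and len(heat_vals) >= min_group_size:
            res = mann_whitney(ctrl_vals, heat_vals)
            comp.u, comp.p_raw, comp.method = res.u, res.p, res.method
            testable.append(len(comparisons))
            raw_ps.append(res.p)
        comparisons.append(comp)

    if raw_ps:
        for idx, p_adj in zip(testable, holm_adjust(raw_ps)):
            comparisons[idx].p_holm = p_adj

    return DeltaCqResult(delta_cq=deltas, discarded=discarded, comparisons=comparisons)


def read_cq_table(path) -> list[CqMeasurement]:
    """Read a CSV with columns sample_id, group, gene, cq, minus_rt_cq.

    Empty / NA cq cells mean the well was undetected.
    """
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            CqMeasurement(
                sample_id=str(d["sample_id"]),
                group=str(d["group"]),
                gene=str(d["gene"]),
                cq=None if pd.isna(d["cq"]) else float(d["cq"]),
                minus_rt_cq=None
                if pd.isna(d.get("minus_rt_cq"))
                else float(d["minus_rt_cq"]),
            )
        )
    return out
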