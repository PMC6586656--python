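# Methods

This note records the models, conventions and deliberate design choices
behind `hsp70typer`, in the order a user meets them.

## Sequences, coordinates, ORFs

All coordinates are 1-based and inclusive on the forward strand; a
reverse-strand feature reports the forward-strand interval it spans. ORFs
are complete (ATG through stop) in any of the six frames; every ATG is
paired with its nearest in-frame stop, so nested ORFs sharing a stop are
all reported, sorted by descending product length. The stop codon is part
of the ORF but not of the translation, so a 1,926-bp ORF encodes
1926/3 − 1 = 641 residues. Codons containing the ambiguity base N translate
to X and are never accepted as start or stop codons. Open-ended ORFs
(missing a stop) are not reported: the gene models this package supports
are complete coding sequences.

## Signature grammar and scanning

Degenerate signatures use a deliberately small grammar: a plain letter is a
fixed residue, `X` is a wildcard, and a single parenthesized letter is an
alternative for the immediately preceding position — chosen because it
reproduces the printed eight-residue inducible ATP-site
`S(A)EAYLGK(G)E(A)` exactly. Scanning is exhaustive with a per-pattern
mismatch budget (default 0 for every built-in signature, configurable per
signature for relaxed searches); wildcard positions never count as
mismatches. The N-terminal hexamers (`MRAKST`/`MSKATA`) are anchored at
residue 1 — both observed hexamers include the initiator methionine — and
`GPTIEEVD`/`EEVD` are anchored at the C-terminus. `EEVD` alone decides
cytosolic localization so that proteins with truncated C-termini beyond the
tetrapeptide still classify; `GPTIEEVD` is recorded as supporting evidence.

## Classification rules

Applied in order, never guessing:

1. *Family membership*: at least two of {`IDLGTTYS`, `TVPAYFND`, `NEPTAA`,
   phosphate-binding site} present.
2. *Localization*: `EEVD` tail → cytosolic; family member without it →
   non-cytosolic (organellar paralog); otherwise undetermined.
3. *Inducibility* (family members only): any inducible diagnostic
   ({inducible ATP site, `MRAKST`, `RARFEEM`}) without the cognate ATP site
   → heat-inducible; any cognate diagnostic without the inducible ATP site
   → cognate-like; if both rules (or neither) fire, the verdict is
   undetermined with the conflict visible in the evidence trail.

The score counts type-concordant diagnostics (0–3). On zero-mutation
synthetic fixtures recovery is exact; recovery degrades monotonically as
planted motifs are mutated, which the test suite checks at fixed seeds.

## Domain transfer and region extraction

Queries are aligned to a full-length reference (domain boundaries NBD
1–390, SBD 397–560, CTD 561–641, linker 391–396 unassigned) with a global
pairwise alignment: BLOSUM62, affine gaps (open −11, extend −1), free end
gaps so fragments align to their true region. Each boundary transfers to
the nearest aligned query column; coverage is the aligned fraction of each
reference domain. Alignment identity is reported relative to the shorter
sequence, so a perfect fragment scores 100 while a short spurious block
does not; identity below a configurable floor (default 30%) sets a warning
flag rather than failing. Region extraction returns the query stretch
spanning a reference window — for a query equal to the reference this is
the literal slice, e.g. residues 217–514 give a 298-residue fragment.

## Heat-shock elements

A pentamer unit is `NTTCN` or `NGAAN`; only the central trinucleotide is
constrained and the flanks are free. All five phases are scanned for
maximal runs of alternating units; a run is *canonical* at ≥ 3 units with
no core mismatch and *HSE-like* at ≥ 3 units with exactly one core
mismatch. The one-mismatch budget is a heuristic: published "HSE-like"
instances are not formally defined, and at least one genome-printed example
carries two core substitutions, which this scanner intentionally does not
call. Maximality is budget-aware (a reported run cannot be extended by
another valid in-phase unit without breaking alternation or the budget);
overlapping runs in different phases are reported independently.

Because the reverse complement of `NGAAN` is `NTTCN`, an alternating run
is the same element on both strands, and a naive two-strand scan would
report everything twice. Each run is therefore reported once with its
strand defined by the 5'-most unit (`NGAAN`-first = `+`): under reverse
complement the (units, class) multiset is invariant and the strand label
flips for odd-unit runs. Upstream distance counts the bases strictly
between the element's end and the A of the start codon; an element
overlapping or downstream of the start is an error.

## Differential-expression filter

The filter consumes the output table of an upstream quantification/DE
pipeline; it does not re-estimate expression. Thresholds are strict
inequalities: |log2FC| > 1, adjusted p < 0.001, mean TPM across conditions
> 200. A row with a missing adjusted p is never significant (DE tools emit
NA for independently filtered rows); malformed rows are reported and
skipped without aborting the batch.

## qPCR statistics

ΔCq = Cq_target − Cq_reference (gapdh), so lower ΔCq means higher relative
expression. Sample QC precedes analysis: reference Cq > 30 (below
detection) or reference −RT Cq < 30 (genomic DNA contamination) discards
the sample with a recorded reason. Undetected targets in surviving samples
are censored — excluded from testing but counted — rather than imputed;
with strong induction the control group often sits below detection, and
imputation would manufacture effect sizes.

Group comparisons use the Wilcoxon–Mann–Whitney test. For n + m ≤ 12 the
p-value is exact by complete enumeration of all C(n+m, n) labelings with
midranks for ties; the two-sided p is the probability of |U − nm/2| at
least as extreme as observed (a symmetric tail definition, not a doubled
one-sided tail). Larger samples fall back to the normal approximation with
tie and continuity correction; the method used is always reported. Note
the exact test is discrete and therefore conservative: at 6 vs 6 its
largest achievable level not exceeding 0.05 is 38/924 ≈ 0.041, and the
calibration tests compare the empirical null rejection rate against that
enumerated attained size, not against the nominal level. Holm's step-down
correction is applied across the target genes of one analysis (mirroring
per-species primer-pair families); the family is configurable.

## Synthetic fixtures

Generators emulate the *structure* of the real inputs, not their biology:
uniform-composition backbones with signatures planted at domain-consistent
positions, promoters rejection-sampled to contain no accidental element
before planting, DE tables with exactly the requested number of jointly
passing rows (failing rows cycle all single-failure modes, including an
exact-threshold fold change), and two-group Cq tables with a configurable
ΔCq shift (default −6 cycles, six replicates per group, reference Cq ≈ 18,
target control Cq ≈ 26). Identical parameters and seed give byte-identical
output; every generator returns a truth sidecar sufficient to score
recovery. Consequences of these simplifications: uniform backbones make
planted motifs maximally detectable, so passing recovery tests bounds
performance on idealized data only — real proteomes contain homologous
near-misses, and real promoters have skewed composition that changes the
accidental-element rate. Fixture scale (155/108-row tables, 200-protein
recovery batches, 10,000-replicate null calibrations) was chosen to keep
the full suite in the tens of seconds on one core while leaving binomial
noise well below the asserted margins.

## Known limitations

- The diagnostic signatures are amphipod-derived; outside Amphipoda the
  inducible/cognate split is known to arise independently and these rules
  need re-validation.
- The HSE-like definition is a documented heuristic (one core mismatch);
  promoter context such as chromatin or distance-dependent HSF activity is
  out of scope.
- Consensus ties break alphabetically (flagged); a different tie policy
  will differ at tied columns.
- The identity convention (internal gaps as mismatches, terminal overhangs
  excluded, one-decimal reporting) is one of several reasonable choices
  and is fixed here for reproducibility.
- Multiple-alignment construction, phylogenetics, read processing and
  expression quantification are upstream of this package by design.
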