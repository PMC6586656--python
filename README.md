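# hsp70typer

Rule-based determination of **heat-inducible Hsp70** family members in
amphipods from protein sequence signatures, promoter heat-shock elements,
conservation analysis, differential-expression evidence and qPCR ΔCq
statistics.

## The problem

The 70 kDa heat shock protein family (Hsp/Hsc70) mixes constitutively
expressed cognates (Hsc70) with strongly stress-inducible paralogs (Hsp70).
In non-model crustaceans the two types are not reliably separable by overall
sequence similarity, which makes *hsp70*-based biomarkers for environmental
monitoring unreliable: primers designed against a cognate report a two-fold
"induction" where the true inducible paralog is up-regulated a
thousand-fold. In amphipods, however, a small set of amino-acid signatures
discriminates the types, and `hsp70typer` turns those diagnostics into a
reproducible, testable classifier for people screening transcriptomes or
genomes of non-model taxa.

## The method

A candidate protein is scanned with a built-in set of degenerate signatures
(notation: `X` = wildcard, `(Y)` = alternative for the preceding residue):

| role | signature |
|---|---|
| family membership | `IDLGTTYS`, `TVPAYFND`, `NEPTAA`, phosphate-binding `IFDLGGGTFDVSIL` |
| cytosolic localization | C-terminal `EEVD` (with `GPTIEEVD` and `RARFEEL`/`RARFEEM` as support) |
| nuclear translocation | NLS `KKXXXXXXXXXRRLRT` |
| heat-inducible type | ATP/GTP site `S(A)EAYLGK(G)E(A)`, N-terminal `MRAKST`, `RARFEEM` |
| cognate type | ATP/GTP site `ADAYLGTN`, N-terminal `MSKATA`, `RARFEEL` |

Ordered decision rules produce a family / localization / inducibility
verdict with an explicit evidence trail; contradictory evidence yields
`undetermined` rather than a guess. Supporting modules provide:

- **ORF finding and translation** (six frames, ATG→stop, 1-based inclusive
  coordinates) — a complete 1,926-bp ORF yields a 641-residue protein;
- **domain transfer** from a reference model (NBD 1–390, SBD 397–560,
  CTD 561–641) onto queries via global alignment, and reference-coordinate
  region extraction (e.g. residues 217–514 → a 298-residue fragment);
- **heat-shock-element scanning**: maximal runs of alternating
  `NTTCN`/`NGAAN` pentamers, canonical at ≥ 3 perfect units, HSE-like with
  one core mismatch, reported with their distance upstream of the ORF start;
- **conservation**: pairwise identity, per-column conservation, consensus
  and between-group difference masks;
- **expression evidence**: candidate filtering of a DE results table
  (|log2FC| > 1, adjusted p < 0.001, mean TPM > 200, all strict) and a qPCR
  pipeline (ΔCq = Cq_target − Cq_gapdh, reference-gene QC at Cq 30, exact
  Wilcoxon–Mann–Whitney by complete enumeration, Holm correction);
- **synthetic fixtures**: seeded generators for proteins, promoters, DE and
  Cq tables with planted truth, so everything is testable offline.

## Worked example

Generate a synthetic bundle and run the combined workflow (`cand_1` is a
planted heat-inducible protein with a canonical HSE 1,187 bp upstream of its
ORF start and strong DE/qPCR support; `cand_2` is a planted cognate):

```bash
hsp70typer determine --proteins proteins.fasta \
    --promoters promoters.fasta --starts starts.tsv \
    --de de.tsv --cq cq.csv --out report.tsv
```

`report.tsv` (abridged):

```text
id      family_member  localization  inducibility    score  ...  hse_hits                  de_significant
cand_1  True           cytosolic     heat_inducible  3      ...  canonical@51-65+(d=1187)  True
cand_2  True           cytosolic     cognate_like    3      ...  NA                        False
```

and the JSON summary prints

```json
{"n_cognate_like": 1, "n_heat_inducible": 1, "n_sequences": 2,
 "qpcr": [{"gene": "hsp70_II", "method": "exact", "n_control": 6,
           "n_heat_shock": 6, "p_holm": 0.0021645, "p_raw": 0.0021645,
           "u": 36.0}]}
```

Read: both candidates carry the full family core and the cytosolic EEVD
tail; `cand_1` carries all three inducible diagnostics (score 3) plus a
canonical heat-shock element 1,187 bp upstream and passes the DE filter,
while `cand_2` carries the cognate diagnostics. The qPCR comparison (6 vs 6
replicates, ΔCq shifted by −6 cycles under heat shock) rejects with the
smallest two-sided p the exact test can produce at these sample sizes
(2/924 ≈ 0.0022).

Each subcommand (`orfs`, `classify`, `hse`, `de-filter`, `qpcr`,
`simulate`, `signatures`) is also usable on its own; `hsp70typer simulate`
writes any fixture with its truth sidecar.

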