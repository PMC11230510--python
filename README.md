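# kataegion

Detection and characterisation of kataegis — focal clusters of somatic
single-base substitutions — in tumour SNV catalogs, with epoch-stratified
calling, SV-breakend proximity enrichment, lightweight mutational-signature
refitting, cohort association statistics, and a fully seeded synthetic-cohort
generator for end-to-end testing.

## What it does

- **`kataegion.formats_io`** — SNV (TSV/VCF), SV (BEDPE), BED mask/interval
  and clinical-table I/O with strict coordinate conventions (SNVs 1-based,
  BED/BEDPE 0-based half-open, event spans 1-based inclusive).
- **`kataegion.segmentation`** — exact penalized least-squares
  piecewise-constant fitting (global O(n²) dynamic programme) used to smooth
  log10 inter-mutation distances.
- **`kataegion.caller`** — splits SNVs into early-clonal / late-clonal /
  subclonal calling subsets (unspecified-clonal SNVs enter both clonal
  subsets, unknown SNVs enter all three), applies a burden-adjusted distance
  threshold capped at 1 kbp, emits maximal runs of ≥ 4 SNVs whose smoothed
  inter-mutation distances all fall below threshold, and de-duplicates
  early/late calls that share unspecified SNVs.
- **`kataegion.filters`** — keeps candidates that are substitution-type
  consistent (all members mutate the same pyrimidine-normalized reference
  base) or phase-informative (≥ 2 members share a phase group); a
  consistency-only mode serves cohorts without phasing. Every drop is
  accounted for.
- **`kataegion.sv_proximity`** — nearest-breakend distances measured from the
  event span, matched control regions re-anchored at random same-sample small
  variants, and exact (hypergeometric) enrichment tests in the ≤ 10 kbp and
  0.1–10 Mbp bands.
- **`kataegion.signatures`** — 96-channel substitution and 32-channel
  rearrangement catalogs, non-negative least-squares refitting against a
  supplied reference matrix, cosine-similarity exclusion below 0.5, and
  APOBEC (SBS2 + SBS13) attribution summaries.
- **`kataegion.assoc`** — exact Fisher 2×2 tests, rank-sum tests (exact by
  enumeration for small samples), Benjamini–Hochberg FDR, and bidirectional
  AIC-stepwise logistic / negative-binomial GLMs with correlation-based
  covariate exclusion.
- **`kataegion.simulate`** — seeded synthetic cohorts: background SNVs from a
  homogeneous point process, planted clusters with configurable size/span
  distributions, APOBEC context bias, per-event epochs, partial phasing, and
  SV linkage; plus truth-matching to score callers.
- **`kataegion.pipeline` / `kataegion.cli`** — staged orchestration with a
  content-hash manifest and partial-rerun reuse.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact-segmentation
oracle equivalence, planted-event recovery, null false-call control,
enrichment-test calibration, signature-refit recovery, stepwise-GLM recovery,
and printed-count arithmetic); the other files are per-module unit and
property tests.

## CLI

```bash
# synthetic cohort
kataegion simulate --seed 1 --out sim/

# call -> filter
kataegion call --snvs sim/snvs.tsv --out run/
kataegion filter --candidates run/candidates.tsv --out run/

# breakend proximity enrichment
kataegion sv-enrich --events run/events.tsv --svs sim/svs.bedpe \
    --snvs sim/snvs.tsv --band both --seed 1 --out run/

# signature refitting and cohort models
kataegion signatures --events run/events.tsv --reference ref_sbs96.tsv --out run/
kataegion assoc --events run/events.tsv --clinical clinical.tsv --out run/

# or everything from one YAML config
kataegion run-all --config cfg.yaml
```

A config YAML may contain input paths (`snvs`, `svs`, `mask`, `clinical`,
`sbs96_reference`), stage parameters (`gamma`, `kmin`, `alpha`,
`genome_length`, `max_threshold_bp`, `filter_mode`, `corr_cutoff`,
`max_events_per_sample`), a `seed`, and an optional `sim` block to generate
the inputs instead of reading them. Unknown keys are rejected.

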