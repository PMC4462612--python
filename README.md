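# twinmeth

Differential and variable DNA-methylation analysis for monozygotic (MZ)
twin designs, plus a seeded synthetic-data generator so every stage is
testable without external data.

Given a probe × sample beta-value matrix (methylation fractions in [0, 1])
and a sample sheet assigning samples to twin pairs with a diagnostic group
(`concordant` / `discordant` / `healthy`) and, in discordant pairs, an
affected/unaffected role, the package provides:

- **DMP ranking** (`twinmeth.dmp`) — for every probe, a paired t-test on
  affected-minus-unaffected differences across discordant pairs plus the
  absolute mean difference |Δβ|. Each probe gets two linear rank scores
  (lower P → higher score; larger |Δβ| → higher score); the scores are
  added and probes ranked by the sum. No multiple-testing correction: the
  output is a ranking, with a configurable top-k extract.
- **Cross-group validation** (`twinmeth.dmp_validate`) — one-sided
  Wilcoxon–Mann–Whitney tests of whether a probe's absolute within-pair
  differences in discordant pairs exceed those in concordant and healthy
  pairs (exact permutation P for small tie-free samples, tie-corrected
  normal approximation otherwise).
- **VMP classification** (`twinmeth.vmp`) — absolute within-pair
  differences for all pairs → per-group medians (an m × 3 matrix) →
  inclusive threshold (default median |Δβ| ≥ 0.1) → partition of variable
  probes into group-exclusive and shared Venn regions, with exceedance
  statistics and gene-region feature-category summaries.
- **Enrichment** (`twinmeth.enrich`) — hypergeometric over-representation
  of probe-derived gene lists against GMT gene sets with Benjamini–Hochberg
  FDR. This is a transparent stand-in for GUI/service-based network
  enrichment tools; it makes no attempt to reproduce any specific network
  resource.
- **Simulation** (`twinmeth.simulate`) — seeded generator of twin beta
  matrices with a bimodal baseline, additive per-twin Gaussian noise,
  planted discordant-pair mean shifts and planted group-exclusive large
  within-pair differences, plus truth tables for recovery scoring.
- **Pipeline** (`twinmeth.pipeline`, `twinmeth.cli`) — YAML-config-driven
  orchestration with per-stage TSV outputs and a machine-readable JSON run
  report (schema bundled under `twinmeth/schemas/`).

## Command line

```bash
# generate a synthetic data set (B.tsv, D.csv, ann.csv, truth tables)
twinmeth simulate --seed 1 --n-probes 10000 --out-dir sims/

# rank probes (Δβ = affected minus unaffected, discordant pairs only)
twinmeth dmp --beta sims/B.tsv --design sims/D.csv \
    --annotation sims/ann.csv --top-k 10 --out dmp.tsv

# validate the top probes against concordant and healthy pairs
twinmeth dmp-validate --beta sims/B.tsv --design sims/D.csv \
    --probes dmp.tsv --alpha 0.05 --out val.tsv

# classify variably methylated probes
twinmeth vmp --beta sims/B.tsv --design sims/D.csv \
    --annotation sims/ann.csv --threshold 0.1 --out vmp.tsv

# gene-set over-representation
twinmeth enrich --genes genes.txt --gmt sets.gmt \
    --universe universe.txt --out enrich.tsv

# everything from one YAML config
twinmeth run-all --config run.yaml
```

A minimal `run.yaml`:

```yaml
seed: 1
output_dir: out
simulate:
  n_probes: 10000
  n_dmp: 10
  n_vmp: {concordant: 8, discordant: 17, healthy: 22}
top_k: 10
vmp_threshold: 0.1
alpha_level: 0.05
```

Replace `simulate:` with `input: {beta: B.tsv, design: D.csv,
annotation: ann.csv}` to analyze real data. Exit codes: 0 success, 1 usage
error, 2 data/analysis error.

## File formats

- **Beta matrix** — TSV, header `probe_id\t<sample>...`; missing token
  `NA` (configurable). Values validated to [0, 1].
- **Sample sheet** — CSV with columns `sample_id, pair_id, group,
  affected`; every pair must occur exactly twice with consistent group and
  role flags.
- **Probe annotation** — CSV with columns `probe_id, chr, pos, gene,
  feature`; semicolon-separated multi-values; feature categories drawn
  from {TSS1500, TSS200, 5'UTR, 1st exon, Body, 3'UTR, intergenic}.
- **Gene sets** — standard GMT.

## Notes on conventions

- Δβ is always affected minus unaffected within a discordant pair; the
  ranking uses the absolute value of the mean difference.
- The VMP threshold comparison is inclusive (≥) and operates on the
  per-group *median* of absolute within-pair differences.
- Group column order is fixed to (concordant, discordant, healthy)
  everywhere.
- Missing beta values are allowed; any probe with a missing value in a
  sample used by an analysis is dropped from that analysis with a logged
  count.
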