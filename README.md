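# metlink

Analysis toolkit for matched normal / multi-region primary-tumour / metastasis
sample sets: a somatic-variant filter cascade, metastasis-exclusive variant
set algebra, mutation-spectrum summaries, expression fold-change rankings,
and a rank-based two-sample Kolmogorov–Smirnov association between mutation
load and transcriptome change — plus a synthetic-cohort generator with a
known, tunable mutation→expression coupling for calibration and
power studies.

## Components

| Module | What it does |
| --- | --- |
| `metlink.synthetic_cohort` | Cohort simulator: per-sample variant tables (VCF + annotation TSV), negative-binomial counts, truth record for parameter recovery |
| `metlink.variant_filtering` | Four-stage filter cascade (allele fraction ≥ 0.1 for SNVs, common-homozygote removal, depth ≥ 20 & ≥ 4 non-reference reads per strand, population AF ≤ 1%), substitution classification, spectrum summaries |
| `metlink.cohort_set_ops` | Exclusive metastatic variants (MT minus all PT regions), cross-patient recurrence, length-normalized gene mutation rates |
| `metlink.expression_quant` | Median-of-ratios size factors, per-pair fold-change rankings, Benjamini–Hochberg adjustment, PCA sample QC, Fisher term overrepresentation |
| `metlink.mutation_expression_link` | Two-sample KS test (exact small-sample p by lattice-path enumeration, asymptotic otherwise) of altered vs non-altered gene ranks; sample × class association matrix with −log10 p rendering ("Inf" above 10) |
| `metlink.pipeline` / `metlink.cli` | End-to-end orchestration with YAML config, deterministic outputs and a markdown report |

## CLI

Each stage is a subcommand; `run` drives the whole pipeline from one config:

```sh
# simulate a cohort to plain-text fixtures
cat > cohort.yaml <<EOF
n_patients: 2
pt_regions_per_patient: 2
n_genes: 200
seed: 7
EOF
metlink simulate --config cohort.yaml --out fixtures/

# full pipeline (simulation mode)
cat > run.yaml <<EOF
seed: 7
out_dir: out/
simulate:
  n_patients: 2
  pt_regions_per_patient: 2
  n_genes: 200
EOF
metlink run --config run.yaml
metlink report --run-dir out/
```

Or from existing fixtures: replace the `simulate:` block with
`inputs: {fixture_dir: fixtures/}`. Individual stages are also exposed
(`metlink filter|setops|expr|associate`); see `metlink <cmd> --help`.

Outputs include per-sample filtered variant TSVs with a per-stage count log,
EMV and recurrence tables, a spectrum summary, fold-change rankings, the
association matrix in wide (−log10 p, "Inf" sentinel, blank = not tested)
and long (D, p, n_altered, significance) forms, and a manifest; reruns with
the same config and seed are byte-identical.

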