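# mwastools

A methylome-wide association toolkit covering a complete exposure–methylation
analysis workflow on whole-blood DNA methylation data:

- **exposure** — prescription-derived drug-exposure phenotyping: dispensing
  records are cleaned, merged into active treatment periods (gap/grace
  merging with ceil(quantity/dose) coverage), and each person is classified
  EXPOSED / UNEXPOSED / EXCLUDED at blood draw with 7-day lead/tail rules;
  time-in-treatment comes along for free.
- **mwas** — the association engine: beta→M transform, per-probe
  standardization, omics-relatedness matrix (ORM) construction, REML/BLUP
  phenotype residualization against a kinship kernel, and a per-probe mixed
  linear model with the ORM as random effect (`fast` shares a null-model
  variance ratio; `exact` re-optimizes per probe). Effects are per 1 SD of
  M-value; significance at p < 9.42e-8.
- **dmr** — differentially methylated regions: candidate runs of nearby
  nominally significant same-sign probes (≤500 bp gaps), tested by a
  correlation-adjusted inverse-variance meta-analysis with Bonferroni
  correction over all candidates.
- **enrichment** — exact hypergeometric overlap tests, and circular-permutation
  enrichment between two genome-ordered result sets with concordant-direction
  filtering, 0.1/0.5/1 % top thresholds, and a max-over-thresholds empirical
  correction.
- **mps** — methylation profile score: 10-fold cross-validated LASSO on the
  relatedness-residualized phenotype, weighted-sum scoring of external
  cohorts, per-cohort logistic associations (GLM or GEE for clustered
  cohorts) with Nagelkerke pseudo-R², and DerSimonian–Laird random-effects
  pooling (Q, τ², I²).
- **stats** — Welch t, chi-squared independence tests (Yates on 2×2 only),
  and two-tailed Spearman correlation.
- **synthetic** — seeded generators for everything above: full-sib family
  GRMs, AR(1)-correlated probes along synthetic chromosomes, spiked exposure
  effects, confounded covariates, dispensing streams consistent with a known
  truth, and external cohorts driven by a latent score.
- **io / cli / pipeline** — plain-text readers/writers (TSV/CSV/BED/JSON),
  a click CLI, and a manifest-writing orchestrator.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: printed-value
chi-squared checks, oracle equivalences (brute-force REML, exhaustive
hypergeometric enumeration, soft-threshold closed form, hand-computed
DerSimonian–Laird case), calibration/recovery experiments, and a pipeline
determinism check.

## CLI

```sh
mwastools simulate --out run/sim --seed 7
mwastools exposure --prescriptions run/sim/prescriptions.csv \
    --phenotypes run/sim/phenotypes.tsv --out run/exposure.tsv
mwastools mwas --methylation run/sim/methylation.tsv \
    --phenotypes run/sim/phenotypes.tsv --grm run/sim/grm.tsv \
    --annotation run/sim/annotation.tsv --out run/mwas.tsv
mwastools dmr --results run/mwas.tsv --methylation run/sim/methylation.tsv \
    --annotation run/sim/annotation.tsv --out run/dmr.tsv
mwastools run-all --out run/full     # end-to-end simulated pipeline
```

Other subcommands: `describe`, `enrich`, `mps-train`, `mps-score`, `meta`.
Configuration is YAML (see `mwastools.pipeline.DEFAULT_CONFIG` for the
schema); all randomness flows from named seeds.

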