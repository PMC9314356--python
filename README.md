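# polyres

Polygenic **res**ilience scores for a late-onset, polygenic case-control
setting. The package implements the full workflow for finding common-variant
effects that keep high-genetic-risk individuals unaffected:

1. **Risk scoring** — polygenic risk scores (PRS) from external GWAS summary
   statistics at a P-value threshold (default 0.5), with optional excision of
   a major-effect region (chr19:44.4–46.5 Mb).
2. **Stratification** — two designs select "resilient" controls and
   risk-matched cases per study: design 1 takes controls at or above the 90th
   within-control PRS percentile; design 2 restricts to carriers of a
   major-effect allele and uses the 80th percentile of the region-excised PRS.
3. **Resilience GWAS** — per-study logistic regression (resilient vs
   risk-matched) with age/sex/PC covariates, genomic control, and
   DerSimonian–Laird random-effects meta-analysis.
4. **Risk-orthogonal filtering** — exclusion of risk-associated variants
   (risk P < 0.5) and their LD partners (r² ≥ 0.2 within 1 Mb), then greedy
   LD clumping of the surviving "marginal" variants.
5. **Scoring & evaluation** — nested weight sets at 10 escalating P-value
   thresholds, scored in held-out replication studies, evaluated per study
   (lnOR per score SD), pooled by random-effects meta-analysis with
   Nagelkerke and liability-scale R², plus a controls-vs-cases contrast of
   the PRS/resilience-score correlation.

Because the real cohort genotypes behind such analyses are access-restricted,
the package ships a first-class simulator (`polyres.simulate`) that generates
multi-study case-control cohorts under a liability-threshold model with
additive risk SNPs, one major-effect locus, LD blocks, and resilience SNPs
whose protective effect operates only above a genetic-risk quantile —
together with a matching external "prior risk GWAS" summary-statistics file.

## CLI

Every stage is exposed via the `polyres` entry point (all artifacts are plain
text: VCF, TSV, YAML, JSON):

```sh
polyres simulate --config cfg.yaml --out data/ --seed 7
polyres prs --genotypes data/study1.vcf --samples data/study1.samples.tsv \
    --stats data/prior_risk_gwas.tsv --p-threshold 0.5 \
    [--exclude-region chr19:44400000-46500000] --out prs.tsv
polyres stratify --genotypes ... --samples ... --prs prs.tsv --design 1 --out labels.tsv
polyres gwas --genotypes ... --samples ... --labels labels.tsv \
    --covariates age,sex,PC1,PC2 --out stats.tsv
polyres meta --inputs s1.tsv --inputs s2.tsv --gc --out meta.tsv
polyres evaluate --scores scores.tsv --samples data/study1.samples.tsv \
    --labels labels.tsv --out eval.tsv
polyres meta-eval --inputs eval1.tsv --inputs eval2.tsv --out pooled.tsv
polyres clump --stats marginal.tsv --panel data/reference.vcf \
    --panel-samples data/reference.samples.tsv --out clumped.tsv
polyres prune --resilience meta.tsv --risk data/prior_risk_gwas.tsv \
    --panel data/reference.vcf --panel-samples data/reference.samples.tsv \
    --risk-p 0.5 --r2 0.2 --window-kb 1000 --out marginal.tsv
polyres score --weights w.tsv --genotypes ... --samples ... --out scores.tsv
polyres run --config cfg.yaml --out report/ --seed 7      # whole pipeline
```

A pipeline YAML config combines the simulator block (`sim:`) with analysis
knobs (`n_discovery_studies`, `designs`, `thresholds`, ...); see
`polyres.resilience.PipelineConfig` for the full set and defaults.

## Library

```python
import polyres

cfg = polyres.PipelineConfig(
    sim=polyres.SimulationConfig(n_studies=6, n_cases_per_study=750,
                                 n_controls_per_study=1500, n_variants=2500,
                                 n_risk_snps=100, n_resilience_snps=20,
                                 resilience_gamma=0.15, ld_block_size=5,
                                 ld_block_rho=0.3, seed=1),
    n_discovery_studies=3, designs=(1, 2))
report = polyres.run_pipeline(cfg)
report.designs[1].summary()          # per-threshold OR / CI / P / pooled R2
report.designs[1].discovery_accounting
report.correlation                   # PRS vs resilience-score contrast
```

Every run hard-asserts the **risk-orthogonality certificate**: no scored
variant has risk P < 0.5 nor r² ≥ 0.2 within 1 Mb of any such variant.

## Layout

| module | contents |
| --- | --- |
| `polyres.simulate` | cohort/panel simulator, prior risk GWAS generator |
| `polyres.io` | VCF/TSV readers & writers, validation, allele harmonization |
| `polyres.prs` | weight building, scoring, within-study percentile ranking |
| `polyres.stratify` | designs 1/2, age filter, retention accounting |
| `polyres.assoc` | per-variant logistic GWAS, score evaluation, Nagelkerke & liability R² |
| `polyres.meta` | genomic control, fixed/random-effects meta-analysis, R² pooling |
| `polyres.ld` | LD panel, risk-variant exclusion, greedy clumping, certificate |
| `polyres.resilience` | threshold series, replication evaluation, correlation contrast, pipeline driver |
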