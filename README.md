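# prsvalidate

Validation toolkit for breast-cancer **polygenic risk scores (PRS)** in
admixed case-control cohorts, built around the exome-imputation validation
design: weighted-allele scoring from VCF genotypes/dosages, cohort QC
(first-degree relatedness pruning, monogenic-carrier exclusion, ancestry
grouping), PC-adjusted effect-size estimation, decile/percentile risk
stratification, imputed-vs-sequenced score concordance, and a synthetic
admixed-cohort generator that makes every stage verifiable without access
to patient data.

## Who it is for

Groups validating a published PRS (e.g. a PGS-Catalog scoring file) in
their own case-control cohort — particularly admixed cohorts where
European-derived scores need re-evaluation — and anyone who wants a
simulated cohort with known ground truth to exercise a PRS pipeline end to
end.

## The model

For sample *s* with effect-allele dosages *d&#8339;&#7522;* and per-variant
log-odds weights *β&#7522;*, the score is

```
raw_s        = Σᵢ βᵢ·dsᵢ
normalized_s = (raw_s − 2·Σ_{β<0} β) / (2·Σ_{β>0} β − 2·Σ_{β<0} β)   ∈ [0, 1]
z_s          = (normalized_s − μ_controls) / σ_controls
```

Disease association is estimated by logistic regression of case status on
*z* with z-scored genotype PCs 1–10 as covariates; `exp(coef)` is the **OR
per SD**. Decile (or percentile-scheme) ORs compare each score bin against
the 40–60% median interval on left-open right-closed boundaries.
Classification is summarized by the AUC on a stratified 25% holdout and by
stratified 10-fold cross-validation. Carrier effects of monogenic genes
(BRCA1, BRCA2, TP53, PALB2, PTEN, ATM, CHEK2, TP53 R337H) are reported as
closed-form 2×2 ORs with Wald CIs.

The synthetic cohort follows a liability model: admixture proportions
`q ~ Dirichlet`, genotypes `Binomial(2, q·p_ancestry)`, and
`P(case) = expit(α + γ·z + Σ_g carrier_g·ln OR_g)` with γ the true log-OR
per SD and α solved for the target prevalence. See `docs/methods.md`.

## Worked example

```python
from prsvalidate.pipeline import run_pipeline

config = {
    "seed": 7,
    "out_dir": "scratch/demo",
    "simulate": {"n_cases": 1500, "n_controls": 2300, "n_variants": 500,
                 "n_families": 40},
}
manifest, results = run_pipeline(config, write_outputs=False)

ledger = results["ledger"]
print(f"cohort: {ledger.initial_n} -> {ledger.final_n} "
      f"({ledger.final_cases} cases / {ledger.final_controls} controls)")
overall = results["assoc"][0]
print(f"OR per SD: {overall.or_:.2f} "
      f"(95% CI {overall.ci_low:.2f}-{overall.ci_high:.2f}, p={overall.p_value:.2e})")
top = results["staircase"][-1]
print(f"top-decile OR vs 40-60%: {top.or_:.2f} "
      f"(95% CI {top.ci_low:.2f}-{top.ci_high:.2f})")
print(f"AUC: holdout {results['auc_holdout']:.3f}, "
      f"10-fold CV {results['auc_cv']['mean']:.3f}")
rep = results["concordance"]
print(f"imputed-vs-clean: Spearman rho {rep.spearman_rho:.3f}, "
      f"extreme-decile overlap {rep.extreme_overlap_pct:.0f}%")
```

Output:

```
cohort: 3900 -> 3578 (1296 cases / 2282 controls)
OR per SD: 1.47 (95% CI 1.36-1.58, p=7.62e-25)
top-decile OR vs 40-60%: 2.00 (95% CI 1.55-2.57)
AUC: holdout 0.615, 10-fold CV 0.605
imputed-vs-clean: Spearman rho 0.740, extreme-decile overlap 54%
```

Reading the numbers: 322 of 3900 simulated subjects are excluded by QC
(one member of every first-degree pair, whole family clusters with two or
more first-degree links, and all high-penetrance-gene carriers). Each SD
of polygenic score multiplies the disease odds by ~1.47 (the generating
value was ln 1.43 on the log scale); the top score decile roughly doubles
the odds relative to the median interval; and after imputation-style noise
calibrated to Spearman ρ 0.74, about half of the samples in the extreme
deciles stay in the same extreme decile.

The same analyses are available from the shell:

```bash
prsvalidate simulate --seed 7 --out-dir data/       # VCF + TSVs + truth
prsvalidate qc --metadata data/metadata.tsv --kinship data/kinship.tsv \
    --ancestry data/ancestry.tsv --seed 7 --out qc
prsvalidate score --scoring-file data/scoring.tsv --vcf data/cohort.vcf \
    --metadata data/metadata.tsv --out scores.tsv
prsvalidate run --config analysis.yaml               # full pipeline
```

## File formats

* **Scoring file**: TSV with `rsID, chr_name, chr_position, effect_allele,
  other_allele, effect_weight` (PGS-Catalog layout; column mapping
  configurable).
* **Genotypes**: VCF 4.2 with `GT` and optionally `DS`; multi-allelic
  records are split per alternate allele.
* **Metadata**: TSV `sample_id, status (case|control), sex, age` plus one
  0/1 column per carrier gene.
* **Kinship**: TSV `sample_a, sample_b, degree` (or a `coefficient`
  column; first degree = KING-style band [0.177, 0.354]).
* **Ancestry**: TSV `sample_id, EUR, AFR, EAS, AMR` (proportions summing
  to ~1).
* **Targets**: 0-based half-open BED of exome target regions for the
  distance filter.

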