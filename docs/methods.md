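# Methods

This note documents the statistical model behind `prsvalidate`, the
choices made where the underlying analysis design was open, and what the
synthetic cohort does and does not establish about real data.

## Scoring

A polygenic risk score is the weighted sum `raw_s = Σᵢ βᵢ·dsᵢ` over
scoring variants, where `dsᵢ ∈ [0, 2]` is the dosage of the *effect*
allele and `βᵢ` its log-odds weight. Orientation against the VCF is
resolved per variant from (chrom, pos, unordered allele pair): when the
effect allele is the record's REF, the effect dosage is `2 − alt_dosage`.
A/T and C/G pairs cannot be oriented across strands and are excluded by
default (`allow_ambiguous` overrides); this is the conservative
portability convention for scores applied outside their training
platform.

**Normalization.** The raw sum is min–max normalized over its diploid
bounds — the minimum `2·Σ_{β<0}β` (no effect alleles at positive-weight
variants, two at negative-weight ones) and the maximum `2·Σ_{β>0}β` —
which is the unique affine map forcing the score into [0, 1] for every
possible genotype. The boundary configurations attain 0 and 1 exactly,
and flipping any variant's allele labels while negating its weight leaves
the normalized score unchanged.

**Standardization.** Scores are z-scored against the control
distribution (mean 0, SD 1 in controls by construction), so "OR per SD"
means per control-SD of normalized score.

**Missing dosages** are mean-imputed with twice the effect-allele
frequency estimated from the non-missing cohort dosages. Per-sample
renormalization over observed variants was rejected because it makes
scores incomparable across samples with different missingness patterns.
All dosages are clamped to [0, 2] after arithmetic to guard against
malformed DS fields.

**Variant filtering** precedes matching: zero-weight variants, variants
on an explicit exclusion list (e.g. a pathogenic variant that would
conflate monogenic and polygenic risk), variants farther than
`max_distance_bp` (default 200 bp) from any exome-target interval, and
variants below the cohort MAF floor (default 0.001) are dropped with a
per-reason ledger. The two thresholds are configuration values: they are
methodologically necessary for imputed-exome scoring, but no canonical
values exist, so the defaults are ordinary practice rather than derived
quantities.

## Cohort QC

**Relatedness.** First-degree relationships (stated degree 1, or kinship
coefficient in the KING-style band [0.177, 0.354]) form a graph. An
isolated pair loses one member, chosen by a seeded RNG; any connected
component in which some member has two or more first-degree links is
removed entirely. The component reading is the strictest interpretation
of "two or more first-degree relationships excludes all related
individuals" and is isolated in one function so an alternative policy is
a one-line change. Pruning is idempotent.

**Carrier exclusion.** Samples flagged as pathogenic/likely-pathogenic
carriers in the high-penetrance gene set {BRCA1, BRCA2, TP53, PALB2,
PTEN} (monogenic OR > 5) are removed before any score statistics;
moderate-risk genes (ATM, CHEK2) stay in and are analyzed as 2×2
exposures.

**Ancestry groups.** With admixture proportions `q` over EUR/AFR/EAS/AMR:
EAS-majority if `q_EAS > 0.5`; else Non-EUR-majority if `q_EUR ≤ 0.5`
(right-closed interval); else EUR-majority. The EAS rule takes precedence
and can never conflict with EUR-majority since `q_EAS > 0.5` implies
`q_EUR < 0.5`.

All removals flow into an `ExclusionLedger` that enforces disjoint
removal sets and exact arithmetic (`final = initial − Σ removals`).

## Covariate PCs

PCA is computed **within the analysis cohort** rather than by projection
onto external reference panels: common variants (cohort MAF > 1%,
duplicates and monomorphics dropped) are centered at `2p̂` and scaled by
`√(2p̂(1−p̂))`, and the top-K left singular vectors (randomized truncated
SVD, seeded) scaled by their singular values give the sample PCs.
Downstream usage — z-scored PCs 1–10 as logistic covariates — is
unchanged by this substitution; whether projection onto an external panel
would materially change adjusted ORs cannot be evaluated without such a
panel and is listed under limitations. Each PC's sign is fixed by making
its largest-magnitude loading positive, so results are deterministic.

## Association statistics

* **OR per SD**: maximum-likelihood logistic fit of status on the
  standardized score plus PCs (Newton, 100 iterations); Wald 95% CI and
  two-tailed Wald p. Perfect separation and non-convergence raise a
  diagnostic error rather than returning numbers. Both Nagelkerke
  (headline) and McFadden pseudo-R² are reported since conventions
  differ.
* **Bins**: decile boundaries at the 10–90% quantiles, or the percentile
  scheme {0,1,5,10,20,40,60,80,90,95,99,100}; intervals are left-open
  right-closed (a score equal to a cutpoint falls in the lower bin).
  Boundaries come from **controls** by default, consistent with
  control-standardization (an `all-samples` option exists; which source
  underlies the published convention varies by study).
* **Bin ORs**: logistic fit of status on bin membership (target = 1,
  40–60% reference interval = 0) with PC covariates; without covariates
  this is algebraically the 2×2 contingency OR, an identity verified in
  the tests. Reference-vs-reference returns OR 1 exactly.
* **2×2 carrier ORs**: `(a·d)/(b·c)` with Wald CI
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; a zero cell triggers the
  Haldane–Anscombe +0.5 correction with an explicit flag — small strata
  are expected in 1% tails, and failing there would be worse than a
  flagged conservative estimate.
* **AUC**: rank statistic of the score on a stratified, seeded 25%
  holdout, and mean per-fold AUC under stratified 10-fold CV. The score
  itself is the classifier (no refitting), so CV only varies the
  evaluation subset.
* **Multiplicity**: Bonferroni `min(1, m·p)`, with `m` defaulting to the
  number of simultaneous contrasts in the run.

## Synthetic cohort

The generator produces the statistical structure the pipeline is designed
for, with every latent quantity retained as ground truth:

* **Admixture**: `q ~ Dirichlet(5.0, 0.55, 0.1, 0.55)` over
  (EUR, AFR, EAS, AMR) — median `q_EUR ≈ 0.84`, ~4–5% of samples at or
  below 50% EUR — mixed with a 1.5% EAS-concentrated component
  (`Dirichlet(0.3, 0.1, 8.0, 0.2)`) so an East-Asian-majority subgroup of
  realistic size (~1.5% of the cohort) exists for stratified analysis.
* **Allele frequencies**: a shared ancestral frequency per variant
  (uniform on [0.05, 0.95]) diversified per ancestry by a Balding–Nichols
  Beta draw with Fst (0.10, 0.15, 0.15, 0.12), clipped to [0.01, 0.99] —
  continental-scale differentiation, enough for PCs to recover the
  admixture axes.
* **Genotypes**: `Binomial(2, q·p_ancestry)` — Hardy–Weinberg within each
  individual's mixture, variants independent given ancestry. **No LD is
  simulated**: every statistic in scope consumes dosages, and LD matters
  only to the upstream imputation step, which is out of scope.
* **Disease**: `P(case) = expit(α + γ·z + Σ_g carrier_g·ln OR_g)` with
  `z` the *population*-standardized true score (its mean and SD computed
  in closed form from the Dirichlet-mixture moments, so `γ` is exactly
  the log-OR per population SD). `α` is solved by bisection on a seeded
  8000-sample pilot so the population prevalence hits its target (default
  0.10). Cases and controls are then accumulated chunk-wise until the
  requested sizes (defaults 5598 / 8767) are reached — outcome-dependent
  sampling, under which the logistic slope remains consistent. `γ`
  defaults to ln 1.43; per-variant weights are N(0, 0.05), whose scale
  cancels under standardization.
* **Carriers**: independent Bernoulli flags per gene with plausible
  clinical carrier frequencies (0.08–1.2%) and ORs 2.1–14, acting
  additively on the logit, independent of the polygenic term.
* **Families**: each family is two admixture-drawn parents with
  Mendelian-sampled offspring; even-numbered families contribute a
  parent-child pair (isolated first-degree edge), odd-numbered a full
  trio (child with two first-degree links, so pruning must remove the
  cluster). Sibling genotype correlation is 0.5 by construction.
* **Imputation noise**: each genotype is independently replaced, with
  probability ε, by a fresh Binomial(2, p_individual) draw. Given a target
  Spearman ρ between clean and noisy scores (default 0.74), ε is found by
  bisection using common random draws across iterations, which makes
  ρ(ε) exactly monotone and the search stable.

**What passing tests show — and do not show.** The simulation validates
the *computational* chain: scoring arithmetic, exclusion logic, estimator
consistency (CI coverage 93–97% at the generating effect size, binormal
AUC agreement, decile-staircase monotonicity), and calibration machinery.
It does not establish portability of any real score to any real
population: real cohorts have LD, genotyping batch structure,
ascertainment correlated with ancestry and family history, non-Dirichlet
admixture (e.g. bimodal sub-communities), and imputation error that is
structured by allele frequency and coverage rather than i.i.d.

## Numerical choices

* Degenerate inputs raise typed errors: zero control SD, no scorable
  variants, all-one-sign separation, constant PC columns, fewer
  informative variants than requested components.
* Control-standardization uses the population SD convention (ddof 0);
  exactness of "controls have mean 0, SD 1" is asserted at 1e-8.
* Quantile boundaries use linear interpolation (NumPy default); massive
  ties can make bins unequal but the partition is always exhaustive.
* Problem sizes in the test suite are scaled for a single CPU: simulation
  replicates use 150–400 variants (the score distribution is already
  Gaussian at that width) and cohorts of 3.5k–7.5k, while the acceptance
  script runs the full-size cohort (≈14.6k samples × 2575 variants).
* Seeds are explicit everywhere randomness exists (simulation, pair
  pruning, SVD, splits, noise); the pipeline records them in its run
  manifest, and rerunning a config reproduces outputs bit-identically.

## Known limitations

* Within-cohort PCs stand in for external-panel projection (above).
* The exclusion thresholds for the distance/MAF scoring filters and the
  first-degree kinship band are conventions, not estimates; sensitivity
  to them is left to the user's configuration.
* The concordance "extreme overlap" statistic is defined as same-decile
  membership under each score set's own boundaries, jointly over the top
  and bottom deciles; separate top/bottom percentages are also emitted
  because the joint definition is not the only defensible one.
* The generator's carrier frequencies and family mix are field-realistic
  defaults, not estimates of any particular cohort.
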