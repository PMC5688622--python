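# Methods

## Score construction

The PRS is a plain weighted sum of effect-allele dosages,
`PRS_i = Σ_j d_ij · w_j` with `w_j = log2(OR_j)`. We use the sum rather
than a per-allele average because it keeps leave-one-variant-out scores
exactly additive: removing variant *j* subtracts exactly `d_ij · w_j`,
which the sensitivity analyses (score without the SNCA or GBA locus)
rely on. The choice changes only the scale of "per PRS unit" effect
estimates, not their significance.

The packaged 26-locus table carries, for each locus, the reference and
study allele frequencies, the per-allele odds ratio, the overall call
rate, and a printed weight. For three loci (rs356182/SNCA,
rs117896735/INPP5F, rs17649553/MAPT) the printed weight is **not**
log2 of the printed OR; the source of those printed values is unknown.
The loader therefore derives weights from the ORs by default and offers
a table-weight override (`use_table_weights=True`); the convenience
constructor `load_reference_panel()` uses the override so that scoring
reproduces the published panel verbatim. Both behaviours are tested.
Published with that table is a theoretical score range of +2.5 to −2.1;
a dosage-weighted sum over the 16 printed weights gives +5.02 to −2.45,
so the published range appears to use an unstated scaling convention
and we do not attempt to reproduce it.

Panel selection is strict: call rate > 0.85 (a tie at exactly 0.85 is
excluded). Loci without genotype data, or without an OR, are retained
in the loaded table but can never be selected.

Missing dosages at scoring time are mean-imputed as `2 × study MAF`
(matching common scoring-tool behaviour), with an `omit` policy
available that instead contributes 0 and decrements the per-sample
variant count.

Tertiles are assigned by ranking on (score, sample ID) — the ID breaks
ties so analyses are bit-reproducible — and cutting at ⌈n/3⌉
boundaries; group sizes differ by at most 2.

## Genotype QC

Filters run in a fixed order: hard-call masking, then variant-level
removal, then ancestry restriction. Applying the chain twice equals
applying it once, and no surviving dosage is ever altered.

* **Hard-call filter.** With genotype probabilities present, a genotype
  whose maximum probability is below 0.9 becomes missing. With plain
  dosages, the equivalent intent is applied: a dosage farther than 0.1
  from the nearest integer is an uncertain call and is masked. Variants
  with imputation INFO < 0.3 are masked entirely.
* **Hardy-Weinberg exact test.** Two-sided conditional exact test
  (probabilities of all heterozygote counts no more likely than the
  observed one, conditional on the allele counts), computed with
  log-gamma arithmetic so it is stable for large cohorts. Variants with
  p < 1e-6 are removed. HWE is computed on all samples jointly (cases
  and controls); no installed library provides this test, so it is
  implemented here and verified in the tests against an exact-rational
  enumeration oracle and against 1-df chi-square asymptotics.
* **Call-rate rules.** Per-platform call rate ≥ 0.95 and joint
  (merged-platform) call rate ≥ 0.85, both measured after hard-calling.
  The 95% rule is applied per platform; the scope of that rule relative
  to merging is a genuinely open choice and per-platform is the
  stricter reading. Platforms are merged by sample-namespace union and
  variant intersection.
* **Ancestry restriction.** PCs of the mean-imputed,
  frequency-standardized dosage matrix (SVD; standardization by
  √(2p(1−p))). Samples are partitioned by a deterministic two-means on
  PC1–PC2 initialized at the two most distant samples, and the cluster
  containing the declared reference samples (or the larger one) is
  retained. If the two centers are closer than twice the pooled
  within-cluster RMS radius the split is judged spurious — a single
  homogeneous population is kept whole. This is a reproducible stand-in
  for the visual cluster selection done in practice; it is not a
  substitute for a reference-anchored ancestry analysis.

## Association models

"General linear model" for a binary outcome is implemented as logistic
regression: the published per-PRS-unit status effects (~5) are on a
log-odds-compatible scale that a linear-probability model cannot
produce. Sex is coded female = 1; the PRS enters untransformed;
CIs are Wald at 95%; no multiple-testing correction is applied
(single-variant results are explicitly nominal). Outcome separation is
reported as a flagged non-converged result rather than a crash; a
constant predictor is an error.

Survival uses Cox proportional hazards with Efron tie handling
(lifelines), onset as the event for cases, controls censored at last
assessment; a cases-only refit probes sensitivity to control
censoring. The tertile analysis reports Kaplan-Meier curves per
tertile, a T1-vs-T3 log-rank test, and — because "the effect between
the first and third tertiles" has no standard estimator on the odds
scale — the exponentiated Cox coefficient of the T3-vs-T1 indicator,
explicitly labelled hazard-ratio scale.

The ROC increment reports apparent (in-sample) AUCs of the
covariate-only and covariate+PRS logistic models, computed by the rank
(Mann-Whitney) formulation; no cross-validation is attempted because
the quantity of interest is the increment, not an out-of-sample
estimate.

Family-history-stratified reruns keep all controls in both strata for
status models (cases are split, controls are shared).

## Biomarker harmonization

Raw CSF levels from different immunoassay kits are on incompatible
scales. Harmonized values are `log10(raw) − mean(log10(raw))` within
each platform × analyte stratum. Centering only — no division by the
stratum SD — because the combined standardized summaries in this kind
of study retain raw log10-scale dispersion (SDs ≈ 0.12–0.21), which
unit-variance scaling would destroy. Disease status is deliberately not
part of the stratum; centering within status groups would erase the
case-control contrast. The transform is exactly invariant to per-kit
multiplicative rescaling, and per-stratum harmonized means are zero to
1e-9 (tested). Singleton strata are an error.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs:

| parameter | default | rationale |
|---|---|---|
| cases/controls per platform | 336/139 and 493/293 | the emulated study's composition (1261 total) |
| panel | packaged 16-variant panel, printed weights | one source of truth shared with the scorer |
| effect_scale | 1.0 | per-allele disease ORs equal the panel's |
| onset shift | −4 y per PRS unit | onset decades earlier at the extremes is implausible; −4 y/unit over the realized ~2-unit score range matches reported onset spans |
| onset mean ± SD | 61 ± 9 y | typical idiopathic PD onset |
| control age mean ± SD | 64 ± 9 y | slightly older censoring ages |
| female fraction | 33.53% cases, 45.60% controls | emulated study composition |
| family history | 25% cases, 3% controls | emulated study composition |
| biomarker log10 means | per-platform control means (e.g. Aβ1–42 378.4 vs 926.4 pg/mL) | reproduces the ~2.4-fold raw platform gap |
| biomarker log10 SD | 0.15 | mid-range of observed standardized SDs |
| PRS→biomarker slope | 0 per analyte | null by default; configurable |
| missingness | per-variant panel call rates | QC exercises realistic gaps |

Genotypes are binomial(2, study MAF) under HWE, with degenerate
probability triples (mass 1 on the drawn genotype) so hard-calling is
exercised without noise. Disease status is Bernoulli with
`P(case) = expit(α + effect_scale · PRS)`; α is solved by root-finding
per platform so the expected case fraction matches the configured
counts — realized counts are therefore binomially random around the
targets, which downstream models must (and do) tolerate. Case onset is
`61 − 4·(PRS − mean PRS) + N(0, 9)` clipped to [25, 95]; the case age
at last assessment is onset plus a positive follow-up offset
(|N(3.7, 2)| years) so assessment never precedes onset — the follow-up
distribution is the package's own choice, as only mean ages are
published. Ancestry PCs are drawn N(0, 1) independent of everything,
so they act as pure noise covariates.

What the generator does **not** emulate: linkage disequilibrium between
panel loci (treated as independent GWAS hits), genome-wide background
variation, platform batch effects beyond a scale shift, differential
onset vs risk weights per locus (an override hook exists but defaults
to shared weights), and any real genotype-phenotype correlation
structure. Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed generative model, not
replication of real-cohort effect sizes — the published real-data
betas came from access-controlled cohorts and are out of reach by
construction.

Everything is deterministic: each stage draws from
`default_rng([seed, stage])`, so a config and seed give byte-identical
outputs.

## Numerical choices and problem sizes

* HWE tail membership uses a 1+1e-12 relative tolerance when comparing
  point probabilities, avoiding float-noise misclassification of the
  observed configuration.
* Logistic fits flag quasi-separation when the Wald SE exceeds 1e4.
* Cox fits drop covariates that are constant in the analysis subset
  (they carry no information and destabilize the optimizer).
* The two-means ancestry split is seeded deterministically (most
  distant pair), so no RNG is involved in QC.
* Recovery and type-I-error suites run 100 replicates at the default
  cohort size (n = 1261); the acceptance script uses 20 replicates for
  its direction-recovery summary. These sizes give Monte-Carlo error
  small enough to resolve direction recovery ≥ 95% and a 5% nominal
  type-I rate, while keeping the default suite fast.

## Known limitations

* Allele matching against genotype files is by variant ID and effect
  allele only — no strand flipping or liftover; a mismatch is an error,
  never a silent flip.
* The exact HWE test assumes autosomal diploid genotypes; X-chromosome
  male hemizygosity is not modelled (the panel's only X-adjacent
  concern does not arise in the packaged table).
* LD-proxy search for unusable loci and genotype imputation itself are
  out of scope; the pipeline starts from imputed dosages.
* Apparent AUCs are optimistic relative to cross-validated ones; the
  reported increment is an in-sample quantity.
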