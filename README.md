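# pdprs

A tested, reusable pipeline for Parkinson-disease (PD) polygenic risk
score (PRS) analysis: panel construction from a printed GWAS risk-locus
table, post-imputation genotype QC, per-individual scoring, and a full
association suite covering disease status, age at onset and CSF
biomarker levels across two assay platforms.

## The problem

PD GWAS meta-analyses report ~26 risk loci whose individual effects are
small. A weighted PRS aggregates them into one per-individual value

```
PRS_i = Σ_j  d_ij · w_j ,        w_j = log2(OR_j)
```

where `d_ij ∈ [0, 2]` is individual *i*'s imputed effect-allele dosage
at locus *j* and `OR_j` the per-allele odds ratio from the meta-analysis.
Protective alleles (OR < 1) get negative weights; OR = 1 contributes
nothing. Only loci with an overall call rate strictly above 85% enter
the scoring panel — with the packaged 26-locus table that leaves a
16-variant panel. The score is then tested against:

* **disease status** — logistic regression,
  `status ~ PRS + age at last assessment + sex + PC1 + PC2`;
* **age at onset** — Cox proportional hazards (Efron ties) with onset
  as the event for cases and controls censored at last assessment,
  `onset ~ PRS + sex + PC1 + PC2`, plus Kaplan-Meier curves by PRS
  tertile with a T1-vs-T3 log-rank test;
* **CSF biomarkers** (α-synuclein, Aβ1–42, t-tau, p-tau) — linear models
  on log10-transformed, platform-mean-centered levels,
  `level ~ PRS + age at LP + sex + PC1 + PC2`.

Real PD genotype cohorts are access-controlled, so the package ships a
synthetic two-cohort generator (`pdprs.simulate`) that reproduces the
statistical structure of such a study — HWE genotypes at the study
allele frequencies, per-variant missingness matching the panel call
rates, logistic disease liability on the PRS, PRS-shifted onset ages
with censored controls, and two biomarker platforms on different raw
scales — so every stage is testable end to end without any download.

## Worked example

```python
from pdprs import (SimulationConfig, simulate_dataset, assign_tertiles,
                   status_association, aao_survival, km_tertile_analysis,
                   harmonize, biomarker_association, roc_increment,
                   load_reference_panel)

panel = load_reference_panel()
print(f"panel: {len(panel)} variants, sum of weights = {sum(panel.weights):.3f}")

cfg = SimulationConfig(seed=42)
matrix, cohort, scores, biomarkers = simulate_dataset(cfg)

res = status_association(scores, cohort)
surv = aao_survival(scores, cohort)
km = km_tertile_analysis(assign_tertiles(scores), cohort)
auc0, auc1 = roc_increment(scores, cohort)
ttau = biomarker_association(scores, harmonize(biomarkers), cohort, "t_tau")
```

prints

```
panel: 16 variants, sum of weights = 1.287
cohort: 1261 samples (839 cases, 422 controls)
PD status  ~ PRS: beta = 1.10 (95% CI 0.80-1.39), p = 3.74e-13
onset (Cox) ~ PRS: hazard beta = 0.59, p = 5.17e-17
tertile T3 vs T1: HR = 1.83, log-rank p = 2.17e-12
AUC: 0.574 (covariates) -> 0.652 (+PRS)
CSF t-tau ~ PRS: beta = -0.003, p = 0.72
```

Read: each PRS unit multiplies the disease odds by e^1.10 ≈ 3.0 in this
synthetic cohort (the generator's true value is e^1.0), higher PRS means
earlier onset (positive hazard coefficient), the top PRS third has ~1.8×
the onset hazard of the bottom third, adding the PRS to the
covariate-only classifier raises the AUC by ~8 points, and t-tau shows
no PRS effect — as generated (the biomarker effect defaults to zero).

The same pipeline is available from the shell:

```sh
pdprs simulate --seed 2 --out sim/
pdprs score --dosages sim/dosages.tsv --out scores.tsv
pdprs associate --scores scores.tsv --cohort sim/cohort.tsv \
    --biomarkers sim/biomarkers.tsv --out associations.tsv
```

`pdprs score` also accepts real data: a samples × variants dosage TSV
(or a VCF with `DS`/`GP` FORMAT fields via `pdprs.io.read_vcf_dosages`)
plus any risk-locus table in the packaged TSV dialect.

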