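# malebc

A candidate-SNP case-control association toolkit for male breast cancer
studies. Male breast cancer is rare (~1% of breast cancer), so cohorts are
small and individual-level data are typically not deposited; this package
re-implements the complete statistical machinery of such a study — genotyping
QC, per-SNP association, male-vs-female effect comparison, and power
analysis — and exercises it end-to-end on synthetic cohorts with the same
design: 457 cases and 1608 controls attempted, 54 plate duplicates, 49
samples failing a ≥2-no-call rule, and 18 non-European exclusions, leaving
433 cases and 1569 controls for analysis of a 12-SNP panel.

## What it computes

**Association.** For each locus with risk-allele dosage g ∈ {0, 1, 2},
unconditional logistic regression fitted by an in-package IRLS maximiser:

- multiplicative (trend) model, logit P(case) = α + βg: per-allele
  OR = e^β, 1-df likelihood-ratio test;
- unconstrained genotype model: OR_het and OR_hom against the zero-copy
  baseline, 2-df LRT;
- Wald 95% CIs, exp(β̂ ± 1.959964·SE); complete-case per SNP;
- a case-only model for a genotype trend with age at diagnosis (risk-allele
  count as binomial with two trials per subject), plus age-stratified trend
  ORs.

**QC.** A sample-exclusion cascade (≥2 no-calls → duplicate collapse →
ancestry), duplicate concordance, and the exact conditional Hardy-Weinberg
test in controls (heterozygote-count enumeration in log space).

**Effect comparison.** With both OR sets log-normal, the per-SNP statistic is

    χ² = (ln OR_male − ln OR_female)² / (se_m² + se_f²),   1 df,

with SEs reconstructed from published CIs as (ln hi − ln lo)/(2z). Summing
over the panel gives a global k-df test. The published female reference
panel for the 12 loci ships with the package.

**Power.** Analytic power of the trend test via the allele-count normal
approximation, cross-validated by cohort simulation.

## Worked example

```python
from malebc import (CohortSpec, default_snp_panel, simulate_cohort,
                    apply_exclusions, analyze_panel, compare_panel,
                    female_reference_panel, PowerSpec, power_analytic)

manifest, genotypes = simulate_cohort(default_snp_panel(), CohortSpec(seed=11))
manifest, genotypes, qc = apply_exclusions(manifest, genotypes)
print(qc.n_cases_final, qc.n_controls_final)   # 433 1569

table1 = analyze_panel(manifest, genotypes)
table2, glob, _ = compare_panel(table1, female_reference_panel())
print(round(glob.chi_sq_total, 2), glob.df)    # 41.69 12

print(round(power_analytic(PowerSpec(433, 1569, 0.30, 1.15, 0.05)), 3))  # 0.399
```

The first line reproduces the exclusion arithmetic exactly (457 − 11 − 13
cases, 1608 − 34 − 5 controls). The global χ² of 41.69 on 12 df is large
because this simulated cohort was *generated* with the male ORs, which
genuinely differ from the female reference values at several loci. The last
number is the analytic power to detect a per-allele OR of 1.15 at MAF 0.30
with this design — about 40%, which is why small candidate studies miss
modest effects.

The same stages are available from a shell:

```
malebc simulate --out-dir sim --seed 11
malebc qc --manifest sim/manifest.tsv --genotypes sim/genotypes.tsv --out qc.json
malebc assoc --manifest sim/manifest.tsv --genotypes sim/genotypes.tsv --out table1.tsv
malebc compare --male table1.tsv --female refs.tsv --out table2.tsv
malebc power --n-cases 433 --n-controls 1569 --maf 0.30 --or 1.15 --alpha 0.05
malebc run --config pipeline.yaml
```

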