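# Methods

## Scope and data model

The package analyses a panel of candidate SNPs in an unmatched case-control
design. Genotypes are risk-allele dosages g ∈ {0, 1, 2} with missing calls
kept distinct from zero (nullable integers in memory, `NA` in TSV). A
sample manifest carries case/control status, age at diagnosis, ER status,
histology, duplicate-pair labels, and ancestry flags. Because
individual-level data for studies of this design are generally not
deposited, a first-class synthetic-cohort generator provides inputs with
the statistical structure the analysis assumes.

## Cohort generator

Controls at a locus with risk-allele frequency p are drawn from
Hardy-Weinberg proportions ((1−p)², 2p(1−p), p²). Cases are drawn from
those weights multiplied by ψ^g for a per-allele odds ratio ψ (or by
(1, ψ_het, ψ_hom) when an unconstrained pair is supplied), renormalised.
This is the exact inverse of the logistic disease model fitted downstream,
so the generating ψ is the estimand of the trend model. Loci are simulated
independently — the default 12-locus panel sits on distinct chromosome
arms, but absence of LD is a stated limitation for any other use. Controls
carry no sex labels: the emulated design pooled male and female controls
and no model here uses sex.

Defaults reproduce the emulated study's dimensions: 457 cases, 1608
controls, 54 plate-duplicate samples (2119 attempted), designated
≥2-no-call failures of 11 cases / 34 controls / 4 duplicate members, and
13 + 5 non-European flags. Artifact counts are applied exactly rather than
sampled so the QC cascade is deterministic; to keep the designated failure
counts exact, sporadic no-calls (rate 0.0005 per call) are capped at one
per non-designated sample, and designated failures receive exactly two
missing loci. Duplicate copies flip each call to a different dosage with
probability 0.002, targeting the ~99.8% pairwise concordance typical of
well-run genotyping.

Case ages are a discretised normal, loc 66.6, sd 10.2, truncated to the
recruitment window 18–79. A symmetric truncated normal cannot reproduce
the slightly asymmetric target quartiles (59 / 65.5 / 72) exactly — the
upper truncation compresses the third quartile — and this parameterisation
lands at integer-age quartiles (59, 65, 71), which we accept as the closest
simple family. ER status is known for ~58% of cases (98% of those
positive); histology is 92.1% invasive / 7.2% DCIS / remainder unknown.

What the generator does *not* emulate: linkage disequilibrium, population
stratification, plate effects, genotype-calling error that correlates
across loci, and control-source heterogeneity. Tests passing on these
cohorts therefore validate the statistical machinery, not robustness to
those real-data features.

## QC cascade

Order of application: (1) exclude samples with no-calls at ≥2 panel loci
(threshold configurable; evaluated from the genotype table itself);
(2) compute duplicate concordance over loci where both members are called,
then collapse each surviving pair, retaining the member with the higher
call rate (first-listed on ties — the emulated study does not say which
member was kept); (3) exclude non-European samples. The report conserves
samples exactly: attempted = final + excluded + removed duplicate members.
A duplicate member whose partner was removed in step 1 survives as the
subject's analysis sample.

### Exact Hardy-Weinberg test

Conditioning on n diploid samples and n_rare copies of the rarer allele,
the heterozygote count h (same parity as n_rare) has conditional
probability ∝ 2^h / (n_hom_rare! · h! · n_hom_common!). The two-sided
p-value sums probabilities of all configurations no more probable than the
one observed. Weights are computed in log space via `gammaln` and
normalised after shifting by the maximum, so n in the thousands neither
overflows nor underflows. Ties are included using a relative slack of 1e-9
on the probability scale, so exactly equiprobable configurations (which
occur: e.g. counts (5, 3, 1)) always enter together. The distribution for
each (n, n_rare) pair is cached, making exhaustive sweeps cheap. The test
is conservative by construction; HWE is evaluated in post-exclusion
controls only, complete-case per locus.

## Association models

Logistic regression is maximised by damped Newton/IRLS with frequency
weights: genotype tables collapse to six weighted design rows, so each fit
is a few 2×2 or 3×3 solves. Step-halving guarantees a non-decreasing
log-likelihood trace (asserted in tests). Convergence at log-likelihood
change < 1e-10 or gradient norm < 1e-8, maximum 50 iterations; covariance
is the inverse observed information at the optimum. Quasi-complete
separation (any |β| > 15) yields a flagged, non-converged result rather
than an exception. Monomorphic loci report an undefined OR with p = 1 and
a flag; an empty genotype class drops that indicator, flags it, and reduces
the LRT df accordingly.

Headline p-values are likelihood-ratio tests (1 df trend, 2 df genotype
model); Wald CIs exp(β̂ ± z·SE) accompany the ORs, with z = 1.959964 pinned
rather than 1.96 so results are bit-reproducible against the CI-to-SE
inversion. Analyses are complete-case per SNP (panel completion in this
setting exceeds 99.9%; no imputation). No covariates are adjusted for. The
Bonferroni threshold for a 12-SNP panel is 0.05/12 = 4.17×10⁻³.

The case-only age model treats the risk-allele count as binomial with two
trials per subject and the logit of the per-allele probability linear in
age (years, centred for conditioning; the slope is unaffected). The
orientation of this regression is a genuinely open choice; the stratified
alternative — trend ORs for cases aged <60, 60–69, ≥70 against all
controls — is provided alongside.

## Effect comparison

Both OR sets are taken as log-normal. Per SNP, d = ln OR_m − ln OR_f,
v = se_m² + se_f², χ² = d²/v on 1 df; ratio e^d with CI exp(d ± z√v); the
global statistic is the exact sum of member χ² on k df. Standard errors
are reconstructed from published CIs as (ln hi − ln lo)/(2z); reference
estimates therefore enter with their own sampling variance, and male and
female estimates are treated as independent. When both a CI and an SE are
supplied they must agree within 1e-6 on the log scale (the CI wins);
degenerate CIs give SE 0, and two zero-variance estimates that disagree
raise an error rather than return an infinite statistic.

Recomputation from printed (rounded) inputs carries irreducible error:
ratios of rounded ORs reproduce published ratio tables to about ±0.05,
but because χ² is quadratic in d, per-SNP statistics can move by >1 — the
unrounded internal estimates behind a published table are unrecoverable.
Tests therefore assert ratio-level agreement and the stability of the
combined verdict, not per-SNP χ² equality.

## Power

Analytic power uses the allele-count normal approximation: with control
frequency p₀ and the case frequency p_c implied by the multiplicative
model, Var(ln ÔR) ≈ 1/(2·n_case·p_c q_c) + 1/(2·n_ctrl·p₀ q₀), and
two-sided power is Φ(λ − z) + Φ(−λ − z), λ = |ln OR|/SE. At OR = 1 this
returns exactly α. The approximation is validated against simulation
(fresh cohorts per replicate, per-replicate seeds spawned from the master
seed, rejection at LRT p ≤ α) and agrees within 3 percentage points over
the tested design grid; the weakest agreement (~2.5 points) is at low MAF,
where the allele-count approximation is known to be coarse. "MAF 30%" in a
power statement is interpreted as control risk-allele frequency 0.30.

## Determinism and problem sizes

All randomness flows from one master seed through
`numpy.random.SeedSequence` spawn keys (one stream per pipeline stage, one
per simulation replicate), so every table and report is a pure function of
(config, seed); pipeline determinism is verified by double-run byte
comparison. Simulation-based checks use 2,000 replicates for power and
calibration and 500 for parameter recovery — enough that Monte-Carlo error
(≈1–2 points) is small against the tolerances tested; consistency of the
trend estimator is checked as a geometric mean over 20 replicates of
50,000 + 50,000 samples, since a single replicate's sampling error at that
size (~0.01 on the log scale) is of the same order as the 1% bound being
demonstrated. The exact-HWE implementation is swept exhaustively against
integer-arithmetic enumeration for every table with n ≤ 200.

## Known limitations

- No LD, stratification, or covariate adjustment; conditional (matched)
  logistic regression is out of scope.
- The OR-comparison test assumes independent estimates; comparing a cohort
  against a reference that shares samples would overstate precision.
- The analytic power formula degrades at low MAF and extreme ORs; the
  simulator is the arbiter there.
- VCF support is deliberately minimal (single-ALT diploid GT).
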