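# Methods

`statinpgx` reproduces, as a tested pipeline over synthetic cohorts, the
analysis chain of candidate-gene pharmacogenetic studies of atorvastatin
exposure in healthy volunteers pooled from bioequivalence trials: cohort
simulation → star-allele phenotyping → non-compartmental PK analysis →
dose/weight-normalised two-stage statistics. This note records the models,
the calibration of the defaults, the numerical conventions, and what the
synthetic cohorts do and do not capture.

## Cohort simulation

**Structure.** The default cohort has 156 subjects in five single-dose
80 mg arms (A/B/C/D/E with n = 14/30/39/37/36); arm D co-administers
ezetimibe and samples 30 time points over 0–72 h, the others sample 20
points over 0–48 h. The female fraction (85/156) and per-sex weight,
height and age distributions are set to the published per-sex means and
CV% of the emulated study population; draws are truncated normals redrawn
until the trial inclusion bounds hold (age 18–55 years, BMI 18–30 kg/m²).

**Pharmacokinetic model.** Concentrations follow a one-compartment model
with first-order absorption:

C(t) = D·k_a / (V/F · (k_a − k_e)) · (e^{−k_e t} − e^{−k_a t}),
k_e = (CL/F)/(V/F)

The typical-subject parameters are CL/F = 480 L/h, V/F = 6300 L (so that
k_e = 0.0762 h⁻¹, i.e. t₁/₂ ≈ 9.1 h, and AUC_∞ = D/(CL/F) ≈ 167 ng·h/mL
at the reference 67.7 kg body weight) and k_a = 2.5 h⁻¹ (t_max ≈ 1.4 h).
CL/F and V/F scale linearly with body weight around 67.7 kg, which makes
weight-normalised clearance weight-invariant — the mechanism behind the
"sex differences disappear after dose/weight correction" phenomenon.

A one-compartment fit to these targets necessarily understates the
observed peak: real atorvastatin profiles are multiphasic (fast
distribution produces C_max ≈ 39 ng/mL while the terminal phase is slow),
and no single-compartment parameterisation can reproduce AUC, t₁/₂ and
C_max simultaneously. We match AUC, t₁/₂ and t_max and accept a lower
absolute C_max (≈ 12–17 ng/mL); all C_max analyses in the pipeline are
within-cohort contrasts, which are unaffected by the absolute scale.

**Between-subject variability.** Log-normal, median-preserving, with
CV 57% on CL/F and V/F (the published total CV of dose/weight-corrected
exposure) and 40% on k_a. The log-deviations of CL/F and V/F share a
correlation of 0.8: with independent draws the induced k_e = CL/V would
have a CV near 85%, far above the published half-life CV of ≈ 29%; the
correlation brings the simulated t₁/₂ dispersion to that scale.
Because the variability is median-preserving and log-normal, simulated
*arithmetic* means run above the typical-value predictions (E[1/CL]
exceeds 1/CL_typ by e^{σ²/2} ≈ 1.15); group contrasts are unaffected.

**Genotypes.** Panel variants are drawn as two independent allele draws
per subject (Hardy–Weinberg by construction). Frequencies come from the
published genotype counts where printed (SLCO1B1 rs4149056 q = 38/240;
CYP3A5 rs776746 *3 q = 270/312 ≈ 0.865; SLC22A1 rs72552763 and
rs34059508; UGT2B7 rs7439366) and otherwise from values typical of a
mixed European/Latin-American cohort, documented in
`src/statinpgx/config.py`. Variants are sampled independently (no linkage
disequilibrium) and identically across race strata. A configurable
Bernoulli masking rate (default 0) turns calls missing to exercise the
imputation rule.

**Genotype effects.** Effects act multiplicatively on CL/F only. The
multiplier for a genotype group is its published mean Cl/F divided by the
reference group's (SLCO1B1 DF 0.78, PF 0.446; CYP3A5 *1/*1 0.473, *1/*3
0.986; SLC22A1 *2/*2 0.687; …), so the reference multiplier is exactly 1
and a 2.24-fold exposure contrast corresponds to a 0.446 clearance
multiplier. Multipliers are applied through the actual
genotype→phenotype translation layer, so a simulated effect can only be
recovered if the translation chain is correct.

**Assay.** Proportional log-normal noise with CV 15% (a typical validated
LC–MS/MS performance level) and a 0.25 ng/mL lower limit of
quantification; sub-LLOQ samples are below-quantification marks, and the
pre-dose sample is always BQL.

**ADRs.** Per-subject Bernoulli indicators: gastrointestinal symptoms at
the published per-arm rates (10/36 in E, 2/37 in D, 1/30 in B, zero
elsewhere), headache in females only at 11/85 (making the sex–headache
logistic a deliberate quasi-separation case), myalgia at 3/156 uniformly.

**What the generator does not emulate.** Crossover periods and sequences
(each subject contributes one reference-formulation profile), metabolite
kinetics, enterohepatic recirculation, ezetimibe interaction kinetics
beyond the arm flag, linkage disequilibrium, race-specific allele
frequencies, and batch structure in missingness. Passing tests therefore
demonstrate that the analysis chain recovers effects *of the assumed
form* under realistic dispersion — not that the chain is robust to
model misspecification in real data.

## Non-compartmental analysis

AUC_t is the plain linear trapezoid over retained points (the log-linear
"log-down" rule is available behind a flag, off by default). BQL policy:
pre-peak BQL values count as 0, post-peak BQL samples are dropped, and the
profile ends at the last quantifiable point. The terminal rate constant is
−slope of the OLS fit of ln C on t over the best terminal window: all
suffixes of ≥ 3 positive concentrations starting strictly after t_max are
evaluated, the window with maximal adjusted R² wins, and ties go to the
longer window (deterministic). AUC_∞ = AUC_t + C_last/k_e, with a flag
when the extrapolated fraction exceeds 20%. Cl/F = D/(AUC_∞·W) in
mL/(h·kg) after mg→ng conversion, Vd/F = (Cl/F)/k_e, t₁/₂ = ln 2/k_e,
t_max ties resolve to the earliest time.

Units: published tables of this kind sometimes print Cl/F with an
ambiguous "L/h·kg" label at a 9×10³ magnitude that back-calculates to
mL/(h·kg); the engine computes in consistent units (mL/(h·kg), mL/kg) and
the reporting layer displays Vd/F in L/kg. Comparisons against published
group cells use magnitude *ratios* only, which are unit-free.

## Genotype → phenotype translation

All allele definitions live in versioned TSV data files
(`src/statinpgx/pgx/data/`): the variant panel (rsid, ref/alt, star
allele, function, activity value), per-gene rules, diplotype→phenotype
maps, and activity-score cutpoints. Nothing gene-specific is hard-coded.

Missing or failed calls are imputed as homozygous reference ("not
mutated") and recorded per assignment. Each alternate allele at a defining
variant contributes one star-allele copy; with multiple heterozygous
single-variant alleles the trans configuration is assumed (standard
unphased convention); if more than two copies accumulate, the two most
deleterious are kept and the assignment is flagged.

Per-gene rules: SLCO1B1 maps diplotypes over {*1, *1B, *5} to NF/DF/PF
(*1B is normal-function; rs4149015 and rs11045879 are carried as
annotations only). CYP3A5 *1 is defined by the absence of *3 and *6;
the analysis groups subjects by functional *1 count (*1/*1, *1/*3,
*3/*3). CYP2D6 and CYP2C9 use activity scores (CYP2D6 scaled by copy
number/2, so a whole-gene deletion on both alleles scores 0 → PM);
cutpoint intervals are half-open and tile the score axis because
copy-number scaling lands between canonical scores. CYP1A2 uses a
pluggable activity table over *1A/*1B/*1C/*1F. SLC22A1 and ABCB1 use the
merged-haplotype rule (0 variant alleles → wild-type, 1 → heterozygous,
≥ 2 → mutant), ABCB1 additionally with the C3435T/G2677T/A/C1236T core
subset. SLC22A1 *2 and *5 are also reported as per-allele genotypes
(*1/*1, *1/*2, *2/*2) because group contrasts are published in that
representation. UGT2B7 rs7439366 is stored as the nucleotide genotype
(TT/TC/CC) with the star label as an alias, since star naming for this
variant is inconsistent across sources. CYP2B6 phenotyping uses *5 and
*9 only (*4 is intentionally excluded, per the panel's documented scope).

## Statistics

PK parameters are analysed as natural logs; AUC_∞ and C_max are first
divided by dose/weight (AUC/DW, C_max/DW). Stage 1 screens each
categorical covariate separately: equal-variance two-sided t test for two
levels, one-way equal-variance ANOVA with Bonferroni-adjusted pairwise
post-hocs for three or more (Welch variants available by flag). Groups
with n < 2 are reported descriptively only; race strata with n < 6 are
merged into a combined level before testing. Stage 2 fits OLS of each log
outcome on all covariates with univariate p < 0.05, with the significance
threshold α* = 0.05/k, k = number of screened-in covariates. Bonferroni
is applied exactly twice (post-hocs and α*); no FDR anywhere.

Model coding: reference levels are NF, *3/*3, *1/*1, wild-type, female,
Caucasian, no-ezetimibe. The SLCO1B1 term enters the multivariate model
as the combined DF+PF contrast (univariate keeps three levels). When both
trial arm and ezetimibe screen in, the ezetimibe indicator is aliased to
the arm-D dummy and is dropped from the model (logged); covariates
measured on less than a configurable fraction of subjects (default 50%)
are likewise excluded and logged.

ADR incidence uses Pearson chi-square without continuity correction;
logistic regressions add log AUC/DW as a PK covariate. Quasi- or complete
separation (e.g. an ADR occurring in one sex only) is detected and
reported as a flag; an L2-penalised fit supplies finite coefficients in
that case rather than imitating a divergent maximum-likelihood estimate.

Hardy–Weinberg equilibrium is tested per variant by the 1-df Pearson
goodness-of-fit chi-square (expected counts from the estimated allele
frequency) and by the exact test that enumerates heterozygote counts at
fixed allele counts; monomorphic variants are flagged and excluded from
deviation calls. The two p values agree closely in the rejection-relevant
tail; near the null the exact p is discrete and can exceed the chi-square
p by ~0.1, which is expected behaviour, not error.

## Problem sizes and determinism

All randomness flows from one integer seed through
`numpy.random.default_rng`; identical configurations give byte-identical
persisted outputs (checksummed in the run manifest). The test suite
checks the NCA engine against the closed-form one-compartment oracle on
dense grids to five half-lives; parameter recovery over 200 replicate
156-subject cohorts; type-I calibration of the univariate screen and the
HWE chi-square over 10⁴ null replicates; and the exact HWE distribution
against a 2×10⁴-draw allele-pairing permutation oracle. The acceptance
script reports single-cohort summaries at n = 156 and pools 10 replicate
cohorts for genotype-group exposure folds so the small PF and CYP3A5
*1/*1 groups are always populated.

## Limitations

Under Hardy–Weinberg sampling at the calibrated frequencies, the extreme
genotype groups are intrinsically small in a 156-subject cohort: PF is
expected at n ≈ 3.9 and CYP3A5 *1/*1 at n ≈ 2.8, and the *1/*1 group is
entirely absent in ≈ 6% of cohorts. Single-cohort genotype contrasts are
therefore noisy: at the calibrated effect sizes and 57% dispersion, the
SLCO1B1 ANOVA flags in roughly 85% of replicate cohorts and the CYP3A5
ANOVA in under half, and the arithmetic-mean ordering NF < DF < PF holds
in ≈ 90%. This is a property of the study design being emulated, not of
the implementation; detecting rare-genotype effects reliably at these
frequencies requires either larger cohorts or pooling, as the acceptance
script does for its fold estimates.
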