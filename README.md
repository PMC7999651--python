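# statinpgx

Candidate-gene pharmacogenetic analysis of atorvastatin bioavailability,
packaged as a reproducible pipeline for pharmacologists and biostatisticians
working with healthy-volunteer bioequivalence cohorts. The pipeline answers
the question such studies pose: *which pharmacogene phenotypes — above all
the SLCO1B1 transporter function class — predict atorvastatin exposure once
dose and body weight are accounted for?*

Because subject-level data from such trials are not publicly deposited, the
package ships a first-class synthetic-cohort generator calibrated to the
published group-level summaries (demographics, Hardy–Weinberg genotype
counts, per-genotype clearance means), so every downstream stage is testable
end to end without any download.

## What it computes

1. **Cohort simulation** (`statinpgx.cohort`) — 156 subjects in five
   single-dose 80 mg arms; one-compartment profiles
   C(t) = D·k_a/(V/F·(k_a−k_e))·(e^{−k_e t} − e^{−k_a t}) with log-normal
   between-subject variability and genotype-dependent clearance
   multipliers applied through the real phenotyping layer.
2. **Star-allele translation** (`statinpgx.pgx`) — data-driven
   diplotype calling and phenotype assignment: SLCO1B1 NF/DF/PF, CYP3A5
   expresser genotypes, CYP2D6/CYP2C9/CYP1A2 activity scores (with copy
   number), SLC22A1/ABCB1 merged haplotypes; missing calls imputed as
   homozygous reference and tracked.
3. **Non-compartmental PK** (`statinpgx.nca`) — trapezoidal AUC_t,
   terminal slope λ_z by best-adjusted-R² log-linear regression,
   AUC_∞ = AUC_t + C_last/k_e, C_max/t_max, t₁/₂ = ln2/k_e,
   Cl/F = D/(AUC_∞·W), Vd/F = Cl/F/k_e.
4. **Two-stage statistics** (`statinpgx.stats`, `statinpgx.hwe`) —
   log-scale AUC/DW and C_max/DW screening (t test / ANOVA + Bonferroni
   post-hocs), multivariate OLS at α* = 0.05/k, chi-square ADR incidence
   tests, separation-aware logistic regression, and Hardy–Weinberg
   chi-square + exact tests.
5. **Reporting** (`statinpgx.reporting`) — stratified n/mean/CV% summary
   tables and a single `run_pipeline()` driver with a checksummed manifest.

## Worked example

The analysis is driven by numbered scripts (each a thin wrapper over the
library; all outputs land under `results/`):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_translate_genotypes.py
python analysis/03_run_nca.py
python analysis/04_run_stats.py --seed 1
python analysis/05_make_tables.py
```

With seed 1 this prints, along the way:

```
simulated 156 subjects (86 female) across arms {'A': 14, 'B': 30, 'C': 39, 'D': 37, 'E': 36}
translated 156 subjects; SLCO1B1 {'NF': 107, 'DF': 43, 'PF': 6}; CYP3A5 {'*3/*3': 119, '*1/*3': 35, '*1/*1': 2}
NCA on 156 profiles; 156 with a valid terminal fit
mean AUC∞ 241.9 ng·h/mL, mean Cmax 17.4 ng/mL, mean t1/2 10.7 h, median extrapolated fraction 0.041
k = 6 covariates screened in; alpha* = 0.00833
level   n  auc_dw  auc_dw_cv
   DF  43   206.6       42.6
   NF 107   191.4       76.6
   PF   6   423.3       77.5
Total 156   204.5       72.9
```

Reading the output: the six SLCO1B1 poor-function carriers show roughly
twice the dose/weight-corrected exposure (AUC/DW 423 vs 191 kg·h·ng/mL/mg)
of normal-function subjects — the simulated clearance deficit (PF
multiplier ≈ 0.45, calibrated from published group means) recovered by the
full genotype→phenotype→NCA→statistics chain. Six covariates passed the
univariate screen in this cohort, so the multivariate significance
threshold is 0.05/6 ≈ 0.0083. Equivalent to the scripts:

```python
from statinpgx import run_pipeline
res = run_pipeline(seed=1, out_dir="results/stats")
print(res.summaries["pk_by_slco1b1"])
```

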