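"""Published group-level summaries used to calibrate the cohort simulator.

The study this pipeline emulates reports only group-level summaries
(per-sex demographics, per-genotype PK means with CV%, genotype counts,
per-trial ADR counts); subject-level data are not deposited.  Those printed
summaries are therefore *inputs*: they parameterise the synthetic cohort
(allele frequencies, clearance multipliers, dispersion) and serve as
recombination checks for the reporting layer.

All PK group means below are dose/weight-normalised AUC (``auc_dw``,
kg·h·ng/(mL·mg)) and apparent weight-normalised clearance (``cl_f``, printed
magnitude ≈ 9×10³; the printed unit label is internally inconsistent in the
source tables, so only ratios of these cells are ever used).
"""

from __future__ import annotations

import math

# --- demographic summaries (per-sex / per-race means with CV%) -------------

DEMOGRAPHICS_BY_SEX = {
    # sex: (n, weight kg, CV%, bmi, CV%, height m, CV%, age y, CV%)
    "F": {"n": 85, "weight": 61.5, "weight_cv": 13.8, "bmi": 23.1,
          "bmi_cv": 13.4, "height": 1.63, "height_cv": 3.7,
          "age": 30.1, "age_cv": 28.2},
    "M": {"n": 71, "weight": 75.3, "weight_cv": 12.7, "bmi": 24.4,
          "bmi_cv": 10.2, "height": 1.75, "height_cv": 4.0,
          "age": 27.8, "age_cv": 27.0},
}

DEMOGRAPHICS_TOTAL = {"n": 156, "weight": 67.7, "bmi": 23.7,
                      "height": 1.69, "age": 29.0}

RACE_COUNTS = {"Caucasian": 81, "Latin-American": 70, "Black": 4, "Arabic": 1}

# --- raw exposure by sex (before dose/weight correction) --------------------

AUC_INF_BY_SEX = {"F": (85, 183.6, 90.7), "M": (71, 146.3, 83.4)}   # n, mean, SD
AUC_INF_TOTAL = (156, 166.6, 89.1)
CMAX_BY_SEX = {"F": (85, 44.8, 25.5), "M": (71, 32.0, 23.3)}
CMAX_TOTAL = (156, 39.0, 25.3)

MEAN_T_HALF_H = 9.1

# --- trial arms -------------------------------------------------------------

#: (arm id, n, sampling schedule id, dose mg, ezetimibe co-administration)
TRIAL_ARMS = [
    ("A", 14, "0-48h", 80.0, False),
    ("B", 30, "0-48h", 80.0, False),
    ("C", 39, "0-48h", 80.0, False),
    ("D", 37, "0-72h", 80.0, True),
    ("E", 36, "0-48h", 80.0, False),
]

# --- per-genotype PK group summaries ---------------------------------------

#: gene -> level -> dict(n, auc_dw, auc_dw_cv, cl_f, cl_f_cv)
PK_BY_GENOTYPE = {
    "SLCO1B1": {
        "NF": {"n": 86, "auc_dw": 122.6, "auc_dw_cv": 44.9, "cl_f": 9827.4, "cl_f_cv": 43.1},
        "DF": {"n": 30, "auc_dw": 181.5, "auc_dw_cv": 59.3, "cl_f": 7680.4, "cl_f_cv": 67.0},
        "PF": {"n": 4, "auc_dw": 283.7, "auc_dw_cv": 41.4, "cl_f": 4382.7, "cl_f_cv": 60.2},
    },
    "CYP3A5": {
        "*1/*1": {"n": 5, "auc_dw": 244.2, "auc_dw_cv": 21.5, "cl_f": 4405.1, "cl_f_cv": 23.7},
        "*1/*3": {"n": 32, "auc_dw": 153.7, "auc_dw_cv": 70.3, "cl_f": 9181.8, "cl_f_cv": 55.0},
        "*3/*3": {"n": 119, "auc_dw": 131.8, "auc_dw_cv": 52.0, "cl_f": 9309.2, "cl_f_cv": 42.7},
    },
    "SLC22A1*2": {
        "*1/*1": {"n": 71, "auc_dw": 131.8, "auc_dw_cv": 48.7, "cl_f": 9393.2, "cl_f_cv": 47.7},
        "*1/*2": {"n": 41, "auc_dw": 151.2, "auc_dw_cv": 66.2, "cl_f": 9136.4, "cl_f_cv": 54.0},
        "*2/*2": {"n": 8, "auc_dw": 195.7, "auc_dw_cv": 51.8, "cl_f": 6449.1, "cl_f_cv": 47.9},
    },
    "SLC22A1*5": {
        "*1/*1": {"n": 114, "auc_dw": 144.6, "auc_dw_cv": 57.0, "cl_f": 8933.1, "cl_f_cv": 49.3},
        "*1/*5": {"n": 6, "auc_dw": 105.6, "auc_dw_cv": 58.4, "cl_f": 12455.2, "cl_f_cv": 56.3},
    },
    "UGT2B7": {
        "*1/*1": {"n": 9, "auc_dw": 159.6, "auc_dw_cv": 80.6, "cl_f": 8821.0, "cl_f_cv": 43.8},
        "*1/*2": {"n": 12, "auc_dw": 108.9, "auc_dw_cv": 29.5, "cl_f": 9990.2, "cl_f_cv": 22.7},
        "*2/*2": {"n": 15, "auc_dw": 130.4, "auc_dw_cv": 41.1, "cl_f": 8751.0, "cl_f_cv": 28.3},
    },
}

PK_TOTAL = {"n": 156, "auc_dw": 139.9, "auc_dw_cv": 57.3, "cl_f": 9125.9,
            "cl_f_cv": 46.4, "t_half": 9.1, "t_half_cv": 28.6,
            "tmax": 1.4, "tmax_cv": 57.1, "vd_f": 120.8, "vd_f_cv": 60.6}

#: reference level per stratifier (all multipliers are 1 at the reference)
REFERENCE_LEVEL = {
    "SLCO1B1": "NF",
    "CYP3A5": "*3/*3",
    "SLC22A1*2": "*1/*1",
    "SLC22A1*5": "*1/*1",
    "UGT2B7": "*1/*1",
}

# --- genotype counts backing the allele-frequency calibration ---------------

#: rsid -> (hom-ref n, het n, hom-alt n) in the genotyped subset
GENOTYPE_COUNTS = {
    "rs4149056": (86, 30, 4),     # SLCO1B1 *5; NF/DF/PF group sizes
    "rs776746": (5, 32, 119),     # CYP3A5 *3 is the alternate (common) allele
    "rs72552763": (71, 41, 8),    # SLC22A1 *2
    "rs34059508": (114, 6, 0),    # SLC22A1 *5
    "rs7439366": (9, 12, 15),     # UGT2B7 (n=36 subset)
}

# --- adverse drug reactions -------------------------------------------------

#: per-trial counts of subjects with at least one GI-symptom ADR
ADR_GI_BY_TRIAL = {"A": 0, "B": 1, "C": 0, "D": 2, "E": 10}
ADR_HEADACHE_TOTAL = 11          # all observed in females (separation)
ADR_MYALGIA_TOTAL = 3
ADR_SUBJECTS_TOTAL = 21


def allele_frequency(counts: tuple[int, int, int]) -> float:
    """Alternate-allele frequency from (hom-ref, het, hom-alt) counts."""
    n_ref, n_het, n_alt = counts
    total = n_ref + n_het + n_alt
    if total == 0:
        raise ValueError("empty genotype counts")
    return (n_het + 2 * n_alt) / (2 * total)


def calibrate_effect_multipliers(
    pk_by_genotype: dict | None = None,
    reference_level: dict | None = None,
) -> dict[tuple[str, str], float]:
    """Derive clearance multipliers from per-genotype mean Cl/F cells.

    The multiplier for a genotype/phenotype group is its mean Cl/F divided by
    the reference group's mean Cl/F, so the reference multiplier is exactly 1
    and a group with a 2.24-fold higher mean exposure gets a CL multiplier of
    ≈ 1/2.24 ≈ 0.446.
    """
    pk_by_genotype = pk_by_genotype if pk_by_genotype is not None else PK_BY_GENOTYPE
    reference_level = reference_level if reference_level is not None else REFERENCE_LEVEL
    multipliers: dict[tuple[str, str], float] = {}
    for gene, groups in pk_by_genotype.items():
        ref = reference_level[gene]
        ref_clf = groups[ref]["cl_f"]
        if ref_clf <= 0:
            raise ValueError(f"non-positive reference Cl/F for {gene}")
        for level, cells in groups.items():
            if cells["cl_f"] <= 0:
                raise ValueError(f"non-positive Cl/F for {gene} {level}")
            multipliers[(gene, level)] = cells["cl_f"] / ref_clf
    return multipliers


def lognormal_sigma(cv: float) -> float:
    """Log-scale SD of a log-normal with the given coefficient of variation."""
    if cv < 0:
        raise ValueError("CV must be non-negative")
    return math.sqrt(math.log1p(cv * cv))
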