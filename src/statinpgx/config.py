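"""Simulation configuration: the full parameterisation of a synthetic cohort.

The defaults reproduce the study conditions of the emulated trials: 156
healthy volunteers across five bioequivalence arms, 80 mg single oral doses,
0–48 h or 0–72 h sampling, genotypes drawn in Hardy–Weinberg equilibrium at
frequencies calibrated from the printed genotype counts, and log-normal
between-subject pharmacokinetic variability with genotype-specific clearance
multipliers calibrated from the printed per-group Cl/F means.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from statinpgx import calibration

# Sampling schedules (h post-dose).  The short schedule has 20 time points to
# 48 h, the long one 30 points to 72 h (used by the ezetimibe arm).
SCHEDULES: dict[str, tuple[float, ...]] = {
    "0-48h": (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 2.5, 3.0,
              4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 24.0, 30.0, 36.0, 48.0),
    "0-72h": (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.25,
              2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 14.0,
              16.0, 20.0, 24.0, 30.0, 36.0, 42.0, 48.0, 56.0, 64.0, 72.0),
}


@dataclass(frozen=True)
class TrialArm:
    arm_id: str
    n: int
    schedule_id: str
    dose_mg: float
    ezetimibe: bool


@dataclass(frozen=True)
class PkBase:
    """Typical-subject PK parameters at the reference body weight.

    ``cl_f_l_h`` / ``v_f_l`` are apparent (bioavailability-uncorrected) oral
    clearance and volume; both scale linearly with body weight around
    ``ref_weight_kg`` so that weight-normalised clearance is weight-invariant.
    """

    cl_f_l_h: float = 480.0
    v_f_l: float = 6300.0
    ka_per_h: float = 2.5
    ref_weight_kg: float = 67.7


@dataclass(frozen=True)
class DemographicMeans:
    weight_mean: float
    weight_cv: float
    height_mean: float
    height_cv: float
    age_mean: float
    age_cv: float


@dataclass
class SimulationConfig:
    n_subjects: int
    trial_arms: list[TrialArm]
    sex_ratio: float                      # fraction female
    demographic_means: dict[str, DemographicMeans]
    race_probs: dict[str, float]
    allele_freqs: dict[str, float]        # rsid -> alt-allele frequency
    cyp2d6_cn_probs: dict[int, float]
    pk_base: PkBase
    effect_multipliers: dict[tuple[str, str], float]
    bsv_cv: dict[str, float]              # keys: cl, v, ka
    cl_v_corr: float = 0.8
    residual_cv: float = 0.15
    lloq: float = 0.25                    # ng/mL
    missing_rate: float = 0.0             # per (subject, variant) Bernoulli
    age_bounds: tuple[float, float] = (18.0, 55.0)
    bmi_bounds: tuple[float, float] = (18.0, 30.0)
    adr_gi_rate_by_arm: dict[str, float] = field(default_factory=dict)
    adr_headache_rate_by_sex: dict[str, float] = field(default_factory=dict)
    adr_myalgia_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if sum(a.n for a in self.trial_arms) != self.n_subjects:
            raise ValueError("trial arm sizes must sum to n_subjects")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        for rsid, freq in self.allele_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"allele frequency for {rsid} outside [0, 1]")
        for key, cv in self.bsv_cv.items():
            if cv < 0:
                raise ValueError(f"negative CV for {key}")
        if self.residual_cv < 0:
            raise ValueError("negative residual CV")
        for key, mult in self.effect_multipliers.items():
            if mult <= 0:
                raise ValueError(f"non-positive multiplier for {key}")
        if not -1.0 < self.cl_v_corr < 1.0:
            raise ValueError("cl_v_corr must be in (-1, 1)")
        if abs(sum(self.race_probs.values()) - 1.0) > 1e-9:
            raise ValueError("race probabilities must sum to 1")
        ke = self.pk_base.cl_f_l_h / self.pk_base.v_f_l
        if math.isclose(ke, self.pk_base.ka_per_h, rel_tol=1e-9):
            raise ValueError("ka equal to ke: degenerate absorption model")

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["effect_multipliers"] = {
            f"{gene}|{level}": v for (gene, level), v in self.effect_multipliers.items()
        }
        d["cyp2d6_cn_probs"] = {str(k): v for k, v in self.cyp2d6_cn_probs.items()}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        d["trial_arms"] = [TrialArm(**a) if isinstance(a, dict) else a
                           for a in d["trial_arms"]]
        d["demographic_means"] = {
            sex: DemographicMeans(**m) if isinstance(m, dict) else m
            for sex, m in d["demographic_means"].items()
        }
        if isinstance(d["pk_base"], dict):
            d["pk_base"] = PkBase(**d["pk_base"])
        d["effect_multipliers"] = {
            tuple(k.split("|", 1)): v for k, v in d["effect_multipliers"].items()
        }
        d["cyp2d6_cn_probs"] = {int(k): v for k, v in d["cyp2d6_cn_probs"].items()}
        for tup_key in ("age_bounds", "bmi_bounds"):
            if tup_key in d and isinstance(d[tup_key], list):
                d[tup_key] = tuple(d[tup_key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: alternate-allele frequencies for panel variants without printed genotype
#: counts; values are typical of a mixed European / Latin-American cohort and
#: exist to exercise genotype translation and HWE testing, not to calibrate
#: any effect size.
ASSUMED_ALLELE_FREQS: dict[str, float] = {
    "rs2306283": 0.40,    # SLCO1B1 *1B
    "rs4149015": 0.06,    # SLCO1B1 annotation-only
    "rs11045879": 0.20,   # SLCO1B1 annotation-only
    "rs10264272": 0.005,  # CYP3A5 *6
    "rs12208357": 0.07,   # SLC22A1 *3
    "rs1045642": 0.52,    # ABCB1 C3435T
    "rs2032582": 0.43,    # ABCB1 G2677T/A
    "rs1128503": 0.42,    # ABCB1 C1236T
    "rs10276036": 0.45,   # ABCB1 intronic
    "rs3842": 0.11,       # ABCB1 3'-UTR
    "rs3892097": 0.19,    # CYP2D6 *4
    "rs28371725": 0.09,   # CYP2D6 *41
    "rs1065852": 0.20,    # CYP2D6 *10
    "rs4244285": 0.15,    # CYP2C19 *2
    "rs12248560": 0.22,   # CYP2C19 *17
    "rs1799853": 0.12,    # CYP2C9 *2
    "rs1057910": 0.07,    # CYP2C9 *3
    "rs3745274": 0.25,    # CYP2B6 *9
    "rs3211371": 0.12,    # CYP2B6 *5
    "rs2069514": 0.05,    # CYP1A2 *1C
    "rs762551": 0.68,     # CYP1A2 *1F (the alternate is the major allele)
    "rs2470890": 0.40,    # CYP1A2 *1B
}


def default_allele_freqs() -> dict[str, float]:
    freqs = dict(ASSUMED_ALLELE_FREQS)
    for rsid, counts in calibration.GENOTYPE_COUNTS.items():
        freqs[rsid] = calibration.allele_frequency(counts)
    return freqs


def default_config(seed: int = 0, *, n_subjects: int | None = None,
                   missing_rate: float = 0.0,
                   effect_multipliers: dict[tuple[str, str], float] | None = None,
                   ) -> SimulationConfig:
    """Study-condition default configuration.

    ``n_subjects`` other than 156 rescales the five arms proportionally
    (largest-remainder rounding) so that small test cohorts keep the trial
    structure.
    """
    arms = [TrialArm(*a) for a in calibration.TRIAL_ARMS]
    if n_subjects is not None and n_subjects != sum(a.n for a in arms):
        total = sum(a.n for a in arms)
        raw = [a.n * n_subjects / total for a in arms]
        ns = [int(x) for x in raw]
        rem = sorted(range(len(arms)), key=lambda i: raw[i] - ns[i], reverse=True)
        for i in rem[: n_subjects - sum(ns)]:
            ns[i] += 1
        arms = [dataclasses.replace(a, n=n) for a, n in zip(arms, ns)]
    n = sum(a.n for a in arms)

    demo = {
        sex: DemographicMeans(
            weight_mean=row["weight"], weight_cv=row["weight_cv"] / 100.0,
            height_mean=row["height"], height_cv=row["height_cv"] / 100.0,
            age_mean=row["age"], age_cv=row["age_cv"] / 100.0,
        )
        for sex, row in calibration.DEMOGRAPHICS_BY_SEX.items()
    }
    race_total = sum(calibration.RACE_COUNTS.values())
    race_probs = {r: c / race_total for r, c in calibration.RACE_COUNTS.items()}

    if effect_multipliers is None:
        effect_multipliers = calibration.calibrate_effect_multipliers()

    return SimulationConfig(
        n_subjects=n,
        trial_arms=arms,
        sex_ratio=calibration.DEMOGRAPHICS_BY_SEX["F"]["n"]
        / calibration.DEMOGRAPHICS_TOTAL["n"],
        demographic_means=demo,
        race_probs=race_probs,
        allele_freqs=default_allele_freqs(),
        cyp2d6_cn_probs={1: 0.03, 2: 0.93, 3: 0.04},
        pk_base=PkBase(),
        effect_multipliers=effect_multipliers,
        bsv_cv={"cl": 0.57, "v": 0.57, "ka": 0.40},
        cl_v_corr=0.8,
        residual_cv=0.15,
        lloq=0.25,
        missing_rate=missing_rate,
        adr_gi_rate_by_arm={
            arm: calibration.ADR_GI_BY_TRIAL[arm] / orig_n
            for arm, orig_n in ((a[0], a[1]) for a in calibration.TRIAL_ARMS)
        },
        adr_headache_rate_by_sex={"F": calibration.ADR_HEADACHE_TOTAL / 85.0,
                                  "M": 0.0},
        adr_myalgia_rate=calibration.ADR_MYALGIA_TOTAL / 156.0,
        seed=seed,
    )
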