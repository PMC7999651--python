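"""Synthetic bioequivalence-cohort generator.

Produces subjects (demographics drawn from truncated per-sex normals honoring
the trial inclusion bounds), panel genotypes drawn in Hardy–Weinberg
equilibrium, genotype-dependent one-compartment concentration–time profiles
with log-normal between-subject variability and proportional assay noise,
and adverse-drug-reaction indicators.

Genotype effects act multiplicatively on apparent clearance and are applied
through the real genotype→phenotype translation layer, so simulated effects
flow exactly along the path the analysis later reverses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from statinpgx import pgx
from statinpgx.calibration import lognormal_sigma
from statinpgx.config import SCHEDULES, SimulationConfig
from statinpgx.nca import ConcTimeProfile
from statinpgx.pk import PkParams, concentration

_MAX_REDRAW = 10_000


@dataclass
class SimulatedCohort:
    subjects: pd.DataFrame           # one row per subject
    genotypes: pd.DataFrame          # long, observable (post-masking)
    genotypes_true: pd.DataFrame     # long, pre-masking ground truth
    cyp2d6_cn: pd.Series
    phenotypes: pd.DataFrame         # wide, from true genotypes
    pk_truth: pd.DataFrame           # true CL_F, V_F, ka, ke per subject
    profiles: list[ConcTimeProfile]
    adr: pd.DataFrame


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    for _ in range(_MAX_REDRAW):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())
    raise RuntimeError("truncation bounds too tight: redraw limit reached")


def sample_demographics(config: SimulationConfig, rng) -> pd.DataFrame:
    """Subject table with sex, race, age, weight, height, BMI and trial arm."""
    config.validate()
    n = config.n_subjects
    ids = [f"S{i:03d}" for i in range(1, n + 1)]
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    races = list(config.race_probs)
    race = rng.choice(races, size=n, p=[config.race_probs[r] for r in races])

    weight = np.empty(n)
    height = np.empty(n)
    age = np.empty(n)
    a_lo, a_hi = config.age_bounds
    b_lo, b_hi = config.bmi_bounds
    for s, means in config.demographic_means.items():
        m = sex == s
        k = int(m.sum())
        if k == 0:
            continue
        age[m] = _truncated_normal(rng, means.age_mean,
                                   means.age_mean * means.age_cv, a_lo, a_hi, k)
        # joint redraw of weight/height until BMI falls inside the bounds
        w = rng.normal(means.weight_mean, means.weight_mean * means.weight_cv, k)
        h = rng.normal(means.height_mean, means.height_mean * means.height_cv, k)
        for _ in range(_MAX_REDRAW):
            bmi = w / h**2
            bad = (bmi < b_lo) | (bmi > b_hi) | (w <= 0) | (h <= 0)
            if not bad.any():
                break
            nb = int(bad.sum())
            w[bad] = rng.normal(means.weight_mean,
                                means.weight_mean * means.weight_cv, nb)
            h[bad] = rng.normal(means.height_mean,
                                means.height_mean * means.height_cv, nb)
        else:
            raise RuntimeError("BMI truncation bounds too tight")
        weight[m] = w
        height[m] = h

    arm_col = np.empty(n, dtype=object)
    sched = np.empty(n, dtype=object)
    dose = np.empty(n)
    ez = np.zeros(n, dtype=bool)
    start = 0
    for arm in config.trial_arms:
        arm_col[start:start + arm.n] = arm.arm_id
        sched[start:start + arm.n] = arm.schedule_id
        dose[start:start + arm.n] = arm.dose_mg
        ez[start:start + arm.n] = arm.ezetimibe
        start += arm.n

    return pd.DataFrame({
        "subject_id": ids, "sex": sex, "race": race,
        "age": age, "weight_kg": weight, "height_m": height,
        "trial_arm": arm_col, "schedule_id": sched, "dose_mg": dose,
        "ezetimibe": ez,
    }).assign(bmi=lambda d: d["weight_kg"] / d["height_m"] ** 2)


def sample_genotypes(config: SimulationConfig, subjects: pd.DataFrame,
                     rng) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """HWE genotypes for the panel: two independent allele draws per variant.

    Returns ``(observable, truth, cyp2d6_cn)`` where ``observable`` has
    missing calls masked to "." at the configured rate.
    """
    defs = pgx.load_definitions()
    panel = defs.panel
    n = len(subjects)
    rows = []
    for row in panel.itertuples():
        freq = config.allele_freqs.get(row.rsid)
        if freq is None:
            raise ValueError(f"no allele frequency configured for {row.rsid}")
        draws = rng.random((n, 2)) < freq
        a1 = np.where(draws[:, 0], row.alt, row.ref)
        a2 = np.where(draws[:, 1], row.alt, row.ref)
        rows.append(pd.DataFrame({
            "subject_id": subjects["subject_id"].to_numpy(),
            "gene": row.gene, "rsid": row.rsid,
            "allele1": a1, "allele2": a2,
        }))
    truth = pd.concat(rows, ignore_index=True)

    observable = truth.copy()
    if config.missing_rate > 0:
        mask = rng.random(len(observable)) < config.missing_rate
        observable.loc[mask, ["allele1", "allele2"]] = "."

    cns = sorted(config.cyp2d6_cn_probs)
    cn = rng.choice(cns, size=n, p=[config.cyp2d6_cn_probs[c] for c in cns])
    cyp2d6_cn = pd.Series(cn, index=subjects["subject_id"].to_numpy(),
                          name="cyp2d6_cn")
    return observable, truth, cyp2d6_cn


def subject_pk_params(config: SimulationConfig, subjects: pd.DataFrame,
                      phenotypes: pd.DataFrame, rng) -> pd.DataFrame:
    """True apparent PK parameters per subject.

    Clearance and volume scale linearly with weight around the reference
    weight; between-subject log-normal deviations on CL and V are correlated
    (``cl_v_corr``) so the induced elimination rate dispersion stays near the
    observed half-life CV; genotype multipliers act on clearance only.
    """
    n = len(subjects)
    s_cl = lognormal_sigma(config.bsv_cv["cl"])
    s_v = lognormal_sigma(config.bsv_cv["v"])
    s_ka = lognormal_sigma(config.bsv_cv["ka"])
    rho = config.cl_v_corr
    z = rng.standard_normal((n, 2))
    eta_cl = s_cl * z[:, 0]
    eta_v = s_v * (rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1])
    eta_ka = s_ka * rng.standard_normal(n)

    w_scale = subjects["weight_kg"].to_numpy() / config.pk_base.ref_weight_kg
    mult = np.ones(n)
    phen = phenotypes.loc[subjects["subject_id"]]
    for (stratifier, level), m in config.effect_multipliers.items():
        col = pgx.STRATIFIER_COLUMN[stratifier]
        mult *= np.where(phen[col].to_numpy() == level, m, 1.0)

    cl = config.pk_base.cl_f_l_h * w_scale * mult * np.exp(eta_cl)
    v = config.pk_base.v_f_l * w_scale * np.exp(eta_v)
    ka = config.pk_base.ka_per_h * np.exp(eta_ka)
    return pd.DataFrame({
        "subject_id": subjects["subject_id"].to_numpy(),
        "cl_f_l_h": cl, "v_f_l": v, "ka_per_h": ka, "ke_per_h": cl / v,
        "cl_multiplier": mult,
    }).set_index("subject_id")


def simulate_profile(subject_id: str, schedule_id: str, dose_mg: float,
                     params: PkParams, rng, residual_cv: float,
                     lloq: float) -> ConcTimeProfile:
    """One noisy concentration–time profile; sub-LLOQ samples are marked BQL."""
    times = np.asarray(SCHEDULES[schedule_id], dtype=float)
    clean = concentration(times, dose_mg, params)
    if residual_cv > 0:
        noise = np.exp(rng.normal(0.0, lognormal_sigma(residual_cv), times.size))
        conc = clean * noise
    else:
        conc = clean.copy()
    conc[times == 0.0] = 0.0
    conc = np.where(conc < lloq, np.nan, conc)
    return ConcTimeProfile(subject_id=subject_id, schedule_id=schedule_id,
                           times=times, concentrations=conc, lloq=lloq)


def sample_adrs(config: SimulationConfig, subjects: pd.DataFrame,
                rng) -> pd.DataFrame:
    """Per-subject ADR indicators (GI symptoms, headache, myalgia)."""
    n = len(subjects)
    gi_rate = subjects["trial_arm"].map(
        lambda a: config.adr_gi_rate_by_arm.get(a, 0.0)).to_numpy()
    hd_rate = subjects["sex"].map(
        lambda s: config.adr_headache_rate_by_sex.get(s, 0.0)).to_numpy()
    gi = rng.random(n) < gi_rate
    hd = rng.random(n) < hd_rate
    my = rng.random(n) < config.adr_myalgia_rate
    return pd.DataFrame({
        "subject_id": subjects["subject_id"].to_numpy(),
        "adr_gi": gi, "adr_headache": hd, "adr_myalgia": my,
        "adr_any": gi | hd | my,
    })


def simulate_cohort(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> SimulatedCohort:
    """Full synthetic cohort under one configuration (deterministic per seed)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    subjects = sample_demographics(config, rng)
    observable, truth, cyp2d6_cn = sample_genotypes(config, subjects, rng)
    phen_wide, _ = pgx.translate_cohort(truth, cyp2d6_cn)
    pk_truth = subject_pk_params(config, subjects, phen_wide, rng)
    profiles = []
    for row in subjects.itertuples():
        p = pk_truth.loc[row.subject_id]
        params = PkParams(cl_f_l_h=p["cl_f_l_h"], v_f_l=p["v_f_l"],
                          ka_per_h=p["ka_per_h"])
        profiles.append(simulate_profile(row.subject_id, row.schedule_id,
                                         row.dose_mg, params, rng,
                                         config.residual_cv, config.lloq))
    adr = sample_adrs(config, subjects, rng)
    return SimulatedCohort(subjects=subjects, genotypes=observable,
                           genotypes_true=truth, cyp2d6_cn=cyp2d6_cn,
                           phenotypes=phen_wide, pk_truth=pk_truth,
                           profiles=profiles, adr=adr)


def profiles_frame(profiles: list[ConcTimeProfile]) -> pd.DataFrame:
    """Long (subject_id, time_h, conc_ng_ml) table; BQL written as NaN."""
    frames = [pd.DataFrame({"subject_id": p.subject_id,
                            "schedule_id": p.schedule_id,
                            "time_h": p.times,
                            "conc_ng_ml": p.concentrations,
                            "lloq": p.lloq})
              for p in profiles]
    return pd.concat(frames, ignore_index=True)
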