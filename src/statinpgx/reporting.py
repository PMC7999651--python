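"""Stratified summary tables and the end-to-end pipeline driver."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from statinpgx import io, pgx, stats
from statinpgx.cohort import SimulatedCohort, profiles_frame, simulate_cohort
from statinpgx.config import SimulationConfig, default_config
from statinpgx.hwe import hwe_table
from statinpgx.nca import nca_table

#: columns summarised in PK tables (display units; Vd/F shown in L/kg)
PK_SUMMARY_COLUMNS = ["auc_dw", "cmax_dw", "tmax", "t_half",
                      "vd_f_l_kg", "cl_f_w"]
DEMO_SUMMARY_COLUMNS = ["weight_kg", "bmi", "height_m", "age"]

#: candidate grouping variables for the univariate screen
CANDIDATE_PREDICTORS = [
    "sex", "race_merged", "trial_arm", "ezetimibe",
    "slco1b1_phenotype", "cyp3a5_genotype",
    "slc22a1_star2", "slc22a1_star5", "ugt2b7",
    "slc22a1_haplotype", "abcb1_haplotype", "abcb1_core_haplotype",
]


def group_summary(dataset: pd.DataFrame, stratifier: str,
                  columns: list[str]) -> pd.DataFrame:
    """Per-level n, arithmetic mean and CV% for each column, plus a Total row.

    Means and CV% are computed on the untransformed scale (CV% =
    100·SD/mean), matching how PK summary tables are conventionally printed
    even when inference runs on logs.
    """
    if stratifier not in dataset.columns:
        raise ValueError(f"stratifier column {stratifier!r} not present")
    rows = []

    def one(level, sub):
        row = {"level": level, "n": len(sub)}
        for col in columns:
            v = sub[col].dropna()
            mean = float(v.mean()) if len(v) else np.nan
            sd = float(v.std(ddof=1)) if len(v) > 1 else np.nan
            row[col] = mean
            row[col + "_cv"] = 100.0 * sd / mean if mean else np.nan
        return row

    for level, sub in dataset.groupby(stratifier, observed=True, sort=True):
        rows.append(one(str(level), sub))
    rows.append(one("Total", dataset))
    return pd.DataFrame(rows)


def render_markdown(summary: pd.DataFrame, title: str,
                    decimals: int = 1) -> str:
    """Markdown rendering with 1-decimal display rounding (pure function)."""
    disp = summary.copy()
    for col in disp.columns:
        if disp[col].dtype.kind == "f":
            disp[col] = disp[col].round(decimals)
    lines = [f"### {title}", "", "| " + " | ".join(disp.columns) + " |",
             "|" + "---|" * len(disp.columns)]
    for _, row in disp.iterrows():
        lines.append("| " + " | ".join(str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"


@dataclass
class PipelineResult:
    config: SimulationConfig
    cohort: SimulatedCohort | None
    dataset: pd.DataFrame
    nca: pd.DataFrame
    phenotypes_wide: pd.DataFrame
    phenotypes_long: pd.DataFrame
    univariate: list
    univariate_table: pd.DataFrame
    multivariate: dict
    logistic: dict
    adr_tests: pd.DataFrame
    hwe: pd.DataFrame
    summaries: dict
    k_screened: int
    alpha_star: float
    excluded_predictors: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def build_analysis_dataset(subjects: pd.DataFrame, phenotypes: pd.DataFrame,
                           nca: pd.DataFrame, adr: pd.DataFrame,
                           race_min_n: int = 6) -> pd.DataFrame:
    """Join subjects × phenotypes × NCA × ADR into one row per subject."""
    df = (subjects.merge(nca, on="subject_id", suffixes=("", "_nca"))
          .merge(phenotypes.reset_index(), on="subject_id")
          .merge(adr, on="subject_id", how="left"))
    if df["subject_id"].duplicated().any():
        raise ValueError("subject appears more than once after join")
    df["race_merged"] = stats.merge_small_levels(df["race"], min_n=race_min_n)
    for col in df.columns:
        if col.startswith("adr_"):
            df[col] = df[col].fillna(False).astype(bool)
    df = stats.normalize_exposure(df)
    df["vd_f_l_kg"] = df["vd_f_w"] / 1000.0
    df["slco1b1_df_pf"] = np.where(df["slco1b1_phenotype"] == "NF",
                                   "NF", "DF or PF")
    return df


def _multivariate_predictors(screened: list[str]) -> list[str]:
    """Model-ready predictor list: the SLCO1B1 term enters as the combined
    DF+PF contrast, and ezetimibe is aliased to the trial arm dummy set so it
    is dropped when both screen in."""
    preds = ["slco1b1_df_pf" if p == "slco1b1_phenotype" else p
             for p in screened]
    if "trial_arm" in preds and "ezetimibe" in preds:
        preds.remove("ezetimibe")
    return preds


def run_pipeline(config: SimulationConfig | None = None, *,
                 seed: int | None = None,
                 inputs: dict | None = None,
                 out_dir=None,
                 min_measured_fraction: float = 0.5) -> PipelineResult:
    """Simulate (or load) a cohort and run the complete analysis.

    ``inputs`` may name existing files (keys: subjects, genotypes, profiles,
    adr) instead of simulating.  With ``out_dir`` all intermediate and final
    tables are persisted along with a manifest (seed, arm sizes, checksums).
    """
    if config is None:
        config = default_config(seed=seed if seed is not None else 0)
    elif seed is not None:
        config = SimulationConfig.from_dict({**config.to_dict(), "seed": seed})
    config.validate()

    cohort = None
    if inputs is None:
        cohort = simulate_cohort(config)
        subjects = cohort.subjects
        genotypes = cohort.genotypes
        cyp2d6_cn = cohort.cyp2d6_cn
        profiles = cohort.profiles
        adr = cohort.adr
    else:
        for key in ("subjects", "genotypes", "profiles"):
            if key not in inputs:
                raise ValueError(f"non-simulation mode requires {key!r} input file")
        subjects = io.read_subjects_csv(inputs["subjects"])
        genotypes = io.read_genotypes_csv(inputs["genotypes"])
        profiles = io.read_profiles_csv(inputs["profiles"])
        adr = (io.read_adr_csv(inputs["adr"]) if "adr" in inputs else
               pd.DataFrame({"subject_id": subjects["subject_id"],
                             "adr_any": False}))
        cyp2d6_cn = None

    phen_wide, phen_long = pgx.translate_cohort(genotypes, cyp2d6_cn)
    doses = dict(zip(subjects["subject_id"], subjects["dose_mg"]))
    weights = dict(zip(subjects["subject_id"], subjects["weight_kg"]))
    nca = nca_table(profiles, doses, weights)
    nca_ok = nca.dropna(subset=["auc_inf"])
    dataset = build_analysis_dataset(subjects, phen_wide, nca_ok, adr)

    # ---- stage 1: univariate screen on log-scale PK outcomes --------------
    univariate = stats.univariate_screen(dataset, stats.PK_OUTCOMES,
                                         CANDIDATE_PREDICTORS)
    screened = stats.screened_predictors(univariate)
    excluded = []
    for pred in list(screened):
        measured = dataset[pred].notna().mean()
        if measured < min_measured_fraction:
            screened.remove(pred)
            excluded.append((pred, f"measured on {measured:.0%} of subjects"))
    k = max(1, len(screened))
    alpha_star = stats.bonferroni_alpha(k)

    # ---- stage 2: multivariate models per outcome -------------------------
    multivariate = {}
    preds = _multivariate_predictors(screened)
    if preds:
        for outcome in stats.PK_OUTCOMES:
            multivariate[outcome] = stats.multivariate_model(
                dataset, outcome, preds, k=k)

    # ---- ADR analyses ------------------------------------------------------
    adr_rows = []
    logistic = {}
    adr_cols = [c for c in ("adr_gi", "adr_headache", "adr_myalgia", "adr_any")
                if c in dataset.columns]
    for ind in adr_cols:
        sig_preds = []
        for var in CANDIDATE_PREDICTORS:
            try:
                stat, p, _ = stats.adr_incidence_test(dataset, ind, var)
            except ValueError:
                continue
            adr_rows.append({"adr": ind, "grouping": var,
                             "chi2": stat, "p_value": p})
            if p < 0.05:
                sig_preds.append(var)
        if sig_preds:
            logistic[ind] = stats.logistic_adr_model(
                dataset, ind, _multivariate_predictors(sig_preds) + ["log_auc_dw"])
    adr_tests = pd.DataFrame(adr_rows)

    # ---- HWE on observed (unimputed) calls --------------------------------
    defs = pgx.load_definitions()
    observed_calls = genotypes[(genotypes["allele1"] != ".")
                               & (genotypes["allele2"] != ".")]
    hwe = hwe_table(observed_calls, defs.panel)

    # ---- summary tables ----------------------------------------------------
    summaries = {
        "demographics_by_sex": group_summary(dataset, "sex",
                                             DEMO_SUMMARY_COLUMNS),
        "demographics_by_race": group_summary(dataset, "race_merged",
                                              DEMO_SUMMARY_COLUMNS),
        "pk_by_sex": group_summary(dataset, "sex", PK_SUMMARY_COLUMNS),
        "pk_by_trial": group_summary(dataset, "trial_arm", PK_SUMMARY_COLUMNS),
        "pk_by_ezetimibe": group_summary(dataset, "ezetimibe",
                                         PK_SUMMARY_COLUMNS),
        "pk_by_race": group_summary(dataset, "race_merged", PK_SUMMARY_COLUMNS),
        "pk_by_slco1b1": group_summary(dataset, "slco1b1_phenotype",
                                       PK_SUMMARY_COLUMNS),
        "pk_by_cyp3a5": group_summary(dataset, "cyp3a5_genotype",
                                      PK_SUMMARY_COLUMNS),
    }

    result = PipelineResult(
        config=config, cohort=cohort, dataset=dataset, nca=nca,
        phenotypes_wide=phen_wide, phenotypes_long=phen_long,
        univariate=univariate,
        univariate_table=stats.univariate_frame(univariate),
        multivariate=multivariate, logistic=logistic, adr_tests=adr_tests,
        hwe=hwe, summaries=summaries, k_screened=k, alpha_star=alpha_star,
        excluded_predictors=excluded,
    )
    result.manifest = _build_manifest(result, out_dir)
    if out_dir is not None:
        _persist(result, Path(out_dir))
    return result


def _build_manifest(result: PipelineResult, out_dir) -> dict:
    from statinpgx import __version__

    return {
        "package_version": __version__,
        "seed": result.config.seed,
        "n_subjects": int(result.config.n_subjects),
        "arm_sizes": {a.arm_id: a.n for a in result.config.trial_arms},
        "k_screened": result.k_screened,
        "alpha_star": result.alpha_star,
        "excluded_predictors": [list(e) for e in result.excluded_predictors],
        "checksums": {},
    }


def _persist(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = result.config.seed
    written = {}

    def save(df, name, index=False):
        path = out_dir / name
        io._write_with_header(df, path, seed, index=index)
        written[name] = path

    if result.cohort is not None:
        save(result.cohort.subjects, "subjects.csv")
        io.write_genotypes_csv(result.cohort.genotypes,
                               out_dir / "genotypes.csv", seed)
        written["genotypes.csv"] = out_dir / "genotypes.csv"
        io.write_profiles_csv(result.cohort.profiles,
                              out_dir / "profiles.csv", seed)
        written["profiles.csv"] = out_dir / "profiles.csv"
        save(result.cohort.adr, "adr.csv")
    save(result.phenotypes_long, "phenotypes.csv")
    save(result.nca, "nca.csv")
    save(result.dataset, "analysis_dataset.csv")
    save(result.univariate_table, "univariate.csv")
    if result.multivariate:
        rows = []
        for outcome, m in result.multivariate.items():
            for term in m.coefficients.index:
                rows.append({"outcome": outcome, "term": term,
                             "coefficient": m.coefficients[term],
                             "p_value": m.p_values[term],
                             "r_squared": m.r_squared,
                             "alpha_star": m.alpha_star,
                             "significant_bonferroni":
                                 term in m.significant_bonferroni})
        save(pd.DataFrame(rows), "multivariate.csv")
    save(result.adr_tests, "adr_tests.csv")
    save(result.hwe, "hwe.csv")
    md = []
    for name, summary in result.summaries.items():
        save(summary, f"summary_{name}.csv")
        md.append(render_markdown(summary, name))
    (out_dir / "summaries.md").write_text("\n".join(md))
    result.config.to_yaml(out_dir / "config.yaml")
    written["config.yaml"] = out_dir / "config.yaml"
    result.manifest["checksums"] = {
        name: io.sha256sum(path) for name, path in sorted(written.items())
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
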