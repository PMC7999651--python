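"""Synthetic-cohort generator: demographics, HWE genotypes, profiles,
clearance-multiplier calibration."""

import numpy as np
import pandas as pd
import pytest

from statinpgx import pgx
from statinpgx.calibration import calibrate_effect_multipliers
from statinpgx.cohort import (sample_demographics, sample_genotypes,
                              simulate_cohort, simulate_profile)
from statinpgx.config import SCHEDULES, default_config
from statinpgx.pk import PkParams, analytic_auc_inf, analytic_cmax, analytic_tmax, concentration


def _big_config(n, seed=5, sex_ratio=None):
    cfg = default_config(seed=seed, n_subjects=n)
    if sex_ratio is not None:
        cfg.sex_ratio = sex_ratio
    return cfg


class TestDemographics:
    def test_per_sex_means_converge(self, rng):
        cfg = _big_config(20000, sex_ratio=0.5)
        subj = sample_demographics(cfg, rng)
        f = subj[subj.sex == "F"]
        m = subj[subj.sex == "M"]
        assert f["weight_kg"].mean() == pytest.approx(61.5, rel=0.02)
        assert m["weight_kg"].mean() == pytest.approx(75.3, rel=0.02)
        assert f["height_m"].mean() == pytest.approx(1.63, rel=0.02)

    def test_inclusion_bounds_enforced(self, rng):
        subj = sample_demographics(_big_config(5000), rng)
        assert subj["age"].between(18, 55).all()
        assert subj["bmi"].between(18, 30).all()

    def test_bmi_consistent_with_weight_height(self, rng):
        subj = sample_demographics(_big_config(200), rng)
        np.testing.assert_allclose(
            subj["bmi"], subj["weight_kg"] / subj["height_m"] ** 2)

    def test_degenerate_sex_ratio_all_female(self, rng):
        subj = sample_demographics(_big_config(100, sex_ratio=1.0), rng)
        assert (subj["sex"] == "F").all()

    def test_zero_subjects_rejected(self, rng):
        cfg = default_config(seed=1)
        cfg.n_subjects = 0
        cfg.trial_arms = []
        with pytest.raises(ValueError):
            sample_demographics(cfg, rng)

    def test_impossible_truncation_bounds(self, rng):
        cfg = _big_config(50)
        cfg.bmi_bounds = (49.0, 50.0)
        with pytest.raises(RuntimeError):
            sample_demographics(cfg, rng)


class TestGenotypes:
    def test_hwe_homozygote_fraction_at_calibrated_frequency(self, rng):
        # *3/*3 fraction should approach q² = 0.865² ≈ 74.9%
        cfg = _big_config(10000)
        subj = sample_demographics(cfg, rng)
        _, truth, _ = sample_genotypes(cfg, subj, rng)
        g = truth[truth.rsid == "rs776746"]
        hom = ((g.allele1 == "G") & (g.allele2 == "G")).mean()
        assert hom == pytest.approx(0.748, abs=0.02)

    @pytest.mark.parametrize("freq,allele", [(0.0, "ref"), (1.0, "alt")])
    def test_degenerate_frequencies(self, rng, freq, allele):
        cfg = _big_config(200)
        cfg.allele_freqs = {r: freq for r in cfg.allele_freqs}
        subj = sample_demographics(cfg, rng)
        _, truth, _ = sample_genotypes(cfg, subj, rng)
        merged = truth.merge(pgx.load_definitions().panel, on="rsid")
        expected = merged["ref"] if allele == "ref" else merged["alt"]
        assert (merged["allele1"] == expected).all()
        assert (merged["allele2"] == expected).all()

    def test_missing_rate_masks_calls(self, rng):
        cfg = _big_config(500)
        cfg.missing_rate = 0.3
        subj = sample_demographics(cfg, rng)
        obs, truth, _ = sample_genotypes(cfg, subj, rng)
        frac = (obs["allele1"] == ".").mean()
        assert frac == pytest.approx(0.3, abs=0.02)
        assert not (truth["allele1"] == ".").any()

    def test_frequency_outside_unit_interval_rejected(self):
        cfg = _big_config(50)
        cfg.allele_freqs["rs776746"] = 1.2
        with pytest.raises(ValueError):
            cfg.validate()


class TestProfiles:
    def test_noise_free_profile_matches_closed_form(self, rng):
        params = PkParams(480.0, 6300.0, 2.5)
        prof = simulate_profile("S1", "0-48h", 80.0, params, rng,
                                residual_cv=0.0, lloq=0.0)
        expected = concentration(prof.times, 80.0, params)
        obs = np.nan_to_num(prof.concentrations)
        np.testing.assert_allclose(obs, expected, rtol=1e-9)

    def test_noise_free_peak_matches_analytic_to_six_digits(self):
        params = PkParams(480.0, 6300.0, 2.5)
        t = np.linspace(0, 48, 200001)
        c = concentration(t, 80.0, params)
        assert c.max() == pytest.approx(analytic_cmax(80.0, params), rel=1e-6)
        assert t[c.argmax()] == pytest.approx(analytic_tmax(params), abs=2e-3)

    def test_values_below_lloq_marked_bql(self, rng):
        params = PkParams(480.0, 6300.0, 2.5)
        prof = simulate_profile("S1", "0-48h", 80.0, params, rng,
                                residual_cv=0.0, lloq=5.0)
        clean = concentration(prof.times, 80.0, params)
        assert np.isnan(prof.concentrations[clean < 5.0]).all()

    def test_predose_sample_is_bql(self, rng):
        params = PkParams(480.0, 6300.0, 2.5)
        prof = simulate_profile("S1", "0-72h", 80.0, params, rng,
                                residual_cv=0.15, lloq=0.25)
        assert prof.times[0] == 0.0 and np.isnan(prof.concentrations[0])

    def test_schedules_have_study_sampling_density(self):
        assert len(SCHEDULES["0-48h"]) == 20 and SCHEDULES["0-48h"][-1] == 48.0
        assert len(SCHEDULES["0-72h"]) == 30 and SCHEDULES["0-72h"][-1] == 72.0


class TestCalibration:
    def test_reference_groups_have_unit_multiplier(self):
        mult = calibrate_effect_multipliers()
        assert mult[("SLCO1B1", "NF")] == 1.0
        assert mult[("CYP3A5", "*3/*3")] == 1.0

    def test_slco1b1_pf_multiplier_matches_exposure_fold(self):
        mult = calibrate_effect_multipliers()
        assert mult[("SLCO1B1", "PF")] == pytest.approx(0.446, abs=0.001)
        assert 1 / mult[("SLCO1B1", "PF")] == pytest.approx(2.24, abs=0.01)

    def test_cyp3a5_expresser_multiplier(self):
        mult = calibrate_effect_multipliers()
        assert mult[("CYP3A5", "*1/*1")] == pytest.approx(0.473, abs=0.001)


class TestDeterminism:
    def test_same_seed_same_cohort(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(small_config)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.profiles[0].concentrations,
                                      b.profiles[0].concentrations)

    def test_genotype_effects_flow_through_translation(self, small_cohort):
        # subjects whose clearance multiplier differs from 1 must carry a
        # non-reference level on at least one effect-bearing column
        phen = small_cohort.phenotypes
        truth = small_cohort.pk_truth
        non_ref = (
            (phen["slco1b1_phenotype"] != "NF")
            | (phen["cyp3a5_genotype"] != "*3/*3")
            | (phen["slc22a1_star2"] != "*1/*1")
            | (phen["slc22a1_star5"] != "*1/*1")
            | (phen["ugt2b7"] != "*1/*1")
        )
        has_mult = truth["cl_multiplier"] != 1.0
        assert (has_mult[has_mult].index == non_ref[non_ref].index).all()
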