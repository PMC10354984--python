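import numpy as np
import pandas as pd
import pytest

from methpanel.preprocess import m_to_beta
from methpanel.simulate import (
    PANEL_GENES,
    PANEL_SITE_COUNTS,
    SimulationConfig,
    generate_cohort,
    generate_height,
    generate_manifest,
    generate_methylation,
    simulate_dataset,
)
from conftest import small_config


class TestManifest:
    def test_panel_dimensions(self):
        counts = [PANEL_SITE_COUNTS[g] for g in PANEL_GENES]
        manifest = generate_manifest(28, counts, 600, seed=1)
        signal = manifest[manifest["probe_class"] == "signal"]
        assert len(signal) == 627
        assert signal["gene"].nunique() == 28

    def test_single_probe_section_deterministic(self):
        manifest = generate_manifest(1, 1, 1, seed=9)
        signal = manifest[manifest["probe_class"] == "signal"]
        assert len(signal) == 1
        assert signal["gene_section"].iloc[0] in ("Promoter", "Body", "5'UTR",
                                                  "1stExon", "3'UTR")

    def test_seeded_determinism(self):
        a = generate_manifest(5, 10, 20, seed=3)
        b = generate_manifest(5, 10, 20, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_positions_positive_and_controls_have_negative_category(self):
        manifest = generate_manifest(4, 8, 12, seed=2)
        assert (manifest["position"] > 0).all()
        ctrl = manifest[manifest["probe_class"] == "control"]
        assert "negative" in set(ctrl["control_category"])
        signal = manifest[manifest["probe_class"] == "signal"]
        assert (signal["control_category"] == "none").all()

    def test_gap_distribution_spans_1000bp(self):
        manifest = generate_manifest(10, 30, 5, seed=4)
        signal = manifest[manifest["probe_class"] == "signal"]
        gaps = signal.groupby("gene")["position"].apply(
            lambda s: np.diff(np.sort(s.to_numpy())))
        gaps = np.concatenate(gaps.to_numpy())
        assert (gaps < 1000).any() and (gaps > 1000).any()

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            generate_manifest(0, 5, 5, seed=1)
        with pytest.raises(ValueError):
            generate_manifest(2, [3], 5, seed=1)


class TestCohort:
    def test_shape_and_gc_rate(self):
        sheet = generate_cohort(818, 392, seed=7)
        assert len(sheet) == 1210
        pat = sheet[sheet["group"] == "patient"]
        gc = pat["gc_treatment"].astype(bool).sum()
        # generator parameter 210/818; allow 4 binomial sds
        se = np.sqrt(818 * (210 / 818) * (1 - 210 / 818))
        assert abs(gc - 210) < 4 * se

    def test_healthy_only(self):
        sheet = generate_cohort(0, 5, seed=1)
        assert len(sheet) == 5
        for col in ("pim3", "pelod", "strongkids", "randomisation_arm",
                    "diagnosis", "gc_treatment", "picu_los"):
            assert sheet[col].isna().all()

    def test_male_fraction_within_binomial_ci(self):
        sheet = generate_cohort(818, 0, seed=13)
        frac = (sheet["sex"] == "male").mean()
        se = np.sqrt(0.581 * (1 - 0.581) / 818)
        assert abs(frac - 0.581) < 4 * se

    def test_ages_nonnegative(self):
        sheet = generate_cohort(50, 50, seed=2)
        assert (sheet["age_at_followup"] > 0).all()
        assert (sheet["age_at_admission"] >= 0).all()

    def test_determinism(self):
        pd.testing.assert_frame_equal(generate_cohort(20, 10, seed=5),
                                      generate_cohort(20, 10, seed=5))


class TestMethylation:
    def test_null_config_no_group_difference(self):
        ds = simulate_dataset(small_config(seed=31))
        grp = (ds.sample_sheet["group"] == "patient").to_numpy()
        diff = ds.beta[grp].mean(axis=0) - ds.beta[~grp].mean(axis=0)
        # mean beta diff at every probe within sampling error of 0
        assert np.abs(diff).max() < 0.12
        assert np.abs(diff).mean() < 0.03

    def test_planted_shift_matches_logistic_transform(self):
        # big cohort so the empirical difference is tight
        cfg = small_config(n_patients=800, n_healthy=400, noise_sd_M=0.3,
                           batch_effect_sd=0.0, age_effect_sd_M=0.0,
                           sex_effect_sd_M=0.0,
                           planted_dmps={"cg00000001": -0.2}, seed=41)
        ds = simulate_dataset(cfg)
        grp = (ds.sample_sheet["group"] == "patient").to_numpy()
        emp = (ds.beta.loc[grp, "cg00000001"].mean()
               - ds.beta.loc[~grp, "cg00000001"].mean())
        # expected difference: average the logistic transform over the
        # probe's M distribution in each group (Monte Carlo closed form)
        rng = np.random.default_rng(0)
        base = ds.beta["cg00000001"]
        m0 = np.log2(np.clip(base[~grp], 1e-3, 1 - 1e-3)
                     / (1 - np.clip(base[~grp], 1e-3, 1 - 1e-3))).mean()
        draws = rng.normal(m0, 0.3, 200_000)
        expect = (m_to_beta(draws - 0.2) - m_to_beta(draws)).mean()
        assert emp < 0
        assert emp == pytest.approx(expect, abs=0.02)

    def test_beta_bounded_controls_positive(self, small_dataset):
        assert float(small_dataset.beta.min().min()) >= 0.0
        assert float(small_dataset.beta.max().max()) <= 1.0
        assert (small_dataset.control_intensities.to_numpy() > 0).all()

    def test_same_seed_bit_identical(self):
        a = simulate_dataset(small_config(seed=8))
        b = simulate_dataset(small_config(seed=8))
        assert np.array_equal(a.beta.to_numpy(), b.beta.to_numpy())
        assert np.array_equal(a.control_intensities.to_numpy(),
                              b.control_intensities.to_numpy())

    def test_unknown_planted_probe_raises(self):
        cfg = small_config(planted_dmps={"cg99999999": 0.5})
        with pytest.raises(KeyError):
            simulate_dataset(cfg)


class TestHeight:
    def test_zero_coefficients_no_association(self):
        ds = simulate_dataset(small_config(n_patients=300, seed=17))
        sheet = ds.sample_sheet
        mask = (sheet["group"] == "patient") & sheet["height_4y"].notna()
        m = np.log2(ds.beta.loc[mask, "cg00000001"]
                    / (1 - ds.beta.loc[mask, "cg00000001"]))
        y = sheet.loc[mask, "height_4y"]
        r = np.corrcoef(m, y)[0, 1]
        assert abs(r) < 0.15

    def test_planted_coefficient_recovered(self):
        from methpanel.dmp import build_design_matrix
        from methpanel.height import HEIGHT_COVARIATES, fit_height_model
        from methpanel.preprocess import beta_to_m

        cfg = small_config(n_patients=658, n_healthy=0, batch_effect_sd=0.0,
                           height_coefficients={"cg00000003": 3.0},
                           height_missing_fraction=0.0, seed=19)
        ds = simulate_dataset(cfg)
        sheet = ds.sample_sheet
        design = build_design_matrix(sheet, covariates=HEIGHT_COVARIATES,
                                     group_column=None)
        m = beta_to_m(ds.beta["cg00000003"].to_numpy())
        fit, coef, p = fit_height_model(sheet["height_4y"].to_numpy(), m, design)
        mi = fit.column_names.index("methylation")
        se = fit.stdev_unscaled[mi] * np.sqrt(fit.residual_variance)
        assert abs(coef - 3.0) < 2.5 * se
        assert p < 0.05

    def test_heights_positive_and_missing_fraction(self, small_dataset):
        sheet = small_dataset.sample_sheet
        pat = sheet[sheet["group"] == "patient"]
        heights = pat["height_4y"]
        assert (heights.dropna() > 0).all()
        assert heights.isna().mean() == pytest.approx(160 / 818, abs=0.05)
        assert sheet.loc[sheet["group"] == "healthy", "height_4y"].isna().all()

    def test_same_seed_identical_heights(self):
        a = simulate_dataset(small_config(seed=23)).sample_sheet["height_4y"]
        b = simulate_dataset(small_config(seed=23)).sample_sheet["height_4y"]
        pd.testing.assert_series_equal(a, b)
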