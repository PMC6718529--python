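"""Site-wise linear models against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methdmr.datamodel import BetaMatrix, ParameterError, SampleSheet
from methdmr.ewas import (
    age_slopes,
    bh_adjust,
    build_design,
    fit_interaction,
    fit_sitewise,
    moderate_variances,
)

from conftest import make_matrix


def _sheet(groups, ages, sexes, ids=None):
    ids = ids or [f"S{i}" for i in range(len(groups))]
    return SampleSheet(pd.DataFrame(
        {"group": groups, "age": ages, "sex": sexes}, index=ids))


class TestBuildDesign:
    def test_group_coding(self):
        sheet = _sheet(["control", "control", "case", "case"],
                       [20, 30, 40, 50], ["F", "M", "F", "M"])
        design = build_design(sheet, terms=("intercept", "group"))
        np.testing.assert_array_equal(design["group"], [0, 0, 1, 1])
        np.testing.assert_array_equal(design["intercept"], 1.0)

    def test_interaction_column_is_product(self):
        sheet = _sheet(["control", "control", "case", "case", "control", "case"],
                       [20, 30, 40, 50, 25, 35], ["F", "M", "F", "M", "M", "F"])
        design = build_design(sheet, interaction=True)
        np.testing.assert_array_equal(
            design["group:age"], design["group"] * design["age"])

    def test_single_sex_cohort_rank_error(self):
        sheet = _sheet(["control", "case", "control", "case"],
                       [20, 30, 40, 50], ["F", "F", "F", "F"])
        with pytest.raises(ParameterError, match="rank deficient"):
            build_design(sheet)


class TestFitSitewise:
    def test_two_group_closed_form(self):
        # y = (0, 1, 1, 2)/2 against group (0,0,1,1): textbook two-sample t
        sheet = _sheet(["control", "control", "case", "case"],
                       [20, 21, 22, 23], ["F", "F", "F", "F"])
        matrix = make_matrix(np.array([[0.0, 0.5, 0.5, 1.0]]),
                             sample_ids=sheet.sample_ids)
        design = build_design(sheet, terms=("intercept", "group"))
        res = fit_sitewise(matrix, design, moderate=False).iloc[0]
        assert res["effect"] == pytest.approx(0.5, abs=1e-12)
        assert res["se"] == pytest.approx(0.7071 / 2, abs=1e-4)
        assert res["stat"] == pytest.approx(1.4142, abs=1e-4)
        assert res["df"] == 2
        assert res["p"] == pytest.approx(0.2929, abs=1e-4)

    def test_matches_ols_oracle_probewise(self, rng):
        sheet = _sheet(["control"] * 5 + ["case"] * 5,
                       rng.integers(20, 50, 10), ["F", "M"] * 5)
        matrix = make_matrix(rng.uniform(0.2, 0.8, size=(30, 10)),
                             sample_ids=sheet.sample_ids)
        design = build_design(sheet)
        res = fit_sitewise(matrix, design, moderate=False)
        X = design.to_numpy()
        j = list(design.columns).index("group")
        for i in range(0, 30, 7):
            y = matrix.values.iloc[i].to_numpy()
            beta_hat, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
            dfres = 10 - X.shape[1]
            s2 = float(rss[0]) / dfres
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[j, j])
            t = beta_hat[j] / se
            p = 2 * stats.t.sf(abs(t), dfres)
            assert res["effect"].iloc[i] == pytest.approx(beta_hat[j], abs=1e-9)
            assert res["se"].iloc[i] == pytest.approx(se, abs=1e-9)
            assert res["p"].iloc[i] == pytest.approx(p, abs=1e-9)

    def test_sample_permutation_invariance(self, rng):
        sheet = _sheet(["control"] * 4 + ["case"] * 4,
                       rng.integers(20, 50, 8), ["F", "M"] * 4)
        matrix = make_matrix(rng.uniform(0.2, 0.8, size=(10, 8)),
                             sample_ids=sheet.sample_ids)
        design = build_design(sheet)
        base = fit_sitewise(matrix, design, moderate=False)
        perm = list(rng.permutation(sheet.sample_ids))
        matrix_p = BetaMatrix(matrix.values[perm])
        res = fit_sitewise(matrix_p, design, moderate=False)
        pd.testing.assert_frame_equal(base, res)

    def test_sign_convention_effect_and_stat_agree(self, rng):
        sheet = _sheet(["control"] * 4 + ["case"] * 4,
                       [20, 25, 30, 35] * 2, ["F", "M"] * 4)
        matrix = make_matrix(rng.uniform(0.2, 0.8, size=(50, 8)),
                             sample_ids=sheet.sample_ids)
        design = build_design(sheet)
        res = fit_sitewise(matrix, design, moderate=True)
        nonzero = res[res["stat"] != 0]
        assert (np.sign(nonzero["effect"]) == np.sign(nonzero["stat"])).all()
        assert ((res["q"] >= res["p"] - 1e-15) | (res["q"] == 1)).all()


class TestModeration:
    def test_identical_variances_noop(self):
        s2 = np.full(100, 0.04)
        params, moderated = moderate_variances(s2, d=10)
        assert params.d0 == np.inf
        np.testing.assert_allclose(moderated, 0.04, atol=1e-12)
        assert params.s0_sq == pytest.approx(0.04, abs=1e-12)

    def test_infinite_d0_limit_returns_prior_everywhere(self):
        # variance spread narrower than chi-square sampling noise -> d0 = inf
        rng = np.random.default_rng(0)
        s2 = np.exp(rng.normal(0, 0.01, 5000))
        params, moderated = moderate_variances(s2, d=4)
        assert params.d0 == np.inf
        np.testing.assert_allclose(moderated, params.s0_sq, atol=1e-12)

    def test_hierarchical_parameter_recovery(self):
        # true model: sigma^2 ~ s0^2 * d0 / chi2_{d0}, s^2 = sigma^2 chi2_d / d
        rng = np.random.default_rng(1)
        d0_true, s0_true, d = 4.0, 1.0, 16
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=10000)
        s2 = sigma2 * rng.chisquare(d, size=10000) / d
        params, moderated = moderate_variances(s2, d=d)
        assert params.s0_sq == pytest.approx(s0_true, rel=0.05)
        assert params.d0 == pytest.approx(d0_true, rel=0.25)
        # shrinkage blends towards the prior
        assert moderated.std() < s2.std()

    def test_moderated_variance_formula(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(8, 500) / 8
        params, moderated = moderate_variances(s2, d=8)
        if np.isfinite(params.d0):
            expected = (params.d0 * params.s0_sq + 8 * s2) / (params.d0 + 8)
            np.testing.assert_allclose(moderated, expected, atol=1e-12)


class TestBHAdjust:
    @pytest.mark.parametrize("p, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.04, 0.01], [0.04, 0.02]),
        ([0.5], [0.5]),
    ])
    def test_hand_applied_step_up(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.2])


class TestInteraction:
    def test_six_sample_brute_force_oracle(self):
        sheet = _sheet(["control"] * 3 + ["case"] * 3,
                       [20, 30, 40, 20, 30, 40], ["F", "F", "F", "F", "F", "F"])
        y = np.array([0.30, 0.35, 0.38, 0.33, 0.45, 0.55])
        matrix = make_matrix(y[None, :], sample_ids=sheet.sample_ids)
        design = build_design(sheet, terms=("intercept", "group", "age"),
                              interaction=True)
        res, _n = fit_interaction(matrix, design, moderate=False)
        X = design.to_numpy()
        beta_hat = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta_hat
        s2 = resid @ resid / (6 - 4)
        cov = s2 * np.linalg.inv(X.T @ X)
        j = list(design.columns).index("group:age")
        t = beta_hat[j] / np.sqrt(cov[j, j])
        p = 2 * stats.t.sf(abs(t), 2)
        row = res.iloc[0]
        assert row["effect"] == pytest.approx(beta_hat[j], abs=1e-12)
        assert row["stat"] == pytest.approx(t, abs=1e-9)
        assert row["p"] == pytest.approx(p, abs=1e-9)

    def test_single_age_cohort_rejected(self):
        sheet = _sheet(["control", "control", "case", "case"],
                       [30, 30, 30, 30], ["F", "M", "F", "M"])
        design = pd.DataFrame({
            "intercept": 1.0,
            "group": [0, 0, 1, 1],
            "age": [30, 30, 30, 30],
            "group:age": [0, 0, 30, 30],
        }, index=sheet.sample_ids)
        matrix = make_matrix(np.full((3, 4), 0.5), sample_ids=sheet.sample_ids)
        with pytest.raises(ParameterError, match="unidentifiable"):
            fit_interaction(matrix, design)


class TestAgeSlopes:
    def test_noiseless_injected_slope_recovered_exactly(self):
        from methdmr import synthetic
        manifest = synthetic.generate_manifest(50, n_chroms=1, seed=1,
                                               snp_fraction=0.0)
        sheet = synthetic.generate_cohort(8, 8, seed=2)
        baselines = pd.Series(0.0, index=manifest.sort_genomic().probe_ids)
        truth = synthetic.generate_truth(
            manifest, n_dmrs=0, seed=3, n_age_probes=10,
            age_slope_range=(0.0014, 0.0014))
        matrix, _ = synthetic.simulate_betas(
            manifest, sheet, truth, baselines=baselines,
            noise_sd_logit=0.0, measurement_sd_beta=0.0, seed=4)
        design = build_design(sheet)
        res = age_slopes(matrix, design, moderate=False)
        injected = list(truth.age_slopes)
        np.testing.assert_allclose(
            res.loc[injected, "slope_pp_per_year"], 0.14, atol=1e-9)
        others = [p for p in res.index if p not in truth.age_slopes]
        np.testing.assert_allclose(
            res.loc[others, "slope_pp_per_year"], 0.0, atol=1e-9)

    def test_age_shift_only_moves_intercept(self, rng):
        sheet = _sheet(["control"] * 4 + ["case"] * 4,
                       [20, 30, 40, 50, 20, 30, 40, 50], ["F", "M"] * 4)
        matrix = make_matrix(rng.uniform(0.2, 0.8, size=(20, 8)),
                             sample_ids=sheet.sample_ids)
        design = build_design(sheet)
        base = age_slopes(matrix, design, moderate=False)
        shifted = design.copy()
        shifted["age"] = shifted["age"] + 100
        res = age_slopes(matrix, shifted, moderate=False)
        np.testing.assert_allclose(base["slope_pp_per_year"],
                                   res["slope_pp_per_year"], atol=1e-9)
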