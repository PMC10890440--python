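import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from glycomet import (DataError, ScanSpec, fit_interaction_model, run_scan,
                      standardize, storey_qvalues, sum_normalize)
from glycomet.association import InteractionScanner, estimate_pi0

from conftest import make_matrix


def _three_group_data(seed=0, n=20, slopes=(0.5, -1.0, 2.0), noise=0.0):
    rng = np.random.default_rng(seed)
    groups = np.repeat(["IMI", "BAND", "RYGB"], n)
    x = rng.normal(size=3 * n)
    y = np.concatenate([
        s * x[i * n:(i + 1) * n] + noise * rng.normal(size=n)
        for i, s in enumerate(slopes)
    ])
    return y, x, groups


class TestFitInteractionModel:
    def test_two_group_toy_reproduces_published_contrast(self):
        # within-group slopes 1.74 (IMI) and 17.38 (RYGB): the interaction
        # contrast must be their difference, 15.64
        x = np.tile(np.linspace(-1, 1, 15), 2)
        y = np.concatenate([1.74 * x[:15], 17.38 * x[15:]])
        rec = fit_interaction_model(y, x, ["IMI"] * 15 + ["RYGB"] * 15)
        assert rec.contrasts["RYGB_vs_IMI"][0] == pytest.approx(15.64, abs=1e-8)

    def test_contrast_identity_holds_for_all_pairs(self):
        y, x, groups = _three_group_data(seed=1, noise=0.3)
        rec = fit_interaction_model(y, x, groups)
        bs = {g: rec.beta_star[g][0] for g in ("IMI", "BAND", "RYGB")}
        assert rec.contrasts["RYGB_vs_IMI"][0] == pytest.approx(
            bs["RYGB"] - bs["IMI"], abs=1e-10)
        assert rec.contrasts["RYGB_vs_BAND"][0] == pytest.approx(
            bs["RYGB"] - bs["BAND"], abs=1e-10)
        assert rec.contrasts["BAND_vs_IMI"][0] == pytest.approx(
            bs["BAND"] - bs["IMI"], abs=1e-10)

    def test_null_with_zero_noise_gives_exactly_zero_contrast(self):
        y, x, groups = _three_group_data(seed=2, slopes=(1.3, 1.3, 1.3), noise=0.0)
        rec = fit_interaction_model(y, x, groups)
        for est, _, _ in rec.contrasts.values():
            assert abs(est) < 1e-10

    def test_matches_separate_per_group_fits(self):
        # oracle: per-group OLS slopes, pooled residual variance, and the
        # delta-method contrast SE (group blocks are independent)
        y, x, groups = _three_group_data(seed=3, noise=0.7)
        rec = fit_interaction_model(y, x, groups)
        n, k = len(y), 6
        rss, slopes, se_unit = 0.0, {}, {}
        for g in ("IMI", "BAND", "RYGB"):
            sel = groups == g
            X = np.column_stack([np.ones(sel.sum()), x[sel]])
            beta, res, *_ = np.linalg.lstsq(X, y[sel], rcond=None)
            slopes[g] = beta[1]
            rss += float(((y[sel] - X @ beta) ** 2).sum())
            se_unit[g] = np.sqrt(np.linalg.inv(X.T @ X)[1, 1])
        sigma2 = rss / (n - k)
        for g in slopes:
            est, se = rec.beta_star[g]
            assert est == pytest.approx(slopes[g], abs=1e-10)
            assert se == pytest.approx(np.sqrt(sigma2) * se_unit[g], abs=1e-10)
        est, se, p = rec.contrasts["RYGB_vs_IMI"]
        se_oracle = np.sqrt(sigma2 * (se_unit["RYGB"] ** 2 + se_unit["IMI"] ** 2))
        assert se == pytest.approx(se_oracle, abs=1e-10)
        t = (slopes["RYGB"] - slopes["IMI"]) / se_oracle
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - k), abs=1e-12)

    def test_exposure_scaling_equivariance(self):
        y, x, groups = _three_group_data(seed=4, noise=0.5)
        rec1 = fit_interaction_model(y, x, groups)
        rec2 = fit_interaction_model(y, 10.0 * x, groups)
        for g in rec1.beta_star:
            assert rec2.beta_star[g][0] == pytest.approx(
                rec1.beta_star[g][0] / 10.0, rel=1e-10)
        for c in rec1.contrasts:
            assert rec2.contrasts[c][0] == pytest.approx(
                rec1.contrasts[c][0] / 10.0, rel=1e-10)

    def test_covariates_with_zero_effect_leave_slopes_unbiased(self):
        rng = np.random.default_rng(55)
        y, x, groups = _three_group_data(seed=5, noise=0.0)
        cov = pd.DataFrame({"age": rng.normal(size=len(y))})
        rec = fit_interaction_model(y, x, groups, covariates=cov)
        assert rec.beta_star["RYGB"][0] == pytest.approx(2.0, abs=1e-8)

    def test_small_or_degenerate_groups_raise(self):
        with pytest.raises(DataError, match="fewer than 3"):
            fit_interaction_model([1, 2, 3, 4], [1, 2, 3, 4],
                                  ["IMI", "IMI", "IMI", "RYGB"])
        x = np.r_[np.ones(10), np.arange(10)]
        with pytest.raises(DataError, match="constant exposure"):
            fit_interaction_model(np.arange(20.0), x, ["IMI"] * 10 + ["RYGB"] * 10)

    def test_rank_deficient_covariates_raise(self):
        y, x, groups = _three_group_data(seed=6, noise=0.2)
        cov = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(DataError, match="rank"):
            fit_interaction_model(y, x, groups, covariates=cov)

    def test_missing_reference_group_raises(self):
        with pytest.raises(DataError, match="reference"):
            fit_interaction_model([1.0] * 6, [1, 2, 3, 1, 2, 3],
                                  ["BAND"] * 3 + ["RYGB"] * 3, reference="IMI")


class TestStoreyQvalues:
    def test_all_ones_stay_one(self):
        assert np.allclose(storey_qvalues(np.ones(10)), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_equals_bh_when_pi0_is_one(self, ps):
        p = np.asarray(ps)
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh, atol=1e-12)

    def test_monotone_in_p_and_never_below_scaled_bh(self):
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(0, 0.01, 120), rng.uniform(0, 1, 380)])
        pi0 = estimate_pi0(p)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        bh = multipletests(p, method="fdr_bh")[1]
        assert (q >= pi0 * bh - 1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_signal_plus_flat_null_mixture_detected(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([np.full(50, 0.001), rng.uniform(0.5, 1.0, 50)])
        q = storey_qvalues(p)
        assert (q[:50] < 0.05).all()

    def test_out_of_range_p_raises(self):
        with pytest.raises(DataError):
            storey_qvalues([0.5, 1.2])

    def test_short_vectors_fall_back_to_pi0_one(self):
        assert estimate_pi0(np.random.default_rng(0).uniform(size=50)) == 1.0


class TestRunScan:
    def test_single_metabolite_q_equals_p(self):
        rng = np.random.default_rng(9)
        vals = rng.lognormal(2, 0.4, size=(60, 1))
        mat = make_matrix(vals, [True], ["IMI"] * 10 + ["BAND"] * 10 + ["RYGB"] * 10)
        cohort = pd.DataFrame({
            "group": ["IMI"] * 10 + ["BAND"] * 10 + ["RYGB"] * 10,
            "female": rng.integers(0, 2, 30),
            "age": rng.normal(50, 8, 30),
            "bmi_baseline": rng.normal(45, 5, 30),
            "weight_baseline": rng.normal(120, 10, 30),
            "weight_year1": rng.normal(100, 10, 30),
            "fpg_baseline": rng.normal(100, 10, 30),
            "fpg_year1": rng.normal(95, 10, 30),
            "hba1c_baseline": rng.normal(6, 0.5, 30),
            "hba1c_year1": rng.normal(5.5, 0.5, 30),
        }, index=mat.participants)
        table = run_scan(cohort, mat, ScanSpec("fpg", "baseline"))
        assert len(table) == 1
        row = table.iloc[0]
        assert row["q_rygb_vs_imi"] == pytest.approx(row["p_rygb_vs_imi"])

    def test_planted_effect_attains_smallest_q(self, small_cohort):
        cohort, matrix, _ = small_cohort
        table = run_scan(cohort, sum_normalize(matrix), ScanSpec("fpg", "baseline"))
        assert table["q_rygb_vs_imi"].idxmin() == "M0006"
        # identity between contrast and slope difference holds scan-wide
        gap = (table["beta_rygb_vs_imi"]
               - (table["beta_star_rygb"] - table["beta_star_imi"])).abs().max()
        assert gap < 1e-10

    def test_failed_fits_flagged_not_dropped(self, small_cohort):
        cohort, matrix, _ = small_cohort
        mat = sum_normalize(matrix).copy()
        mat.values["M0030"] = 1.0  # constant exposure cannot be standardized
        table = run_scan(cohort, mat, ScanSpec("fpg", "baseline"))
        assert "M0030" in table.index
        assert table.loc["M0030", "error"] != ""
        assert np.isnan(table.loc["M0030", "q_rygb_vs_imi"])

    def test_scanner_estimator_facade(self, small_cohort):
        cohort, matrix, _ = small_cohort
        sc = InteractionScanner(outcome="fpg", exposure="change").fit(
            sum_normalize(matrix), cohort)
        assert sc.results_.shape[0] == matrix.n_metabolites
        assert sc.get_params()["outcome"] == "fpg"

    def test_volcano_view_extracts_one_contrast(self, small_cohort):
        from glycomet.association import volcano_table

        cohort, matrix, _ = small_cohort
        table = run_scan(cohort, sum_normalize(matrix), ScanSpec("fpg", "baseline"))
        v = volcano_table(table, "RYGB_vs_IMI")
        assert list(v.columns) == ["known", "beta", "p", "q"]
        assert np.allclose(v["beta"], table["beta_rygb_vs_imi"], equal_nan=True)
        with pytest.raises(DataError):
            volcano_table(table, "SLEEVE_vs_IMI")

    def test_empty_metabolite_set_raises(self, small_cohort):
        cohort, matrix, _ = small_cohort
        empty = matrix.subset_features([])
        with pytest.raises(DataError):
            run_scan(cohort, empty, ScanSpec("fpg", "baseline"))
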