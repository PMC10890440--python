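import numpy as np
import pandas as pd
import pytest

from glycomet import (DataError, ModuleDetector, NetworkConfig, adjacency,
                      choose_soft_power, detect_modules, hub_metabolite,
                      mdc_permutation_test, mdc_statistic, tom_similarity)
from glycomet.evaluation import tom_brute_force
from glycomet.network import scale_free_fit


def _equicorr(rng, n, m, rho):
    g = rng.standard_normal((n, 1))
    return np.sqrt(rho) * g + np.sqrt(1 - rho) * rng.standard_normal((n, m))


class TestAdjacency:
    def test_perfect_correlation_is_one_at_any_power(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 3 * x + 1})
        for power in (1, 6, 12):
            assert adjacency(X, power).loc["a", "b"] == pytest.approx(1.0)

    def test_exact_half_correlation_to_the_sixth(self):
        u = np.array([1.0, -1.0, 1.0, -1.0]) / 2
        v = np.array([1.0, 1.0, -1.0, -1.0]) / 2
        X = pd.DataFrame({"a": u, "b": 0.5 * u + np.sqrt(0.75) * v})
        assert adjacency(X, 6).loc["a", "b"] == pytest.approx(0.5 ** 6, abs=1e-12)

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 5)))
        A = adjacency(X, 6)
        for i in range(5):
            for j in range(5):
                r = np.corrcoef(X.iloc[:, i], X.iloc[:, j])[0, 1]
                expect = 1.0 if i == j else abs(r) ** 6
                assert A.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_constant_column_raises_with_name(self):
        X = pd.DataFrame({"ok": np.arange(5.0), "flat": np.ones(5)})
        with pytest.raises(DataError, match="flat"):
            adjacency(X, 6)

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 6)), columns=list("abcdef"))
        perm = list("dbface")
        A = adjacency(X, 4)
        Ap = adjacency(X[perm], 4)
        pd.testing.assert_frame_equal(Ap, A.loc[perm, perm])


class TestTOM:
    def test_complete_graph_gives_unit_overlap(self):
        a = np.ones((3, 3))
        assert np.allclose(tom_similarity(a).to_numpy(), 1.0)

    def test_empty_graph_gives_zero_off_diagonal(self):
        t = tom_similarity(np.eye(4)).to_numpy()
        assert np.allclose(t - np.eye(4), 0.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = rng.random((6, 6))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            got = tom_similarity(a).to_numpy()
            assert np.abs(got - tom_brute_force(a)).max() < 1e-12

    def test_asymmetric_input_raises(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(DataError):
            tom_similarity(a)

    def test_entries_in_unit_interval_and_symmetric(self):
        rng = np.random.default_rng(3)
        a = rng.random((8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        t = tom_similarity(a).to_numpy()
        assert ((t >= 0) & (t <= 1)).all() and np.allclose(t, t.T)


class TestSoftPower:
    def test_fallback_when_no_power_fits(self):
        # all features nearly identical: connectivity has no spread, the
        # scale-free fit is degenerate at every power
        rng = np.random.default_rng(4)
        base = rng.standard_normal(50)
        X = pd.DataFrame({f"f{i}": base + 1e-6 * rng.standard_normal(50)
                          for i in range(12)})
        with pytest.warns(RuntimeWarning, match="falling back"):
            assert choose_soft_power(X) == 6

    def test_deterministic_and_in_range_on_hub_data(self):
        rng = np.random.default_rng(5)
        center = rng.standard_normal(100)
        cols = {"hub": center}
        for i in range(20):
            cols[f"leaf{i}"] = 0.9 * center + np.sqrt(1 - 0.81) * rng.standard_normal(100)
        for i in range(20):
            cols[f"noise{i}"] = rng.standard_normal(100)
        X = pd.DataFrame(cols)
        p1 = choose_soft_power(X)
        assert 1 <= p1 <= 20
        assert choose_soft_power(X) == p1

    def test_scale_free_fit_matches_binned_regression_oracle(self):
        rng = np.random.default_rng(6)
        k = rng.pareto(2.0, size=300) + 0.5
        r2, slope = scale_free_fit(k, n_bins=10)
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        xs, ys = [], []
        for b in range(10):
            sel = idx == b
            if sel.sum() and k[sel].mean() > 0:
                xs.append(np.log10(k[sel].mean()))
                ys.append(np.log10(sel.mean()))
        slope_o, _ = np.polyfit(xs, ys, 1)
        r_o = np.corrcoef(xs, ys)[0, 1]
        assert r2 == pytest.approx(r_o ** 2, abs=1e-12)
        assert slope == pytest.approx(slope_o, abs=1e-12)

    def test_too_few_features_raise(self):
        with pytest.raises(DataError):
            choose_soft_power(pd.DataFrame(np.random.default_rng(0).normal(size=(50, 5))))


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(np.hstack([
            _equicorr(rng, 100, 10, 0.8),
            _equicorr(rng, 100, 10, 0.8),
            rng.standard_normal((100, 20)),
        ]))
        det = ModuleDetector(soft_power=4).fit(X)
        # the two largest modules are exactly the planted blocks
        assert set(det.modules_) >= {"turquoise", "blue"}
        blocks = [set(range(10)), set(range(10, 20))]
        found = [set(det.modules_["turquoise"]), set(det.modules_["blue"])]
        assert found[0] in blocks and found[1] in blocks and found[0] != found[1]

    def test_independent_features_mostly_grey(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.standard_normal((100, 40)))
        det = ModuleDetector(soft_power=6).fit(X)
        assert (det.assignment_ == "grey").mean() >= 0.9

    def test_single_tight_block_forms_one_module(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(_equicorr(rng, 100, 20, 0.9))
        det = ModuleDetector(soft_power=4).fit(X)
        assert len(det.modules_) == 1
        assert len(det.modules_["turquoise"]) >= 18

    def test_all_grey_warns_but_returns(self):
        tom = pd.DataFrame(np.eye(6), index=list("abcdef"), columns=list("abcdef"))
        with pytest.warns(RuntimeWarning, match="grey"):
            labels = detect_modules(tom, 0.5, 5)
        assert (labels == "grey").all()

    def test_config_validation(self):
        with pytest.raises(DataError):
            NetworkConfig(tree_cut_height=1.5)
        with pytest.raises(DataError):
            NetworkConfig(n_perm=10)


class TestHub:
    def test_star_center_has_max_connectivity(self):
        rng = np.random.default_rng(10)
        center = rng.standard_normal(2000)
        cols = {"center": center}
        for i in range(6):
            cols[f"leaf{i}"] = 0.9 * center + np.sqrt(0.19) * rng.standard_normal(2000)
        A = adjacency(pd.DataFrame(cols), 2)
        assert hub_metabolite(A, list(cols)) == "center"

    def test_two_member_tie_breaks_lexicographically(self):
        A = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=["b", "a"], columns=["b", "a"])
        assert hub_metabolite(A, ["b", "a"]) == "a"

    def test_matches_argmax_oracle(self):
        rng = np.random.default_rng(11)
        n = 7
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        ids = [f"m{i}" for i in range(n)]
        A = pd.DataFrame(a, index=ids, columns=ids)
        conn = {i: sum(a[ids.index(i), ids.index(j)] for j in ids if j != i) for i in ids}
        assert hub_metabolite(A, ids) == max(sorted(ids), key=lambda i: conn[i])

    def test_empty_module_raises(self):
        A = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(DataError):
            hub_metabolite(A, [])


class TestMDC:
    def test_identical_groups_give_exactly_zero(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        assert mdc_statistic(X, X, list("abcde"), 6) == 0.0

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(13)
        XA = pd.DataFrame(_equicorr(rng, 40, 5, 0.6), columns=list("abcde"))
        XB = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        t = mdc_statistic(XA, XB, list("abcde"), 2)
        assert mdc_statistic(XB, XA, list("abcde"), 2) == pytest.approx(-t, abs=1e-12)

    def test_equicorrelation_expectation(self):
        # module of 5 => 10 pairs; rho 0.8 vs 0.0 at power 1 => ~8
        rng = np.random.default_rng(14)
        XA = pd.DataFrame(_equicorr(rng, 200, 5, 0.8), columns=list("abcde"))
        XB = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        assert mdc_statistic(XA, XB, list("abcde"), 1) == pytest.approx(8.0, abs=1.0)

    def test_missing_member_raises(self):
        rng = np.random.default_rng(15)
        XA = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        XB = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abd"))
        with pytest.raises(DataError, match="missing"):
            mdc_statistic(XA, XB, list("abc"), 2)

    def test_permutation_floor_and_determinism(self):
        rng = np.random.default_rng(16)
        cols = [f"m{i}" for i in range(8)]
        XA = pd.DataFrame(_equicorr(rng, 60, 8, 0.9), columns=cols)
        XB = pd.DataFrame(rng.normal(size=(60, 8)), columns=cols)
        r1 = mdc_permutation_test(XA, XB, cols, 1, n_perm=1000, rng=123)
        assert r1.perm_p == pytest.approx(1.0 / 1001.0)
        assert r1.call == "GOC"
        r2 = mdc_permutation_test(XA, XB, cols, 1, n_perm=1000, rng=123)
        assert r2.perm_p == r1.perm_p and r2.statistic == r1.statistic

    def test_planted_goc_module_recovered_end_to_end(self):
        # simulate -> normalize -> residualize -> detect -> MDC: the module
        # co-regulated only in RYGB must be found and called GOC vs IMI
        from glycomet.evaluation import end_to_end_goc_recovery

        r = end_to_end_goc_recovery(seed=31, n_seeds=50)
        assert r["recovery_rate"] >= 0.9

    def test_small_groups_rejected(self):
        rng = np.random.default_rng(17)
        cols = list("abc")
        X = pd.DataFrame(rng.normal(size=(4, 3)), columns=cols)
        Y = pd.DataFrame(rng.normal(size=(20, 3)), columns=cols)
        with pytest.raises(DataError, match=">= 5 samples"):
            mdc_permutation_test(X, Y, cols, 1, n_perm=100)
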