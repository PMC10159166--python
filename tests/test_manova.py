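"""MANOVA scatter decomposition, trace statistics and F approximations."""

import numpy as np
import pytest

from plantsig import manova as M


def _groups(rng, n1=40, n2=45, offset=(0.0, 0.0, 0.0)):
    a = rng.standard_normal((n1, 3))
    b = rng.standard_normal((n2, 3)) + np.asarray(offset)
    return [M.GroupedMetrics("a", a), M.GroupedMetrics("b", b)]


class TestScatter:
    def test_identical_groups_zero_between(self):
        x = np.random.default_rng(0).standard_normal((30, 3))
        w, b = M.scatter_matrices([M.GroupedMetrics("a", x), M.GroupedMetrics("b", x)])
        assert np.allclose(b, 0.0, atol=1e-10)

    def test_single_coordinate_offset_rank_one_between(self):
        rng = np.random.default_rng(1)
        groups = _groups(rng, offset=(2.0, 0.0, 0.0))
        _, b = M.scatter_matrices(groups)
        assert np.linalg.matrix_rank(b, tol=1e-8) == 1

    def test_within_plus_between_equals_total(self):
        rng = np.random.default_rng(2)
        groups = _groups(rng)
        w, b = M.scatter_matrices(groups)
        all_x = np.vstack([g.values for g in groups])
        dev = all_x - all_x.mean(axis=0)
        assert np.allclose(w + b, dev.T @ dev, atol=1e-8)


class TestEigenvalues:
    def test_zero_between_all_zero(self):
        x = np.random.default_rng(3).standard_normal((30, 3))
        w, b = M.scatter_matrices([M.GroupedMetrics("a", x), M.GroupedMetrics("b", x)])
        assert np.allclose(M.manova_eigenvalues(w, b), 0.0, atol=1e-8)

    def test_two_groups_single_nonzero_eigenvalue(self):
        rng = np.random.default_rng(4)
        w, b = M.scatter_matrices(_groups(rng, offset=(1.0, 0.5, 0.0)))
        lam = M.manova_eigenvalues(w, b)
        assert lam[0] > 0
        assert np.allclose(lam[1:], 0.0, atol=1e-8)

    def test_agrees_with_generalized_eigenproblem(self):
        from scipy.linalg import eigh

        rng = np.random.default_rng(5)
        a = rng.standard_normal((3, 3))
        w = a @ a.T + 3 * np.eye(3)
        c = rng.standard_normal((3, 2))
        b = c @ c.T
        lam = M.manova_eigenvalues(w, b)
        expected = np.sort(eigh(b, w, eigvals_only=True))[::-1]
        assert np.allclose(lam, np.clip(expected, 0, None), atol=1e-10)


class TestTraceStatistics:
    def test_printed_two_group_row(self):
        # single discriminant eigenvalue of the two-group comparison
        s = M.trace_statistics([0.051001])
        assert round(s["pillai"], 6) == 0.048526
        assert round(s["wilks"], 6) == 0.951474
        assert s["hotelling"] == pytest.approx(0.051001)
        assert s["roy"] == pytest.approx(0.051001)

    def test_printed_intercept_row(self):
        s = M.trace_statistics([9.448972])
        assert round(s["pillai"], 6) == 0.904297
        assert round(s["wilks"], 6) == 0.095703

    def test_printed_groupwise_rows(self):
        assert round(M.trace_statistics([39.23723])["pillai"], 6) == 0.975147
        assert round(M.trace_statistics([38.03857])["wilks"], 6) == 0.025616

    def test_zero_eigenvalue(self):
        s = M.trace_statistics([0.0])
        assert s == {"pillai": 0.0, "hotelling": 0.0, "wilks": 1.0, "roy": 0.0}

    def test_single_variate_identities(self):
        # for s = 1: V = U/(1+U), Wilks = 1 - V, Roy = U
        for lam in (0.051001, 9.448972, 39.23723, 38.03857, 0.7):
            s = M.trace_statistics([lam])
            assert s["pillai"] == pytest.approx(s["hotelling"] / (1 + s["hotelling"]))
            assert s["wilks"] == pytest.approx(1 - s["pillai"])
            assert s["roy"] == pytest.approx(s["hotelling"])


class TestOneWay:
    def test_matches_two_sample_hotelling_t2(self):
        rng = np.random.default_rng(6)
        groups = _groups(rng, offset=(0.5, 0.0, 0.2))
        res = M.oneway_manova(groups)
        a, b = groups[0].values, groups[1].values
        n1, n2, p = len(a), len(b), 3
        d = a.mean(0) - b.mean(0)
        sp = ((n1 - 1) * np.cov(a, rowvar=False)
              + (n2 - 1) * np.cov(b, rowvar=False)) / (n1 + n2 - 2)
        t2 = (n1 * n2 / (n1 + n2)) * d @ np.linalg.solve(sp, d)
        f = t2 * (n1 + n2 - p - 1) / ((n1 + n2 - 2) * p)
        for key in ("pillai", "wilks", "hotelling", "roy"):
            assert res.f_stats[key] == pytest.approx(f, abs=1e-8)
            assert res.df1[key] == p
            assert res.df2[key] == n1 + n2 - p - 1

    def test_matches_statsmodels(self):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(7)
        groups = _groups(rng, n1=35, n2=50, offset=(0.4, -0.2, 0.1))
        res = M.oneway_manova(groups)
        frame = pd.DataFrame(np.vstack([g.values for g in groups]),
                             columns=["x", "y", "z"])
        frame["g"] = ["a"] * 35 + ["b"] * 50
        sm = MANOVA.from_formula("x + y + z ~ g", data=frame).mv_test()
        table = sm.results["g"]["stat"]
        assert res.statistics["wilks"] == pytest.approx(
            table.loc["Wilks' lambda", "Value"])
        assert res.statistics["pillai"] == pytest.approx(
            table.loc["Pillai's trace", "Value"])
        assert res.f_stats["wilks"] == pytest.approx(
            table.loc["Wilks' lambda", "F Value"])
        assert res.p_values["pillai"] == pytest.approx(
            table.loc["Pillai's trace", "Pr > F"])

    def test_three_group_statsmodels_cross_check(self):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(8)
        groups = [
            M.GroupedMetrics(lbl, rng.standard_normal((n, 3)) + off)
            for lbl, n, off in (("a", 30, 0.0), ("b", 35, 0.3), ("c", 25, -0.2))
        ]
        res = M.oneway_manova(groups)
        frame = pd.DataFrame(np.vstack([g.values for g in groups]),
                             columns=["x", "y", "z"])
        frame["g"] = ["a"] * 30 + ["b"] * 35 + ["c"] * 25
        table = MANOVA.from_formula("x + y + z ~ g", data=frame).mv_test()
        stat = table.results["g"]["stat"]
        for mine, theirs in (("wilks", "Wilks' lambda"),
                             ("pillai", "Pillai's trace"),
                             ("hotelling", "Hotelling-Lawley trace")):
            assert res.statistics[mine] == pytest.approx(stat.loc[theirs, "Value"])
            assert res.f_stats[mine] == pytest.approx(
                stat.loc[theirs, "F Value"], rel=1e-6)

    def test_strong_effect_tiny_p(self):
        rng = np.random.default_rng(9)
        groups = _groups(rng, n1=100, n2=100, offset=(1.0, 1.0, 1.0))
        res = M.oneway_manova(groups)
        assert res.p_values["wilks"] < 1e-6

    def test_affine_invariance_of_pillai_and_wilks(self):
        rng = np.random.default_rng(10)
        groups = _groups(rng, offset=(0.5, 0.1, 0.0))
        res1 = M.oneway_manova(groups)
        a_mat = np.array([[2.0, 0.3, 0.0], [0.0, 1.5, -0.2], [0.1, 0.0, 0.7]])
        shifted = [
            M.GroupedMetrics(g.label, g.values @ a_mat.T + np.array([1.0, -2.0, 0.5]))
            for g in groups
        ]
        res2 = M.oneway_manova(shifted)
        assert res1.statistics["pillai"] == pytest.approx(res2.statistics["pillai"])
        assert res1.statistics["wilks"] == pytest.approx(res2.statistics["wilks"])

    def test_type_one_error_calibration_quick(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            res = M.oneway_manova(_groups(rng, n1=25, n2=25))
            rejections += res.p_values["wilks"] < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.03


class TestGroupLocation:
    def test_centered_group_zero_statistics(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((40, 3))
        x -= x.mean(axis=0)  # exactly centered at the reference
        res = M.group_location_test(M.GroupedMetrics("g", x))
        assert res.statistics["pillai"] == pytest.approx(0.0, abs=1e-12)
        assert res.statistics["wilks"] == pytest.approx(1.0)

    def test_matches_textbook_one_sample_t2(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal((25, 3)) + 0.4
        res = M.group_location_test(M.GroupedMetrics("g", x))
        n, p = 25, 3
        m = x.mean(axis=0)
        t2 = n * m @ np.linalg.solve(np.cov(x, rowvar=False), m)
        f = t2 * (n - p) / ((n - 1) * p)
        assert res.f_stats["pillai"] == pytest.approx(f, abs=1e-8)
        assert res.eigenvalues[0] == pytest.approx(t2 / (n - 1))

    def test_eigenvalue_identity_with_trace_statistics(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((30, 3)) + 0.2
        res = M.group_location_test(M.GroupedMetrics("g", x))
        lam = res.eigenvalues[0]
        assert res.statistics["pillai"] == pytest.approx(lam / (1 + lam))


class TestModelResults:
    def test_two_group_fit_summary(self):
        rng = np.random.default_rng(15)
        groups = _groups(rng, n1=30, n2=30, offset=(0.3, 0.0, 0.0))
        results = M.Manova(groups).fit()
        summ = results.summary()
        # one-way (4 rows) + two location tests (4 each) + paired (4)
        assert len(summ) == 16
        assert {"Statistic", "Value", "F", "df1", "df2", "p"} <= set(summ.columns)
        assert results.paired is not None

    def test_null_p_values_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(16)
        pvals = [
            M.oneway_manova(_groups(rng, n1=20, n2=20)).p_values["wilks"]
            for _ in range(300)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
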