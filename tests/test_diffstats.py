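import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import ceburden as cb
from ceburden.diffstats import bicor, bicor_matrix


def bicor_oracle(x, y):
    """Independently coded biweight midcorrelation (complete pairs only)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]

    def weighted(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (9.0 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        return (v - med) * w

    ax, ay = weighted(x), weighted(y)
    if ax is None or ay is None:
        return stats.pearsonr(x, y).statistic
    return float(np.dot(ax, ay) / np.sqrt(np.dot(ax, ax) * np.dot(ay, ay)))


class TestBicor:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).normal(size=25)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(10, 40)
            x, y = rng.normal(size=(2, n))
            assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-10)

    def test_pairwise_complete_handling(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 40))
        x[[1, 5, 9]] = np.nan
        y[[2, 7]] = np.nan
        assert bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-10)

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0] * 10 + [2.0])  # median absolute deviation 0
        y = np.arange(11.0)
        assert bicor(x, y) == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-10)

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError):
            bicor([1.0, 2.0], [3.0, 4.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=6, max_size=30),
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_symmetry_bounds_and_affine_invariance(self, xs, seed, scale, shift):
        x = np.array(xs)
        y = np.random.default_rng(seed).normal(size=len(x))
        if np.median(np.abs(x - np.median(x))) == 0:
            return
        r = bicor(x, y)
        assert -1.0 <= r <= 1.0
        assert bicor(y, x) == pytest.approx(r, abs=1e-12)
        assert bicor(scale * x + shift, y) == pytest.approx(r, abs=1e-8)

    def test_matrix_path_matches_scalar_on_complete_data(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 6))
        R = bicor_matrix(X)
        for i in range(6):
            for j in range(i):
                assert R[i, j] == pytest.approx(bicor(X[:, i], X[:, j]), abs=1e-10)


class TestCorrelateGrid:
    def test_perfect_feature_target(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=30)
        feats = pd.DataFrame([t], index=["f"], columns=[f"s{i}" for i in range(30)])
        targets = pd.DataFrame({"t": t}, index=feats.columns)
        res = cb.correlate_grid(feats, targets)
        assert res.coefficient.loc["f", "t"] == pytest.approx(1.0)
        assert res.p_value.loc["f", "t"] < 1e-12

    def test_df_tracks_pairwise_n(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        x_miss = x.copy()
        x_miss[:10] = np.nan
        cols = [f"s{i}" for i in range(40)]
        feats = pd.DataFrame([x_miss], index=["f"], columns=cols)
        targets = pd.DataFrame({"t": y}, index=cols)
        res = cb.correlate_grid(feats, targets)
        assert res.n_used.loc["f", "t"] == 30
        # equals the complete-case subset computation
        sub = cb.correlate_grid(
            pd.DataFrame([x[10:]], index=["f"], columns=cols[10:]),
            pd.DataFrame({"t": y[10:]}, index=cols[10:]),
        )
        assert res.coefficient.loc["f", "t"] == pytest.approx(
            sub.coefficient.loc["f", "t"]
        )
        assert res.p_value.loc["f", "t"] == pytest.approx(sub.p_value.loc["f", "t"])

    def test_disjoint_samples_error(self):
        feats = pd.DataFrame([[1.0]], columns=["a"])
        targets = pd.DataFrame({"t": [1.0]}, index=["b"])
        with pytest.raises(ValueError):
            cb.correlate_grid(feats, targets)


class TestAnovaBH:
    def test_identical_groups_give_f_zero_p_one(self):
        x = np.random.default_rng(0).normal(size=10)
        m = pd.DataFrame([np.concatenate([x, x])], index=["f"])
        m.columns = [f"s{i}" for i in range(20)]
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=m.columns)
        res = cb.anova_bh(m, groups)
        assert res.table.loc["f", "stat"] == pytest.approx(0.0)
        assert res.table.loc["f", "p"] == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(50, 80)))
        m.columns = [f"s{i}" for i in range(80)]
        groups = pd.Series(np.repeat(list("abcd"), 20), index=m.columns)
        m.loc[0, groups == "d"] += 3.0
        res = cb.anova_bh(m, groups)
        assert res.table.loc[0, "q"] < 0.01

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(5, 30)))
        m.columns = [f"s{i}" for i in range(30)]
        groups = pd.Series(np.repeat(list("abc"), 10), index=m.columns)
        res = cb.anova_bh(m, groups)
        for f in m.index:
            vals = [m.loc[f, groups == g].to_numpy() for g in "abc"]
            F, p = stats.f_oneway(*vals)
            assert res.table.loc[f, "stat"] == pytest.approx(F)
            assert res.table.loc[f, "p"] == pytest.approx(p)

    def test_single_group_error(self):
        m = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        with pytest.raises(ValueError):
            cb.anova_bh(m, pd.Series(["g", "g"], index=["a", "b"]))

    def test_bh_hand_stepup(self):
        q = cb.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_bh_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(500)
        p[rng.random(500) < 0.1] = np.nan
        q = cb.bh_adjust(p)
        ok = np.isfinite(p)
        ref = multipletests(p[ok], method="fdr_bh")[1]
        assert np.allclose(q[ok], ref, atol=1e-12)
        assert np.isnan(q[~ok]).all()


class TestGroupContrast:
    def make(self, shift=0.0, seed=0, n=15):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.2, (30, n))
        b = rng.normal(0, 0.2, (30, n))
        a[0] += shift
        m = pd.DataFrame(np.hstack([a, b]))
        m.columns = [f"s{i}" for i in range(2 * n)]
        groups = pd.Series(["x"] * n + ["y"] * n, index=m.columns)
        return m, groups

    def test_identical_groups_ns(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(10, 5))
        m = pd.DataFrame(np.hstack([a, a]))
        m.columns = [f"s{i}" for i in range(10)]
        groups = pd.Series(["x"] * 5 + ["y"] * 5, index=m.columns)
        res = cb.group_contrast(m, groups, "x", "y")
        assert (res.table["log2fc"] == 0).all()
        assert (res.table["class"] == "ns").all()

    def test_planted_increase_detected(self):
        m, groups = self.make(shift=1.0)
        res = cb.group_contrast(m, groups, "x", "y")
        assert res.table.loc[0, "class"] == "increased"

    def test_label_swap_antisymmetry(self):
        m, groups = self.make(shift=1.0, seed=3)
        a = cb.group_contrast(m, groups, "x", "y").table
        b = cb.group_contrast(m, groups, "y", "x").table
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["p"], b["p"], equal_nan=True)

    def test_welch_equals_anova_on_equal_variance_two_group(self):
        m, groups = self.make(seed=5)
        welch = cb.group_contrast(m, groups, "x", "y").table
        anova = cb.anova_bh(m, groups).table
        # equal group sizes: F == t^2 numerically
        assert np.allclose(anova["stat"], welch["stat"] ** 2, rtol=1e-6)


class TestSpearmanBurden:
    def test_perfect_and_inverted(self):
        b = pd.Series(np.arange(20.0), index=[f"s{i}" for i in range(20)])
        m = pd.DataFrame([b.to_numpy(), -b.to_numpy()], index=["up", "dn"],
                         columns=b.index)
        res = cb.spearman_burden(m, b)
        assert res.loc["up", "rho"] == pytest.approx(1.0)
        assert res.loc["dn", "rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(90)]
        m = pd.DataFrame(rng.normal(size=(500, 90)), columns=cols)
        b = pd.Series(rng.normal(size=90), index=cols)
        res = cb.spearman_burden(m, b)
        rb = stats.rankdata(b)
        for f in m.index[:50]:
            oracle = stats.pearsonr(stats.rankdata(m.loc[f]), rb).statistic
            assert res.loc[f, "rho"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_feature_reported_missing(self):
        cols = [f"s{i}" for i in range(10)]
        m = pd.DataFrame([[1.0] * 10], index=["const"], columns=cols)
        m.loc["const", cols[0]] = np.nan  # route through the pairwise path
        b = pd.Series(np.arange(10.0), index=cols)
        res = cb.spearman_burden(m, b)
        assert np.isnan(res.loc["const", "rho"])


class TestCeGeneBias:
    def make_result(self, rhos, qs, genes):
        return pd.DataFrame({"rho": rhos, "p": qs, "q": qs}, index=genes)

    def test_negative_skew_detected(self):
        genes = [f"g{i}" for i in range(40)]
        rhos = [-0.5] * 34 + [0.5] * 6
        qs = [0.001] * 40
        res = self.make_result(rhos, qs, genes)
        nneg, npos, p = cb.ce_gene_bias(res, genes)
        assert (nneg, npos) == (34, 6)
        assert p < 0.01

    def test_no_significant_genes(self):
        genes = ["a", "b"]
        res = self.make_result([0.5, -0.5], [0.9, 0.9], genes)
        assert cb.ce_gene_bias(res, genes) == (0, 0, 1.0)

    def test_empty_intersection_error(self):
        res = self.make_result([0.5], [0.01], ["a"])
        with pytest.raises(ValueError):
            cb.ce_gene_bias(res, ["zzz"])
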