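import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import ceburden as cb
from ceburden import synthetic as syn
from ceburden.treecut import cutree_hybrid


def tom_oracle(A):
    """Triple-loop brute force topological overlap."""
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestSoftAdjacency:
    def test_closed_forms(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 20)))
        corr = np.array([[1.0, 0.0], [0.0, 1.0]])
        A = cb.soft_adjacency(expr, beta=24.5, corr=corr)
        assert A[0, 0] == pytest.approx(1.0)
        assert A[0, 1] == pytest.approx(2.0**-24.5)
        corr_neg = np.array([[1.0, -1.0], [-1.0, 1.0]])
        A = cb.soft_adjacency(expr, beta=24.5, corr=corr_neg)
        assert A[0, 1] == pytest.approx(0.0)

    def test_raising_beta_shrinks_edges(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(10, 30)))
        low = cb.soft_adjacency(expr, beta=6.0)
        high = cb.soft_adjacency(expr, beta=12.0)
        off = ~np.eye(10, dtype=bool)
        inside = (low[off] > 0) & (low[off] < 1)
        assert (high[off][inside] < low[off][inside]).all()

    def test_nonpositive_beta_error(self):
        with pytest.raises(ValueError):
            cb.soft_adjacency(pd.DataFrame(np.eye(3)), beta=0.0)


class TestTopologicalOverlap:
    def test_hand_example_three_nodes(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 1.0)
        T = cb.topological_overlap(A)
        # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert T[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(T), 1.0)

    def test_diagonal_adjacency_gives_zero_overlap(self):
        T = cb.topological_overlap(np.eye(4))
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(T[off], 0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            M = rng.random((20, 20))
            A = (M + M.T) / 2
            np.fill_diagonal(A, 1.0)
            assert np.allclose(cb.topological_overlap(A), tom_oracle(A), atol=1e-12)

    def test_asymmetric_input_error(self):
        A = np.random.default_rng(0).random((4, 4))
        with pytest.raises(ValueError):
            cb.topological_overlap(A)


class TestDetectModules:
    def block_diss(self, sizes, within=0.5, between=0.01, seed=0):
        rng = np.random.default_rng(seed)
        n = sum(sizes)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        sim = np.full((n, n), between)
        for m in range(len(sizes)):
            idx = labels == m
            sim[np.ix_(idx, idx)] = within
        sim += rng.normal(0, 0.002, (n, n))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        d = np.clip(1 - sim, 0, None)
        np.fill_diagonal(d, 0.0)
        return d, labels

    def test_planted_blocks_recovered(self):
        d, truth = self.block_diss([40] * 6)
        lab = cb.detect_modules(d)
        assert adjusted_rand_score(truth, lab) >= 0.9

    def test_block_below_min_size_unassigned(self):
        d, truth = self.block_diss([40, 40, 10], seed=1)
        lab = cb.detect_modules(d, min_module_size=15)
        small = truth == 2
        assert (lab[small] == 0).all()

    def test_single_homogeneous_block_is_one_module(self):
        d, _ = self.block_diss([60])
        lab = cb.detect_modules(d)
        assert (lab == 1).all()

    def test_pure_noise_yields_no_modules(self):
        rng = np.random.default_rng(3)
        sim = np.abs(rng.normal(0, 1e-6, (80, 80)))
        sim = (sim + sim.T) / 2
        d = np.clip(1 - sim, 0, None)
        np.fill_diagonal(d, 0.0)
        lab = cb.detect_modules(d)
        assert (lab == 0).all()

    def test_modules_numbered_by_decreasing_size(self):
        d, truth = self.block_diss([20, 60, 40], seed=2)
        lab = cb.detect_modules(d)
        sizes = pd.Series(lab[lab > 0]).value_counts()
        assert list(sizes.index) == sorted(sizes.index)  # M1 largest first
        assert sizes.loc[1] >= sizes.loc[2] >= sizes.loc[3]

    def test_nonsquare_error(self):
        with pytest.raises(ValueError):
            cb.detect_modules(np.zeros((3, 4)))

    def test_nonzero_diagonal_error(self):
        with pytest.raises(ValueError):
            cb.detect_modules(np.eye(5))


class TestEigenproteins:
    def test_identical_profiles_fully_explained(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=30)
        expr = pd.DataFrame(
            np.tile(profile, (5, 1)) * rng.uniform(0.5, 2.0, size=(5, 1)),
            index=[f"f{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(30)],
        )
        labels = pd.Series(1, index=expr.index)
        eps = cb.module_eigenproteins(expr, labels)
        assert eps.variance_explained["M1"] == pytest.approx(1.0)
        assert np.allclose(eps.kme["M1"], 1.0, atol=1e-8)

    def test_sign_convention(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(12, 40)),
                            columns=[f"s{i}" for i in range(40)])
        labels = pd.Series([1] * 6 + [2] * 6, index=expr.index)
        eps = cb.module_eigenproteins(expr, labels)
        Z = (expr.T - expr.T.mean()) / expr.T.std(ddof=0)
        for m in (1, 2):
            mean_prof = Z.T[labels == m].mean(axis=0)
            r = np.corrcoef(eps.eigenproteins[f"M{m}"], mean_prof)[0, 1]
            assert r >= 0

    def test_two_orthogonal_half_modules_split_variance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        b -= a * (a @ b) / (a @ a)  # orthogonalize
        rows = [a] * 10 + [b] * 10
        expr = pd.DataFrame(rows, columns=[f"s{i}" for i in range(40)])
        expr.index = [f"f{i}" for i in range(20)]
        labels = pd.Series(1, index=expr.index)
        eps = cb.module_eigenproteins(expr, labels)
        assert eps.variance_explained["M1"] == pytest.approx(0.5, abs=0.02)

    def test_single_feature_module_error(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 10)))
        labels = pd.Series([1, 2], index=expr.index)
        with pytest.raises(ValueError):
            cb.module_eigenproteins(expr, labels)


class TestMergeModules:
    def correlated_modules(self, rho, seed=0, size=20, n=60):
        rng = np.random.default_rng(seed)
        f1 = rng.normal(size=n)
        f2 = rho * f1 + np.sqrt(1 - rho**2) * rng.normal(size=n)
        rows = [f1 + 0.05 * rng.normal(size=n) for _ in range(size)]
        rows += [f2 + 0.05 * rng.normal(size=n) for _ in range(size)]
        expr = pd.DataFrame(rows, columns=[f"s{i}" for i in range(n)])
        expr.index = [f"f{i}" for i in range(2 * size)]
        labels = pd.Series([1] * size + [2] * size, index=expr.index)
        return expr, labels

    def test_nearly_collinear_modules_merge(self):
        expr, labels = self.correlated_modules(0.995)
        merged = cb.merge_modules(expr, labels, cut_height=0.07)
        assert merged.nunique() == 1

    def test_distinct_modules_stay_separate(self):
        expr, labels = self.correlated_modules(0.5)
        merged = cb.merge_modules(expr, labels, cut_height=0.07)
        assert merged.nunique() == 2

    def test_idempotent(self):
        expr, labels = self.correlated_modules(0.5, seed=3)
        once = cb.merge_modules(expr, labels)
        twice = cb.merge_modules(expr, once)
        assert (once == twice).all()


class TestModuleTraitAssociation:
    def test_eigenprotein_equal_to_trait(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(30)]
        e = pd.DataFrame({"M1": rng.normal(size=30)}, index=samples)
        traits = pd.DataFrame({"pt": e["M1"]}, index=samples)
        res = cb.module_trait_association(e, traits)
        assert res.coefficient.loc["M1", "pt"] == pytest.approx(1.0)

    def test_disease_contrast_restricted_to_control_plus_group(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(30)]
        meta = pd.DataFrame(
            {"group": ["Control"] * 10 + ["LATE"] * 10 + ["AD"] * 10}, index=samples
        )
        e = pd.DataFrame({"M1": np.r_[np.zeros(10), np.ones(10), rng.normal(size=10)]},
                         index=samples)
        e["M1"] += 0.01 * rng.normal(size=30)
        res = cb.module_trait_association(e, None, meta)
        assert res.coefficient.loc["M1", "LATE_vs_Control"] > 0.9

    def test_tiny_group_reported_missing(self):
        samples = [f"s{i}" for i in range(12)]
        meta = pd.DataFrame({"group": ["Control"] * 10 + ["AD"] * 2}, index=samples)
        e = pd.DataFrame({"M1": np.arange(12.0)}, index=samples)
        res = cb.module_trait_association(e, None, meta, min_group=3)
        assert np.isnan(res.coefficient.loc["M1", "AD_vs_Control"])


class TestEigenproteinAnova:
    def test_constant_eigenprotein_ns(self):
        samples = [f"s{i}" for i in range(12)]
        e = pd.DataFrame({"M1": np.ones(12)}, index=samples)
        labels = pd.Series(["low"] * 4 + ["intermediate"] * 4 + ["high"] * 4,
                           index=samples)
        res = cb.eigenprotein_anova(e, labels)
        assert res.table.loc["M1", "p"] == pytest.approx(1.0)

    def test_burden_loaded_module_significant(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(30)]
        labels = pd.Series(["low"] * 10 + ["intermediate"] * 10 + ["high"] * 10,
                           index=samples)
        shift = labels.map({"low": 0.0, "intermediate": 1.0, "high": 2.0})
        e = pd.DataFrame({"M1": shift + 0.3 * rng.normal(size=30)}, index=samples)
        res = cb.eigenprotein_anova(e, labels)
        assert res.table.loc["M1", "p"] < 0.01

    def test_single_subtype_error(self):
        e = pd.DataFrame({"M1": np.arange(4.0)}, index=list("abcd"))
        labels = pd.Series(["low"] * 4, index=list("abcd"))
        with pytest.raises(ValueError):
            cb.eigenprotein_anova(e, labels)


class TestEndToEndNetwork:
    def test_planted_module_recovery_full_coverage(self):
        meta, _, gt = syn.generate_cohort(n_subjects=90, seed=7)
        ms = syn.ModuleSpec(
            n_features=900,
            module_sizes=(150,) * 6,
            burden_assoc=(0.6, -0.6, 0, 0, 0.4, 0),
            n_ce_negative=0, n_ce_positive=0,
            n_concordant_down=0, n_concordant_up=0,
            age_slope_sd=0, sex_effect_sd=0, pmi_slope_sd=0, batch_offset_sd=0,
            mcar_rate=0.02, mnar_rate=0.02,
        )
        prot = syn.generate_proteome(meta, gt, ms, seed=7)
        model, eps = cb.build_network(prot.biological().values)
        truth = gt.features["module"].reindex(model.labels.index)
        assert adjusted_rand_score(truth, model.labels) >= 0.8
        assert (model.labels == 0).mean() <= 0.10
        # eigenprotein sign convention holds for every module
        Z = model.labels
        expr = prot.biological().values.loc[model.labels.index]
        X = expr.to_numpy()
        mu = np.nanmean(X, axis=1, keepdims=True)
        sd = np.nanstd(X, axis=1, keepdims=True)
        Zs = np.where(np.isfinite(X), (X - mu) / sd, 0.0)
        for m in eps.eigenproteins.columns:
            mid = int(m[1:])
            prof = Zs[(Z == mid).to_numpy()].mean(axis=0)
            assert np.corrcoef(eps.eigenproteins[m], prof)[0, 1] >= 0
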