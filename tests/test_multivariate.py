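import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecostoich import multivariate as mv


rng0 = np.random.default_rng(12345)


class TestAssembly:
    def test_default_design_gives_15_by_25(self, default_features):
        assert default_features.raw.shape == (15, 25)
        assert tuple(default_features.raw.columns) == mv.FEATURE_VARIABLES

    def test_columns_are_standardized(self, default_features):
        assert np.abs(default_features.data.mean()).max() < 1e-9
        assert np.abs(default_features.data.std(ddof=1) - 1).max() < 1e-9

    def test_quantification_variables_excluded(self, default_features):
        assert not any(v.startswith(("CFU", "MPN", "TDE", "EPI"))
                       for v in default_features.raw.columns)

    def test_roles_partition_chemical_and_biological(self, default_features):
        roles = set(default_features.roles.values())
        assert roles == {"chemical", "biological"}


class TestPCA:
    def test_perfectly_correlated_pair_loads_on_one_axis(self):
        x = rng0.normal(size=30)
        frame = mv.zscore(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        res = mv.pca(frame)
        assert res.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_total_variance_conserved_and_fractions_sum_to_one(self, default_features):
        res = mv.pca(default_features)
        assert res.explained.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        total = default_features.data.shape[1]
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-9)

    def test_scores_times_loadings_reconstruct_matrix(self, default_features):
        res = mv.pca(default_features)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.abs(recon - default_features.data.to_numpy()).max() < 1e-8

    def test_rotation_invariance_of_total_variance(self):
        X = rng0.normal(size=(20, 6))
        Q, _ = np.linalg.qr(rng0.normal(size=(6, 6)))
        e1 = mv.pca(pd.DataFrame(X)).eigenvalues
        e2 = mv.pca(pd.DataFrame(X @ Q)).eigenvalues
        assert e1.sum() == pytest.approx(e2.sum(), rel=1e-9)


class TestComponentTests:
    def test_separated_groups_detected(self):
        vals = np.concatenate([np.zeros(5), np.full(5, 10.0), np.full(5, 20.0)])
        vals += rng0.normal(0, 0.01, 15)
        scores = pd.DataFrame({"PC1": vals})
        groups = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        res = mv.component_tests(scores, groups)["PC1"]
        assert res["anova_p"] < 1e-6
        assert all(p < 0.05 for p in res["tukey_p"].values())
        # rank-based Dunn has low power at n=5: only the extreme pair resolves
        assert res["dunn_p"][("a", "c")] < 0.01
        assert res["kruskal_p"] < 0.01

    def test_too_few_observations_skipped_with_reason(self):
        res = mv.component_tests(pd.DataFrame({"PC1": [1.0, 2.0]}), pd.Series(["a", "b"]))
        assert "skipped" in res["PC1"]

    def test_dunn_matches_kruskal_direction(self):
        # under one shared distribution nothing should be significant
        scores = pd.DataFrame({"PC1": rng0.normal(size=15)})
        groups = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        res = mv.component_tests(scores, groups)["PC1"]
        assert res["kruskal_p"] > 0.01
        assert min(res["dunn_p"].values()) > 0.01


class TestKMeans:
    def test_separated_clusters_recovered(self):
        X = pd.DataFrame(np.concatenate([
            rng0.normal(0, 0.1, (5, 2)),
            rng0.normal(5, 0.1, (5, 2)),
            rng0.normal(10, 0.1, (5, 2))]))
        groups = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        _, purity = mv.kmeans_clusters(X, groups, k=3, seed=0)
        assert purity == 1.0

    def test_single_cluster_purity_is_largest_group_share(self):
        X = pd.DataFrame(rng0.normal(size=(15, 2)))
        groups = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        _, purity = mv.kmeans_clusters(X, groups, k=1, seed=0)
        assert purity == pytest.approx(5 / 15)

    def test_purity_invariant_to_group_renaming(self):
        X = pd.DataFrame(rng0.normal(size=(15, 2)))
        groups = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        renamed = groups.map({"a": "x", "b": "y", "c": "z"})
        _, p1 = mv.kmeans_clusters(X, groups, k=3, seed=7)
        _, p2 = mv.kmeans_clusters(X, renamed, k=3, seed=7)
        assert p1 == p2


class TestSpearman:
    def test_monotone_and_reversed(self):
        a = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        b = pd.DataFrame({"up": [1.0, 8, 27, 64, 125], "down": [5.0, 4, 3, 2, 1]})
        rho, p, sig = mv.spearman_matrix(a, b)
        assert rho.loc["x", "up"] == pytest.approx(1.0)
        assert rho.loc["x", "down"] == pytest.approx(-1.0)

    def test_matches_rank_based_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5])
        rho, _, _ = mv.spearman_matrix(pd.DataFrame({"x": x}), pd.DataFrame({"y": y}))
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert rho.loc["x", "y"] == pytest.approx(oracle, rel=1e-12)

    def test_constant_column_undefined(self):
        rho, p, _ = mv.spearman_matrix(pd.DataFrame({"c": [1.0, 1, 1, 1]}),
                                       pd.DataFrame({"y": [1.0, 2, 3, 4]}))
        assert math.isnan(rho.loc["c", "y"])


class TestVIF:
    def test_orthogonal_variables_kept_with_unit_vif(self):
        env = pd.DataFrame({"TOC": [1.0, -1, 1, -1, 1, -1],
                            "TN": [1.0, 1, -1, -1, 1, -1]})
        selected, vifs, dropped = mv.vif_screen(env, threshold=2.0)
        assert set(selected) == {"TOC", "TN"} and not dropped
        assert all(v < 1.5 for v in vifs.values())

    def test_duplicated_variable_dropped(self):
        x = rng0.normal(size=10)
        env = pd.DataFrame({"a": x, "b": x, "c": rng0.normal(size=10)})
        selected, vifs, dropped = mv.vif_screen(env)
        assert len(dropped) == 1 and len(selected) == 2
        assert all(v < 2.0 for v in vifs.values())

    def test_exact_linear_combination_dropped_first(self):
        x1, x2 = rng0.normal(size=10), rng0.normal(size=10)
        env = pd.DataFrame({"combo": x1 + x2, "x1": x1, "x2": x2})
        selected, _, dropped = mv.vif_screen(env)
        assert dropped[0] == "combo"
        assert set(selected) == {"x1", "x2"}

    def test_single_variable_has_unit_vif(self):
        selected, vifs, _ = mv.vif_screen(pd.DataFrame({"a": rng0.normal(size=5)}))
        assert vifs == {"a": 1.0}


class TestRDA:
    def setup_method(self):
        self.rng = np.random.default_rng(99)
        self.Y = pd.DataFrame(self.rng.normal(size=(20, 5)),
                              columns=[f"y{i}" for i in range(5)])

    def test_env_equal_to_response_column_explains_its_share(self):
        env = pd.DataFrame({"e": self.Y["y0"]})
        res = mv.rda(self.Y, env, n_perm=99, seed=0, axis_tests=False)
        # fitted SS >= the full variance of y0 itself
        Yc = self.Y - self.Y.mean()
        share = (Yc["y0"] ** 2).sum() / (Yc ** 2).sum().sum()
        assert res.constrained_fraction >= share - 1e-12
        assert res.constrained_fraction == pytest.approx(share, abs=0.15)

    def test_r2_matches_per_column_regression_oracle(self):
        import statsmodels.api as sm
        env = pd.DataFrame({"a": self.rng.normal(size=20), "b": self.rng.normal(size=20)})
        res = mv.rda(self.Y, env, n_perm=99, seed=0, axis_tests=False)
        Yc = self.Y - self.Y.mean()
        X = sm.add_constant(env.to_numpy())
        ss_fit = sum(
            sm.OLS(Yc[c].to_numpy(), X).fit().ess for c in self.Y.columns)
        assert res.r2 == pytest.approx(ss_fit / (Yc ** 2).sum().sum(), rel=1e-9)
        n, m = 20, 2
        assert res.adj_r2 == pytest.approx(1 - (1 - res.r2) * (n - 1) / (n - m - 1), rel=1e-12)

    def test_constrained_and_unconstrained_fractions_sum_to_one(self):
        env = pd.DataFrame({"a": self.rng.normal(size=20)})
        res = mv.rda(self.Y, env, n_perm=99, seed=0, axis_tests=False)
        assert res.explained.sum() == pytest.approx(1.0, rel=1e-9)

    def test_permutation_p_reproducible_with_seed(self):
        env = pd.DataFrame({"a": self.rng.normal(size=20)})
        r1 = mv.rda(self.Y, env, n_perm=199, seed=42)
        r2 = mv.rda(self.Y, env, n_perm=199, seed=42)
        assert r1.p_global == r2.p_global and r1.p_axes == r2.p_axes
        assert r1.p_terms == r2.p_terms

    def test_collinear_env_raises(self):
        x = self.rng.normal(size=20)
        env = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            mv.rda(self.Y, env, n_perm=99, seed=0)


class TestPermanova:
    def small_instance(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(6, 4)))
        X.iloc[:3] += 1.0
        return X, ["a"] * 3 + ["b"] * 3

    def test_exact_p_matches_centroid_oracle(self):
        """Pairwise-distance route equals an independent centroid-SS oracle
        enumerated over all 20 balanced label splits."""
        X, groups = self.small_instance()
        res = mv.permanova(X, groups, n_perm="exact")

        arr = X.to_numpy()
        def f_of(labels):
            labels = np.asarray(labels)
            ssw = sum(((arr[labels == g] - arr[labels == g].mean(axis=0)) ** 2).sum()
                      for g in set(labels))
            sst = ((arr - arr.mean(axis=0)) ** 2).sum()
            return ((sst - ssw) / 1) / (ssw / 4)
        f_obs = f_of(groups)
        perm_f = [f_of(["a" if i in c else "b" for i in range(6)])
                  for c in itertools.combinations(range(6), 3)]
        assert res.pseudo_F == pytest.approx(f_obs, rel=1e-9)
        assert res.p_value == pytest.approx(
            np.mean([f >= f_obs - 1e-12 for f in perm_f]), abs=1e-12)
        assert res.permutations == 20

    def test_matches_reference_implementation(self, default_features):
        pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova
        res = mv.permanova(default_features.data, default_features.groups,
                           n_perm=999, seed=0)
        dm = DistanceMatrix(squareform(pdist(default_features.data.to_numpy())),
                            ids=list(default_features.data.index))
        ref = sk_permanova(dm, grouping=list(default_features.groups), permutations=999)
        assert res.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)
        assert abs(res.p_value - ref["p-value"]) < 0.02

    def test_invariant_under_rotation_and_reproducible(self, default_features):
        X = default_features.data
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(X.shape[1],) * 2))
        r1 = mv.permanova(X, default_features.groups, n_perm=499, seed=11)
        r2 = mv.permanova(pd.DataFrame(X.to_numpy() @ Q, index=X.index),
                          default_features.groups, n_perm=499, seed=11)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, rel=1e-9)
        assert r1.R2 == pytest.approx(r2.R2, rel=1e-9)
        assert r1.p_value == r2.p_value  # same seed, distance-preserving map

    def test_r2_bounds_and_dispersion(self, default_features):
        res = mv.permanova(default_features.data, default_features.groups,
                           n_perm=199, seed=0)
        assert 0.0 <= res.R2 <= 1.0
        assert 0.0 < res.p_value <= 1.0
        assert not math.isnan(res.dispersion_p)

    def test_heteroscedastic_groups_fail_dispersion_check(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(np.concatenate([
            rng.normal(0, 0.05, (8, 3)), rng.normal(0, 5.0, (8, 3))]))
        res = mv.permanova(X, ["a"] * 8 + ["b"] * 8, n_perm=199, seed=0)
        assert res.dispersion_p < 0.05

    def test_degenerate_identical_points_flagged(self):
        X = pd.DataFrame(np.zeros((6, 3)))
        res = mv.permanova(X, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert math.isnan(res.pseudo_F)
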