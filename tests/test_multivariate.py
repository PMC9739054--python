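import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.decomposition import PCA as SkPCA

import wheatscreen as ws
from wheatscreen.errors import AnalysisError, ParameterError
from wheatscreen.io_formats import TraitInfo, TraitRegistry
from wheatscreen.multivariate import TraitMatrix, standardize


def random_matrix(n=10, p=6, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n, p))
    return TraitMatrix(
        genotypes=[f"G{i}" for i in range(n)],
        traits=[f"t{j}" for j in range(p)],
        values=standardize(vals),
        standardized=True,
        raw_values=vals,
    )


def adjusted_from_sim(seed=3):
    fb, _, _ = ws.simulate_fieldbook(ws.SimulationSpec(seed=seed))
    return fb, {t: ws.adjust_means(fb, t) for t in fb.trait_names}


class TestBuildTraitMatrix:
    def test_two_genotype_standardization(self):
        fb = ws.FieldBook(
            pd.DataFrame(
                {
                    "genotype": ["C1", "C2", "C1", "C2"],
                    "block": ["B1", "B1", "B2", "B2"],
                    "is_check": [True] * 4,
                    "Y": [1.0, 3.0, 1.0, 3.0],
                }
            )
        )
        tm = ws.build_trait_matrix({"Y": ws.adjust_means(fb, "Y")})
        np.testing.assert_allclose(
            tm.values.ravel(), [-1 / np.sqrt(2), 1 / np.sqrt(2)]
        )

    def test_constant_column_rejected(self):
        with pytest.raises(AnalysisError, match="zero variance"):
            standardize(np.ones((5, 2)))

    def test_columns_standardized_on_random_matrices(self):
        fb, adjusted = adjusted_from_sim()
        tm = ws.build_trait_matrix(adjusted)
        assert np.abs(tm.values.mean(axis=0)).max() < 1e-9
        assert np.abs(tm.values.std(axis=0, ddof=1) - 1).max() < 1e-9
        assert tm.values.shape == (46, len(adjusted))


class TestPCA:
    def test_two_correlated_traits_pc1_100pct(self):
        x = np.linspace(0, 1, 8)
        vals = np.column_stack([x, 2 * x + 1])
        tm = TraitMatrix(["g%d" % i for i in range(8)], ["a", "b"], standardize(vals),
                         standardized=True)
        res = ws.pca(tm, n_components=1)
        assert res.proportion[0] == pytest.approx(100.0)

    def test_eigenvalues_match_brute_force_solver(self):
        """Eigenvalues agree with an independent SVD-based solver to 1e-8."""
        for seed in range(5):
            tm = random_matrix(10, 6, seed)
            res = ws.pca(tm, n_components=6)
            sk = SkPCA(n_components=6).fit(tm.values)
            # sklearn scales by (n-1) internally via explained_variance_
            np.testing.assert_allclose(res.eigenvalues, sk.explained_variance_, atol=1e-8)
            assert res.eigenvalues.sum() == pytest.approx(6.0)

    def test_scores_uncorrelated_before_rotation(self):
        tm = random_matrix(20, 5, 1)
        res = ws.pca(tm, n_components=5)
        c = np.corrcoef(res.scores.to_numpy(), rowvar=False)
        assert np.abs(c - np.eye(5)).max() < 1e-8

    def test_varimax_preserves_retained_variance(self):
        tm = random_matrix(15, 6, 2)
        plain = ws.pca(tm, n_components=2)
        rot = ws.pca(tm, n_components=2, rotation="varimax")
        assert (rot.loadings.to_numpy() ** 2).sum() == pytest.approx(
            (plain.loadings.to_numpy() ** 2).sum()
        )
        assert rot.rotation_applied == "varimax"

    def test_cos2_traits_sum_to_one(self):
        tm = random_matrix(12, 4, 3)
        res = ws.pca(tm, n_components=4)
        np.testing.assert_allclose(res.cos2_traits.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(res.cos2_genotypes.sum(axis=1), 1.0, atol=1e-9)

    def test_row_permutation_invariance(self):
        tm = random_matrix(14, 5, 4)
        perm = np.random.default_rng(0).permutation(14)
        tm2 = TraitMatrix(
            [tm.genotypes[i] for i in perm], tm.traits, tm.values[perm],
            standardized=True,
        )
        a = ws.pca(tm, n_components=3)
        b = ws.pca(tm2, n_components=3)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(
            a.loadings.to_numpy(), b.loadings.to_numpy(), atol=1e-9
        )

    def test_deterministic_sign_convention(self):
        tm = random_matrix(10, 5, 5)
        res = ws.pca(tm, n_components=3)
        L = res.loadings.to_numpy()
        for j in range(3):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_too_many_components(self):
        tm = random_matrix(10, 4, 6)
        with pytest.raises(ParameterError):
            ws.pca(tm, n_components=5)


class TestCorrelations:
    def test_self_and_negated(self):
        x = np.random.default_rng(0).normal(size=12)
        vals = np.column_stack([x, -x, x + 0.001 * np.arange(12)])
        tm = TraitMatrix([f"g{i}" for i in range(12)], ["a", "b", "c"],
                         standardize(vals), standardized=True)
        res = ws.correlation_matrix(tm)
        assert res.r.loc["a", "a"] == 1.0
        assert res.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_closed_form_t_oracle(self):
        rng = np.random.default_rng(7)
        n = 15
        vals = rng.normal(size=(n, 3))
        tm = TraitMatrix([f"g{i}" for i in range(n)], ["a", "b", "c"],
                         standardize(vals), standardized=True)
        res = ws.correlation_matrix(tm)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            x, y = vals[:, i], vals[:, j]
            r = np.corrcoef(x, y)[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            names = ["a", "b", "c"]
            assert res.r.iloc[i, j] == pytest.approx(r, rel=1e-9)
            assert res.p.iloc[i, j] == pytest.approx(p, rel=1e-6)
            assert res.significant.loc[names[i], names[j]] == (p < 0.05)

    def test_holm_adjustment_never_decreases_p(self):
        tm = random_matrix(12, 4, 8)
        raw = ws.correlation_matrix(tm)
        adj = ws.correlation_matrix(tm, adjust="holm")
        assert (adj.p.to_numpy() >= raw.p.to_numpy() - 1e-12).all()


class TestClustering:
    def test_two_tight_groups_recovered(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 0.1, size=(6, 3))
        b = rng.normal(10, 0.1, size=(6, 3))
        vals = np.vstack([a, b])
        tm = TraitMatrix([f"g{i}" for i in range(12)], ["x", "y", "z"],
                         standardize(vals), standardized=True)
        tree = ws.hierarchical_clusters(tm, k=2)
        labels = tree.assignments
        assert labels.iloc[:6].nunique() == 1 and labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[6]

    def test_single_leaf(self):
        tm = TraitMatrix(["only"], ["x", "y"], np.array([[0.0, 1.0]]))
        tree = ws.hierarchical_clusters(tm, k=1)
        assert tree.leaf_order == ["only"] and tree.linkage_matrix.shape[0] == 0

    def test_ward_heights_nondecreasing(self):
        tm = random_matrix(20, 4, 13)
        tree = ws.hierarchical_clusters(tm, method="ward", k=3)
        heights = tree.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_bad_k(self):
        tm = random_matrix(5, 3, 0)
        with pytest.raises(ParameterError):
            ws.hierarchical_clusters(tm, k=9)


class TestRanking:
    def registry(self, traits, directions):
        return TraitRegistry({t: TraitInfo("", d) for t, d in zip(traits, directions)})

    def test_best_everywhere_ranks_first(self):
        vals = np.array([[5.0, 5.0], [3.0, 4.0], [1.0, 1.0]])
        tm = TraitMatrix(["top", "mid", "low"], ["a", "b"], standardize(vals),
                         standardized=True, raw_values=vals)
        reg = self.registry(["a", "b"], ["higher_better", "higher_better"])
        res = ws.rank_genotypes(tm, reg, top_n=1, bottom_n=1)
        assert res.table.index[0] == "top"
        assert res.table.loc["top", "final_rank"] == 1.0
        assert res.table.loc["top", "tolerance_class"] == "top"
        assert res.table.loc["low", "tolerance_class"] == "low"

    def test_lower_better_direction(self):
        vals = np.array([[1.0], [2.0], [3.0]])
        tm = TraitMatrix(["a", "b", "c"], ["t"], standardize(vals),
                         standardized=True, raw_values=vals)
        reg = self.registry(["t"], ["lower_better"])
        res = ws.rank_genotypes(tm, reg, top_n=1, bottom_n=1)
        assert list(res.table.index) == ["a", "b", "c"]

    def test_composite_matches_brute_force_toy(self):
        # 4 genotypes x 3 traits; trait c is lower_better
        vals = np.array(
            [[4.0, 1.0, 2.0], [3.0, 2.0, 1.0], [2.0, 3.0, 4.0], [1.0, 4.0, 3.0]]
        )
        tm = TraitMatrix(["g1", "g2", "g3", "g4"], ["a", "b", "c"],
                         standardize(vals), standardized=True, raw_values=vals)
        reg = self.registry(["a", "b", "c"],
                            ["higher_better", "higher_better", "lower_better"])
        res = ws.rank_genotypes(tm, reg)
        # hand enumeration: a-ranks (1,2,3,4); b-ranks (4,3,2,1); c-ranks (2,1,4,3)
        expected = {"g1": (1 + 4 + 2) / 3, "g2": (2 + 3 + 1) / 3,
                    "g3": (3 + 2 + 4) / 3, "g4": (4 + 1 + 3) / 3}
        for g, score in expected.items():
            assert res.table.loc[g, "composite_score"] == pytest.approx(score)

    def test_scale_invariance(self):
        fb, adjusted = adjusted_from_sim(seed=9)
        reg = ws.study_trait_registry()
        tm1 = ws.build_trait_matrix(adjusted)
        scaled = {
            t: ws.adjust_means(
                ws.FieldBook(fb.data.assign(**{t2: fb.data[t2] * (3.0 if t2 == t else 1.0)
                                               for t2 in fb.trait_names})), t)
            for t in fb.trait_names
        }
        tm2 = ws.build_trait_matrix(scaled)
        r1 = ws.rank_genotypes(tm1, reg)
        r2 = ws.rank_genotypes(tm2, reg)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_missing_direction_rejected(self):
        vals = np.array([[1.0], [2.0]])
        tm = TraitMatrix(["a", "b"], ["t"], standardize(vals),
                         standardized=True, raw_values=vals)
        with pytest.raises(ParameterError):
            ws.rank_genotypes(tm, TraitRegistry({}))
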