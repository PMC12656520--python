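import numpy as np
import pandas as pd
import pytest

from seedhtt import (
    DataError,
    TraitMatrix,
    hcpc,
    pca,
    trait_correlations,
)

RNG = np.random.default_rng(12345)


@pytest.fixture(scope="module")
def trait_matrix():
    """Six synthetic cultivars × five trait columns (stand-in trait table)."""
    data = RNG.normal(size=(6, 5))
    df = pd.DataFrame(
        data,
        index=[f"cv{i}" for i in range(6)],
        columns=["oleic", "linoleic", "linolenic", "palmitic", "stearic"],
    )
    df["Tb"] = RNG.normal(10, 3, size=6)
    df["theta_HT"] = RNG.normal(800, 300, size=6)
    return TraitMatrix(
        df,
        active_columns=["oleic", "linoleic", "linolenic", "palmitic", "stearic"],
        supplementary_columns=["Tb", "theta_HT"],
    )


class TestPca:
    def test_matches_brute_force_eigendecomposition(self, trait_matrix):
        res = pca(trait_matrix)
        X = trait_matrix.active.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        C = np.corrcoef(Z, rowvar=False)
        w, v = np.linalg.eig(C)  # independent route (non-symmetric solver)
        order = np.argsort(w.real)[::-1]
        w = w.real[order]
        v = v.real[:, order]
        np.testing.assert_allclose(res.eigenvalues, w, atol=1e-10)
        for k in range(v.shape[1]):
            got = res.loadings.iloc[:, k].to_numpy()
            exp = v[:, k] * np.sqrt(max(w[k], 0.0))
            if np.dot(got, exp) < 0:
                exp = -exp
            np.testing.assert_allclose(got, exp, atol=1e-10)

    def test_cross_check_against_sklearn(self, trait_matrix):
        sk = pytest.importorskip("sklearn.decomposition")
        X = trait_matrix.active.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = sk.PCA().fit(Z)
        res = pca(trait_matrix)
        np.testing.assert_allclose(
            res.eigenvalues, ref.explained_variance_, atol=1e-10
        )
        for k in range(res.scores.shape[1]):
            a = res.scores.iloc[:, k].to_numpy()
            b = ref.transform(Z)[:, k]
            if np.dot(a, b) < 0:
                b = -b
            np.testing.assert_allclose(a, b, atol=1e-8)

    def test_variance_and_contribution_sums(self, trait_matrix):
        res = pca(trait_matrix)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-8)
        for col in res.contributions:
            assert res.contributions[col].sum() == pytest.approx(100.0, abs=1e-8)
        assert ((res.cos2 >= 0) & (res.cos2 <= 1)).all().all()

    def test_full_rank_square_case_accounts_for_everything(self):
        # six observations on five independent variables: five components
        df = pd.DataFrame(RNG.normal(size=(6, 5)), columns=list("abcde"))
        res = pca(TraitMatrix(df, list("abcde")))
        assert len(res.eigenvalues) == 5
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-8)

    def test_duplicated_column_symmetry(self):
        df = pd.DataFrame(RNG.normal(size=(8, 3)), columns=["a", "b", "c"])
        df["a2"] = df["a"]
        res = pca(TraitMatrix(df, ["a", "a2", "b", "c"]))
        # atol above machine noise: the duplicate pair spawns a numerically
        # zero eigenvalue whose loading is O(sqrt(eps)) rather than exactly 0
        np.testing.assert_allclose(
            res.loadings.loc["a"], res.loadings.loc["a2"], atol=1e-6
        )
        np.testing.assert_allclose(
            res.cos2.loc["a"], res.cos2.loc["a2"], atol=1e-6
        )

    def test_score_geometry(self, trait_matrix):
        res = pca(trait_matrix)
        S = res.scores.to_numpy()
        np.testing.assert_allclose(S.mean(0), 0.0, atol=1e-10)
        cov = np.cov(S, rowvar=False, ddof=1)
        np.testing.assert_allclose(cov, np.diag(res.eigenvalues), atol=1e-8)

    def test_sign_convention(self, trait_matrix):
        res = pca(trait_matrix)
        for col in res.loadings:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] >= 0

    def test_supplementary_does_not_alter_eigenvalues(self, trait_matrix):
        with_supp = pca(trait_matrix)
        without = pca(
            TraitMatrix(trait_matrix.data, trait_matrix.active_columns, [])
        )
        assert (with_supp.eigenvalues == without.eigenvalues).all()
        assert with_supp.supplementary.shape == (2, 5)
        assert without.supplementary is None

    def test_zero_variance_column_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(DataError, match="flat"):
            pca(TraitMatrix(df, ["a", "flat"]))


class TestHcpc:
    def test_duplicated_groups_recovered(self):
        row_a, row_b = RNG.normal(size=2, loc=0), RNG.normal(size=2, loc=8)
        df = pd.DataFrame(
            [row_a + RNG.normal(0, 1e-6, 2) for _ in range(3)]
            + [row_b + RNG.normal(0, 1e-6, 2) for _ in range(3)],
            columns=["x", "y"],
        )
        res = pca(TraitMatrix(df, ["x", "y"]))
        labels = hcpc(res, 2)
        assert len(set(labels[:3])) == 1
        assert len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_singletons_when_k_equals_rows(self, trait_matrix):
        res = pca(trait_matrix)
        labels = hcpc(res, 6)
        assert sorted(labels) == [1, 2, 3, 4, 5, 6]

    def test_k_exceeding_rows_errors(self, trait_matrix):
        with pytest.raises(DataError):
            hcpc(pca(trait_matrix), 7)

    def test_three_gaussian_blobs_recovered_across_seeds(self):
        centers = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 10]], dtype=float)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows, truth = [], []
            for ci, c in enumerate(centers):
                for _ in range(4):
                    rows.append(c + rng.normal(0, 0.3, size=3))
                    truth.append(ci)
            df = pd.DataFrame(rows, columns=["x", "y", "z"])
            labels = hcpc(pca(TraitMatrix(df, ["x", "y", "z"])), 3)
            # perfect recovery up to label permutation
            mapping = {}
            for lab, t in zip(labels, truth):
                mapping.setdefault(t, lab)
                assert mapping[t] == lab
            assert len(set(mapping.values())) == 3

    def test_permutation_equivariance(self, trait_matrix):
        res = pca(trait_matrix)
        base = hcpc(res, 3)
        perm = RNG.permutation(len(trait_matrix.data))
        shuffled = TraitMatrix(
            trait_matrix.data.iloc[perm],
            trait_matrix.active_columns,
            trait_matrix.supplementary_columns,
        )
        labels_perm = hcpc(pca(shuffled), 3)
        # same partition: pairs together before iff together after
        for i in range(len(perm)):
            for j in range(i + 1, len(perm)):
                assert (base[perm[i]] == base[perm[j]]) == (
                    labels_perm[i] == labels_perm[j]
                )


class TestTraitCorrelations:
    def test_self_correlation_is_one(self, trait_matrix):
        out = trait_correlations(trait_matrix, "oleic")
        r = out.set_index("trait").loc["oleic", "r"]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_orthogonalized_target_gives_zero(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        y = y - np.dot(y, x) / np.dot(x, x) * x  # remove the x component
        y = y - y.mean() + 0  # still orthogonal after centering? enforce below
        x = x - x.mean()
        y = y - np.dot(y, x) / np.dot(x, x) * x
        df = pd.DataFrame({"x": x, "target": y})
        out = trait_correlations(TraitMatrix(df, ["x"]), "target")
        assert abs(out["r"].iloc[0]) < 1e-10

    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(21)
        n = 200
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.8**2) * rng.normal(size=n)
        df = pd.DataFrame({"x": x, "target": y})
        out = trait_correlations(TraitMatrix(df, ["x"]), "target")
        assert out["r"].iloc[0] == pytest.approx(0.8, abs=0.05)
        assert not out["low_power"].iloc[0]

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "target": [1.0, 2.0, 3.0]})
        out = trait_correlations(TraitMatrix(df, ["flat"]), "target")
        assert out["undefined"].iloc[0]
        assert np.isnan(out["r"].iloc[0])
        assert out["low_power"].iloc[0]
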