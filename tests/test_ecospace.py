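import numpy as np
import pandas as pd
import pytest

from radiad.ecospace import (
    gower_matrix, phylo_residual, nmds_embed, hull_areas, ecospace_pipeline,
    EcospaceEmbedding,
)
from radiad.tree import patristic_matrix

from helpers import gower_bruteforce


class TestGower:
    def test_hand_example(self):
        # masses 0 and 1 (range 2 via a third row), same diet, different
        # activity: (0.5 + 0 + 1)/3 = 0.5
        df = pd.DataFrame(
            {
                "ln_mass_g": [0.0, 1.0, 2.0],
                "diet": ["f", "f", "o"],
                "activity": ["n", "d", "d"],
            },
            index=["s1", "s2", "s3"],
        )
        D = gower_matrix(df)
        assert D.loc["s1", "s2"] == pytest.approx(0.5)

    def test_identical_rows_zero(self):
        df = pd.DataFrame(
            {"ln_mass_g": [1.0, 1.0, 3.0], "diet": ["f", "f", "f"],
             "activity": ["n", "n", "n"]},
            index=list("abc"),
        )
        assert gower_matrix(df).loc["a", "b"] == 0.0

    def test_maximal_difference_is_one(self):
        df = pd.DataFrame(
            {"ln_mass_g": [0.0, 5.0], "diet": ["f", "o"],
             "activity": ["n", "d"]},
            index=["a", "b"],
        )
        assert gower_matrix(df).loc["a", "b"] == pytest.approx(1.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "ln_mass_g": rng.normal(6, 1.5, 25),
                "diet": rng.choice(["f", "o", "g"], 25),
                "activity": rng.choice(["n", "d"], 25),
            },
            index=[f"s{i}" for i in range(25)],
        )
        D = gower_matrix(df)
        ref = gower_bruteforce(df, ["ln_mass_g"], ["diet", "activity"])
        assert np.allclose(D.to_numpy(), ref)

    def test_zero_range_variable_dropped(self):
        df = pd.DataFrame(
            {"ln_mass_g": [2.0, 2.0], "diet": ["f", "o"], "activity": ["n", "n"]},
            index=["a", "b"],
        )
        with pytest.warns(UserWarning, match="zero range"):
            D = gower_matrix(df)
        assert D.loc["a", "b"] == pytest.approx(0.5)  # mean of (1, 0)


class TestPhyloResidual:
    def test_exact_linear_relation_gives_zero(self):
        rng = np.random.default_rng(1)
        n = 8
        P = rng.uniform(1, 10, (n, n))
        P = (P + P.T) / 2
        np.fill_diagonal(P, 0)
        idx = [f"s{i}" for i in range(n)]
        Dp = pd.DataFrame(P, index=idx, columns=idx)
        Dt = 0.3 + 0.05 * Dp
        Dt.values[np.diag_indices(n)] = 0.0
        # only off-diagonal pairs enter the regression
        R = phylo_residual(Dt, Dp)
        iu = np.tril_indices(n, -1)
        assert np.allclose(R.to_numpy()[iu], 0.0, atol=1e-12)

    def test_three_species_hand_ols(self):
        idx = ["a", "b", "c"]
        Dt = pd.DataFrame(0.0, index=idx, columns=idx)
        Dp = pd.DataFrame(0.0, index=idx, columns=idx)
        # pairs (ab, ac, bc): trait (1, 2, 3) on phylo (1, 2, 4)
        Dt.loc["b", "a"] = Dt.loc["a", "b"] = 1.0
        Dt.loc["c", "a"] = Dt.loc["a", "c"] = 2.0
        Dt.loc["c", "b"] = Dt.loc["b", "c"] = 3.0
        Dp.loc["b", "a"] = Dp.loc["a", "b"] = 1.0
        Dp.loc["c", "a"] = Dp.loc["a", "c"] = 2.0
        Dp.loc["c", "b"] = Dp.loc["b", "c"] = 4.0
        R = phylo_residual(Dt, Dp)
        x = np.array([1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 3.0])
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
        assert R.loc["b", "a"] == pytest.approx(resid[0], abs=1e-12)
        assert R.loc["c", "a"] == pytest.approx(resid[1], abs=1e-12)
        assert R.loc["c", "b"] == pytest.approx(resid[2], abs=1e-12)

    def test_residual_mean_zero(self, small_bundle):
        b = small_bundle
        sp = pd.DataFrame({
            "ln_mass_g": b.traits,
            "diet": b.niche.str.split("-").str[1],
            "activity": b.niche.str.split("-").str[0],
        }).dropna()
        Dt = gower_matrix(sp)
        Dp = patristic_matrix(b.tree).loc[sp.index, sp.index]
        R = phylo_residual(Dt, Dp)
        iu = np.tril_indices(len(R), -1)
        assert abs(R.to_numpy()[iu].mean()) < 1e-10

    def test_constant_phylo_distance_errors(self):
        idx = list("abc")
        Dt = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=idx, columns=idx)
        Dp = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=idx, columns=idx)
        Dp[:] = np.where(np.eye(3), 0.0, 2.0)
        with pytest.raises(ValueError, match="constant"):
            phylo_residual(Dt, Dp)


class TestNMDS:
    def test_collinear_points_embed_with_near_zero_stress_k1(self):
        x = np.linspace(0, 1, 8)
        D = np.abs(x[:, None] - x[None, :])
        idx = [f"p{i}" for i in range(8)]
        emb = nmds_embed(pd.DataFrame(D, index=idx, columns=idx), k=1,
                         n_starts=8, seed=0)
        assert emb.stress < 0.02

    def test_stress_nonincreasing_in_k(self, small_bundle):
        b = small_bundle
        sp = pd.DataFrame({
            "ln_mass_g": b.traits,
            "diet": b.niche.str.split("-").str[1],
            "activity": b.niche.str.split("-").str[0],
        }).dropna().iloc[:25]
        D = gower_matrix(sp)
        e2 = nmds_embed(D, k=2, n_starts=8, seed=1)
        e3 = nmds_embed(D, k=3, n_starts=8, seed=1)
        assert e3.stress <= e2.stress + 0.02

    def test_asymmetric_matrix_rejected(self):
        D = pd.DataFrame([[0, 1.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            nmds_embed(D)

    def test_coordinates_centered(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        idx = [f"p{i}" for i in range(10)]
        emb = nmds_embed(pd.DataFrame(D, index=idx, columns=idx),
                         n_starts=4, seed=3)
        assert np.allclose(emb.coords.mean(axis=0), 0.0, atol=1e-8)


class TestHulls:
    def _embedding(self, pts, names):
        return EcospaceEmbedding(
            coords=pd.DataFrame(pts, index=names, columns=["MDS1", "MDS2"]),
            stress=0.0, k=2,
        )

    def test_unit_square(self):
        emb = self._embedding(
            [[0, 0], [1, 0], [1, 1], [0, 1]], list("abcd")
        )
        out = hull_areas(emb, {"all": list("abcd")})
        assert out["all"]["area"] == pytest.approx(1.0)

    def test_triangle_shoelace(self):
        emb = self._embedding([[0, 0], [2, 0], [0, 2]], list("abc"))
        out = hull_areas(emb, {"all": list("abc")})
        assert out["all"]["area"] == pytest.approx(2.0)

    def test_collinear_zero_with_flag(self):
        emb = self._embedding([[0, 0], [1, 1], [2, 2]], list("abc"))
        out = hull_areas(emb, {"line": list("abc")})
        assert out["line"]["area"] == 0.0
        assert out["line"]["degenerate"]

    def test_too_few_points_zero_with_flag(self):
        emb = self._embedding([[0, 0], [1, 1]], list("ab"))
        out = hull_areas(emb, {"pair": list("ab")})
        assert out["pair"]["area"] == 0.0
        assert out["pair"]["degenerate"]

    def test_subset_hull_never_larger(self):
        rng = np.random.default_rng(7)
        for rep in range(10):
            pts = rng.normal(size=(20, 2))
            names = [f"p{i}" for i in range(20)]
            emb = self._embedding(pts, names)
            subset = list(rng.choice(names, size=8, replace=False))
            out = hull_areas(emb, {"all": names, "sub": subset})
            assert out["sub"]["area"] <= out["all"]["area"] + 1e-12

    def test_contraction_ratio(self):
        emb = self._embedding(
            [[0, 0], [4, 0], [0, 4], [1, 0], [0, 1], [1, 1]],
            ["e1", "e2", "e3", "x1", "x2", "x3"],
        )
        out = hull_areas(emb, {"all": ["e1", "e2", "e3", "x1", "x2", "x3"],
                               "extant": ["x1", "x2", "x3"]})
        assert out["contraction_ratio"] == pytest.approx(0.5 / 8.0)


class TestPipeline:
    def test_deterministic_under_seed(self, small_bundle):
        b = small_bundle
        sp = pd.DataFrame({
            "ln_mass_g": b.traits,
            "diet": b.niche.str.split("-").str[1],
            "activity": b.niche.str.split("-").str[0],
            "extinct": b.extinct,
        }).dropna()
        Dp = patristic_matrix(b.tree).loc[sp.index, sp.index]
        e1 = ecospace_pipeline(sp, Dp, n_starts=4, seed=11)
        e2 = ecospace_pipeline(sp, Dp, n_starts=4, seed=11)
        assert np.allclose(e1.coords.to_numpy(), e2.coords.to_numpy())
        assert e1.hulls["all"]["area"] == pytest.approx(e2.hulls["all"]["area"])

    def test_extinction_contracts_ecospace(self, small_bundle):
        # extinct species are the largest-bodied: losing them shrinks the
        # occupied hull
        b = small_bundle
        sp = pd.DataFrame({
            "ln_mass_g": b.traits,
            "diet": b.niche.str.split("-").str[1],
            "activity": b.niche.str.split("-").str[0],
            "extinct": b.extinct,
        }).dropna()
        Dp = patristic_matrix(b.tree).loc[sp.index, sp.index]
        emb = ecospace_pipeline(sp, Dp, n_starts=6, seed=5)
        assert emb.hulls["contraction_ratio"] < 1.0
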