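import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from skbio.stats.distance import DistanceMatrix

from microdorm.model import ValidationError
from microdorm.preprocess import sqrt_wisconsin
from microdorm.stats import (
    beta_dispersion,
    bray_curtis,
    distance_decay,
    geographic_distances,
    mantel,
    partial_mantel,
    pcoa,
    permanova,
    shannon,
)


def naive_bray_curtis(x: np.ndarray) -> np.ndarray:
    """Double-loop Bray-Curtis oracle over columns."""
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = np.abs(x[:, i] - x[:, j]).sum()
            den = (x[:, i] + x[:, j]).sum()
            d[i, j] = num / den
    return d


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        m = pd.DataFrame({"a": [1, 0], "b": [1, 0], "c": [0, 3]})
        dm = bray_curtis(m)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_standardization_chain_example(self):
        m = pd.DataFrame({"s1": [4, 1], "s2": [1, 4]}, index=["A", "B"])
        dm = bray_curtis(sqrt_wisconsin(m))
        assert dm["s1", "s2"] == pytest.approx(1 / 3)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.random((6, 5)) + 0.01
            dm = bray_curtis(pd.DataFrame(x))
            np.testing.assert_allclose(dm.data, naive_bray_curtis(x), atol=1e-12)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError, match="all-zero"):
            bray_curtis(pd.DataFrame({"a": [1, 1], "b": [0, 0]}))


class TestShannon:
    def test_single_taxon_zero(self):
        assert shannon([7]) == 0.0

    def test_uniform_is_log_richness(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_hand_computed(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_errors(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])


class TestPcoa:
    def test_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.random((7, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(7)]))
        coords = res.coordinates.to_numpy()
        d2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_three_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_duplicated_sample_coincides(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1, 1, 0]])
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        np.testing.assert_allclose(
            res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-10
        )

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            pcoa(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]))


class TestPermanova:
    def test_perfectly_separated_groups(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        dm = DistanceMatrix(d, ids=list("abcd"))
        design = pd.DataFrame({"g": ["x", "x", "y", "y"]}, index=list("abcd"))
        res = permanova(dm, design, ["g"], n_perm=999, seed=0)
        assert res.r2("g") == pytest.approx(1.0)
        # only 3 distinct partitions of 2+2 labels; 1/3 of permutations tie
        assert res.p("g") == pytest.approx(1 / 3, abs=0.06)

    def test_matches_vegan_sequential_table(self, vegan_fixture):
        counts, meta = vegan_fixture
        dm = bray_curtis(sqrt_wisconsin(counts))
        res = permanova(dm, meta, ["g", "h"], n_perm=99, seed=0)
        # frozen from R vegan 2.7 adonis2(d ~ g + h, by="terms")
        assert res.table.loc["g", "SS"] == pytest.approx(0.0118191068127, abs=1e-10)
        assert res.table.loc["h", "SS"] == pytest.approx(0.0211564505914, abs=1e-10)
        assert res.table.loc["g", "R2"] == pytest.approx(0.060470551638, abs=1e-10)
        assert res.table.loc["h", "R2"] == pytest.approx(0.108243563430, abs=1e-10)
        assert res.table.loc["g", "F"] == pytest.approx(0.65469, abs=1e-5)
        assert res.table.loc["h", "F"] == pytest.approx(1.17191, abs=1e-5)
        assert res.table.loc["Residual", "df"] == 9

    def test_r2_partition_and_p_floor(self, vegan_fixture):
        counts, meta = vegan_fixture
        dm = bray_curtis(sqrt_wisconsin(counts))
        res = permanova(dm, meta, ["g", "h"], n_perm=49, seed=1)
        assert res.table.loc[["g", "h", "Residual"], "R2"].sum() == pytest.approx(1.0, abs=1e-10)
        assert (res.table["p"].dropna() >= 1 / 50).all()

    def test_cumulative_r2_nondecreasing(self, vegan_fixture):
        counts, meta = vegan_fixture
        dm = bray_curtis(sqrt_wisconsin(counts))
        r_one = permanova(dm, meta, ["g"], n_perm=9, seed=0)
        r_two = permanova(dm, meta, ["g", "h"], n_perm=9, seed=0)
        cum_one = r_one.table.loc["g", "R2"]
        cum_two = r_two.table.loc[["g", "h"], "R2"].sum()
        assert cum_two >= cum_one - 1e-12
        assert r_two.table.loc["g", "R2"] == pytest.approx(cum_one, abs=1e-12)

    def test_single_level_term_rejected(self, vegan_fixture):
        counts, meta = vegan_fixture
        dm = bray_curtis(sqrt_wisconsin(counts))
        meta = meta.assign(const="z")
        with pytest.raises(ValidationError, match="single level"):
            permanova(dm, meta, ["const"], n_perm=9, seed=0)

    def test_strata_respected(self, vegan_fixture):
        counts, meta = vegan_fixture
        dm = bray_curtis(sqrt_wisconsin(counts))
        res = permanova(dm, meta, ["h"], n_perm=99, seed=3, strata="g")
        assert 0 < res.p("h") <= 1.0


class TestBetaDispersion:
    def test_matches_vegan_centroid_distances(self, vegan_fixture):
        counts, meta = vegan_fixture
        dm = bray_curtis(sqrt_wisconsin(counts))
        res = beta_dispersion(dm, meta["g"], n_perm=99, seed=0)
        expected = [
            0.0868263433570, 0.0585024567053, 0.1279414639099, 0.1055998905851,
            0.0675540419867, 0.1213757856913, 0.1067332128201, 0.1219884801771,
            0.1861669891320, 0.1431958401798, 0.1557789395418, 0.1419591070371,
        ]  # frozen from R vegan 2.7 betadisper(type="centroid")
        np.testing.assert_allclose(res.distances.to_numpy(), expected, atol=1e-10)
        assert res.f_statistic == pytest.approx(8.83086705968, abs=1e-8)

    def test_identical_samples_have_zero_dispersion(self):
        d = np.zeros((4, 4))
        d[:2, 2:] = 1.0
        d[2:, :2] = 1.0
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = beta_dispersion(dm, pd.Series(list("xxyy"), index=list("abcd")), n_perm=19, seed=0)
        np.testing.assert_allclose(res.distances.to_numpy(), 0.0, atol=1e-12)

    def test_singleton_group_excluded_with_warning(self, vegan_fixture):
        counts, meta = vegan_fixture
        dm = bray_curtis(sqrt_wisconsin(counts))
        groups = meta["g"].copy()
        groups.iloc[0] = "solo"
        with pytest.warns(UserWarning, match="singleton"):
            res = beta_dispersion(dm, groups, n_perm=19, seed=0)
        assert "solo" not in res.group_means.index


class TestMantel:
    def test_affine_invariance(self, vegan_fixture):
        counts, _ = vegan_fixture
        dm = bray_curtis(sqrt_wisconsin(counts))
        dm2 = DistanceMatrix(2.0 * dm.data, ids=list(dm.ids))
        r, _ = mantel(dm, dm2, n_perm=19, seed=0)
        assert r == pytest.approx(1.0)

    def test_matches_vegan_statistic(self, vegan_fixture):
        counts, _ = vegan_fixture
        dm = bray_curtis(sqrt_wisconsin(counts))
        geo = np.abs(np.subtract.outer(np.arange(12.0), np.arange(12.0)))
        r, _ = mantel(dm, DistanceMatrix(geo, ids=list(dm.ids)), n_perm=19, seed=0)
        assert r == pytest.approx(-0.0908082570109, abs=1e-10)  # frozen from vegan

    def test_equals_direct_triangle_correlation(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = squareform(rng.random(6))
            b = squareform(rng.random(6))
            ids = list("abcd")
            r, _ = mantel(
                DistanceMatrix(a, ids=ids), DistanceMatrix(b, ids=ids), n_perm=9, seed=0
            )
            direct = pearsonr(squareform(a), squareform(b)).statistic
            assert r == pytest.approx(direct, abs=1e-12)

    def test_constant_triangle_rejected(self):
        ids = list("abc")
        flat = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=ids)
        other = DistanceMatrix(squareform([1.0, 2.0, 3.0]), ids=ids)
        with pytest.raises(ValidationError, match="constant"):
            mantel(flat, other, n_perm=9, seed=0)


class TestPartialMantel:
    def test_closed_form_partial_correlation(self):
        rng = np.random.default_rng(5)
        ids = [str(i) for i in range(5)]
        a, b, c = (DistanceMatrix(squareform(rng.random(10)), ids=ids) for _ in range(3))
        r, _ = partial_mantel(a, b, c, n_perm=9, seed=0)
        ta, tb, tc = (squareform(m.data) for m in (a, b, c))
        r_ab = pearsonr(ta, tb).statistic
        r_ac = pearsonr(ta, tc).statistic
        r_bc = pearsonr(tb, tc).statistic
        expected = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        assert r == pytest.approx(expected, abs=1e-10)

    def test_fully_confounded_covariate_zeroes_partial_r(self):
        rng = np.random.default_rng(6)
        ids = [str(i) for i in range(6)]
        a = DistanceMatrix(squareform(rng.random(15)), ids=ids)
        b = DistanceMatrix(squareform(rng.random(15)), ids=ids)
        r, _ = partial_mantel(a, b, b, n_perm=9, seed=0)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_uncorrelated_covariate_leaves_r_similar(self):
        rng = np.random.default_rng(7)
        ids = [str(i) for i in range(20)]
        x = rng.random(20)
        y = x + rng.normal(0, 0.05, 20)
        da = DistanceMatrix(np.abs(np.subtract.outer(x, x)), ids=ids)
        db = DistanceMatrix(np.abs(np.subtract.outer(y, y)), ids=ids)
        dc = DistanceMatrix(squareform(rng.random(190)), ids=ids)
        r_simple, _ = mantel(da, db, n_perm=9, seed=0)
        r_partial, _ = partial_mantel(da, db, dc, n_perm=9, seed=0)
        assert abs(r_partial - r_simple) < 0.1


class TestDistanceDecay:
    def _structured(self, rng, n_sites=5, turnover=1.0):
        """Communities whose composition drifts with 1-D location."""
        locs = np.linspace(0, 1000, n_sites)
        ids = [f"s{i}" for i in range(n_sites)]
        base = rng.random((30, n_sites))
        drift = np.exp(turnover * np.outer(rng.normal(0, 1, 30), locs / 1000.0))
        comm = pd.DataFrame(base * drift, columns=ids)
        geo = geographic_distances(pd.DataFrame({"x": locs, "y": 0.0}, index=ids))
        return bray_curtis(comm), geo

    def test_turnover_yields_positive_r(self):
        hits = 0
        for seed in range(20):
            comm, geo = self._structured(np.random.default_rng(seed), n_sites=8, turnover=3.0)
            table = distance_decay(comm, geo, n_perm=99, seed=seed)
            hits += table.loc["overall", "mantel_r"] > 0
        assert hits >= 19

    def test_unstructured_r_centered_on_zero(self):
        rs = []
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            comm, geo = self._structured(rng, n_sites=8, turnover=0.0)
            table = distance_decay(comm, geo, n_perm=9, seed=seed)
            rs.append(table.loc["overall", "mantel_r"])
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.1

    def test_zero_distances_rejected(self):
        rng = np.random.default_rng(8)
        comm = bray_curtis(pd.DataFrame(rng.random((10, 4)), columns=list("abcd")))
        geo = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(ValidationError, match="positive"):
            distance_decay(comm, geo)
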