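"""Mantel and Spearman sympatry statistics against independent oracles."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from allopatry import (
    DegenerateMatrixError,
    LabeledMatrix,
    LabelMismatchError,
    SiteRecord,
    SiteTable,
    geographic_distance_matrix,
    mantel,
    similarity_to_distance,
    spearman_sympatry,
    standardize_upper_triangle,
    sympatry_matrix,
)

from conftest import SIX_NEW_ISOLATES
from oracles import (
    exhaustive_mantel_p,
    pearson_upper_triangles,
    random_distance_matrix,
)


def _dist(values, labels=None):
    n = values.shape[0]
    labels = labels or [f"L{i}" for i in range(n)]
    return LabeledMatrix(labels, values, kind="distance_km")


class TestStandardize:
    def test_three_entry_z_scores(self):
        # upper triangle {1, 2, 3}: mean 2, sample sd 1 -> {-1, 0, 1}
        v = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        z = standardize_upper_triangle(_dist(v))
        assert np.allclose(z, [-1.0, 0.0, 1.0])

    def test_constant_entries_degenerate(self):
        v = np.full((4, 4), 5.0)
        np.fill_diagonal(v, 0.0)
        with pytest.raises(DegenerateMatrixError):
            standardize_upper_triangle(_dist(v))

    def test_fixture_standardization_moments(self, ddh):
        z = standardize_upper_triangle(similarity_to_distance(ddh))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.var(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestMantelStatistic:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = _dist(random_distance_matrix(rng, 5))
        res = mantel(x, x, n_perm=0)
        assert res.r_m == pytest.approx(1.0, abs=1e-12)
        assert res.d == 10

    def test_positive_affine_invariance_and_negation(self):
        rng = np.random.default_rng(1)
        v = random_distance_matrix(rng, 5)
        w = 3.0 * v + 7.0
        np.fill_diagonal(w, 0.0)  # affine transform of the off-diagonal entries
        assert mantel(_dist(v), _dist(w), n_perm=0).r_m == pytest.approx(1.0)
        # negating one matrix flips the sign of the statistic
        assert pearson_upper_triangles(v, -v) == pytest.approx(-1.0)

    def test_statistic_equals_pearson_oracle(self):
        rng = np.random.default_rng(2)
        for n in (4, 5, 6):
            for _ in range(20):
                x = random_distance_matrix(rng, n)
                y = random_distance_matrix(rng, n)
                res = mantel(_dist(x), _dist(y), n_perm=0)
                assert res.r_m == pytest.approx(pearson_upper_triangles(x, y), abs=1e-12)

    def test_statistic_matches_scikit_bio(self):
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        from skbio import DistanceMatrix

        rng = np.random.default_rng(3)
        x = random_distance_matrix(rng, 6)
        y = random_distance_matrix(rng, 6)
        r_skbio, _, _ = skbio_mantel(
            DistanceMatrix(x), DistanceMatrix(y), permutations=0
        )
        assert mantel(_dist(x), _dist(y), n_perm=0).r_m == pytest.approx(
            float(r_skbio), abs=1e-12
        )

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(4)
        x = _dist(random_distance_matrix(rng, 5))
        y = _dist(random_distance_matrix(rng, 5))
        assert mantel(x, y, n_perm=0).r_m == mantel(y, x, n_perm=0).r_m

    def test_label_reconciliation_by_name_not_position(self):
        rng = np.random.default_rng(5)
        v = random_distance_matrix(rng, 4)
        labels = ["a", "b", "c", "d"]
        x = _dist(v, labels)
        perm = [2, 0, 3, 1]
        y = _dist(v[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert mantel(x, y, n_perm=0).r_m == pytest.approx(1.0, abs=1e-12)

    def test_label_mismatch_names_difference(self):
        rng = np.random.default_rng(6)
        x = _dist(random_distance_matrix(rng, 4), ["a", "b", "c", "d"])
        y = _dist(random_distance_matrix(rng, 4), ["a", "b", "c", "e"])
        with pytest.raises(LabelMismatchError, match="d.*e|e.*d"):
            mantel(x, y)


class TestMantelPermutation:
    def test_exhaustive_p_equals_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for n in (4, 5):
            for _ in range(5):
                x = random_distance_matrix(rng, n)
                y = random_distance_matrix(rng, n)
                for alt in ("greater", "less", "two-sided"):
                    res = mantel(_dist(x), _dist(y), n_perm=10**6, alternative=alt)
                    assert res.exhaustive
                    assert res.p_value == pytest.approx(
                        exhaustive_mantel_p(x, y, alt), abs=1e-12
                    )

    def test_monte_carlo_close_to_exhaustive(self):
        rng = np.random.default_rng(8)
        x = random_distance_matrix(rng, 6)
        y = random_distance_matrix(rng, 6)
        exact = mantel(_dist(x), _dist(y), n_perm=10**6).p_value
        mc = mantel(_dist(x), _dist(y), n_perm=719, seed=123).p_value
        # 719 < 6! forces the Monte-Carlo path; binomial error bound
        se = np.sqrt(exact * (1 - exact) / 719)
        assert abs(mc - exact) < 4 * se + 2 / 719

    def test_seed_required_for_monte_carlo(self):
        rng = np.random.default_rng(9)
        x = _dist(random_distance_matrix(rng, 8))
        y = _dist(random_distance_matrix(rng, 8))
        with pytest.raises(ValueError, match="seed"):
            mantel(x, y, n_perm=99)

    def test_fixture_isolation_by_distance_signal(self, ddh, site_table):
        geo = geographic_distance_matrix(site_table)
        gen = similarity_to_distance(ddh.reorder(site_table.names))
        res = mantel(gen, geo, n_perm=10**6)
        assert res.exhaustive and res.n == 6
        assert res.r_m > 0
        assert res.p_value <= 0.05


class TestSympatryMatrix:
    def test_all_same_plate(self):
        table = SiteTable(SiteRecord(f"s{i}", plate="P") for i in range(3))
        m = sympatry_matrix(table)
        assert np.all(m.values == 1.0)

    def test_fixture_plate_blocks(self, nine_strain_plate_table):
        m = sympatry_matrix(nine_strain_plate_table)
        eurasian = ["SolV", "Fur", "Rib", "Fdl", "Ice"]
        for a in eurasian:
            for b in eurasian:
                assert m.loc(a, b) == 1.0
        for a in eurasian:
            for b in ("Yel", "Phi", "V4", "Kam1"):
                assert m.loc(a, b) == 0.0
        assert m.loc("Yel", "Kam1") == 0.0

    def test_pairwise_distinct_plates_identity_pattern(self):
        table = SiteTable(SiteRecord(f"s{i}", plate=f"P{i}") for i in range(4))
        m = sympatry_matrix(table)
        assert np.array_equal(m.values, np.eye(4))

    def test_missing_plate_listed(self):
        table = SiteTable([SiteRecord("a", plate="P"), SiteRecord("b")])
        with pytest.raises(ValueError, match="b"):
            sympatry_matrix(table)


class TestSpearmanSympatry:
    @staticmethod
    def _toy(genetic_values, plates):
        labels = [f"s{i}" for i in range(len(plates))]
        gen = LabeledMatrix(labels, genetic_values, kind="similarity_percent")
        table = SiteTable(
            SiteRecord(lab, plate=p) for lab, p in zip(labels, plates)
        )
        return gen, sympatry_matrix(table)

    def test_within_plate_concordance_positive(self):
        v = np.array(
            [
                [100, 95, 40, 41],
                [95, 100, 42, 43],
                [40, 42, 100, 96],
                [41, 43, 96, 100],
            ],
            dtype=float,
        )
        gen, symp = self._toy(v, ["A", "A", "B", "B"])
        assert spearman_sympatry(gen, symp, n_perm=0).r_s > 0

    def test_ties_match_textbook_average_rank_oracle(self):
        # two tied genetic values among the six pairs of a 4-label example
        v = np.array(
            [
                [100, 90, 80, 80],
                [90, 100, 70, 60],
                [80, 70, 100, 50],
                [80, 60, 50, 100],
            ],
            dtype=float,
        )
        gen, symp = self._toy(v, ["A", "A", "B", "B"])
        res = spearman_sympatry(gen, symp, n_perm=0)
        iu = np.triu_indices(4, k=1)
        rho, _ = spearmanr(v[iu], symp.values[iu])
        assert res.r_s == pytest.approx(float(rho), abs=1e-12)

    def test_all_sympatric_degenerate(self):
        rng = np.random.default_rng(10)
        v = rng.uniform(0, 99, (4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 100.0)
        gen, symp = self._toy(v, ["A", "A", "A", "A"])
        with pytest.raises(DegenerateMatrixError):
            spearman_sympatry(gen, symp, n_perm=0)

    def test_fixture_nine_strain_positive(self, ddh, nine_strain_plate_table):
        symp = sympatry_matrix(nine_strain_plate_table)
        res = spearman_sympatry(ddh, symp, n_perm=9999, seed=17)
        assert res.r_s > 0
        assert res.n == 9 and res.n_pairs == 36
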