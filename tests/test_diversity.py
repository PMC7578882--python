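"""Alpha/beta diversity estimators against independent formula oracles."""

import numpy as np
import pytest
from scipy import stats
from skbio.diversity.alpha import ace as skbio_ace, chao1 as skbio_chao1

from gutmarkers.diversity import (
    DistanceMatrix,
    ace,
    bray_curtis,
    chao1,
    group_overlap,
    observed_otus,
    pcoa,
    rarefaction_curve,
    shannon,
)
from gutmarkers.tables import OtuTable


def random_count_vectors(n, rng, size=30, max_count=20):
    for _ in range(n):
        v = rng.integers(0, max_count, size=size)
        if v.sum() == 0:
            v[0] = 1
        yield v


class TestObservedOtus:
    def test_examples(self):
        assert observed_otus([0, 0, 5]) == 1
        assert observed_otus([0, 0, 0]) == 0

    def test_matches_enumeration(self, rng):
        for v in random_count_vectors(100, rng):
            assert observed_otus(v) == sum(1 for c in v if c > 0)


class TestShannon:
    def test_uniform_is_log_k(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(np.log(4), abs=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([7, 0, 0]) == 0.0

    def test_formula_oracle(self, rng):
        for v in random_count_vectors(200, rng):
            p = v[v > 0] / v.sum()
            expected = -(p * np.log(p)).sum()
            assert shannon(v) == pytest.approx(expected, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_bounded_by_log_richness(self, rng):
        for v in random_count_vectors(200, rng):
            s = observed_otus(v)
            assert shannon(v) <= np.log(max(s, 1)) + 1e-12


class TestChao1:
    def test_no_singletons_gives_observed(self):
        assert chao1([3, 5, 2, 0]) == 3.0  # F1=0 -> S_obs

    def test_hand_worked_value(self):
        # S_obs=5, F1=2, F2=1 -> 5 + 2*1/(2*2) = 5.5
        assert chao1([1, 1, 2, 3, 4]) == 5.5

    def test_never_below_observed_and_matches_skbio(self, rng):
        for v in random_count_vectors(300, rng, size=40, max_count=5):
            c = chao1(v)
            assert c >= observed_otus(v)
            assert c == pytest.approx(skbio_chao1(v, bias_corrected=True), abs=1e-9)


class TestAce:
    def test_all_abundant_gives_observed(self):
        assert ace([20, 30, 40]) == 3.0

    def test_matches_skbio(self, rng):
        for v in random_count_vectors(300, rng, size=40, max_count=15):
            rare = v[(v > 0) & (v <= 10)]
            if rare.size == 0 or (rare == 1).sum() == rare.sum():
                continue  # skbio raises on the degenerate-coverage cases
            assert ace(v) == pytest.approx(skbio_ace(v), abs=1e-9)

    def test_degenerate_coverage_falls_back_to_chao1(self):
        v = np.array([1, 1, 1, 50])
        assert ace(v) == chao1(v)

    def test_never_below_observed(self, rng):
        for v in random_count_vectors(300, rng, size=40, max_count=15):
            assert ace(v) >= observed_otus(v) - 1e-12


class TestRarefactionCurve:
    def test_depth_one_and_full_depth(self):
        counts = np.array([[5, 5, 0], [2, 2, 6]])
        table = OtuTable(["S1", "S2"], ["A", "B", "C"], counts)
        curve = rarefaction_curve(table, [1, 10], reps=5, seed=0)
        assert curve.loc[1, "all"] == 1.0
        expected_full = np.mean([observed_otus(c) for c in counts])
        assert curve.loc[10, "all"] == expected_full

    def test_matches_closed_form_expectation(self):
        """E[observed at depth d] = sum_j 1 - C(N-n_j, d)/C(N, d)."""
        counts = np.array([[12, 6, 2, 0, 1]])
        table = OtuTable(["S1"], list("ABCDE"), counts)
        d, N = 8, counts.sum()
        expected = sum(
            1 - stats.hypergeom(N, n_j, d).pmf(0) for n_j in counts[0] if n_j > 0
        )
        curve = rarefaction_curve(table, [d], reps=400, seed=1)
        # MC error of the mean of 400 reps
        assert curve.loc[d, "all"] == pytest.approx(expected, abs=0.15)

    def test_empty_depths_rejected(self, random_table):
        with pytest.raises(ValueError):
            rarefaction_curve(random_table, [], reps=2, seed=0)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = OtuTable(["S1", "S2"], ["A", "B"], np.array([[3, 3], [3, 3]]))
        assert bray_curtis(t).d[0, 1] == 0.0
        t = OtuTable(["S1", "S2"], ["A", "B"], np.array([[5, 0], [0, 5]]))
        assert bray_curtis(t).d[0, 1] == 1.0

    def test_formula_oracle(self, rng):
        for _ in range(100):
            x = rng.random(6)
            y = rng.random(6)
            x, y = x / x.sum(), y / y.sum()
            dm = bray_curtis(
                __import__("pandas").DataFrame([x, y], index=["a", "b"]))
            expected = 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())
            assert dm.d[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_axioms(self, rng, random_table):
        d = bray_curtis(random_table).d
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert d.min() >= 0 and d.max() <= 1


class TestPcoa:
    def test_recovers_collinear_points(self):
        pts = np.array([0.0, 1.0, 3.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        axis1 = res.coordinates[:, 0]
        centered = pts - pts.mean()
        err = min(np.abs(axis1 - centered).max(), np.abs(axis1 + centered).max())
        assert err < 1e-9

    def test_identical_samples_identical_coords(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(DistanceMatrix(list("abc"), d))
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_eigenvalue_trace_identity(self, random_table):
        dm = bray_curtis(random_table)
        res = pcoa(dm)
        d2 = dm.d**2
        n = d2.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        gower = -0.5 * j @ d2 @ j
        eig = np.linalg.eigvalsh(gower)
        assert res.eigenvalues.sum() == pytest.approx(eig[eig > 0].sum(), abs=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() <= 1 + 1e-12

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1.0], [0.5, 0]]))


class TestGroupOverlap:
    def test_identical_groups(self):
        counts = np.array([[1, 0, 2], [1, 0, 2]])
        t = OtuTable(["S1", "S2"], list("ABC"), counts)
        out = group_overlap(t, ["g1", "g2"])
        assert out == {"shared": 2, "unique_per_group": {"g1": 0, "g2": 0}, "total": 2}

    def test_disjoint_supports(self):
        counts = np.array([[3, 0], [0, 3]])
        t = OtuTable(["S1", "S2"], list("AB"), counts)
        out = group_overlap(t, ["g1", "g2"])
        assert out["shared"] == 0
        assert out["unique_per_group"] == {"g1": 1, "g2": 1}

    def test_matches_set_algebra(self, rng):
        counts = rng.integers(0, 3, size=(8, 15))
        groups = np.array(["x"] * 4 + ["y"] * 4)
        t = OtuTable([f"S{i}" for i in range(8)], [f"O{j}" for j in range(15)], counts)
        out = group_overlap(t, groups)
        x_set = {j for j in range(15) if counts[:4, j].sum() >= 1}
        y_set = {j for j in range(15) if counts[4:, j].sum() >= 1}
        assert out["shared"] == len(x_set & y_set)
        assert out["unique_per_group"] == {"x": len(x_set - y_set), "y": len(y_set - x_set)}
        assert out["total"] == len(x_set | y_set)
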