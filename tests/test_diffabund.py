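"""Wilcoxon/Kruskal-Wallis screens and LDA effect sizes."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutmarkers.diffabund import (
    aggregate_taxa,
    kruskal_wallis,
    lda_effect_size,
    wilcoxon_rank_sum,
    wilcoxon_screen,
)
from gutmarkers.tables import OtuTable, TaxonomyMap


class TestAggregateTaxa:
    def test_single_genus_collapses_to_row_totals(self):
        counts = np.array([[1, 2, 3], [4, 0, 6]])
        t = OtuTable(["S1", "S2"], ["O1", "O2", "O3"], counts)
        tax = TaxonomyMap({o: ("Bacteria", "Firmicutes", "Clostridia",
                               "Clostridiales", "Lachnospiraceae", "Blautia")
                           for o in t.otu_ids})
        agg = aggregate_taxa(t, tax, "genus")
        assert agg.otu_ids == ["Blautia"]
        assert agg.counts[:, 0].tolist() == [6, 10]

    def test_truncated_lineage_pooled_and_conserved(self, rng):
        counts = rng.integers(0, 9, size=(4, 6))
        t = OtuTable([f"S{i}" for i in range(4)], [f"O{j}" for j in range(6)], counts)
        tax = TaxonomyMap({
            "O0": ("Bacteria", "Firmicutes"),
            "O1": ("Bacteria", "Firmicutes", "Clostridia"),
            "O2": ("Bacteria", "Proteobacteria", "Gamma"),
            "O3": ("Bacteria", "Proteobacteria", "Gamma"),
            "O4": ("Bacteria",),
            "O5": ("Bacteria", "Firmicutes", "Bacilli"),
        })
        agg = aggregate_taxa(t, tax, "class")
        assert agg.counts.sum() == counts.sum()  # conservation at every rank
        # brute-force group-by
        expected = {}
        label = {"O0": "Firmicutes_norank", "O1": "Clostridia", "O2": "Gamma",
                 "O3": "Gamma", "O4": "Bacteria_norank", "O5": "Bacilli"}
        for j, o in enumerate(t.otu_ids):
            expected.setdefault(label[o], np.zeros(4, dtype=int))
            expected[label[o]] += counts[:, j]
        for name, col in expected.items():
            assert agg.counts[:, agg.otu_ids.index(name)].tolist() == col.tolist()

    def test_empty_taxonomy_rejected(self, random_table):
        with pytest.raises(ValueError):
            aggregate_taxa(random_table, TaxonomyMap({}), "genus")


class TestWilcoxon:
    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_exact_complete_separation(self):
        """3-vs-3 complete separation: p = 2/C(6,3) ... = 0.1 two-sided."""
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_enumeration(self, rng):
        """Exact p equals brute-force enumeration over rank assignments."""
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:4].sum()
        n = len(pooled)
        mu = 4 * (n + 1) / 2
        count = sum(
            1 for c in combinations(range(n), 4)
            if abs(ranks[list(c)].sum() - mu) >= abs(obs - mu) - 1e-12
        )
        expected = count / len(list(combinations(range(n), 4)))
        assert wilcoxon_rank_sum(x, y) == pytest.approx(expected, abs=1e-12)

    def test_monotone_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=15) + 0.5
        p1 = wilcoxon_rank_sum(x, y)
        p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestWilcoxonScreen:
    def test_frame_contract(self, rng):
        abund = pd.DataFrame(rng.random((10, 4)), columns=list("ABCD"))
        groups = np.array(["CASE"] * 5 + ["CONTROL"] * 5)
        abund.loc[groups == "CASE", "A"] += 10  # planted difference
        out = wilcoxon_screen(abund, groups)
        assert out.loc["A", "selected"]
        assert out.loc["A", "direction"] == "CASE"
        assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()
        assert (out["selected"] == (out["p_value"] < 0.05)).all()

    def test_requires_two_groups(self, rng):
        abund = pd.DataFrame(rng.random((4, 2)))
        with pytest.raises(ValueError):
            wilcoxon_screen(abund, ["CASE"] * 4)


class TestKruskalWallis:
    def test_two_group_equivalence_with_wilcoxon(self, rng):
        """KW with k=2 equals the tie-corrected Wilcoxon normal approximation."""
        for _ in range(20):
            x = rng.integers(0, 6, size=12).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=15).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            assert kruskal_wallis(x, y) == pytest.approx(
                wilcoxon_rank_sum(x, y), abs=1e-9)

    def test_degenerate_all_equal(self):
        assert kruskal_wallis([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_three_group_formula_oracle(self, rng):
        groups = [rng.normal(size=8), rng.normal(size=9) + 1, rng.normal(size=7) + 2]
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        idx = np.cumsum([0] + [len(g) for g in groups])
        h = 12 / (n * (n + 1)) * sum(
            ranks[idx[i]:idx[i + 1]].sum() ** 2 / len(g)
            for i, g in enumerate(groups)
        ) - 3 * (n + 1)
        _, tie_counts = np.unique(pooled, return_counts=True)
        h /= 1 - ((tie_counts**3 - tie_counts).sum() / (n**3 - n))
        expected = stats.chi2.sf(h, df=2)
        assert kruskal_wallis(*groups) == pytest.approx(expected, abs=1e-9)


class TestLdaEffectSize:
    def _frame(self, case_vals, ctrl_vals, name="F"):
        abund = pd.DataFrame({name: np.concatenate([case_vals, ctrl_vals])})
        groups = np.array(["CASE"] * len(case_vals) + ["CONTROL"] * len(ctrl_vals))
        return abund, groups

    def test_equal_means_fails(self, rng):
        vals = rng.random(10) * 1e-3
        abund, groups = self._frame(vals, vals)
        out = lda_effect_size(abund, groups, seed=0)
        assert not out.loc["F", "passes"]
        assert out.loc["F", "lda_score_log10"] < 2

    def test_large_separation_passes_toward_case(self, rng):
        case = 0.1 + rng.normal(0, 1e-4, 12)   # ~1e5 after 1e6 scaling
        ctrl = 0.001 + rng.normal(0, 1e-5, 12)  # ~1e3
        abund, groups = self._frame(case, ctrl)
        out = lda_effect_size(abund, groups, seed=0)
        assert out.loc["F", "passes"]
        assert out.loc["F", "enriched_group"] == "CASE"
        assert out.loc["F", "lda_score_log10"] == pytest.approx(5.0, abs=0.3)

    def test_zero_variance_feature(self):
        abund, groups = self._frame(np.full(5, 0.2), np.full(5, 0.2))
        out = lda_effect_size(abund, groups, seed=0)
        assert out.loc["F", "lda_score_log10"] == 0.0
        assert not out.loc["F", "passes"]

    def test_label_permutation_symmetry(self, rng):
        """Under exchangeability, flipping labels only flips the direction."""
        vals = rng.random(20)
        abund = pd.DataFrame({"F": vals})
        groups = np.array(["CASE"] * 10 + ["CONTROL"] * 10)
        out1 = lda_effect_size(abund, groups, seed=1)
        flipped = np.where(groups == "CASE", "CONTROL", "CASE")
        out2 = lda_effect_size(abund, flipped, seed=1)
        assert out1.loc["F", "enriched_group"] != out2.loc["F", "enriched_group"]
        # |score| distribution unchanged under many permutations
        scores = []
        for i in range(50):
            perm = rng.permutation(groups)
            if len(set(perm[:10])) == 1:
                continue
            scores.append(lda_effect_size(abund, perm, seed=2).loc["F", "lda_score_log10"])
        assert np.ptp(scores) < 2  # no systematic blow-up under the null
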