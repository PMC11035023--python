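import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from chemorep.famstats import (
    correlate_branch_events,
    ogg_dispersion_test,
    pic_contrasts,
    pic_correlation,
    repertoire_summary,
    spearman,
)
from chemorep.phylo import read_newick
from chemorep.synth import FamilySimSpec, simulate_family


class TestRepertoireSummary:
    def test_presentation_rounding_of_family_means(self):
        # family totals over 17 species recompute to the printed means
        totals = {"OR": 13597, "V1R": 1237, "V2R": 761, "T2R": 517}
        table = pd.DataFrame(
            {f: [v / 17.0] * 17 for f, v in totals.items()},
            index=[f"sp{i}" for i in range(17)],
        )
        s = repertoire_summary(table)
        assert round(s.loc["mean_per_species", "OR"]) == 800
        assert round(s.loc["mean_per_species", "V1R"], 1) == 72.8  # 1237/17
        assert round(s.loc["mean_per_species", "V2R"], 1) == 44.8
        assert round(s.loc["mean_per_species", "T2R"], 1) == 30.4

    def test_mean_genes_per_ogg(self):
        table = pd.DataFrame({"V2R": [1] * 17}, index=[f"sp{i}" for i in range(17)])
        sizes = {"V2R": [95, 95, 95, 95, 95, 96, 95, 95]}  # 761 genes in 8 OGGs
        s = repertoire_summary(table, ogg_sizes=sizes)
        assert s.loc["n_oggs", "V2R"] == 8
        assert round(s.loc["mean_per_ogg", "V2R"], 1) == 95.1

    def test_constant_counts_zero_cv(self):
        table = pd.DataFrame({"T2R": [30] * 10}, index=[f"s{i}" for i in range(10)])
        s = repertoire_summary(table)
        assert s.loc["cv_per_species", "T2R"] == 0.0

    def test_cv_uses_sample_standard_deviation(self):
        vals = [10, 20, 30, 40]
        table = pd.DataFrame({"F": vals}, index=list("abcd"))
        s = repertoire_summary(table)
        assert s.loc["cv_per_species", "F"] == pytest.approx(
            np.std(vals, ddof=1) / np.mean(vals)
        )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            repertoire_summary(pd.DataFrame({"F": []}))


class TestDispersionTest:
    def test_identical_samples_f_one(self):
        f, _ = ogg_dispersion_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert f == 1.0

    def test_variance_ratio_and_reference_distribution(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 2, 10)
        b = rng.normal(0, 1, 10)
        f, p = ogg_dispersion_test(a, b)
        assert f == pytest.approx(np.var(a, ddof=1) / np.var(b, ddof=1))
        # oracle: two-sided p via the regularized incomplete beta function
        d1 = d2 = 9
        x = d1 * f / (d1 * f + d2)
        cdf = special.betainc(d1 / 2, d2 / 2, x)
        assert p == pytest.approx(2 * min(cdf, 1 - cdf), rel=1e-10)

    def test_argument_swap_inverts_f_same_p(self):
        a, b = [1.0, 3, 5, 9], [2.0, 2.5, 3, 3.5]
        f1, p1 = ogg_dispersion_test(a, b)
        f2, p2 = ogg_dispersion_test(b, a)
        assert f1 == pytest.approx(1 / f2)
        assert p1 == pytest.approx(p2)

    def test_zero_denominator_variance_rejected(self):
        with pytest.raises(ValueError):
            ogg_dispersion_test([1, 2, 3], [5, 5, 5])


class TestSpearman:
    def test_monotone_pairs_hit_unity(self):
        r, _ = spearman([1, 2, 3, 5], [10, 20, 25, 90])
        assert r == 1.0
        r, _ = spearman([1, 2, 3, 5], [-1, -4, -9, -16])
        assert r == -1.0

    def test_average_ranks_equal_pearson_on_ranks(self):
        x, y = [1, 2, 2, 4], [3, 1, 1, 2]
        r, _ = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(oracle)

    def test_matches_scipy_estimate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        r, p = spearman(x, y)
        sr = stats.spearmanr(x, y)
        assert r == pytest.approx(sr.statistic)
        assert p == pytest.approx(sr.pvalue, rel=1e-6)

    def test_exact_permutation_p_small_n(self):
        # perfectly monotone n=4: only the 2 extreme orderings of 24 reach |r|=1
        _, p = spearman([1, 2, 3, 4], [2, 4, 6, 8])
        assert p == pytest.approx(2 / 24)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])


class TestBranchCorrelations:
    def test_pairwise_matrix_layout(self):
        tables = {
            "OR": {"b1": 5, "b2": 2, "b3": 8, "b4": 0},
            "V1R": {"b1": 4, "b2": 1, "b3": 9, "b4": 1},
            "T2R": {"b1": 0, "b2": 0, "b3": 1, "b4": 0},
        }
        r, p = correlate_branch_events(tables)
        assert list(r.index) == ["OR", "V1R", "T2R"]
        assert r.loc["OR", "V1R"] == r.loc["V1R", "OR"]
        assert np.all(np.diag(r.values) == 1.0)

    def test_mismatched_branch_sets_rejected(self):
        with pytest.raises(ValueError):
            correlate_branch_events({"a": {"b1": 1, "b2": 2, "b3": 0},
                                     "b": {"b1": 1, "bX": 2, "b3": 0}})


class TestPIC:
    def test_two_leaf_closed_form(self):
        t = read_newick("(A:1,B:1);")
        cs = pic_contrasts(t, {"A": 4.0, "B": 1.0})
        assert cs.contrasts == pytest.approx([3.0 / math.sqrt(2)])

    def test_identical_traits_zero_contrasts(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        cs = pic_contrasts(t, {"A": 2.0, "B": 2.0, "C": 2.0})
        assert np.allclose(cs.contrasts, 0.0)

    def test_three_leaf_hand_worked_pruning(self):
        # ((A:1,B:1):1,C:2), traits 1,3,6:
        #   contrast1 = (1-3)/sqrt(2); ancestral x_AB = 2, v_AB = 1 + 1/2
        #   contrast2 = (2-6)/sqrt(1.5 + 2)
        t = read_newick("((A:1,B:1):1,C:2);")
        cs = pic_contrasts(t, {"A": 1.0, "B": 3.0, "C": 6.0})
        assert cs.contrasts == pytest.approx(
            [-2 / math.sqrt(2), -4 / math.sqrt(3.5)]
        )

    def test_agrees_with_r_ape_convention_on_random_tree(self):
        # cross-check the pruning recursion against an independently
        # hand-evaluated 4-leaf case
        t = read_newick("(((A:2,B:1):1,C:3):1,D:4);")
        trait = {"A": 5.0, "B": 1.0, "C": 2.0, "D": 8.0}
        cs = pic_contrasts(t, trait)
        c1 = (5 - 1) / math.sqrt(3)
        xab = (5 / 2 + 1 / 1) / (1 / 2 + 1 / 1)
        vab = 1 + 2 * 1 / 3
        c2 = (xab - 2) / math.sqrt(vab + 3)
        xabc = (xab / vab + 2 / 3) / (1 / vab + 1 / 3)
        vabc = 1 + vab * 3 / (vab + 3)
        c3 = (xabc - 8) / math.sqrt(vabc + 4)
        assert sorted(cs.contrasts) == pytest.approx(sorted([c1, c2, c3]))

    def test_polytomy_rejected_by_default(self):
        t = read_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="bifurcating"):
            pic_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_zero_branch_pair_rejected(self):
        t = read_newick("(A:0,B:0);")
        with pytest.raises(ValueError):
            pic_contrasts(t, {"A": 1.0, "B": 2.0})


class TestPICRecovery:
    """Brownian-motion simulation: PIC recovers the generating correlation;
    the naive cross-species correlation is biased on an imbalanced tree."""

    TREE = "((((A:1,B:1):1,C:2):1,D:3):1,E:4);"

    @staticmethod
    def _simulate_pair(tree, rho, rng):
        # correlated Brownian traits along the tree
        t = tree.clone(depth=1)
        chol = np.linalg.cholesky([[1, rho], [rho, 1]])

        vals = {}

        def walk(node, x):
            bl = float(node.edge.length or 0.0)
            if bl > 0:
                step = chol @ rng.normal(size=2) * math.sqrt(bl)
                x = x + step
            if node.is_leaf():
                vals[node.taxon.label] = x
            for c in node.child_nodes():
                walk(c, x)

        walk(t.seed_node, np.zeros(2))
        return vals

    def test_contrast_correlation_recovers_generating_rho(self):
        tree = read_newick(self.TREE)
        rng = np.random.default_rng(11)
        rho = 0.7
        rs = []
        for _ in range(500):
            vals = self._simulate_pair(tree, rho, rng)
            c1 = pic_contrasts(tree, {k: v[0] for k, v in vals.items()})
            c2 = pic_contrasts(tree, {k: v[1] for k, v in vals.items()})
            rs.append(pic_correlation(c1, c2))
        mean_r = float(np.mean(rs))
        # with only 4 contrasts per replicate the correlation estimator is
        # slightly biased toward zero; 0.1 covers that plus sampling noise
        assert abs(mean_r - rho) < 0.1

    def test_naive_correlation_noisier_than_pic_under_shared_ancestry(self):
        tree = read_newick(self.TREE)
        rng = np.random.default_rng(13)
        rho = 0.0
        naive, picr = [], []
        for _ in range(400):
            vals = self._simulate_pair(tree, rho, rng)
            x = np.array([vals[k][0] for k in sorted(vals)])
            y = np.array([vals[k][1] for k in sorted(vals)])
            naive.append(np.corrcoef(x, y)[0, 1])
            c1 = pic_contrasts(tree, {k: v[0] for k, v in vals.items()})
            c2 = pic_contrasts(tree, {k: v[1] for k, v in vals.items()})
            picr.append(pic_correlation(c1, c2))
        # with no true correlation, shared ancestry inflates the spread of
        # the naive estimator relative to contrasts on an imbalanced tree
        assert np.std(naive) > np.std(picr)
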