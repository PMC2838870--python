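"""Differential-connectivity statistics and the permutation scheme."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from diffnet import (
    ModuleSet,
    ScoreMatrix,
    bh_adjust,
    class_mda,
    gene_mda,
    nonoverlap_statistic,
    permutation_pvalue,
    pool_rows,
)
from diffnet.diff_tests import gene_mda_all, nonoverlap_from_labels

from conftest import make_expression


def module_set(modules, universe, m=2):
    return ModuleSet([frozenset(mod) for mod in modules], list(universe), m, 0.5)


def score(vals):
    vals = np.asarray(vals, float)
    return ScoreMatrix(vals, [f"g{i + 1}" for i in range(len(vals))], "correlation")


class TestNonOverlap:
    UNIVERSE = [f"g{i}" for i in range(1, 9)]

    def test_identical_structures_score_zero(self):
        m1 = module_set([{"g1", "g2", "g3"}, {"g4", "g5"}], self.UNIVERSE)
        assert nonoverlap_statistic(m1, m1) == 0.0

    def test_disjoint_apart_from_anchor_scores_one(self):
        m1 = module_set([{"g1", "g2", "g3"}], self.UNIVERSE)
        m2 = module_set([{"g1", "g4", "g5"}], self.UNIVERSE)
        assert nonoverlap_statistic(m1, m2) == 1.0

    def test_hand_worked_partial_overlap(self):
        # G = {g1, g2}; each term 1 - (2-1)/(6-1) = 0.8
        m1 = module_set([{"g1", "g2", "g3", "g4"}], self.UNIVERSE)
        m2 = module_set([{"g1", "g2", "g5", "g6"}], self.UNIVERSE)
        assert nonoverlap_statistic(m1, m2) == pytest.approx(0.8)

    def test_no_shared_module_genes_gives_zero(self):
        m1 = module_set([{"g1", "g2"}], self.UNIVERSE)
        m2 = module_set([{"g3", "g4"}], self.UNIVERSE)
        assert nonoverlap_statistic(m1, m2) == 0.0

    def test_mismatched_universe_rejected(self):
        m1 = module_set([{"g1", "g2"}], ["g1", "g2"])
        m2 = module_set([{"g1", "g2"}], ["g1", "g2", "g3"])
        with pytest.raises(ValueError, match="universe"):
            nonoverlap_statistic(m1, m2)

    def test_label_implementation_matches_object_implementation(self):
        g = np.random.default_rng(3)
        for _ in range(100):
            p = int(g.integers(4, 15))
            universe = [f"g{i}" for i in range(p)]
            lab1 = g.integers(-1, 3, size=p)
            lab2 = g.integers(-1, 3, size=p)
            lab1 = _canonical(lab1)
            lab2 = _canonical(lab2)
            m1 = _labels_to_modules(lab1, universe)
            m2 = _labels_to_modules(lab2, universe)
            assert nonoverlap_from_labels(lab1, lab2) == pytest.approx(
                nonoverlap_statistic(m1, m2)
            )


def _canonical(lab):
    """Renumber labels to 0..k-1 keeping -1 for unassigned."""
    out = np.full(lab.shape, -1)
    mapping = {}
    for i, v in enumerate(lab):
        if v < 0:
            continue
        out[i] = mapping.setdefault(v, len(mapping))
    return out


def _labels_to_modules(lab, universe):
    mods = [
        frozenset(universe[i] for i in np.flatnonzero(lab == v))
        for v in range(lab.max() + 1)
        if (lab == v).any()
    ]
    return ModuleSet(mods, universe, 1, 0.5)


class TestMDAStatistics:
    def test_identical_scores_give_zero(self):
        s = score(np.eye(4))
        assert class_mda(s, s, ["g1", "g2", "g3"]) == 0.0
        assert all(gene_mda(s, s, g) == 0.0 for g in s.gene_ids)

    def test_two_gene_class_is_absolute_difference(self):
        s1 = score([[1, 0.5], [0.5, 1]])
        s2 = score([[1, 0.1], [0.1, 1]])
        assert class_mda(s1, s2, ["g1", "g2"]) == pytest.approx(0.4)
        assert gene_mda(s1, s2, "g1") == pytest.approx(0.4)

    def test_hand_worked_three_gene_class(self):
        s1 = score([[1, 0.5, 0.2], [0.5, 1, -0.1], [0.2, -0.1, 1]])
        s2 = score([[1, 0.1, 0.2], [0.1, 1, 0.3], [0.2, 0.3, 1]])
        assert class_mda(s1, s2, ["g1", "g2", "g3"]) == pytest.approx(0.8 / 3)

    def test_hand_worked_single_gene(self):
        s1 = score([[1, 0.5, -0.5], [0.5, 1, 0], [-0.5, 0, 1]])
        s2 = score([[1, 0.1, 0.1], [0.1, 1, 0], [0.1, 0, 1]])
        assert gene_mda(s1, s2, "g1") == pytest.approx(0.5)

    def test_correlation_distance_bounded_by_two(self, rng):
        s1 = score(np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-1, 1, (5, 5))), -1, 1))
        s2 = score(np.clip((lambda a: (a + a.T) / 2)(rng.uniform(-1, 1, (5, 5))), -1, 1))
        assert all(gene_mda(s1, s2, g) <= 2.0 for g in s1.gene_ids)

    def test_small_class_and_unknown_genes_rejected(self):
        s = score(np.eye(3))
        with pytest.raises(ValueError, match="at least 2"):
            class_mda(s, s, ["g1"])
        with pytest.raises(KeyError, match="gX"):
            class_mda(s, s, ["g1", "gX"])
        with pytest.raises(KeyError):
            gene_mda(s, s, "gX")

    def test_vectorized_gene_mda_matches_scalar(self, rng):
        a = rng.uniform(-1, 1, (6, 6))
        b = rng.uniform(-1, 1, (6, 6))
        s1, s2 = score((a + a.T) / 2), score((b + b.T) / 2)
        vec = gene_mda_all(s1.values, s2.values)
        for j, g in enumerate(s1.gene_ids):
            assert vec[j] == pytest.approx(gene_mda(s1, s2, g))


class TestPoolRows:
    def test_stacking_order_and_sizes(self, rng):
        x1 = make_expression(rng.standard_normal((3, 4)))
        x2 = make_expression(rng.standard_normal((5, 4)))
        pooled = pool_rows(x1, x2)
        assert (pooled.n1, pooled.n2) == (3, 5)
        np.testing.assert_array_equal(pooled.pooled[:3], x1.values)
        np.testing.assert_array_equal(pooled.pooled[3:], x2.values)
        np.testing.assert_allclose(
            pooled.pooled.sum(axis=0), x1.values.sum(axis=0) + x2.values.sum(axis=0)
        )

    def test_gene_mismatch_rejected(self, rng):
        x1 = make_expression(rng.standard_normal((3, 2)), ["a", "b"])
        x2 = make_expression(rng.standard_normal((3, 2)), ["b", "a"])
        with pytest.raises(ValueError, match="gene"):
            pool_rows(x1, x2)


class TestPermutationPValue:
    def test_constant_statistic_gives_p_one(self, rng):
        x1 = make_expression(rng.standard_normal((4, 3)))
        x2 = make_expression(rng.standard_normal((4, 3)))
        res = permutation_pvalue(x1, x2, lambda a, b: 1.0, n_permutations=50, seed=0)
        assert res.p_value == 1.0

    def test_matches_exhaustive_enumeration(self):
        # tiny two-by-two design: all 4! = 24 row permutations enumerable
        x1 = np.array([[1.0, 0.2], [2.0, -0.5]])
        x2 = np.array([[5.0, 1.5], [6.0, 2.5]])
        pooled = np.vstack([x1, x2])

        def stat(a, b):
            return abs(a.mean() - b.mean())

        observed = stat(x1, x2)
        exact = np.mean(
            [
                stat(pooled[list(perm[:2])], pooled[list(perm[2:])]) >= observed
                for perm in itertools.permutations(range(4))
            ]
        )
        res = permutation_pvalue(x1, x2, stat, n_permutations=2000, seed=42)
        se = np.sqrt(exact * (1 - exact) / 2000)
        assert abs(res.p_value - exact) <= 3 * se

    def test_pvalues_lie_on_permutation_grid(self, rng):
        x1 = make_expression(rng.standard_normal((5, 3)))
        x2 = make_expression(rng.standard_normal((5, 3)))
        res = permutation_pvalue(
            x1, x2, lambda a, b: float(np.abs(a.mean(0) - b.mean(0)).sum()),
            n_permutations=40, seed=1,
        )
        assert res.p_value in {i / 40 for i in range(41)}

    def test_null_pvalues_approximately_uniform(self):
        # both groups from the same distribution: p over replicates ~ U(0,1)
        pvals = []
        for rep in range(200):
            g = np.random.default_rng(1000 + rep)
            x1 = g.standard_normal((10, 4))
            x2 = g.standard_normal((10, 4))
            res = permutation_pvalue(
                x1, x2,
                lambda a, b: float(np.abs(np.corrcoef(a, rowvar=False)
                                          - np.corrcoef(b, rowvar=False)).sum()),
                n_permutations=100, seed=rep,
            )
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").statistic < 0.12

    def test_requires_at_least_one_permutation(self, rng):
        x = make_expression(rng.standard_normal((4, 3)))
        with pytest.raises(ValueError):
            permutation_pvalue(x, x, lambda a, b: 0.0, n_permutations=0)


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_step_up_with_cumulative_minimum(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=(1000, 8))
        for row in p:
            assert (bh_adjust(row) >= row - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_step_up_invariants(self, pvals):
        """Adjusted values inflate, stay in [0,1] and preserve the p-value order."""
        raw = np.asarray(pvals)
        adj = bh_adjust(raw)
        assert (adj >= raw - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(raw, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestStatisticBounds:
    @given(st.integers(3, 8), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_mda_statistics_nonnegative_and_bounded(self, p, seed):
        g = np.random.default_rng(seed)
        a, b = g.uniform(-1, 1, (p, p)), g.uniform(-1, 1, (p, p))
        s1, s2 = score((a + a.T) / 2), score((b + b.T) / 2)
        genes = s1.gene_ids
        assert 0.0 <= class_mda(s1, s2, genes) <= 2.0
        assert all(0.0 <= gene_mda(s1, s2, gg) <= 2.0 for gg in genes)
        # with exactly two genes, both statistics coincide
        s1_small, s2_small = score(s1.values[:2, :2]), score(s2.values[:2, :2])
        assert gene_mda(s1_small, s2_small, "g1") == pytest.approx(
            class_mda(s1_small, s2_small, ["g1", "g2"])
        )
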