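"""k-of-n pools and the exact multiset intersection statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import fibsig as f
from fibsig.multiset import (
    intersection_distribution,
    membership_matrix,
    subset_union_filter,
)


class TestEnumeration:
    @pytest.mark.parametrize(
        "n,k,expected", [(9, 7, 46), (5, 4, 6), (3, 3, 1), (4, 1, 15)]
    )
    def test_subset_counts(self, n, k, expected):
        combos = f.enumerate_combinations(f.CombinationScheme(n, k))
        assert len(combos) == expected
        assert len(set(combos)) == expected  # each subset listed once
        assert combos == sorted(combos, key=lambda c: (len(c), c))

    def test_invalid_scheme(self):
        with pytest.raises(ValueError):
            f.CombinationScheme(5, 6)


class TestKofNFilter:
    def _random_membership(self, rng, genes=50, cohorts=9):
        data = rng.random((genes, cohorts)) < 0.5
        return pd.DataFrame(
            data, index=[f"G{i}" for i in range(genes)],
            columns=[f"c{j}" for j in range(cohorts)],
        )

    def test_threshold_semantics(self):
        m = pd.DataFrame(
            [[True] * 7 + [False] * 2, [True] * 6 + [False] * 3],
            index=["in7", "in6"], columns=[f"c{j}" for j in range(9)],
        )
        gs = f.k_of_n_filter(m, f.CombinationScheme(9, 7))
        assert "in7" in gs and "in6" not in gs

    def test_equals_subset_union_oracle(self, rng):
        """Row-sum filter must match explicit enumeration over all subsets."""
        scheme = f.CombinationScheme(9, 7)
        for _ in range(5):
            m = self._random_membership(rng)
            assert f.k_of_n_filter(m, scheme) == subset_union_filter(m, scheme)

    def test_k_equals_n_is_intersection_k1_is_union(self, rng):
        m = self._random_membership(rng, genes=40, cohorts=4)
        inter = f.k_of_n_filter(m, f.CombinationScheme(4, 4))
        assert inter.as_set() == set(m.index[m.all(axis=1)])
        union = f.k_of_n_filter(m, f.CombinationScheme(4, 1))
        assert union.as_set() == set(m.index[m.any(axis=1)])

    def test_all_true_membership_keeps_everything(self):
        m = pd.DataFrame(True, index=["a", "b"], columns=["c1", "c2", "c3"])
        assert len(f.k_of_n_filter(m, f.CombinationScheme(3, 2))) == 2

    def test_membership_matrix_from_lists(self):
        lists = [f.GeneSet("c1", ["A", "B"]), f.GeneSet("c2", ["B", "C"])]
        m = membership_matrix(lists)
        assert m.loc["B"].all() and not m.loc["A", "c2"]


class TestExactIntersection:
    def test_two_set_case_is_hypergeometric_tail(self):
        stat = f.exact_intersection_test([672, 5271], 241, 20_000)
        ref = stats.hypergeom.sf(240, 20_000, 672, 5271)
        assert abs(stat.p_value - ref) < 1e-12
        assert np.isclose(stat.expected, 672 * 5271 / 20_000)

    def test_saturated_sets(self):
        stat = f.exact_intersection_test([30, 30, 30], 30, 30)
        assert stat.p_value == pytest.approx(1.0)
        dist = intersection_distribution((30, 30, 30), 30)
        assert dist[30] == pytest.approx(1.0)

    def test_distribution_sums_to_one_and_order_invariant(self):
        sizes = (10, 12, 15)
        d1 = intersection_distribution(sizes, 30)
        d2 = intersection_distribution(tuple(reversed(sizes)), 30)
        assert abs(d1.sum() - 1) < 1e-9
        np.testing.assert_allclose(d1, d2[: len(d1)], atol=1e-12)

    def test_three_set_p_matches_monte_carlo(self):
        draws = 100_000
        stat = f.exact_intersection_test([10, 12, 15], 4, 30)
        tally = f.mc_intersection_oracle([10, 12, 15], 30, draws, seed=123)
        p_hat = sum(v for k, v in tally.items() if k >= 4) / draws
        se = np.sqrt(p_hat * (1 - p_hat) / draws)
        assert abs(stat.p_value - p_hat) <= 3 * se

    def test_p_monotone_in_observed(self):
        ps = [
            f.exact_intersection_test([10, 12, 15], obs, 30).p_value
            for obs in range(11)
        ]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @settings(deadline=None, max_examples=20)
    @given(
        st.integers(5, 40).flatmap(
            lambda n: st.tuples(
                st.just(n),
                st.lists(st.integers(1, n), min_size=2, max_size=4),
            )
        )
    )
    def test_distribution_normalized_for_random_configs(self, cfg):
        n, sizes = cfg
        dist = intersection_distribution(tuple(sizes), n)
        assert abs(dist.sum() - 1) < 1e-9
        assert (dist >= -1e-15).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            f.exact_intersection_test([10, 40], 5, 30)
        with pytest.raises(ValueError):
            f.exact_intersection_test([10, 12], 11, 30)


class TestMcOracle:
    def test_reproducible_and_saturated(self):
        t1 = f.mc_intersection_oracle([5, 5], 10, 1000, seed=7)
        t2 = f.mc_intersection_oracle([5, 5], 10, 1000, seed=7)
        assert t1 == t2
        full = f.mc_intersection_oracle([10, 10], 10, 1000, seed=7)
        assert full == {10: 1000}

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            f.mc_intersection_oracle([5, 5], 10, 10, seed=0)


class TestBuildSignature:
    def test_identical_pools(self):
        gs = f.GeneSet("a", [f"g{i}" for i in range(10)])
        res = f.build_signature(gs, f.GeneSet("b", gs.genes), background_n=100)
        assert res.fibsig == gs
        assert res.stats.fold_enrichment == pytest.approx(100 / 10)

    def test_disjoint_pools(self):
        a = f.GeneSet("a", ["A", "B"])
        b = f.GeneSet("b", ["C", "D"])
        res = f.build_signature(a, b, background_n=50)
        assert len(res.fibsig) == 0
        assert res.stats.p_value == pytest.approx(1.0)

    def test_background_smaller_than_union(self):
        a = f.GeneSet("a", ["A", "B"])
        b = f.GeneSet("b", ["C", "D"])
        with pytest.raises(ValueError, match="smaller than pool union"):
            f.build_signature(a, b, background_n=3)

    def test_fold_enrichment_near_one_for_random_sets(self, rng):
        """Independent random pools should show no enrichment on average."""
        N, n1, n2 = 300, 60, 80
        folds = []
        for _ in range(200):
            s1 = rng.choice(N, n1, replace=False)
            s2 = rng.choice(N, n2, replace=False)
            obs = len(set(s1) & set(s2))
            folds.append(obs / (n1 * n2 / N))
        se = np.std(folds, ddof=1) / np.sqrt(len(folds))
        assert abs(np.mean(folds) - 1) <= 3 * se + 1e-9
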