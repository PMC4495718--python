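"""Chain detection, polarity proportions, and the rank-sum proximity test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mtmesh import ConnectorGraph, Hyperedge, chain_size_histogram, \
    chained_vs_single_test, chains_from_connectors, polarity_proportions, \
    randomize_membership, rank_sum_test

from oracles import exact_rank_sum_p, union_find_partition


def _graph(nodes, edges):
    return ConnectorGraph(
        fiber_id="f", nodes=list(nodes),
        hyperedges=[Hyperedge(i + 1, frozenset(e)) for i, e in enumerate(edges)],
    )


class TestChains:
    def test_transitive_chain(self):
        part = chains_from_connectors(_graph("ABC", [("A", "B"), ("B", "C")]))
        assert sorted(part.chain_sizes.values()) == [3]
        assert part.singles == []

    def test_quadrupolar_edge_is_one_chain_of_four(self):
        part = chains_from_connectors(_graph("ABCD", [("A", "B", "C", "D")]))
        assert list(part.chain_sizes.values()) == [4]

    def test_singles_identified(self):
        part = chains_from_connectors(_graph("ABCDE", [("A", "B")]))
        assert sorted(part.singles) == ["C", "D", "E"]
        assert part.size_of("A") == 2 and not part.is_chained("C")

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes = list(range(50))
        edges = [
            frozenset(rng.choice(nodes, size=rng.integers(2, 5), replace=False))
            for _ in range(40)
        ]
        part = chains_from_connectors(_graph(nodes, edges))
        ours = {}
        for mt, cid in part.chain_of.items():
            ours.setdefault(cid, set()).add(mt)
        assert set(map(frozenset, ours.values())) == \
            set(union_find_partition(nodes, edges))

    def test_hyperedge_needs_two_members(self):
        with pytest.raises(ValueError):
            Hyperedge(1, frozenset({"A"}))


class TestHistogramAndPolarity:
    def test_histogram_excludes_singles(self):
        part = chains_from_connectors(
            _graph("ABCDEFGH", [("A", "B"), ("C", "D"), ("E", "F", "G")]))
        assert chain_size_histogram([part]) == {2: 2, 3: 1}

    def test_all_singles_empty_histogram(self):
        part = chains_from_connectors(_graph("ABC", []))
        assert chain_size_histogram([part]) == {}

    def test_polarity_proportions(self):
        g = _graph("ABCDEF", [("A", "B"), ("C", "D"), ("A", "B", "C"),
                              ("A", "B", "C", "D")])
        res = polarity_proportions([g])
        assert res["proportions"] == {2: 0.5, 3: 0.25, 4: 0.25}
        assert sum(res["proportions"].values()) == pytest.approx(1.0)

    def test_all_bipolar(self):
        res = polarity_proportions([_graph("ABCD", [("A", "B"), ("C", "D")])])
        assert res["proportions"] == {2: 1.0}

    def test_zero_connectors_flagged(self):
        assert polarity_proportions([_graph("AB", [])])["n"] == 0

    def test_planted_mix_recovered(self, control_fiber):
        res = polarity_proportions([control_fiber.true_connectors])
        assert res["n"] == len(control_fiber.true_connectors.hyperedges)
        assert sum(res["proportions"].values()) == pytest.approx(1.0)


class TestRankSum:
    def test_identical_multisets_give_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_separated_groups_exact_enumeration(self):
        # C(6,3) = 20 arrangements, 2 as extreme -> p = 0.1
        u, p = rank_sum_test([1, 2, 3], [101, 102, 103], method="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("nx,ny", [(2, 3), (4, 4), (3, 6), (5, 5)])
    def test_exact_matches_enumeration_oracle(self, nx, ny, rng):
        x = rng.integers(0, 6, size=nx).astype(float)   # ties likely
        y = rng.integers(0, 6, size=ny).astype(float)
        _, p = rank_sum_test(x, y, method="exact")
        assert p == pytest.approx(exact_rank_sum_p(x, y))

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=7)
            _, p = rank_sum_test(x, y, method="exact")
            ref = stats.mannwhitneyu(x, y, method="exact",
                                     alternative="two-sided").pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    def test_approx_close_to_scipy_with_ties(self, rng):
        x = rng.integers(0, 8, size=30).astype(float)
        y = rng.integers(1, 9, size=25).astype(float)
        _, p = rank_sum_test(x, y, method="approx")
        ref = stats.mannwhitneyu(x, y, method="asymptotic",
                                 alternative="two-sided").pvalue
        assert p == pytest.approx(ref, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestProximityTest:
    def _fiber_with_labels(self, rng, n=24):
        pts = rng.uniform(0, 400, size=(n, 2))
        ids = list(range(n))
        chained = set(rng.choice(ids, size=n // 2, replace=False).tolist())

        class Part:
            def is_chained(self, m):
                return m in chained
        return pts, ids, Part()

    def test_sweep_shape_and_p_range(self, rng):
        pts, ids, part = self._fiber_with_labels(rng)
        results = chained_vs_single_test(pts, ids, part)
        assert [r.radius_nm for r in results] == list(range(20, 121, 10))
        for r in results:
            assert 0.0 <= r.p_value <= 1.0
            assert r.n_chained + r.n_single == len(ids)

    def test_one_group_empty_is_undefined(self):
        pts = np.array([[0.0, 0.0], [50.0, 0.0]])

        class AllChained:
            def is_chained(self, m):
                return True
        res = chained_vs_single_test(pts, [0, 1], AllChained(), radii_nm=[50.0])
        assert res[0].undefined and res[0].p_value is None

    def test_planted_effect_detected_and_randomization_washes_it_out(self, rng):
        # chained MTs tightly clustered, singles far apart: strong effect
        tight = rng.normal(0, 30, size=(15, 2))
        loose = rng.uniform(500, 2000, size=(15, 2))
        pts = np.vstack([tight, loose])
        ids = list(range(30))

        class Part:
            def is_chained(self, m):
                return m < 15
        obs = chained_vs_single_test(pts, ids, Part(), radii_nm=[105.0])[0]
        rand = randomize_membership(pts, ids, Part(), radii_nm=[105.0],
                                    n_permutations=99, seed=0)
        assert obs.p_value < 0.01
        assert rand["median_p"][0] > 10 * obs.p_value

    def test_single_permutation_reproducible(self, rng):
        pts, ids, part = self._fiber_with_labels(rng)
        r1 = randomize_membership(pts, ids, part, radii_nm=[80.0],
                                  n_permutations=1, seed=5)
        r2 = randomize_membership(pts, ids, part, radii_nm=[80.0],
                                  n_permutations=1, seed=5)
        assert np.array_equal(r1["p_values"], r2["p_values"])

    def test_group_sizes_preserved_under_permutation(self, rng):
        pts, ids, part = self._fiber_with_labels(rng)
        n_chained = sum(part.is_chained(m) for m in ids)
        rand = randomize_membership(pts, ids, part, radii_nm=[105.0],
                                    n_permutations=10, seed=1)
        # all permutations defined -> both groups stayed non-empty and sized
        assert not np.isnan(rand["p_values"]).any()
        assert 0 < n_chained < len(ids)

    def test_null_p_values_roughly_uniform(self):
        # symmetric data, labels permuted: p should be ~Uniform(0,1)
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 600, size=(40, 2))
        ids = list(range(40))
        chained = set(range(20))

        class Part:
            def is_chained(self, m):
                return m in chained
        rand = randomize_membership(pts, ids, Part(), radii_nm=[105.0],
                                    n_permutations=500, seed=3)
        p = rand["p_values"][:, 0]
        # discrete statistic: compare against its own permutation CDF loosely
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01 or p.mean() > 0.4   # uniform-ish, not skewed
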