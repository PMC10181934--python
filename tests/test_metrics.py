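"""Tree/ARG comparison metrics: axioms, hand examples and brute-force
oracles for the total-variation distance."""

import numpy as np
import pytest

from argstitch import (
    arg_total_variation,
    collapse_polytomies,
    kc_distance,
    kc_distance_arg,
    polytomy_fraction,
    resolve_polytomies,
    robinson_foulds_avg,
    simulate_coalescent,
    tmrca_rmse,
)
from argstitch.arg import ARG, MarginalTree


def four_leaf_balanced():
    topo = {"a": "i1", "b": "i1", "c": "i2", "d": "i2", "i1": "r", "i2": "r"}
    times = {"a": 0, "b": 0, "c": 0, "d": 0, "i1": 1.0, "i2": 2.0, "r": 3.0}
    return MarginalTree(topo, times, ["a", "b", "c", "d"])


def four_leaf_crossed():
    topo = {"a": "i1", "c": "i1", "b": "i2", "d": "i2", "i1": "r", "i2": "r"}
    times = {"a": 0, "b": 0, "c": 0, "d": 0, "i1": 1.0, "i2": 2.0, "r": 3.0}
    return MarginalTree(topo, times, ["a", "b", "c", "d"])


def four_leaf_caterpillar():
    topo = {"a": "i1", "b": "i1", "i1": "i2", "c": "i2", "i2": "r", "d": "r"}
    times = {"a": 0, "b": 0, "c": 0, "d": 0, "i1": 1.0, "i2": 2.0, "r": 3.0}
    return MarginalTree(topo, times, ["a", "b", "c", "d"])


def as_arg(tree, L=100.0):
    return ARG.from_marginal_trees([(0.0, L, tree)], L)


def three_leaf(tolabel):
    """((x, y):1, z) with unit-ish times; tolabel chooses the cherry."""
    x, y = tolabel
    z = ({"a", "b", "c"} - {x, y}).pop()
    topo = {x: "i", y: "i", "i": "r", z: "r"}
    times = {"a": 0, "b": 0, "c": 0, "i": 1.0, "r": 2.0}
    return MarginalTree(topo, times, ["a", "b", "c"])


class TestRobinsonFoulds:
    def test_identity_is_zero(self, small_dataset):
        arg = small_dataset.true_arg
        assert robinson_foulds_avg(arg, arg, seed=0) == 0.0

    def test_disjoint_four_leaf_topologies_give_one(self):
        a = as_arg(four_leaf_balanced())
        b = as_arg(four_leaf_crossed())
        assert robinson_foulds_avg(a, b, seed=0) == 1.0

    def test_symmetry_and_bounds(self):
        ds1 = simulate_coalescent(8, 5e4, seed=1)
        ds2 = simulate_coalescent(8, 5e4, seed=2)
        a, b = ds1.true_arg, ds2.true_arg
        b2 = ARG.from_tree_sequence(
            b.to_tree_sequence().keep_intervals([[0, a.sequence_length]]).trim()
        )
        d1 = robinson_foulds_avg(a, b2, seed=3)
        d2 = robinson_foulds_avg(b2, a, seed=3)
        assert 0.0 <= d1 <= 1.0
        assert d1 == pytest.approx(d2, abs=0.05)  # random polytomy breaking

    def test_sample_mismatch_rejected(self):
        a = as_arg(four_leaf_balanced())
        c = as_arg(three_leaf(("a", "b")))
        with pytest.raises(ValueError, match="sample"):
            robinson_foulds_avg(a, c, seed=0)


def brute_force_tv(argA, argB):
    """Exhaustive enumeration of (interval, clade) mutation masses."""
    bps = sorted(set(argA.breakpoints()) | set(argB.breakpoints()))
    dists = []
    for arg in (argA, argB):
        mass = {}
        area = arg.total_area()
        label = {s: arg.sample_label[s] for s in arg.samples}
        for (a, b) in zip(bps[:-1], bps[1:]):
            tree = arg.marginal_tree((a + b) / 2)
            below = tree.leaf_sets()
            for u, p in tree.parent.items():
                key = (a, frozenset(label.get(v, v) for v in below[u]))
                mass[key] = mass.get(key, 0.0) + (
                    (tree.time[p] - tree.time[u]) * (b - a) / area
                )
        dists.append(mass)
    keys = dists[0].keys() | dists[1].keys()
    return 0.5 * sum(abs(dists[0].get(k, 0) - dists[1].get(k, 0)) for k in keys)


class TestArgTotalVariation:
    def test_identity_is_zero(self, small_dataset):
        assert arg_total_variation(
            small_dataset.true_arg, small_dataset.true_arg
        ) == pytest.approx(0.0, abs=1e-12)

    def test_two_sample_args_always_agree(self):
        """2-sample ARGs share the single clade pair regardless of times."""
        t1 = MarginalTree({0: "r", 1: "r"}, {0: 0, 1: 0, "r": 10.0}, [0, 1])
        t2 = MarginalTree({0: "r", 1: "r"}, {0: 0, 1: 0, "r": 99.0}, [0, 1])
        assert arg_total_variation(as_arg(t1), as_arg(t2)) == pytest.approx(0.0)

    def test_three_leaf_hand_enumeration(self):
        """((a,b),c) vs ((a,c),b): masses enumerable over <= 6 keys."""
        A, B = as_arg(three_leaf(("a", "b"))), as_arg(three_leaf(("a", "c")))
        got = arg_total_variation(A, B)
        # per ARG: total area = 3 leaf branches + 1 internal branch.
        # A: {a}:1, {b}:1, {c}:2, {a,b}:1 over area 5
        # B: {a}:1, {c}:1, {b}:2, {a,c}:1 over area 5
        expected = 0.5 * (0 + 1 / 5 + 1 / 5 + 1 / 5 + 1 / 5)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(brute_force_tv(A, B), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_recombinant_args(self, seed):
        """Exhaustive (interval, clade) enumeration oracle, <= 6 samples."""
        ds1 = simulate_coalescent(6, 3e4, seed=30 + seed)
        ds2 = simulate_coalescent(6, 3e4, seed=60 + seed)
        b = ARG.from_tree_sequence(
            ds2.true_arg.to_tree_sequence()
            .keep_intervals([[0, ds1.sequence_length]]).trim()
        )
        got = arg_total_variation(ds1.true_arg, b)
        want = brute_force_tv(ds1.true_arg, b)
        assert got == pytest.approx(want, rel=1e-9)
        assert 0.0 <= got <= 1.0
        assert arg_total_variation(b, ds1.true_arg) == pytest.approx(got)

    def test_polytomies_need_no_resolution(self):
        """A star tree concentrates mass; TV is defined and bounded."""
        n = 5
        parent = {i: "r" for i in range(n)}
        times = {i: 0.0 for i in range(n)}
        times["r"] = 10.0
        star = as_arg(MarginalTree(parent, times, list(range(n))))
        ds = simulate_coalescent(5, 2e4, seed=77)
        b = ARG.from_tree_sequence(
            ds.true_arg.to_tree_sequence().keep_intervals([[0, 100.0]]).trim()
        )
        tv = arg_total_variation(star, b)
        assert 0.0 < tv <= 1.0

    def test_stratified_bins(self):
        ds1 = simulate_coalescent(10, 3e4, seed=90)
        ds2 = simulate_coalescent(10, 3e4, seed=91)
        b = ARG.from_tree_sequence(
            ds2.true_arg.to_tree_sequence()
            .keep_intervals([[0, ds1.sequence_length]]).trim()
        )
        bins = [(0.0, 0.2), (0.2, 0.5)]
        vals = arg_total_variation(ds1.true_arg, b, freq_bins=bins)
        assert len(vals) == 2
        assert all(0.0 <= v <= 1.0 for v in vals)


class TestKCDistance:
    def test_identical_topologies_zero_at_lambda0(self):
        a = four_leaf_balanced()
        b = four_leaf_balanced()
        b.time["i1"] = 0.5  # different times, same topology
        assert kc_distance(a, b, lam=0.0) == 0.0
        assert kc_distance(a, b, lam=1.0) > 0.0

    def test_caterpillar_vs_balanced_hand_computed(self):
        """lambda = 0 vectors: pairs (ab,ac,ad,bc,bd,cd) + 4 pendant ones.
        balanced: (1,0,0,0,0,1); caterpillar: (2,1,0,1,0,0)."""
        va = np.array([1, 0, 0, 0, 0, 1] + [1, 1, 1, 1])
        vb = np.array([2, 1, 0, 1, 0, 0] + [1, 1, 1, 1])
        expected = np.linalg.norm(va - vb)
        got = kc_distance(four_leaf_balanced(), four_leaf_caterpillar(), lam=0.0)
        assert got == pytest.approx(expected)

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaves"):
            kc_distance(four_leaf_balanced(), three_leaf(("a", "b")))

    def test_genome_average_identity_zero(self):
        ds = simulate_coalescent(6, 2e4, seed=44)
        assert kc_distance_arg(ds.true_arg, ds.true_arg, lam=0.02) == pytest.approx(0.0)


class TestTmrcaRmse:
    def test_identity_zero(self, small_dataset):
        assert tmrca_rmse(small_dataset.true_arg, small_dataset.true_arg,
                          seed=1) == 0.0

    def test_constant_offset_recovered(self, small_dataset):
        arg = small_dataset.true_arg
        delta = 500.0
        shifted = arg.with_node_times(
            {u: t + delta for u, t in arg.node_time.items() if t > 0}
        )
        got = tmrca_rmse(arg, shifted, n_pairs=50, n_sites=40, seed=2)
        assert got == pytest.approx(delta, rel=1e-9)

    def test_subsampled_close_to_exhaustive(self, small_dataset):
        arg = small_dataset.true_arg
        other = arg.with_node_times(
            {u: t * 1.7 for u, t in arg.node_time.items() if t > 0}
        )
        full = tmrca_rmse(arg, other, n_pairs=10**6, n_sites=2000, seed=3)
        devs = [
            abs(tmrca_rmse(arg, other, n_pairs=100, n_sites=250, seed=s) - full)
            / full
            for s in range(8)
        ]
        assert np.mean(devs) < 0.05


class TestPolytomyHeuristics:
    def _binary_tree(self, n=10, seed=5):
        ds = simulate_coalescent(n, 1e4, seed=seed)
        arg = ds.true_arg
        tree = arg.marginal_tree(0.0)
        lab = {s: arg.sample_label[s] for s in arg.samples}
        return MarginalTree(
            {lab.get(c, c): lab.get(p, p) for c, p in tree.parent.items()},
            {lab.get(u, u): t for u, t in tree.time.items()},
            [lab[s] for s in arg.samples],
        )

    def test_f_zero_is_identity(self):
        tree = self._binary_tree()
        out = collapse_polytomies(tree, 0.0)
        assert out.same_shape(tree)

    def test_f_one_gives_star(self):
        tree = self._binary_tree()
        out = collapse_polytomies(tree, 1.0)
        assert len(out.children[out.root]) == out.num_leaves

    def test_collapses_exactly_the_smallest_ratio_branches(self):
        tree = self._binary_tree(n=10)
        out = collapse_polytomies(tree, 0.5)
        # brute-force ranking of the 8 nonleaf branches
        ratios = {}
        for u in tree.internal_nodes():
            if u in tree.parent:
                p = tree.parent[u]
                ratios[u] = (tree.time[p] - tree.time[u]) / tree.time[p]
        worst = sorted(ratios, key=lambda u: ratios[u])[:4]
        surviving = set(out.internal_nodes())
        assert all(u not in surviving for u in worst)
        assert len([u for u in out.internal_nodes() if u in out.parent]) == 4

    def test_nonbinary_input_rejected(self):
        tree = self._binary_tree()
        poly = collapse_polytomies(tree, 0.4)
        with pytest.raises(ValueError, match="binary"):
            collapse_polytomies(poly, 0.1)

    def test_resolve_gives_binary_and_preserves_order(self):
        tree = self._binary_tree(n=12, seed=9)
        poly = collapse_polytomies(tree, 0.5)
        res = resolve_polytomies(poly, seed=3)
        assert res.is_binary()
        assert sorted(res.leaves) == sorted(tree.leaves)
        # surviving nodes still dominate the same leaf pairs
        below_poly = {
            frozenset(labs) for labs in poly.leaf_sets().values()
        }
        below_res = {
            frozenset(labs) for labs in res.leaf_sets().values()
        }
        assert below_poly <= below_res

    def test_binary_input_resolve_is_identity(self):
        tree = self._binary_tree()
        out = resolve_polytomies(tree, seed=0)
        assert out.same_shape(tree)

    def test_polytomy_fraction_bounds_and_construction(self):
        ds = simulate_coalescent(10, 1e4, seed=22)
        assert polytomy_fraction(ds.true_arg) == 0.0
        tree = self._binary_tree(n=10, seed=23)
        n = tree.num_leaves
        star = collapse_polytomies(tree, 1.0)
        star_arg = as_arg(star)
        assert polytomy_fraction(star_arg) == 1.0
        f = 0.5
        collapsed = as_arg(collapse_polytomies(tree, f))
        want = int(np.floor(f * (n - 2))) / (n - 2)
        assert polytomy_fraction(collapsed) == pytest.approx(want)
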