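"""ARG graph structure, threading, mutation sampling and serialization."""

import numpy as np
import pytest

from argstitch import (
    ARG,
    ThreadingInstruction,
    genotypes_of,
    new_arg,
    sample_mutations,
)
from argstitch.arg import export_tree_sequence, import_tree_sequence


def two_sample_arg(t=100.0, L=1e6):
    arg = new_arg(L, label=0)
    arg.thread(ThreadingInstruction(((0.0, arg.samples[0], t),)), label=1)
    return arg


def random_threaded_arg(n, L, seed):
    rng = np.random.default_rng(seed)
    arg = new_arg(L, label=0)
    for i in range(1, n):
        k = rng.integers(1, 4)
        starts = np.sort(rng.uniform(0, L, size=k - 1)) if k > 1 else []
        segs = [(0.0, int(rng.choice(arg.samples)), float(rng.gamma(2, 5000)))]
        for s in starts:
            segs.append((float(s), int(rng.choice(arg.samples)),
                         float(rng.gamma(2, 5000))))
        arg.thread(ThreadingInstruction(tuple(segs)), label=i)
    return arg


class TestNewArgAndThread:
    def test_new_arg_is_single_lineage(self):
        arg = new_arg(1e6)
        assert arg.num_samples == 1
        assert arg.edges == []
        assert arg.total_area() == 0.0
        tree = arg.marginal_tree(5e5)
        assert tree.num_leaves == 1

    def test_two_sample_constant_tmrca(self):
        arg = two_sample_arg(t=123.0)
        for x in (0.0, 3e5, 999999.0):
            tree = arg.marginal_tree(x)
            assert tree.tmrca(arg.samples[0], arg.samples[1]) == 123.0
        assert arg.total_area() == pytest.approx(2 * 123.0 * 1e6)

    def test_invalid_instructions_rejected(self):
        arg = new_arg(1e6)
        s0 = arg.samples[0]
        with pytest.raises(ValueError):
            ThreadingInstruction(((0.0, s0, -1.0),))
        with pytest.raises(ValueError):
            ThreadingInstruction(((0.0, s0, 10.0), (0.0, s0, 10.0)))
        with pytest.raises(ValueError, match="unknown"):
            arg.thread(ThreadingInstruction(((0.0, 999, 10.0),)))

    def test_oracle_roundtrip_reproduces_true_tmrcas(self, small_dataset):
        """Threading with (target, TMRCA) read off a true ARG reproduces the
        threaded sample's pairwise TMRCA to its targets exactly."""
        ts = small_dataset.true_arg.to_tree_sequence()
        focal = ts.samples()[-1]
        others = ts.samples()[:-1]
        # read the closest-relative instruction off the truth
        segs = []
        prev = None
        for tree in ts.trees():
            tm = {u: tree.tmrca(focal, u) for u in others}
            best = min(others, key=lambda u: (tm[u], u))
            key = (int(best), float(tm[best]))
            if key != prev:
                segs.append((tree.interval.left, key[0], key[1]))
                prev = key
        # rebuild the ARG of the others and thread the focal sample
        reduced = ts.simplify(others)
        arg = ARG.from_tree_sequence(reduced)
        node_of_label = {arg.sample_label[s]: s for s in arg.samples}
        remap = {int(u): node_of_label[i] for i, u in enumerate(others)}
        instr = ThreadingInstruction(
            tuple((s, remap[t], h) for s, t, h in segs)
        )
        new = arg.thread(instr, label=len(others))
        arg.validate()
        for (s, t, h), (e, _, _) in zip(
            instr.segments, list(instr.segments[1:]) + [(arg.sequence_length, 0, 0)]
        ):
            mid = (s + e) / 2.0
            tree = arg.marginal_tree(mid)
            assert tree.tmrca(new, t) == pytest.approx(h, rel=1e-12)

    def test_sequential_threading_keeps_graph_valid(self):
        arg = random_threaded_arg(10, 1e5, seed=3)
        arg.validate()
        bps = arg.breakpoints()
        for a, b in zip(bps[:-1], bps[1:]):
            tree = arg.marginal_tree((a + b) / 2)
            assert tree.num_leaves == 10
            for c, p in tree.parent.items():
                assert tree.time[c] < tree.time[p]


class TestMarginalTreeAndArea:
    def test_position_out_of_range(self):
        arg = two_sample_arg()
        with pytest.raises(ValueError):
            arg.marginal_tree(-1.0)
        with pytest.raises(ValueError):
            arg.marginal_tree(1e6)

    def test_trees_constant_within_spans(self):
        arg = random_threaded_arg(5, 1e5, seed=9)
        bps = arg.breakpoints()
        a, b = bps[0], bps[1]
        t1 = arg.marginal_tree(a + (b - a) * 0.25)
        t2 = arg.marginal_tree(a + (b - a) * 0.75)
        assert t1.same_shape(t2)

    def test_matches_simulator_marginal_trees(self, small_dataset):
        arg = small_dataset.true_arg
        ts = arg.to_tree_sequence()
        rng = np.random.default_rng(0)
        for x in rng.uniform(0, arg.sequence_length, size=20):
            tree = arg.marginal_tree(x)
            tst = ts.at(x)
            i, j = rng.choice(arg.num_samples, 2, replace=False)
            si, sj = arg.samples[i], arg.samples[j]
            ui, uj = ts.samples()[i], ts.samples()[j]
            assert tree.tmrca(si, sj) == pytest.approx(tst.tmrca(ui, uj))

    def test_total_area_equals_interval_brute_force(self):
        arg = random_threaded_arg(8, 5e4, seed=21)
        brute = 0.0
        for a, b, tree in arg.trees():
            tbl = sum(
                tree.time[p] - tree.time[c] for c, p in tree.parent.items()
            )
            brute += tbl * (b - a)
        assert arg.total_area() == pytest.approx(brute, rel=1e-9)

    def test_area_additive_over_disjoint_spans(self):
        arg = two_sample_arg(t=50.0, L=2e5)
        half = arg.total_area() / 2
        assert half == pytest.approx(2 * 50.0 * 1e5)


class TestMutationSampling:
    def test_poisson_mean_on_pair_arg(self):
        """E[count] = mu * 2 t L on a two-sample ARG."""
        t, L, mu = 300.0, 1e6, 5e-7
        arg = two_sample_arg(t=t, L=L)
        counts = [
            len(sample_mutations(arg, mu, seed)) for seed in range(400)
        ]
        counts = np.array(counts)
        expected = mu * 2 * t * L
        sem = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * sem

    def test_tiny_rate_gives_no_mutations(self):
        arg = two_sample_arg(t=10.0, L=1e3)
        assert sample_mutations(arg, 1e-15, seed=1) == []

    def test_carrier_sets_match_marginal_trees(self, small_dataset):
        muts = sample_mutations(small_dataset.true_arg, 5e-9, seed=8)
        assert muts
        ts = small_dataset.true_arg.to_tree_sequence()
        for m in muts[:50]:
            tree = ts.at(m.position)
            idx = {int(u): i for i, u in enumerate(ts.samples())}
            below = {idx[int(s)] for s in tree.samples(m.child)}
            assert below == set(m.carrier_set)

    def test_deterministic_given_seed(self):
        arg = two_sample_arg(t=500.0)
        a = sample_mutations(arg, 1e-6, seed=4)
        b = sample_mutations(arg, 1e-6, seed=4)
        assert [m.position for m in a] == [m.position for m in b]


class TestGenotypesAndSerialization:
    def test_genotypes_of_empty(self):
        arg = two_sample_arg()
        X, table = genotypes_of(arg, [])
        assert X.shape == (2, 0) and len(table) == 0

    def test_genotype_carrier_counts(self, small_dataset):
        muts = sample_mutations(small_dataset.true_arg, 5e-9, seed=2)
        X, table = genotypes_of(small_dataset.true_arg, muts)
        np.testing.assert_array_equal(X.sum(axis=0), table["carriers"].to_numpy())
        assert np.all(np.diff(table["position"]) > 0)

    def test_tree_sequence_roundtrip_random_fixtures(self, tmp_path):
        for seed in range(10):
            arg = random_threaded_arg(6, 2e4, seed=seed)
            path = tmp_path / f"a{seed}.trees"
            export_tree_sequence(arg, path)
            back = import_tree_sequence(path)
            assert back.num_samples == arg.num_samples
            assert back.total_area() == pytest.approx(arg.total_area(), rel=1e-9)
            for x in (1.0, 1e4):
                ta, tb = arg.marginal_tree(x), back.marginal_tree(x)
                ra = sorted(
                    tuple(sorted(arg.sample_label[s] for s in labs))
                    for labs in _clades(ta, arg)
                )
                rb = sorted(
                    tuple(sorted(back.sample_label[s] for s in labs))
                    for labs in _clades(tb, back)
                )
                assert ra == rb

    def test_roundtrip_keeps_mutations(self, tmp_path, small_dataset):
        arg = small_dataset.true_arg
        path = tmp_path / "t.trees"
        export_tree_sequence(arg, path)
        back = import_tree_sequence(path)
        assert back.to_tree_sequence().num_sites == small_dataset.num_sites

    def test_malformed_file_raises_parse_error(self, tmp_path):
        bad = tmp_path / "bad.trees"
        bad.write_text("this is not a tree sequence")
        with pytest.raises(ValueError, match="parse"):
            import_tree_sequence(bad)


def _clades(tree, arg):
    sample_set = set(arg.samples)
    return [
        {u for u in labs if u in sample_set}
        for labs in tree.leaf_sets().values()
    ]
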