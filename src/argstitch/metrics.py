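"""ARG and tree comparison metrics.

All ARG-level metrics operate on the joint breakpoint refinement of the two
graphs and weight per-interval quantities by span.  Clades are encoded as
sample-set bitmasks over the shared label order, which makes symmetric
differences and total-variation sums exact set operations.

The ARG total-variation distance compares the probability distributions of
mutations generated by uniform sampling on each ARG: the mass of an
(interval, clade) key is the subtending branch length times the interval
span, divided by the ARG's total area.  Polytomies need no resolution under
this metric; for Robinson-Foulds they are broken randomly (seeded).
"""

from __future__ import annotations

import itertools

import numpy as np

from .arg import ARG, MarginalTree


# --------------------------------------------------------------- utilities


def _check_same_samples(argA: ARG, argB: ARG):
    if sorted(argA.labels) != sorted(argB.labels):
        raise ValueError("ARGs must share the same sample labels")
    if argA.sequence_length != argB.sequence_length:
        raise ValueError("ARGs must share the same sequence length")


def _joint_trees(tsA, tsB):
    """Yield (left, right, treeA, treeB) over the joint breakpoint
    refinement of two tree sequences."""
    itA, itB = tsA.trees(), tsB.trees()
    ta, tb = next(itA), next(itB)
    left = 0.0
    L = tsA.sequence_length
    while left < L:
        right = min(ta.interval.right, tb.interval.right)
        yield left, right, ta, tb
        if right >= L:
            break
        if ta.interval.right <= right:
            ta = next(itA)
        if tb.interval.right <= right:
            tb = next(itB)
        left = right


def _tree_masks(tree, n):
    """Bitmask of descendant sample indices per node of a tskit tree.

    Sample index = position of the node in ``ts.samples()`` (which is label
    order for exported ARGs).  Returns dict node -> int mask.
    """
    idx = {int(u): i for i, u in enumerate(tree.tree_sequence.samples())}
    masks = {}
    for u in tree.nodes(order="postorder"):
        u = int(u)
        m = 1 << idx[u] if u in idx else 0
        for c in tree.children(u):
            m |= masks[int(c)]
        masks[u] = m
    return masks


def _marginal_tree_masks(tree: MarginalTree, label_index):
    below = tree.leaf_sets()
    return {
        u: sum(1 << label_index[lab] for lab in labs)
        for u, labs in below.items()
    }


def _ts_total_area(ts):
    return sum(
        t.total_branch_length * (t.interval.right - t.interval.left)
        for t in ts.trees()
    )


# ---------------------------------------------------------- Robinson-Foulds


def _resolved_clades(tree, n, rng):
    """Nontrivial clade masks (sizes 2..n-1) after random polytomy breaking."""
    full = (1 << n) - 1
    masks = _tree_masks(tree, n)
    clades = []
    for u in masks:
        kids = [int(c) for c in tree.children(u)]
        if not kids:
            continue
        if len(kids) <= 2:
            clades.append(masks[u])
            continue
        # random caterpillar over the children's masks
        parts = [masks[c] for c in kids]
        rng.shuffle(parts)
        acc = parts[0]
        for p in parts[1:]:
            acc |= p
            clades.append(acc)
    return {
        c for c in clades if c != full and bin(c).count("1") >= 2
    }


def robinson_foulds_avg(argA: ARG, argB: ARG, seed: int = 0) -> float:
    """Span-weighted Robinson-Foulds distance, rescaled to [0, 1].

    Per joint interval: polytomies are randomly resolved, then the size of
    the symmetric difference of nontrivial clade sets is divided by the
    total number of nontrivial clades in both trees.
    """
    _check_same_samples(argA, argB)
    tsA, tsB = argA.to_tree_sequence(), argB.to_tree_sequence()
    n = argA.num_samples
    rng = np.random.default_rng(seed)
    acc = 0.0
    for left, right, ta, tb in _joint_trees(tsA, tsB):
        ca = _resolved_clades(ta, n, rng)
        cb = _resolved_clades(tb, n, rng)
        denom = len(ca) + len(cb)
        d = len(ca ^ cb) / denom if denom else 0.0
        acc += d * (right - left)
    return acc / argA.sequence_length


# --------------------------------------------------- ARG total variation


def arg_total_variation(argA: ARG, argB: ARG, freq_bins=None):
    """Total variation between the mutation-sampling distributions.

    Without ``freq_bins`` returns a scalar in [0, 1].  With bins (sequence
    of (lo, hi] MAF limits on the clade carrier fraction) the distributions
    are restricted to each bin and renormalized within it, and a list of
    per-bin distances is returned.
    """
    _check_same_samples(argA, argB)
    tsA, tsB = argA.to_tree_sequence(), argB.to_tree_sequence()
    n = argA.num_samples
    areaA, areaB = _ts_total_area(tsA), _ts_total_area(tsB)

    def interval_masses(tree, span, area):
        masks = _tree_masks(tree, n)
        out = {}
        for u, m in masks.items():
            if m == 0:
                continue
            p = tree.parent(u)
            if p == -1:
                continue
            bl = tree.branch_length(u)
            if bl <= 0:
                continue
            out[m] = out.get(m, 0.0) + bl * span / area
        return out

    if freq_bins is None:
        tv = 0.0
        for left, right, ta, tb in _joint_trees(tsA, tsB):
            span = right - left
            ma = interval_masses(ta, span, areaA)
            mb = interval_masses(tb, span, areaB)
            for key in ma.keys() | mb.keys():
                tv += abs(ma.get(key, 0.0) - mb.get(key, 0.0))
        return min(0.5 * tv, 1.0)

    bins = list(freq_bins)

    def bin_of(mask):
        k = bin(mask).count("1")
        maf = min(k, n - k) / n
        for b, (lo, hi) in enumerate(bins):
            if lo < maf <= hi:
                return b
        return None

    totals = np.zeros((2, len(bins)))
    for pass_id in range(2):
        tv_bins = np.zeros(len(bins))
        for left, right, ta, tb in _joint_trees(tsA, tsB):
            span = right - left
            ma = interval_masses(ta, span, areaA)
            mb = interval_masses(tb, span, areaB)
            for key in ma.keys() | mb.keys():
                b = bin_of(key)
                if b is None:
                    continue
                if pass_id == 0:
                    totals[0, b] += ma.get(key, 0.0)
                    totals[1, b] += mb.get(key, 0.0)
                else:
                    pa = ma.get(key, 0.0) / totals[0, b] if totals[0, b] else 0.0
                    pb = mb.get(key, 0.0) / totals[1, b] if totals[1, b] else 0.0
                    tv_bins[b] += abs(pa - pb)
    out = []
    for b in range(len(bins)):
        if totals[0, b] == 0 and totals[1, b] == 0:
            out.append(0.0)
        elif totals[0, b] == 0 or totals[1, b] == 0:
            out.append(1.0)
        else:
            out.append(min(0.5 * tv_bins[b], 1.0))
    return out


# ------------------------------------------------------------ KC distance


def _kc_vector(tree: MarginalTree, lam: float, leaf_order):
    """Kendall-Colijn vector: root-to-MRCA depths per leaf pair (edges for
    the topology part, time for the branch-length part) plus pendant
    entries, blended by lambda."""
    pos = {lab: k for k, lab in enumerate(leaf_order)}
    n = len(leaf_order)
    npairs = n * (n - 1) // 2

    def pair_index(i, j):
        i, j = min(i, j), max(i, j)
        return i * n - i * (i + 1) // 2 + (j - i - 1)

    topo = np.zeros(npairs + n)
    blen = np.zeros(npairs + n)
    root_t = tree.time[tree.root]
    below = tree.leaf_sets()
    for u in tree.internal_nodes():
        d = tree.depth_edges(u)
        groups = [sorted(below[c]) for c in tree.children[u]]
        for ga, gb in itertools.combinations(groups, 2):
            for a in ga:
                for b in gb:
                    k = pair_index(pos[a], pos[b])
                    topo[k] = d
                    blen[k] = root_t - tree.time[u]
    for lab in leaf_order:
        k = npairs + pos[lab]
        topo[k] = 1.0
        blen[k] = tree.time[tree.parent[lab]] - tree.time[lab]
    return (1.0 - lam) * topo + lam * blen


def kc_distance(treeA: MarginalTree, treeB: MarginalTree, lam: float = 0.0) -> float:
    """Euclidean Kendall-Colijn distance between two rooted trees."""
    if set(treeA.leaves) != set(treeB.leaves):
        raise ValueError("trees must share the same leaves")
    order = sorted(treeA.leaves)
    va = _kc_vector(treeA, lam, order)
    vb = _kc_vector(treeB, lam, order)
    return float(np.linalg.norm(va - vb))


def kc_distance_arg(argA: ARG, argB: ARG, lam: float = 0.0) -> float:
    """Span-weighted genome average of per-interval KC distances."""
    _check_same_samples(argA, argB)
    bps = np.unique(np.concatenate([argA.breakpoints(), argB.breakpoints()]))
    acc = 0.0
    for a, b in zip(bps[:-1], bps[1:]):
        mid = (a + b) / 2.0
        ta = _relabel(argA.marginal_tree(mid), argA)
        tb = _relabel(argB.marginal_tree(mid), argB)
        acc += kc_distance(ta, tb, lam) * (b - a)
    return acc / argA.sequence_length


def _relabel(tree: MarginalTree, arg: ARG) -> MarginalTree:
    """Sample node ids become external labels; internal ids are wrapped so
    they can never collide with a label."""
    ren = {s: arg.sample_label[s] for s in arg.samples}

    def r(u):
        return ren[u] if u in ren else ("n", u)

    parent = {r(c): r(p) for c, p in tree.parent.items()}
    time = {r(u): t for u, t in tree.time.items()}
    leaves = [r(u) for u in tree.leaves]
    return MarginalTree(parent, time, leaves)


# -------------------------------------------------------------- TMRCA RMSE


def tmrca_rmse(argA: ARG, argB: ARG, n_pairs: int = 100, n_sites: int = 50,
               seed: int = 0, log10: bool = False) -> float:
    """RMSE over a seeded subsample of (pair, site) pairwise TMRCAs."""
    _check_same_samples(argA, argB)
    n = argA.num_samples
    rng = np.random.default_rng(seed)
    all_pairs = list(itertools.combinations(range(n), 2))
    if n_pairs >= len(all_pairs):
        pairs = all_pairs
    else:
        pairs = [all_pairs[k] for k in rng.choice(len(all_pairs), n_pairs, replace=False)]
    sites = np.sort(rng.uniform(0, argA.sequence_length, size=n_sites))
    tsA, tsB = argA.to_tree_sequence(), argB.to_tree_sequence()
    sq = 0.0
    cnt = 0
    for ts, sign in ((tsA, 1.0), (tsB, -1.0)):
        it = ts.trees()
        tree = next(it)
        vals = np.empty((len(sites), len(pairs)))
        samples = ts.samples()
        for si, x in enumerate(sites):
            while tree.interval.right <= x:
                tree = next(it)
            for pi, (i, j) in enumerate(pairs):
                vals[si, pi] = tree.tmrca(samples[i], samples[j])
        if sign > 0:
            va = vals
        else:
            vb = vals
    if log10:
        va, vb = np.log10(va), np.log10(vb)
    return float(np.sqrt(np.mean((va - vb) ** 2)))


# -------------------------------------------------------------- polytomies


def collapse_polytomies(tree: MarginalTree, f: float) -> MarginalTree:
    """Collapse the floor(f (N-2)) least-confident nonleaf branches.

    Branches are ranked by branch length divided by parent-node height;
    ratio ties break by older parent first, then node id.  Requires a
    binary input tree.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    if not tree.is_binary():
        raise ValueError("collapse heuristic requires a binary tree")
    out = tree.copy()
    n = out.num_leaves
    branches = [
        u for u in out.internal_nodes() if u in out.parent
    ]
    k = int(np.floor(f * (n - 2)))
    if len(branches) != n - 2:
        raise ValueError("binary rooted tree must have N-2 nonleaf branches")

    def ratio(u):
        p = out.parent[u]
        return (out.time[p] - out.time[u]) / out.time[p]

    ranked = sorted(
        branches, key=lambda u: (ratio(u), -out.time[out.parent[u]], u)
    )
    for u in ranked[:k]:
        p = out.parent[u]
        for c in out.children[u]:
            out.parent[c] = p
            out.children[p].append(c)
        out.children[p].remove(u)
        del out.parent[u]
        del out.children[u]
        del out.time[u]
    return MarginalTree(out.parent, out.time, out.leaves, out.position)


def resolve_polytomies(tree: MarginalTree, seed: int = 0) -> MarginalTree:
    """Randomly break polytomies into caterpillars of zero-length edges."""
    rng = np.random.default_rng(seed)
    parent = dict(tree.parent)
    time = dict(tree.time)
    next_id = min([u for u in time if isinstance(u, int)] + [0]) - 1
    for u in list(tree.internal_nodes()):
        kids = [c for c, p in parent.items() if p == u]
        if len(kids) <= 2:
            continue
        rng.shuffle(kids)
        acc = kids[0]
        for c in kids[1:-1]:
            w = next_id
            next_id -= 1
            time[w] = time[u]
            parent[acc] = w
            parent[c] = w
            acc = w
        parent[acc] = u
        parent[kids[-1]] = u
    return MarginalTree(parent, time, tree.leaves, tree.position)


def collapse_arg(arg: ARG, f: float) -> ARG:
    """Apply the collapse heuristic to every marginal tree of a binary ARG,
    restitching the polytomized trees over the original intervals."""
    pieces = [
        (a, b, collapse_polytomies(_relabel(tree, arg), f))
        for a, b, tree in arg.trees()
    ]
    return ARG.from_marginal_trees(pieces, arg.sequence_length)


def polytomy_fraction(arg: ARG) -> float:
    """Span-weighted mean fraction of collapsed nonleaf branches per tree."""
    n = arg.num_samples
    if n < 3:
        return 0.0
    acc = 0.0
    for a, b, tree in arg.trees():
        nonleaf = sum(1 for u in tree.internal_nodes() if u in tree.parent)
        acc += (1.0 - nonleaf / (n - 2)) * (b - a)
    return acc / arg.sequence_length
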