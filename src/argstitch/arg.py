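"""The ancestral recombination graph (ARG) container and threading primitives.

An ARG is stored as a node/edge graph: nodes carry times (generations,
samples at time 0) and edges carry half-open genomic spans ``[left, right)``
in base pairs.  At every position, following parent edges whose span covers
that position traces each sample to a single marginal root, so the graph
induces a rooted marginal coalescent tree at every site.

New samples are added by *threading*: a piecewise-constant instruction gives,
per genomic segment, an existing sample to attach to and an attachment
height.  Over each segment, the new lineage is spliced onto the path from
the target sample toward the marginal root at the stated height; heights
above the current root create a new root.

Coordinates are 0-based half-open base pairs throughout.  Conversion to and
from the tskit tree-sequence format is lossless for topology, times, spans
and mutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import tskit

#: Height nudge used when an attachment height collides with an existing
#: node time on the target path; keeps node times strictly ordered.
HEIGHT_EPS = 2.0 ** -20


@dataclass
class Edge:
    child: int
    parent: int
    left: float
    right: float


@dataclass(frozen=True)
class Mutation:
    """A single mutation on an ARG branch.

    ``carrier_set`` holds the sample *labels* (not node ids) inheriting the
    derived allele; recurrent mutations are not modelled, so each variant is
    the carrier set of exactly one branch at its position.
    """

    position: float
    child: int
    parent: int
    time: float
    carrier_set: frozenset


@dataclass(frozen=True)
class ThreadingInstruction:
    """Piecewise-constant threading description.

    ``segments`` is a list of ``(start_bp, target_sample_node, height)``;
    each segment implicitly ends at the next start (or the sequence end).
    """

    segments: tuple

    def __post_init__(self):
        segs = tuple((float(s), t, float(h)) for s, t, h in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("instruction needs at least one segment")
        if segs[0][0] != 0.0:
            raise ValueError("first segment must start at 0")
        starts = [s for s, _, _ in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment starts must be strictly increasing")
        if any(h <= 0 for _, _, h in segs):
            raise ValueError("attachment heights must be positive")


class MarginalTree:
    """Rooted tree over the samples at one genomic position.

    Leaves sit at time 0 (or at the ARG's sample times); internal nodes carry
    strictly larger times than their children except for zero-length edges
    introduced by random polytomy resolution.  Children lists allow
    polytomies.
    """

    def __init__(self, parent, time, leaves, position=None):
        self.parent = dict(parent)
        self.time = dict(time)
        self.leaves = list(leaves)
        self.position = position
        self.children = {}
        for c, p in self.parent.items():
            self.children.setdefault(p, []).append(c)
        roots = set()
        for leaf in self.leaves:
            u = leaf
            while u in self.parent:
                u = self.parent[u]
            roots.add(u)
        if len(roots) != 1:
            raise ValueError(f"tree has {len(roots)} roots, expected 1")
        (self.root,) = roots

    @property
    def num_leaves(self):
        return len(self.leaves)

    def nodes_postorder(self):
        out, stack = [], [self.root]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children.get(u, ()))
        return out[::-1]

    def leaf_sets(self):
        """Map node -> frozenset of leaves below it (inclusive for leaves)."""
        below = {}
        for u in self.nodes_postorder():
            kids = self.children.get(u, ())
            if not kids:
                below[u] = frozenset([u])
            else:
                acc = frozenset()
                for c in kids:
                    acc |= below[c]
                below[u] = acc
        return below

    def mrca(self, i, j):
        anc = set()
        u = i
        while True:
            anc.add(u)
            if u not in self.parent:
                break
            u = self.parent[u]
        u = j
        while u not in anc:
            u = self.parent[u]
        return u

    def tmrca(self, i, j):
        return self.time[self.mrca(i, j)]

    def depth_edges(self, u):
        """Number of edges from the root down to node ``u``."""
        d = 0
        while u in self.parent:
            u = self.parent[u]
            d += 1
        return d

    def is_binary(self):
        return all(
            len(kids) == 2 for kids in self.children.values() if kids
        )

    def internal_nodes(self):
        return [u for u, kids in self.children.items() if kids]

    def copy(self):
        return MarginalTree(self.parent, self.time, self.leaves, self.position)

    def newick(self, labels=None):
        labels = labels or {}

        def rec(u):
            kids = self.children.get(u, ())
            if not kids:
                name = labels.get(u, f"n{u}")
            else:
                name = "(" + ",".join(rec(c) for c in kids) + ")"
            pt = self.time[self.parent[u]] if u in self.parent else self.time[u]
            return f"{name}:{pt - self.time[u]:.6g}" if u in self.parent else name

        return rec(self.root) + ";"

    def same_shape(self, other, tol=0.0):
        """Exact (topology, heights) equality via leaf-set comparison."""
        if set(self.leaves) != set(other.leaves):
            return False
        a = {below: self.time[u] for u, below in self.leaf_sets().items()}
        b = {below: other.time[u] for u, below in other.leaf_sets().items()}
        if a.keys() != b.keys():
            return False
        return all(abs(a[k] - b[k]) <= tol for k in a)


class ARG:
    """Node/edge-with-span ancestral recombination graph."""

    def __init__(self, sequence_length: float):
        if sequence_length <= 0:
            raise ValueError("sequence length must be positive")
        self.sequence_length = float(sequence_length)
        self.node_time = {}
        self.samples = []          # sample node ids, in insertion order
        self.sample_label = {}     # node id -> external label (e.g. hap row)
        self.edges = []
        self.mutations = []
        self._next_node = 0
        self._ts = None
        self._ts_node_map = None

    # ------------------------------------------------------------ plumbing

    def add_node(self, time: float) -> int:
        nid = self._next_node
        self._next_node += 1
        self.node_time[nid] = float(time)
        return nid

    def add_sample(self, label=None) -> int:
        nid = self.add_node(0.0)
        self.samples.append(nid)
        self.sample_label[nid] = label if label is not None else len(self.samples) - 1
        return nid

    @property
    def num_samples(self):
        return len(self.samples)

    @property
    def labels(self):
        return [self.sample_label[s] for s in self.samples]

    def _invalidate(self):
        self._ts = None
        self._ts_node_map = None

    def breakpoints(self) -> np.ndarray:
        pts = {0.0, self.sequence_length}
        for e in self.edges:
            if 0.0 < e.left < self.sequence_length:
                pts.add(e.left)
            if 0.0 < e.right < self.sequence_length:
                pts.add(e.right)
        return np.array(sorted(pts))

    def parent_map_at(self, x: float) -> dict:
        return {e.child: e.parent for e in self.edges if e.left <= x < e.right}

    def marginal_tree(self, x: float) -> MarginalTree:
        if not (0.0 <= x < self.sequence_length):
            raise ValueError(f"position {x} outside [0, {self.sequence_length})")
        pmap = self.parent_map_at(x)
        keep = set(self.samples)
        for s in self.samples:
            u = s
            while u in pmap:
                u = pmap[u]
                keep.add(u)
        parent = {c: p for c, p in pmap.items() if c in keep and p in keep}
        time = {u: self.node_time[u] for u in keep}
        return MarginalTree(parent, time, list(self.samples), position=x)

    def trees(self):
        """Yield ``(left, right, MarginalTree)`` over breakpoint intervals."""
        bps = self.breakpoints()
        for a, b in zip(bps[:-1], bps[1:]):
            yield a, b, self.marginal_tree((a + b) / 2.0)

    def total_area(self) -> float:
        """Sum over edges of (parent time - child time) x span length."""
        return float(
            sum(
                (self.node_time[e.parent] - self.node_time[e.child])
                * (e.right - e.left)
                for e in self.edges
            )
        )

    # ----------------------------------------------------------- threading

    def thread(self, instruction: ThreadingInstruction, label=None) -> int:
        """Add one sample according to ``instruction``; returns its node id.

        Implemented as one left-to-right sweep over the existing edge set:
        the marginal parent map is maintained incrementally, the attachment
        edge is resolved per sub-interval, consecutive sub-intervals with
        the same attachment are merged, and all edge splits are applied
        after the sweep (new edges never overlap later segments).
        """
        existing = set(self.samples)
        for _, target, _ in instruction.segments:
            if target not in existing:
                raise ValueError(f"unknown threading target node {target}")
        starts = [s for s, _, _ in instruction.segments]
        if starts[-1] >= self.sequence_length:
            raise ValueError("segment start beyond sequence end")
        new_id = self.add_sample(label=label)

        # sweep events: edge insertions/removals plus segment starts
        events = sorted(
            {e.left for e in self.edges}
            | {e.right for e in self.edges}
            | set(starts)
            | {0.0, self.sequence_length}
        )
        events = [x for x in events if 0.0 <= x <= self.sequence_length]
        ins = {}
        outs = {}
        for e in self.edges:
            ins.setdefault(e.left, []).append(e)
            outs.setdefault(e.right, []).append(e)
        seg_at = np.searchsorted(starts, events[:-1], side="right")

        cur = {}  # child -> active edge
        groups = []  # (key, a, b, h); key identifies the attachment
        for (a, b), seg_idx in zip(zip(events[:-1], events[1:]), seg_at):
            for e in outs.get(a, ()):
                if cur.get(e.child) is e:
                    del cur[e.child]
            for e in ins.get(a, ()):
                cur[e.child] = e
            _, target, height = instruction.segments[int(seg_idx) - 1]
            path = [target]
            while path[-1] in cur:
                path.append(cur[path[-1]].parent)
            h = height
            times = {self.node_time[u] for u in path}
            while h in times:
                h += HEIGHT_EPS
            above_idx = None
            for k, u in enumerate(path):
                if self.node_time[u] > h:
                    above_idx = k
                    break
            if above_idx is None:
                key = ("root", path[-1])
                edge_obj = None
            else:
                edge_obj = cur[path[above_idx - 1]]
                key = ("edge", edge_obj)
            if groups and groups[-1][0] == key and groups[-1][2] == a \
                    and groups[-1][3] == h:
                groups[-1] = (key, groups[-1][1], b, h)
            else:
                groups.append((key, a, b, h))

        # apply modifications: split spans out of attachment edges, insert
        # the new internal nodes and the new sample's edges
        cut_spans = {}
        new_edges = []
        for key, a, b, h in groups:
            w = self.add_node(h)
            if key[0] == "root":
                new_edges.append(Edge(key[1], w, a, b))
            else:
                e = key[1]
                cut_spans.setdefault(id(e), (e, []))[1].append((a, b))
                new_edges.append(Edge(e.child, w, a, b))
                new_edges.append(Edge(w, e.parent, a, b))
            new_edges.append(Edge(new_id, w, a, b))
        if cut_spans:
            replaced = {}
            for eid, (e, cuts) in cut_spans.items():
                pieces = []
                lo = e.left
                for a, b in sorted(cuts):
                    if lo < a:
                        pieces.append(Edge(e.child, e.parent, lo, a))
                    lo = b
                if lo < e.right:
                    pieces.append(Edge(e.child, e.parent, lo, e.right))
                replaced[eid] = pieces
            rebuilt = []
            for e in self.edges:
                if id(e) in replaced:
                    rebuilt.extend(replaced[id(e)])
                else:
                    rebuilt.append(e)
            self.edges = rebuilt
        self.edges.extend(new_edges)
        self._invalidate()
        return new_id

    # ---------------------------------------------------------- validation

    def validate(self):
        """Raise ValueError on any violated graph invariant."""
        for e in self.edges:
            if e.right <= e.left:
                raise ValueError(f"empty edge span on {e}")
            if self.node_time[e.child] >= self.node_time[e.parent]:
                raise ValueError(
                    f"edge {e.child}->{e.parent} violates time ordering"
                )
        by_child = {}
        for e in self.edges:
            by_child.setdefault((e.child, None), []).append(e)
        for (_, _), es in by_child.items():
            spans = sorted((e.left, e.right) for e in es)
            for (l1, r1), (l2, r2) in zip(spans[:-1], spans[1:]):
                if l2 < r1:
                    raise ValueError(
                        f"overlapping parent spans above child {es[0].child}"
                    )
        if self.num_samples >= 1 and self.edges:
            bps = self.breakpoints()
            for a, b in zip(bps[:-1], bps[1:]):
                self.marginal_tree((a + b) / 2.0)  # raises if roots != 1

    # --------------------------------------------------- tskit conversion

    def to_tree_sequence(self) -> tskit.TreeSequence:
        """Export to tskit; samples are written first, in label order."""
        if self._ts is not None:
            return self._ts
        tables = tskit.TableCollection(sequence_length=self.sequence_length)
        order = sorted(self.samples, key=lambda s: self.sample_label[s])
        node_map = {}
        for s in order:
            node_map[s] = tables.nodes.add_row(
                flags=tskit.NODE_IS_SAMPLE, time=self.node_time[s]
            )
        for nid, t in self.node_time.items():
            if nid not in node_map:
                node_map[nid] = tables.nodes.add_row(flags=0, time=t)
        for e in self.edges:
            tables.edges.add_row(
                left=e.left, right=e.right,
                parent=node_map[e.parent], child=node_map[e.child],
            )
        label_to_idx = {self.sample_label[s]: i for i, s in enumerate(order)}
        for mut in sorted(self.mutations, key=lambda m: m.position):
            site = tables.sites.add_row(position=mut.position, ancestral_state="0")
            tables.mutations.add_row(
                site=site, node=node_map[mut.child], derived_state="1",
                time=mut.time,
            )
        tables.sort()
        tables.edges.squash()
        tables.sort()
        tables.build_index()
        self._ts = tables.tree_sequence()
        self._ts_node_map = node_map
        return self._ts

    @classmethod
    def from_tree_sequence(cls, ts: tskit.TreeSequence,
                           materialize_mutations: bool = False) -> "ARG":
        arg = cls(ts.sequence_length)
        times = ts.tables.nodes.time
        id_map = {}
        for i, u in enumerate(ts.samples()):
            nid = arg.add_node(float(times[u]))
            arg.samples.append(nid)
            arg.sample_label[nid] = i
            id_map[int(u)] = nid
        for u in range(ts.num_nodes):
            if u not in id_map:
                id_map[u] = arg.add_node(float(times[u]))
        lut = np.empty(ts.num_nodes, dtype=np.int64)
        for u, v in id_map.items():
            lut[u] = v
        tab = ts.tables.edges
        arg.edges = [
            Edge(int(c), int(p), float(l), float(r))
            for c, p, l, r in zip(
                lut[tab.child], lut[tab.parent], tab.left, tab.right
            )
        ]
        arg._ts = ts
        arg._ts_node_map = {v: k for k, v in id_map.items()}
        if materialize_mutations and ts.num_mutations:
            arg.materialize_mutations()
        return arg

    def materialize_mutations(self):
        """Populate ``self.mutations`` (with carrier sets) from the cached
        tree sequence's mutation table; cost scales with sites x carriers."""
        ts = self.to_tree_sequence()
        times = ts.tables.nodes.time
        rev = self._ts_node_map
        inv = {v: k for k, v in rev.items()} if rev else None
        sample_index = {int(u): i for i, u in enumerate(ts.samples())}
        self.mutations = []
        for var_tree, site, mut in _iter_ts_mutations(ts):
            carriers = frozenset(
                sample_index[int(s)] for s in var_tree.samples(mut.node)
            )
            parent = var_tree.parent(mut.node)
            t = mut.time
            if t is None or (isinstance(t, float) and np.isnan(t)):
                t = float(times[mut.node])
            self.mutations.append(
                Mutation(
                    position=site.position,
                    child=inv[int(mut.node)] if inv else int(mut.node),
                    parent=(inv[int(parent)] if inv else int(parent))
                    if parent != tskit.NULL else -1,
                    time=float(t),
                    carrier_set=carriers,
                )
            )
        return self.mutations

    @classmethod
    def from_marginal_trees(cls, pieces, sequence_length) -> "ARG":
        """Stitch ``(left, right, MarginalTree)`` pieces into one ARG.

        All trees must share the same leaf label set; leaf labels become the
        sample labels, and each tree's internal nodes get fresh node ids.
        """
        arg = cls(sequence_length)
        first = pieces[0][2]
        leaf_ids = {}
        for label in sorted(first.leaves):
            leaf_ids[label] = arg.add_sample(label=label)
        for left, right, tree in pieces:
            if set(tree.leaves) != set(leaf_ids):
                raise ValueError("marginal trees disagree on leaf set")
            local = {}
            for u in tree.nodes_postorder():
                if not tree.children.get(u):
                    local[u] = leaf_ids[u]
                else:
                    local[u] = arg.add_node(tree.time[u])
            for c, p in tree.parent.items():
                arg.edges.append(Edge(local[c], local[p], left, right))
        return arg

    def with_node_times(self, new_times: dict) -> "ARG":
        """Copy of this ARG with node times replaced (topology unchanged)."""
        out = ARG(self.sequence_length)
        out.node_time = {u: float(new_times.get(u, t)) for u, t in self.node_time.items()}
        out.samples = list(self.samples)
        out.sample_label = dict(self.sample_label)
        out.edges = [Edge(e.child, e.parent, e.left, e.right) for e in self.edges]
        out.mutations = list(self.mutations)
        out._next_node = self._next_node
        return out


def _iter_ts_mutations(ts):
    tree = None
    for site in ts.sites():
        for mut in site.mutations:
            if tree is None or not (tree.interval.left <= site.position < tree.interval.right):
                tree = ts.at(site.position)
            yield tree, site, mut


# ------------------------------------------------------------- operations


def new_arg(sequence_length: float, label=None) -> ARG:
    """Fresh ARG containing a single sample lineage and no edges."""
    arg = ARG(sequence_length)
    arg.add_sample(label=label)
    return arg


def sample_mutation_events(arg: ARG, mu: float, seed: int):
    """Draw Poisson mutations area-uniformly on the ARG's edges.

    Returns ``(positions, child_nodes, times, edge_idx)`` arrays sorted by
    position, where nodes are *tskit* node ids of the exported tree sequence.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    ts = arg.to_tree_sequence()
    tab = ts.tables
    t = tab.nodes.time
    areas = (t[tab.edges.parent] - t[tab.edges.child]) * (
        tab.edges.right - tab.edges.left
    )
    total = float(areas.sum())
    rng = np.random.default_rng(seed)
    n = rng.poisson(mu * total)
    if n == 0:
        return (np.empty(0), np.empty(0, int), np.empty(0), np.empty(0, int))
    eidx = rng.choice(len(areas), size=n, p=areas / total)
    left, right = tab.edges.left[eidx], tab.edges.right[eidx]
    pos = left + rng.random(n) * (right - left)
    # re-draw the measure-zero event of coincident positions
    while len(np.unique(pos)) < n:
        _, first = np.unique(pos, return_index=True)
        dup = np.setdiff1d(np.arange(n), first)
        pos[dup] = left[dup] + rng.random(len(dup)) * (right[dup] - left[dup])
    tc, tp = t[tab.edges.child[eidx]], t[tab.edges.parent[eidx]]
    mtime = tc + rng.random(n) * (tp - tc)
    order = np.argsort(pos)
    return pos[order], tab.edges.child[eidx][order], mtime[order], eidx[order]


def mutations_to_tree_sequence(arg: ARG, pos, nodes, times) -> tskit.TreeSequence:
    """Attach sampled mutations to the ARG's exported tree sequence."""
    ts = arg.to_tree_sequence()
    tables = ts.dump_tables()
    tables.sites.reset()
    tables.mutations.reset()
    n = len(pos)
    state = np.full(n, ord("0"), dtype=np.int8)
    offsets = np.arange(n + 1, dtype=np.uint64)
    tables.sites.set_columns(
        position=np.asarray(pos, float),
        ancestral_state=state,
        ancestral_state_offset=offsets,
    )
    tables.mutations.set_columns(
        site=np.arange(n, dtype=np.int32),
        node=np.asarray(nodes, np.int32),
        time=np.asarray(times, float),
        derived_state=np.full(n, ord("1"), dtype=np.int8),
        derived_state_offset=offsets,
        parent=np.full(n, tskit.NULL, dtype=np.int32),
    )
    tables.sort()
    return tables.tree_sequence()


def sample_mutations(arg: ARG, mu: float, seed: int) -> list:
    """Poisson mutation sampling returning :class:`Mutation` records.

    The count is Poisson(mu x total area); branch and position are chosen
    with probability proportional to edge area; the mutation time is uniform
    on the edge's time extent.  Deterministic given ``seed``.
    """
    pos, nodes, times, _ = sample_mutation_events(arg, mu, seed)
    if len(pos) == 0:
        return []
    mts = mutations_to_tree_sequence(arg, pos, nodes, times)
    out = []
    tree = tskit.Tree(mts)
    sample_index = {int(u): i for i, u in enumerate(mts.samples())}
    for site in mts.sites():
        mut = site.mutations[0]
        tree.seek(site.position)
        carriers = frozenset(sample_index[int(s)] for s in tree.samples(mut.node))
        out.append(
            Mutation(
                position=site.position,
                child=int(mut.node),
                parent=int(tree.parent(mut.node)),
                time=float(mut.time),
                carrier_set=carriers,
            )
        )
    return out


def genotypes_of(arg: ARG, mutations: list):
    """Binary genotype matrix (N x M) and site table for given mutations.

    Columns are ordered by position; row ``i`` is the sample with label
    index ``i`` in the ARG's label order.
    """
    import pandas as pd

    muts = sorted(mutations, key=lambda m: m.position)
    n = arg.num_samples
    X = np.zeros((n, len(muts)), dtype=np.int8)
    label_order = {lab: i for i, lab in enumerate(sorted(arg.labels))}
    for k, m in enumerate(muts):
        for c in m.carrier_set:
            X[label_order.get(c, c), k] = 1
    table = pd.DataFrame(
        {
            "position": [m.position for m in muts],
            "carriers": [len(m.carrier_set) for m in muts],
            "frequency": [len(m.carrier_set) / n for m in muts],
            "time": [m.time for m in muts],
        }
    )
    return X, table


def export_tree_sequence(arg: ARG, path):
    ts = arg.to_tree_sequence()
    if arg.mutations and ts.num_mutations == 0:
        ts = mutations_to_tree_sequence(
            arg,
            np.array([m.position for m in arg.mutations]),
            np.array([arg._ts_node_map[m.child] if arg._ts_node_map else m.child
                      for m in arg.mutations], dtype=np.int32),
            np.array([m.time for m in arg.mutations]),
        )
    ts.dump(str(path))


def import_tree_sequence(path) -> ARG:
    try:
        ts = tskit.load(str(path))
    except Exception as exc:  # tskit raises several error types
        raise ValueError(f"could not parse tree-sequence file {path}: {exc}")
    return ARG.from_tree_sequence(ts)


def pairwise_tmrca_matrix(arg: ARG) -> np.ndarray:
    """Genome-averaged (span-weighted) N x N pairwise TMRCA matrix."""
    ts = arg.to_tree_sequence()
    n = ts.num_samples
    acc = np.zeros((n, n))
    for tree in ts.trees():
        span = tree.interval.right - tree.interval.left
        acc += tree_tmrca_matrix(tree, n) * span
    return acc / arg.sequence_length


def tree_tmrca_matrix(tree, n: int) -> np.ndarray:
    """Pairwise TMRCA matrix of one tskit tree (zero diagonal)."""
    T = np.zeros((n, n))
    below = {}
    ts_samples = {int(u): i for i, u in enumerate(tree.tree_sequence.samples())}
    for u in tree.nodes(order="postorder"):
        kids = tree.children(u)
        if not kids:
            below[u] = np.array([ts_samples[int(u)]]) if int(u) in ts_samples else np.array([], int)
            continue
        groups = [below[c] for c in kids]
        t = tree.time(u)
        for a, b in itertools.combinations(groups, 2):
            T[np.ix_(a, b)] = t
            T[np.ix_(b, a)] = t
        own = np.array([ts_samples[int(u)]]) if int(u) in ts_samples else np.array([], int)
        if own.size:
            for g in groups:
                T[np.ix_(own, g)] = t
                T[np.ix_(g, own)] = t
            groups.append(own)
        below[u] = np.concatenate(groups)
    return T
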