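"""All-pairs decoding plus per-site UPGMA clustering of TMRCA matrices.

At every variant site the N x N posterior-mean TMRCA matrix is clustered
with UPGMA; matrix entries are already times to common ancestry, so each
merge happens at the average pairwise TMRCA between the merged clusters
(not at half the distance), which makes ultrametric inputs exactly
recoverable.  Marginal trees are stitched into an ARG using inter-site
midpoints as tree extents, merging adjacent identical trees into one span.
"""

from __future__ import annotations

import itertools

import numpy as np

from .arg import ARG, MarginalTree
from .demography import DemographicModel, GeneticMap
from . import normalize as _norm
from .needle import NeedleConfig
from .pairhmm import build_pair_hmm, decode_pair, discretize_time, oracle_decode

#: minimal height step used when noisy merges would violate time ordering
_TIME_EPS = 2.0 ** -20


def upgma(matrix: np.ndarray, leaf_labels=None) -> MarginalTree:
    """Average-linkage clustering of a TMRCA matrix into a rooted tree.

    Requires a symmetric matrix with zero diagonal and positive
    off-diagonal entries.  Merge ties break on the lexicographically
    smallest cluster pair, identified by the smallest leaf in each cluster.
    """
    D = np.asarray(matrix, float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("need a square matrix of size >= 2")
    if not np.allclose(D, D.T, rtol=0, atol=1e-9):
        raise ValueError("TMRCA matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("TMRCA matrix must have zero diagonal")
    if leaf_labels is None:
        leaf_labels = list(range(n))

    W = D.astype(float).copy()
    np.fill_diagonal(W, np.inf)
    active = list(range(n))                # active cluster slots
    size = {i: 1 for i in range(n)}
    rep = {i: leaf_labels[i] for i in range(n)}   # smallest leaf per cluster
    node_of = {i: leaf_labels[i] for i in range(n)}
    parent, time = {}, {lab: 0.0 for lab in leaf_labels}
    next_internal = -1
    while len(active) > 1:
        sub = W[np.ix_(active, active)]
        dmin = sub.min()
        # tie-break: smallest (rep_a, rep_b) among minimal pairs
        best = None
        for ai, bi in zip(*np.nonzero(sub <= dmin + 0.0)):
            if ai >= bi:
                continue
            a, b = active[ai], active[bi]
            key = tuple(sorted((rep[a], rep[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        h = W[a, b]
        node = next_internal
        next_internal -= 1
        child_max = max(time[node_of[a]], time[node_of[b]])
        time[node] = max(h, child_max + _TIME_EPS)
        parent[node_of[a]] = node
        parent[node_of[b]] = node
        # size-weighted average linkage update
        for c in active:
            if c in (a, b):
                continue
            W[a, c] = W[c, a] = (size[a] * W[a, c] + size[b] * W[b, c]) / (
                size[a] + size[b]
            )
        size[a] += size[b]
        rep[a] = min(rep[a], rep[b])
        node_of[a] = node
        active.remove(b)
    return MarginalTree(parent, time, list(leaf_labels))


def _pairwise_posterior_means(X, positions, genetic_map, demography, config,
                              site_slice=None):
    """Posterior-mean TMRCAs for all pairs: returns array (P, M_sel) plus
    the pair list, decoding the full sequence for context."""
    n, m = X.shape
    pairs = list(itertools.combinations(range(n), 2))
    sel = np.arange(m) if site_slice is None else np.arange(m)[site_slice]
    out = np.empty((len(pairs), len(sel)))
    if config.oracle_arg is not None:
        for k, (i, j) in enumerate(pairs):
            post = oracle_decode(config.oracle_arg, i, j, positions)
            out[k] = post.posterior_mean[sel]
        return out, pairs
    disc = discretize_time(demography, config.D)
    model = build_pair_hmm(
        demography, config.mu, config.rho, disc, mode=config.mode,
        site_frequencies=X.mean(axis=0),
    )
    for k, (i, j) in enumerate(pairs):
        post = decode_pair(model, X[i], X[j], positions, genetic_map)
        out[k] = post.posterior_mean[sel]
    return out, pairs


def _stitch(trees, positions, sequence_length) -> ARG:
    """Merge adjacent identical per-site trees and stitch at midpoints."""
    m = len(positions)
    bounds = np.concatenate(
        [[0.0], (np.asarray(positions[:-1]) + np.asarray(positions[1:])) / 2.0,
         [sequence_length]]
    )
    pieces = []
    start = 0
    for s in range(1, m + 1):
        if s < m and trees[s].same_shape(trees[start]):
            continue
        pieces.append((bounds[start], bounds[s], trees[start]))
        start = s
    return ARG.from_marginal_trees(pieces, sequence_length)


def build_asmc_clust(
    haplotypes, positions, genetic_map: GeneticMap,
    demography: DemographicModel, config: NeedleConfig = NeedleConfig(),
    sequence_length=None,
) -> ARG:
    """Build an ARG from per-site UPGMA trees of all-pairs TMRCA decodes."""
    X = np.asarray(haplotypes)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two haplotypes")
    positions = np.asarray(positions, float)
    if sequence_length is None:
        sequence_length = float(positions[-1]) + 1.0
    post, pairs = _pairwise_posterior_means(
        X, positions, genetic_map, demography, config
    )
    trees = []
    for s in range(m):
        mat = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            mat[i, j] = mat[j, i] = post[k, s]
        trees.append(upgma(mat))
    arg = _stitch(trees, positions, sequence_length)
    if config.normalize:
        rng = np.random.default_rng(config.seed)
        ref = _norm.reference_quantiles(
            demography, n, n_trees=config.normalize_n_trees,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        arg = _norm.normalize(arg, ref)
    return arg


def build_asmc_clust_lowmem(
    haplotypes, positions, genetic_map: GeneticMap,
    demography: DemographicModel, config: NeedleConfig = NeedleConfig(),
    sequence_length=None, chunk_sites: int = 64,
) -> ARG:
    """Memory-lean variant: identical output, one site chunk of TMRCA
    matrices resident at a time (pairs are re-decoded per chunk, trading
    runtime for memory)."""
    X = np.asarray(haplotypes)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two haplotypes")
    positions = np.asarray(positions, float)
    if sequence_length is None:
        sequence_length = float(positions[-1]) + 1.0
    trees = []
    for lo in range(0, m, chunk_sites):
        sl = slice(lo, min(lo + chunk_sites, m))
        post, pairs = _pairwise_posterior_means(
            X, positions, genetic_map, demography, config, site_slice=sl
        )
        for s in range(post.shape[1]):
            mat = np.zeros((n, n))
            for k, (i, j) in enumerate(pairs):
                mat[i, j] = mat[j, i] = post[k, s]
            trees.append(upgma(mat))
    arg = _stitch(trees, positions, sequence_length)
    if config.normalize:
        rng = np.random.default_rng(config.seed)
        ref = _norm.reference_quantiles(
            demography, n, n_trees=config.normalize_n_trees,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        arg = _norm.normalize(arg, ref)
    return arg
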