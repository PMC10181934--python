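"""Genomic relatedness from genotypes and from ARGs.

The genotype GRM is the frequency-weighted cross-product
``K_alpha(i,j) = (1/M) sum_k (x_ik - p_k)(x_jk - p_k) [p_k(1-p_k)]^alpha``.
The ARG-GRM is its expectation under mutations sampled uniformly on the
ARG's area: entry (i, j) accumulates span x (1 - exp(-2 mu t_ij)) over
breakpoint intervals (or the linearization span x 2 mu t_ij).  The Monte
Carlo ARG-GRM samples mutations at a high rate (default 1.65e-7, where the
approximation saturates) and applies the genotype estimator, optionally
stratified by MAF bin.

Comparisons between GRM flavours are made after double-centering, which
removes the row/column mean invariances of the estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .arg import ARG, sample_mutation_events, mutations_to_tree_sequence, tree_tmrca_matrix

MC_MU_DEFAULT = 1.65e-7

#: Default MAF bin edges for stratified ARG-GRMs (log-spaced toward rare).
DEFAULT_MAF_BIN_EDGES = (0.0, 0.001, 0.01, 0.05, 0.1, 0.2, 0.35, 0.5)


@dataclass
class GRM:
    matrix: np.ndarray
    sample_ids: np.ndarray
    provenance: str          # genotype | hamming | exact_arg | monte_carlo
    alpha: float | None = None
    mu: float | None = None
    n_markers: int | None = None
    maf_bin: tuple | None = None

    def __post_init__(self):
        K = np.asarray(self.matrix, float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("GRM must be square")
        if not np.all(np.isfinite(K)):
            raise ValueError("GRM entries must be finite")
        self.matrix = K
        self.sample_ids = np.asarray(self.sample_ids)


def double_center(K: np.ndarray) -> np.ndarray:
    """Project out row and column means (the canonical equivalence for
    comparing GRM flavours)."""
    K = np.asarray(K, float)
    r = K.mean(axis=1, keepdims=True)
    c = K.mean(axis=0, keepdims=True)
    return K - r - c + K.mean()


def _weighted_crossproduct(X, p, alpha, chunk=8192, dtype=np.float32):
    """(1/M) (X-p) diag(w) (X-p)^T accumulated in chunks.

    Uses the symmetric rank-k BLAS update in float32 for large marker
    counts (chunk sums are accumulated in float64).
    """
    from scipy.linalg.blas import dsyrk, ssyrk

    n, m = X.shape
    K = np.zeros((n, n))
    w = (p * (1.0 - p)) ** (alpha / 2.0)
    syrk = ssyrk if dtype == np.float32 else dsyrk
    for lo in range(0, m, chunk):
        sl = slice(lo, min(lo + chunk, m))
        Z = (X[:, sl].astype(dtype) - p[sl].astype(dtype)) * w[sl].astype(dtype)
        K += syrk(1.0, np.asfortranarray(Z), lower=1).astype(np.float64)
    K = np.tril(K) + np.tril(K, -1).T
    return K / m


def grm_from_genotypes(X, alpha: float = 0.0, freqs=None,
                       sample_ids=None) -> GRM:
    """Frequency-weighted genotype GRM; ``p_k`` defaults to column means.

    Monomorphic columns are dropped with a warning.
    """
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    X = np.asarray(X)
    p = X.mean(axis=0).astype(float) if freqs is None else np.asarray(freqs, float)
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"dropping {int((~poly).sum())} monomorphic columns", stacklevel=2
        )
        X, p = X[:, poly], p[poly]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic markers")
    if sample_ids is None:
        sample_ids = np.arange(X.shape[0])
    dtype = np.float32 if X.shape[1] > 20000 else np.float64
    K = _weighted_crossproduct(X, p, alpha, dtype=dtype)
    return GRM(K, sample_ids, "genotype", alpha=alpha, n_markers=X.shape[1])


def hamming_grm(X, sample_ids=None) -> GRM:
    """Normalized Hamming distances: (1/M) sum_k x_ik XOR x_jk."""
    X = np.asarray(X, float)
    n, m = X.shape
    if m == 0:
        raise ValueError("no markers")
    K = (X @ (1.0 - X).T + (1.0 - X) @ X.T) / m
    if sample_ids is None:
        sample_ids = np.arange(n)
    return GRM(K, sample_ids, "hamming", n_markers=m)


def exact_arg_grm(arg: ARG, mu: float, approximation: str = "exact") -> GRM:
    """ARG-GRM from pairwise TMRCAs over breakpoint intervals (alpha = 0).

    ``exact`` accumulates span x (1 - exp(-2 mu t_ij)); ``linear`` uses the
    small-2-mu-t expansion span x 2 mu t_ij.  The diagonal is zero.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if approximation not in ("exact", "linear"):
        raise ValueError("approximation must be 'exact' or 'linear'")
    ts = arg.to_tree_sequence()
    n = ts.num_samples
    K = np.zeros((n, n))
    for tree in ts.trees():
        span = tree.interval.right - tree.interval.left
        T = tree_tmrca_matrix(tree, n)
        if approximation == "exact":
            K += span * -np.expm1(-2.0 * mu * T)
        else:
            K += span * 2.0 * mu * T
    np.fill_diagonal(K, 0.0)
    return GRM(K, np.arange(n), "exact_arg", mu=mu)


def _stream_genotypes(ts, chunk):
    """Yield (int8 genotype chunk of shape n x m_chunk, frequencies)."""
    nm = ts.num_sites * ts.num_samples
    if nm * 4 <= 2 ** 31:  # materialize when comfortably small
        G = ts.genotype_matrix()
        for lo in range(0, G.shape[0], chunk):
            blk = G[lo : lo + chunk].T
            yield blk, blk.mean(axis=0)
        return
    buf = np.empty((chunk, ts.num_samples), dtype=np.int8)
    k = 0
    for var in ts.variants():
        buf[k] = var.genotypes
        k += 1
        if k == chunk:
            blk = buf.T.copy()
            yield blk, blk.mean(axis=0)
            k = 0
    if k:
        blk = buf[:k].T.copy()
        yield blk, blk.mean(axis=0)


def monte_carlo_arg_grm(
    arg: ARG,
    mu: float = MC_MU_DEFAULT,
    alpha: float = 0.0,
    seed: int = 0,
    maf_bins=None,
    chunk: int = 4096,
):
    """Monte Carlo ARG-GRM: sample mutations at rate ``mu``, drop them into
    genotypes and apply the genotype estimator.

    ``maf_bins`` (sequence of (lo, hi] MAF limits) partitions the sampled
    mutation columns before the estimator and returns one GRM per bin.
    Frequencies are carrier fractions among the N samples.
    """
    pos, nodes, times, _ = sample_mutation_events(arg, mu, seed)
    if len(pos) == 0:
        raise ValueError(
            "no mutations sampled; increase mu (the Monte Carlo ARG-GRM "
            "needs a high sampling rate)"
        )
    mts = mutations_to_tree_sequence(arg, pos, nodes, times)
    n = mts.num_samples
    if maf_bins is None:
        K = np.zeros((n, n))
        m_tot = 0
        for blk, p in _stream_genotypes(mts, chunk):
            poly = (p > 0) & (p < 1)
            blk, p = blk[:, poly], p[poly]
            if blk.shape[1] == 0:
                continue
            K += _weighted_crossproduct(blk, p, alpha) * blk.shape[1]
            m_tot += blk.shape[1]
        return GRM(K / m_tot, np.arange(n), "monte_carlo", alpha=alpha,
                   mu=mu, n_markers=m_tot)
    bins = list(maf_bins)
    Ks = [np.zeros((n, n)) for _ in bins]
    ms = [0 for _ in bins]
    for blk, p in _stream_genotypes(mts, chunk):
        maf = np.minimum(p, 1.0 - p)
        for b, (lo, hi) in enumerate(bins):
            sel = (maf > lo) & (maf <= hi) & (p > 0) & (p < 1)
            if not sel.any():
                continue
            Ks[b] += _weighted_crossproduct(blk[:, sel], p[sel], alpha) * int(sel.sum())
            ms[b] += int(sel.sum())
    out = []
    for b, (lo, hi) in enumerate(bins):
        if ms[b] == 0:
            continue
        out.append(
            GRM(Ks[b] / ms[b], np.arange(n), "monte_carlo", alpha=alpha,
                mu=mu, n_markers=ms[b], maf_bin=(lo, hi))
        )
    return out


def maf_bins_from_edges(edges=DEFAULT_MAF_BIN_EDGES):
    return [(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]


# ------------------------------------------------------- GCTA-style output


def write_gcta_grm(grm: GRM, prefix: str):
    """Write GCTA binary GRM triplet (.grm.bin / .grm.N.bin / .grm.id)."""
    n = grm.matrix.shape[0]
    tri = grm.matrix[np.tril_indices(n)]
    tri.astype("<f4").tofile(f"{prefix}.grm.bin")
    m = float(grm.n_markers or 1)
    np.full(tri.shape, m, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in grm.sample_ids:
            fh.write(f"FAM\t{s}\n")


def read_gcta_grm(prefix: str) -> GRM:
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id")]
    n = len(ids)
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    K = np.zeros((n, n))
    K[np.tril_indices(n)] = tri
    K = K + np.tril(K, -1).T
    nbin = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    return GRM(K, np.array(ids), "genotype", n_markers=int(nbin[0]) if nbin.size else None)


def write_grm_tsv(grm: GRM, path):
    np.savetxt(path, grm.matrix, delimiter="\t")
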