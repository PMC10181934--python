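"""Genealogy-wide association and variance-component analysis.

Variants are either genotyped markers or branches of an ARG (sampled at a
mutation rate mu, or enumerated exhaustively).  Association uses linear
regression or a mixed linear model: variance components are estimated by
average-information REML with boundary projection, the phenotype and each
variant are whitened by the fitted covariance, and a per-variant t-test is
run in the whitened space — so an identity GRM reduces the mixed model
exactly to ordinary least squares.

Heritability estimates come from (possibly multi-component) REML after
scaling every GRM to unit mean diagonal; cvBLUP gives leave-one-out
polygenic predictions through the kriging cross-validation identity; and
genome-wide significance thresholds are established by resampling random
phenotypes and taking a percentile of the per-scan minimum p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .arg import ARG
from .grm import GRM

MAC_MIN_DEFAULT = 5
ARG_TEST_MU_DEFAULT = 1e-5


@dataclass
class AssocResult:
    table: pd.DataFrame  # position, maf, mac, beta, se, p, test, provenance

    def __len__(self):
        return len(self.table)

    @property
    def p(self):
        return self.table["p"].to_numpy()

    def min_p(self):
        return float(self.table["p"].min()) if len(self.table) else 1.0


@dataclass
class VarianceComponents:
    sigma2_g: np.ndarray        # one per GRM component
    sigma2_e: float
    h2: float
    h2_se: float
    n_iter: int
    converged: bool
    log: list = field(default_factory=list)

    @property
    def total_genetic(self):
        return float(np.sum(self.sigma2_g))


# ------------------------------------------------------- variant sampling


def sample_test_variants(
    arg: ARG,
    mu: float = ARG_TEST_MU_DEFAULT,
    mac_min: int = MAC_MIN_DEFAULT,
    maf_range=None,
    seed: int = 0,
    exhaustive: bool = False,
):
    """Genotypes of ARG-derived variants, MAC/MAF filtered.

    ``exhaustive`` enumerates one variant per distinct (interval, branch)
    carrier set — equivalent to testing every possible mutation — instead
    of Poisson sampling at rate ``mu``.
    """
    from .arg import mutations_to_tree_sequence, sample_mutation_events

    n = arg.num_samples
    if exhaustive:
        # one variant per distinct branch carrier set, found by bitmask
        # accumulation over each marginal tree; identical carrier sets
        # recurring in other trees are kept once
        from .metrics import _tree_masks

        ts = arg.to_tree_sequence()
        full = (1 << n) - 1
        seen = {}
        for tree in ts.trees():
            mid = (tree.interval.left + tree.interval.right) / 2.0
            masks = _tree_masks(tree, n)
            for u, mask in masks.items():
                if mask == 0 or mask == full or tree.parent(u) == -1:
                    continue
                if mask not in seen:
                    seen[mask] = mid
        if not seen:
            warnings.warn("no variants enumerated")
            return np.zeros((n, 0), np.int8), _site_table([], [])
        order = sorted(seen, key=seen.get)
        nbytes = (n + 7) // 8
        G = np.stack(
            [
                np.unpackbits(
                    np.frombuffer(m.to_bytes(nbytes, "little"), np.uint8),
                    bitorder="little",
                )[:n]
                for m in order
            ],
            axis=1,
        ).astype(np.int8)
        positions = np.array([seen[m] for m in order])
    else:
        pos, nodes, times, _ = sample_mutation_events(arg, mu, seed)
        if len(pos) == 0:
            warnings.warn("no variants sampled at this mutation rate")
            return np.zeros((n, 0), np.int8), _site_table([], [])
        mts = mutations_to_tree_sequence(arg, pos, nodes, times)
        G = mts.genotype_matrix().T.astype(np.int8)
        positions = pos
    mac = np.minimum(G.sum(axis=0), n - G.sum(axis=0))
    keep = mac >= mac_min
    if maf_range is not None:
        maf = mac / n
        keep &= (maf >= maf_range[0]) & (maf <= maf_range[1])
    if not keep.any():
        warnings.warn("all variants removed by MAC/MAF filters")
    return G[:, keep], _site_table(positions[keep], G[:, keep].sum(axis=0) / n)


def _site_table(positions, freqs):
    positions = np.asarray(positions, float)
    freqs = np.asarray(freqs, float)
    return pd.DataFrame(
        {
            "position": positions,
            "frequency": freqs,
            "maf": np.minimum(freqs, 1.0 - freqs) if len(freqs) else freqs,
        }
    )


# --------------------------------------------------------------- AI-REML


def _scale_grms(grms):
    mats = []
    for g in grms:
        K = g.matrix if isinstance(g, GRM) else np.asarray(g, float)
        d = K.diagonal().mean()
        if d <= 0:
            raise ValueError("GRM has non-positive mean diagonal")
        mats.append(K / d)
    return mats


def reml_fit(y, grms, covariates=None, max_iter=100, tol=1e-6) -> VarianceComponents:
    """Average-information REML with EM fallback and boundary projection.

    Components are variances attached to each (unit-diagonal-scaled) GRM
    plus a residual; h2 = sum(sigma2_g) / (sum(sigma2_g) + sigma2_e), with
    a delta-method standard error from the inverse AI matrix.
    """
    y = np.asarray(y, float)
    n = len(y)
    Ks = _scale_grms(grms)
    for K in Ks:
        # cheap Cholesky probe first; eigenvalues only to name the failure
        # (ridge covers single-precision accumulation noise)
        try:
            np.linalg.cholesky(K + 1e-4 * np.eye(len(K)))
        except np.linalg.LinAlgError:
            w = np.linalg.eigvalsh(K)
            raise ValueError(
                f"GRM is not positive semidefinite (min eigenvalue {w.min():.3g})"
            )
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    vy = y.var()
    ncomp = len(Ks) + 1
    theta = np.full(ncomp, vy / ncomp)
    floor = vy * 1e-8
    log = []
    AI = np.eye(ncomp)
    converged = False
    for it in range(max_iter):
        V = theta[-1] * np.eye(n)
        for t, K in zip(theta[:-1], Ks):
            V += t * K
        try:
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            V += np.eye(n) * floor
            Vinv = np.linalg.inv(V)
        XtVinv = X.T @ Vinv
        P = Vinv - XtVinv.T @ np.linalg.solve(XtVinv @ X, XtVinv)
        Py = P @ y
        mats = Ks + [np.eye(n)]
        KPy = [K @ Py for K in mats]
        score = np.array(
            [
                -0.5 * (np.sum(P * K.T) - Py @ KPy[a])
                for a, K in enumerate(mats)
            ]
        )
        PKPy = [P @ v for v in KPy]
        AI = 0.5 * np.array(
            [[KPy[a] @ PKPy[b] for b in range(ncomp)] for a in range(ncomp)]
        )
        try:
            step = np.linalg.solve(AI + np.eye(ncomp) * 1e-10, score)
        except np.linalg.LinAlgError:
            step = None
        new = theta + step if step is not None else None
        if new is None or not np.all(np.isfinite(new)):
            # EM fallback
            new = theta + theta**2 * np.array(
                [(Py @ KPy[a] - np.sum(P * mats[a].T)) / n for a in range(ncomp)]
            )
        new = np.maximum(new, floor)
        delta = np.max(np.abs(new - theta)) / max(vy, 1e-12)
        log.append((it, theta.copy(), float(delta)))
        theta = new
        if delta < tol:
            converged = True
            break
    sg, se = theta[:-1], theta[-1]
    tot = sg.sum() + se
    h2 = float(sg.sum() / tot)
    # delta method: grad h2 wrt theta
    grad = np.empty(ncomp)
    grad[:-1] = se / tot**2
    grad[-1] = -sg.sum() / tot**2
    try:
        cov = np.linalg.inv(AI + np.eye(ncomp) * 1e-10)
        h2_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        h2_se = float("nan")
    return VarianceComponents(
        sigma2_g=sg, sigma2_e=float(se), h2=h2, h2_se=h2_se,
        n_iter=len(log), converged=converged, log=log,
    )


def estimate_h2(y, grms, covariates=None, method: str = "reml") -> VarianceComponents:
    """Heritability by multi-component REML (or Haseman-Elston regression).

    GRMs are scaled to unit mean diagonal so h2 is the fraction of
    phenotypic variance attached to the genetic components.
    """
    if isinstance(grms, (GRM, np.ndarray)):
        grms = [grms]
    if method == "reml":
        return reml_fit(y, grms, covariates=covariates)
    if method != "he":
        raise ValueError("method must be 'reml' or 'he'")
    # Haseman-Elston: regress off-diagonal phenotype products on GRM entries
    y = np.asarray(y, float)
    yc = y - y.mean()
    n = len(y)
    iu = np.triu_indices(n, 1)
    prod = np.outer(yc, yc)[iu]
    Ks = _scale_grms(grms)
    Z = np.column_stack([K[iu] for K in Ks])
    coef, *_ = np.linalg.lstsq(
        np.column_stack([np.ones(len(prod)), Z]), prod, rcond=None
    )
    sg = np.maximum(coef[1:], 0.0)
    vy = yc @ yc / n
    se = max(vy - sg.sum(), vy * 1e-8)
    h2 = float(sg.sum() / (sg.sum() + se))
    return VarianceComponents(
        sigma2_g=sg, sigma2_e=float(se), h2=h2, h2_se=float("nan"),
        n_iter=0, converged=True,
    )


# ----------------------------------------------------------- association


def _whitened_scan(y, G, covariates, L):
    """Per-variant t-tests of y on each column of G after whitening with
    the Cholesky factor L of the covariance (L=None -> identity)."""
    y = np.asarray(y, float)
    G = np.asarray(G, float)
    n = len(y)
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates")
    if L is not None:
        from scipy.linalg import solve_triangular

        y = solve_triangular(L, y, lower=True)
        X = solve_triangular(L, X, lower=True)
        G = solve_triangular(L, G, lower=True)
    # project covariates out of y and variants
    Q, _ = np.linalg.qr(X)
    yr = y - Q @ (Q.T @ y)
    Gr = G - Q @ (Q.T @ G)
    df = n - X.shape[1] - 1
    xx = np.einsum("ij,ij->j", Gr, Gr)
    xy = Gr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xy / xx
        rss = yr @ yr - beta * xy
        sigma2 = rss / df
        se = np.sqrt(sigma2 / xx)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    bad = ~np.isfinite(tstat)
    p[bad] = 1.0
    beta[bad] = 0.0
    se[bad] = np.inf
    return beta, se, p


def _result(G, positions, beta, se, p, test, provenance):
    G = np.asarray(G)
    n = G.shape[0]
    ac = G.sum(axis=0)
    mac = np.minimum(ac, n - ac)
    return AssocResult(
        pd.DataFrame(
            {
                "position": np.asarray(positions, float),
                "maf": mac / n,
                "mac": mac.astype(int),
                "beta": beta,
                "se": se,
                "p": p,
                "test": test,
                "provenance": provenance,
            }
        )
    )


def assoc_linear(y, G, covariates=None, positions=None,
                 provenance: str = "genotype") -> AssocResult:
    """Per-variant ordinary least squares with covariate projection."""
    G = np.asarray(G)
    if positions is None:
        positions = np.arange(G.shape[1])
    beta, se, p = _whitened_scan(y, G, covariates, None)
    return _result(G, positions, beta, se, p, "linear", provenance)


def assoc_mlma(y, G, grm, covariates=None, positions=None,
               provenance: str = "genotype", loco_labels=None) -> AssocResult:
    """Mixed-model association: REML variance components on the GRM, then
    GLS t-tests in the whitened space.

    ``loco_labels`` (chromosome label per variant, with the GRM supplied as
    a dict label -> leave-that-chromosome-out GRM) enables LOCO testing.
    """
    G = np.asarray(G)
    if positions is None:
        positions = np.arange(G.shape[1])
    if loco_labels is not None:
        if not isinstance(grm, dict):
            raise ValueError("LOCO needs one GRM per chromosome label")
        parts = []
        loco_labels = np.asarray(loco_labels)
        for lab in pd.unique(loco_labels):
            sel = loco_labels == lab
            res = assoc_mlma(
                y, G[:, sel], grm[lab], covariates=covariates,
                positions=np.asarray(positions)[sel], provenance=provenance,
            )
            parts.append(res.table)
        return AssocResult(pd.concat(parts, ignore_index=True))
    vc = reml_fit(y, [grm], covariates=covariates)
    K = _scale_grms([grm])[0]
    V = vc.total_genetic * K + vc.sigma2_e * np.eye(len(y))
    V /= V.diagonal().mean()  # scale-free: per-variant sigma re-estimated
    L = np.linalg.cholesky(V)
    beta, se, p = _whitened_scan(y, G, covariates, L)
    return _result(G, positions, beta, se, p, "mlma", provenance)


def genomic_control_lambda(p) -> float:
    """Median chi-square inflation factor of a p-value vector."""
    chi = stats.chi2.isf(np.asarray(p, float), df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


# ------------------------------------------------------------------ BLUP


def cvblup_predict(y, grm, covariates=None):
    """Leave-one-out BLUP predictions of each sample's genetic value.

    Variance components are estimated once by REML on the full data; the
    LOO prediction then follows the kriging cross-validation identity
    ``g_loo,i = y_i - (V^-1 r)_i / (V^-1)_ii`` applied to the
    covariate-adjusted phenotype r.  Returns (predictions, r2, components).
    """
    y = np.asarray(y, float)
    n = len(y)
    vc = reml_fit(y, [grm], covariates=covariates)
    K = _scale_grms([grm])[0]
    V = vc.total_genetic * K + vc.sigma2_e * np.eye(n)
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    r = y - X @ beta
    Vr = Vinv @ r
    pred = r - Vr / Vinv.diagonal()
    ss_tot = np.sum((r - r.mean()) ** 2)
    if ss_tot == 0 or np.std(pred) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(pred, r)[0, 1] ** 2)
    return pred, r2, vc


# ------------------------------------------------------------- thresholds


def resampling_threshold(test_fn, n_random_phenotypes: int = 100, seed: int = 0,
                         alpha: float = 0.05, n_samples: int | None = None):
    """Genome-wide significance threshold from random-phenotype scans.

    ``test_fn(y)`` runs the scan and returns a p-value vector; the
    threshold is the ``alpha`` percentile of the per-replicate minimum p,
    with an order-statistic 95% CI.  Returns (threshold, (lo, hi), minima).
    """
    if n_random_phenotypes < 20:
        raise ValueError("need at least 20 resampling replicates")
    if n_samples is None:
        raise ValueError("n_samples (phenotype length) is required")
    rng = np.random.default_rng(seed)
    minima = []
    for _ in range(n_random_phenotypes):
        y = rng.standard_normal(n_samples)
        p = np.asarray(test_fn(y), float)
        minima.append(p.min() if p.size else 1.0)
    minima = np.sort(minima)
    thr = float(np.quantile(minima, alpha))
    # order-statistic CI on the alpha quantile
    k = stats.binom.interval(0.95, len(minima), alpha)
    lo = minima[int(max(k[0] - 1, 0))]
    hi = minima[int(min(k[1], len(minima) - 1))]
    return thr, (float(lo), float(hi)), minima


# ------------------------------------------------------- power experiment


@dataclass
class PowerConfig:
    """Scaled-down single-causal-variant power experiment.

    One chromosome carries a single causal variant of effect ``beta`` (on
    the standardized genotype); the remaining chromosomes contribute a
    polygenic background at heritability ``h2_background``.  Power is the
    fraction of replicates whose scan of the focal chromosome dips below
    the significance threshold.
    """

    n_hap: int = 500
    chrom_length: float = 1.25e5
    n_background_chroms: int = 21
    causal_maf_target: float = 0.00025
    h2_background: float = 0.5
    methods: tuple = ("true_arg", "array")
    beta_grid: tuple = (0.0, 0.25, 0.5)
    n_reps: int = 25
    mac_min: int = 1  # a desk-scale rare causal variant is a singleton
    array_density: float = 240.0
    n_resampling: int = 40
    seed: int = 0


def _power_variants(dataset, method, mac_min, seed):
    from .simulate import subsample_array_sites

    if method == "true_arg":
        G, table = sample_test_variants(
            dataset.true_arg, mac_min=mac_min, exhaustive=True
        )
        return G, table["position"].to_numpy()
    if method == "sequence":
        G, positions = dataset.haplotypes, dataset.positions
    elif method == "array":
        sub = subsample_array_sites(
            dataset, target_density=min(240.0, dataset.num_sites /
                                        (dataset.sequence_length / 1e6)),
            seed=seed,
        )
        G, positions = sub.haplotypes, sub.positions
    else:
        raise ValueError(f"unknown method {method}")
    n = G.shape[0]
    mac = np.minimum(G.sum(axis=0), n - G.sum(axis=0))
    keep = mac >= mac_min
    return G[:, keep], positions[keep]


def power_experiment(config: PowerConfig = PowerConfig()):
    """Power per effect size per method, at matched resampling thresholds."""
    from .simulate import PhenotypeModel, simulate_coalescent, simulate_phenotype

    rng = np.random.default_rng(config.seed)
    # thresholds: one random-phenotype resampling per method on a reference
    # replicate's variant set
    ref_seed = int(rng.integers(1, 2**31 - 1))
    ref = simulate_coalescent(config.n_hap, config.chrom_length, seed=ref_seed)
    thresholds = {}
    for method in config.methods:
        G, _ = _power_variants(ref, method, config.mac_min, seed=ref_seed)
        thr, _, _ = resampling_threshold(
            lambda y, G=G: assoc_linear(y, G).p,
            n_random_phenotypes=config.n_resampling,
            seed=int(rng.integers(1, 2**31 - 1)),
            n_samples=config.n_hap,
        )
        thresholds[method] = thr
    power = {m: np.zeros(len(config.beta_grid)) for m in config.methods}
    for rep in range(config.n_reps):
        focal = simulate_coalescent(
            config.n_hap, config.chrom_length, seed=int(rng.integers(1, 2**31 - 1))
        )
        maf = focal.maf()
        causal = int(np.argmin(np.abs(maf - config.causal_maf_target)))
        x = focal.haplotypes[:, causal].astype(float)
        x = (x - x.mean()) / max(x.std(), 1e-12)
        bg = np.zeros(config.n_hap)
        if config.n_background_chroms > 0 and config.h2_background > 0:
            bgsim = simulate_coalescent(
                config.n_hap,
                config.chrom_length * config.n_background_chroms,
                seed=int(rng.integers(1, 2**31 - 1)),
            )
            bg, _, _ = simulate_phenotype(
                bgsim.haplotypes,
                PhenotypeModel(
                    h2=1.0, alpha=0.0,
                    causal_sites=tuple(range(bgsim.num_sites)),
                    seed=int(rng.integers(1, 2**31 - 1)),
                ),
            )
            bg = (bg - bg.mean()) / max(bg.std(), 1e-12)
            bg *= np.sqrt(config.h2_background)
        noise = rng.standard_normal(config.n_hap)
        noise /= max(noise.std(), 1e-12)
        noise *= np.sqrt(max(1.0 - config.h2_background, 1e-12))
        variant_sets = {
            m: _power_variants(focal, m, config.mac_min, seed=rep)
            for m in config.methods
        }
        for bi, beta in enumerate(config.beta_grid):
            y = beta * x + bg + noise
            for m in config.methods:
                G, _ = variant_sets[m]
                if G.shape[1] == 0:
                    continue
                res = assoc_linear(y, G)
                if res.min_p() < thresholds[m]:
                    power[m][bi] += 1.0
    for m in config.methods:
        power[m] /= config.n_reps
    return {"power": power, "thresholds": thresholds,
            "beta_grid": list(config.beta_grid)}
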