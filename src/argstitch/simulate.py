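"""Synthetic data generation: coalescent datasets with known true ARGs,
array-like site ascertainment, genotyping error and polygenic phenotypes.

Defaults follow the standard configuration used throughout the package's
experiments: mutation rate mu = 1.65e-8 and recombination rate rho = 1.2e-8
per base pair per generation, under a constant demography of 15,000 diploid
individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import msprime
import numpy as np

from .arg import ARG
from .demography import CONSTANT_15K, DemographicModel, GeneticMap

logger = logging.getLogger(__name__)

MU_DEFAULT = 1.65e-8
RHO_DEFAULT = 1.2e-8

#: 50-bin MAF spectrum emulating genotyping-array ascertainment: arrays are
#: depleted for rare variants and roughly flat across common MAF.  This is a
#: synthetic stand-in spectrum, not an empirical array product spectrum.
_edges = np.linspace(0.0, 0.5, 51)
_mids = (_edges[:-1] + _edges[1:]) / 2.0
DEFAULT_ARRAY_SPECTRUM = _mids ** 0.25
DEFAULT_ARRAY_SPECTRUM /= DEFAULT_ARRAY_SPECTRUM.sum()

#: Array marker density (sites per Mb) emulating a biobank SNP array.
DEFAULT_ARRAY_DENSITY = 240.0

#: Edges of the 50 evenly spaced MAF bins used for array ascertainment.
MAF_BIN_EDGES_50 = _edges


@dataclass
class SimulatedDataset:
    """A coalescent simulation with its ground-truth ARG.

    ``haplotypes`` is the N x M binary matrix of haploid genotypes;
    ``positions`` are strictly increasing physical positions (bp, possibly
    fractional under the continuous-genome model); ``frequencies`` are
    derived-allele fractions (column means).
    """

    true_arg: ARG
    haplotypes: np.ndarray
    positions: np.ndarray
    frequencies: np.ndarray
    genetic_map: GeneticMap
    demography: DemographicModel
    seed: int

    def __post_init__(self):
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("haplotype columns must match positions")

    @property
    def num_samples(self):
        return self.haplotypes.shape[0]

    @property
    def num_sites(self):
        return self.haplotypes.shape[1]

    @property
    def sequence_length(self):
        return self.true_arg.sequence_length

    def maf(self):
        return np.minimum(self.frequencies, 1.0 - self.frequencies)

    def subset_sites(self, idx) -> "SimulatedDataset":
        idx = np.sort(np.asarray(idx, int))
        return SimulatedDataset(
            true_arg=self.true_arg,
            haplotypes=self.haplotypes[:, idx],
            positions=self.positions[idx],
            frequencies=self.frequencies[idx],
            genetic_map=self.genetic_map,
            demography=self.demography,
            seed=self.seed,
        )


@dataclass(frozen=True)
class PhenotypeModel:
    """Polygenic architecture: Var(beta_k) = (p_k (1 - p_k))^alpha.

    ``h2`` is enforced as the *realized* variance ratio Var(g)/Var(y) by
    post-hoc rescaling of the environmental noise, so parameter-recovery
    experiments have a sharp target.
    """

    h2: float
    alpha: float
    causal_sites: tuple
    seed: int

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.h2 > 0 and len(self.causal_sites) == 0:
            raise ValueError("h2 > 0 requires a nonempty causal site set")
        object.__setattr__(self, "causal_sites", tuple(int(c) for c in self.causal_sites))


def _msprime_demography(model: DemographicModel) -> msprime.Demography:
    dem = msprime.Demography()
    dem.add_population(name="pop0", initial_size=model.sizes[0])
    for start, ne in model.epochs[1:]:
        dem.add_population_parameters_change(time=start, initial_size=ne)
    return dem


def simulate_coalescent(
    n_hap: int,
    length_bp: float,
    mu: float = MU_DEFAULT,
    rho: float = RHO_DEFAULT,
    demography: DemographicModel = CONSTANT_15K,
    seed: int = 1,
) -> SimulatedDataset:
    """Simulate haploid sequence data plus its ground-truth ARG.

    Haploid sample lineages evolve on the diploid time scale (a pair
    coalesces at rate 1/(2 Ne)), mutations follow the infinite-sites binary
    model so each variant is the carrier set of one ARG branch.
    """
    if n_hap < 2:
        raise ValueError("need at least two haploid samples")
    if mu <= 0 or rho <= 0:
        raise ValueError("mu and rho must be positive")
    if not isinstance(demography, DemographicModel):
        raise ValueError("demography must be a DemographicModel")
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n_hap, ploidy=1)],
        ploidy=2,
        sequence_length=length_bp,
        recombination_rate=rho,
        demography=_msprime_demography(demography),
        random_seed=int(anc_seed),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=int(mut_seed),
    )
    G = mts.genotype_matrix().astype(np.int8)  # M x N
    positions = np.array([s.position for s in mts.sites()])
    arg = ARG.from_tree_sequence(mts)
    return SimulatedDataset(
        true_arg=arg,
        haplotypes=G.T,
        positions=positions,
        frequencies=G.mean(axis=1),
        genetic_map=GeneticMap.constant(rho, length_bp),
        demography=demography,
        seed=seed,
    )


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``total`` across bins proportionally (largest remainder)."""
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        raise ValueError("spectrum has no mass")
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    rem = total - counts.sum()
    if rem > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:rem]] += 1
    return counts


def subsample_array_sites(
    dataset: SimulatedDataset,
    target_density: float = DEFAULT_ARRAY_DENSITY,
    spectrum: np.ndarray | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Ascertain an array-like site subset matching a target density and
    50-bin MAF spectrum.

    Per-bin quotas use largest-remainder apportionment; within a bin, sites
    are drawn uniformly at random.  Bins with fewer sites than their quota
    contribute what exists (with a warning logged).
    """
    if spectrum is None:
        spectrum = DEFAULT_ARRAY_SPECTRUM
    spectrum = np.asarray(spectrum, float)
    if spectrum.size == 0 or spectrum.sum() <= 0:
        raise ValueError("spectrum must be a nonempty histogram with mass")
    length_mb = dataset.sequence_length / 1e6
    n_target = int(round(target_density * length_mb))
    if n_target > dataset.num_sites:
        raise ValueError(
            f"target density {target_density}/Mb exceeds available "
            f"{dataset.num_sites / length_mb:.1f}/Mb"
        )
    edges = np.linspace(0.0, 0.5, spectrum.size + 1)
    maf = dataset.maf()
    bins = np.clip(np.searchsorted(edges, maf, side="right") - 1, 0, spectrum.size - 1)
    capacity = np.bincount(bins, minlength=spectrum.size)
    rng = np.random.default_rng(seed)
    # Apportion by largest remainder; shortfall in exhausted bins is
    # redistributed over the remaining positive-weight bins, so full-density
    # requests return every site while degenerate spectra stay in their bin.
    take = np.zeros(spectrum.size, dtype=int)
    remaining = n_target
    warned = False
    while remaining > 0:
        open_bins = (spectrum > 0) & (take < capacity)
        if not open_bins.any():
            break
        quota = np.zeros(spectrum.size, dtype=int)
        quota[open_bins] = _largest_remainder(remaining, spectrum[open_bins])
        grant = np.minimum(quota, capacity - take)
        if np.any(quota > grant) and not warned:
            short = np.flatnonzero(quota > grant)
            logger.warning(
                "MAF bins %s have fewer sites than their spectrum quota; "
                "redistributing", short.tolist(),
            )
            warned = True
        take += grant
        remaining -= int(grant.sum())
        if grant.sum() == 0:
            break
    chosen = [
        rng.choice(np.flatnonzero(bins == b), size=k, replace=False)
        for b, k in enumerate(take)
        if k > 0
    ]
    idx = np.sort(np.concatenate(chosen)) if chosen else np.empty(0, int)
    return dataset.subset_sites(idx)


def inject_genotyping_error(haplotypes: np.ndarray, p: float, seed: int) -> np.ndarray:
    """Flip each haploid genotype independently with probability ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("flip probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flips = rng.random(haplotypes.shape) < p
    return np.where(flips, 1 - haplotypes, haplotypes).astype(haplotypes.dtype)


def simulate_phenotype(haplotypes: np.ndarray, model: PhenotypeModel):
    """Simulate a quantitative trait under the alpha architecture.

    Returns ``(y, g, beta)``: the phenotype, the genetic values
    ``g_i = sum_k beta_k x_ik`` and the full-length effect vector (zeros at
    non-causal sites).  The environmental noise is centred, orthogonalized
    against g and rescaled so the realized Var(g)/Var(y) equals ``h2``
    exactly.
    """
    X = np.asarray(haplotypes)
    n, m = X.shape
    causal = np.asarray(model.causal_sites, int)
    if np.any(causal >= m) or np.any(causal < 0):
        raise ValueError("causal site index outside matrix")
    rng = np.random.default_rng(model.seed)
    beta = np.zeros(m)
    if causal.size:
        p = X[:, causal].mean(axis=0)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("monomorphic causal sites are not allowed")
        sd = (p * (1.0 - p)) ** (model.alpha / 2.0)
        beta[causal] = rng.normal(0.0, 1.0, size=causal.size) * sd
    # single-precision product (the exact-h2 rescaling below is in float64
    # on the realized g, so the variance ratio stays exact)
    g = (X.astype(np.float32) @ beta.astype(np.float32)).astype(np.float64)
    if model.h2 >= 1.0:
        return g.copy(), g, beta
    gc = g - g.mean()
    var_g = gc @ gc / n
    e = rng.normal(0.0, 1.0, size=n)
    e = e - e.mean()
    if var_g > 0:
        e = e - (e @ gc) / (gc @ gc) * gc  # exact sample-orthogonality to g
    var_e = e @ e / n
    if model.h2 == 0.0 or var_g == 0.0:
        y = e / np.sqrt(var_e)
        return y, g, beta
    e = e * np.sqrt(var_g * (1.0 - model.h2) / model.h2 / var_e)
    y = g + e
    return y, g, beta
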