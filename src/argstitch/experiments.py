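"""Replicated simulation experiments built from the package's pieces.

These are the experiment designs used for parameter-recovery and
inference-quality evaluation: heritability designs keep a fixed ratio of
5e-3 Mb of sequence per haploid individual, and the inference-quality sweep
uses 64 haploids on 1 Mb of array-density data.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from .arg import ARG
from .assoc import estimate_h2
from .demography import CONSTANT_15K
from .grm import (
    DEFAULT_MAF_BIN_EDGES,
    grm_from_genotypes,
    maf_bins_from_edges,
    monte_carlo_arg_grm,
)
from .metrics import arg_total_variation, tmrca_rmse
from .simulate import PhenotypeModel, simulate_coalescent, simulate_phenotype


@dataclass
class HeritabilityResult:
    h2_arg: np.ndarray
    h2_seq: np.ndarray

    def summary(self):
        def msem(x):
            return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(len(x)))

        return {
            "arg_grm": msem(self.h2_arg),
            "seq_grm": msem(self.h2_seq),
        }


def heritability_experiment(
    n_reps: int = 20,
    n_hap: int = 1000,
    length_bp: float = 5e6,
    h2: float = 0.8,
    alpha: float = -0.5,
    mc_mu: float = 1.65e-7,
    maf_bin_edges=DEFAULT_MAF_BIN_EDGES,
    seed: int = 1,
) -> HeritabilityResult:
    """Recover h2 with the true-ARG Monte Carlo ARG-GRM and with the
    sequence-variant genotype GRM.

    Each replicate simulates a coalescent dataset (mu = 1.65e-8,
    rho = 1.2e-8, constant 15,000-diploid demography by default), draws a
    fully polygenic phenotype with Var(beta_k) = (p_k(1-p_k))^alpha at
    realized heritability ``h2``, and estimates h2 twice by REML:

    * MAF-stratified Monte Carlo ARG-GRM from the ground-truth ARG at
      sampling rate ``mc_mu`` (standard within-bin weighting, alpha = -1);
    * single-component genotype GRM from all sequence variants at the
      generative ``alpha``.
    """
    rng = np.random.default_rng(seed)
    bins = maf_bins_from_edges(maf_bin_edges)
    h2_arg, h2_seq = [], []
    for _ in range(n_reps):
        ds = simulate_coalescent(
            n_hap, length_bp, seed=int(rng.integers(1, 2**31 - 1))
        )
        y, _, _ = simulate_phenotype(
            ds.haplotypes,
            PhenotypeModel(
                h2=h2, alpha=alpha,
                causal_sites=tuple(range(ds.num_sites)),
                seed=int(rng.integers(1, 2**31 - 1)),
            ),
        )
        grms = monte_carlo_arg_grm(
            ds.true_arg, mu=mc_mu, alpha=-1.0,
            seed=int(rng.integers(1, 2**31 - 1)), maf_bins=bins,
        )
        h2_arg.append(estimate_h2(y, grms).h2)
        seq_grm = grm_from_genotypes(ds.haplotypes, alpha=alpha)
        h2_seq.append(estimate_h2(y, [seq_grm]).h2)
    return HeritabilityResult(np.array(h2_arg), np.array(h2_seq))


def random_topology_baseline(template: ARG, demography=CONSTANT_15K,
                             seed: int = 0) -> ARG:
    """Random-topology ARG with coalescent times and a matched marginal
    tree count: independent single-locus coalescent trees tiled over the
    template's breakpoint intervals."""
    bps = template.breakpoints()
    n = template.num_samples
    dem = msprime.Demography()
    dem.add_population(initial_size=demography.sizes[0])
    for start, ne in demography.epochs[1:]:
        dem.add_population_parameters_change(time=start, initial_size=ne)
    reps = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n, ploidy=1)],
        ploidy=2, demography=dem,
        num_replicates=len(bps) - 1, random_seed=max(int(seed), 1),
    )
    pieces = []
    for (a, b), ts in zip(zip(bps[:-1], bps[1:]), reps):
        sub = ARG.from_tree_sequence(ts)
        tree = sub.marginal_tree(0.0)
        relabeled = _label_tree(tree, sub)
        pieces.append((a, b, relabeled))
    return ARG.from_marginal_trees(pieces, template.sequence_length)


def _label_tree(tree, arg):
    ren = {s: arg.sample_label[s] for s in arg.samples}

    def r(u):
        return ren[u] if u in ren else ("n", u)

    parent = {r(c): r(p) for c, p in tree.parent.items()}
    time = {r(u): t for u, t in tree.time.items()}
    return type(tree)(parent, time, [r(u) for u in tree.leaves])


def star_baseline(n: int, sequence_length: float, tmrca: float) -> ARG:
    """Star genealogy: every pair coalesces at one fixed time (the
    topology-free baseline for pairwise-time accuracy)."""
    from .arg import MarginalTree

    parent = {i: "root" for i in range(n)}
    time = {i: 0.0 for i in range(n)}
    time["root"] = tmrca
    tree = MarginalTree(parent, time, list(range(n)))
    return ARG.from_marginal_trees([(0.0, sequence_length, tree)], sequence_length)


@dataclass
class InferenceQualityResult:
    """Accuracy against the genealogy-valued null: a random-topology ARG
    with coalescent times and matched marginal-tree count."""

    densities: list
    tv_needle: np.ndarray      # seeds x densities
    tv_baseline: np.ndarray
    rmse_needle: np.ndarray
    rmse_baseline: np.ndarray


def inference_quality_experiment(
    n_hap: int = 64,
    length_bp: float = 1e6,
    densities=(60.0, 120.0, 240.0),
    n_seeds: int = 5,
    seed: int = 7,
) -> InferenceQualityResult:
    """ARG inference accuracy versus a random-topology baseline, across a
    marker-density grid on array-ascertained data."""
    from .needle import NeedleConfig, build_arg_needle
    from .simulate import subsample_array_sites

    rng = np.random.default_rng(seed)
    densities = list(densities)
    shape = (n_seeds, len(densities))
    tv_n, tv_b = np.zeros(shape), np.zeros(shape)
    rm_n, rm_b = np.zeros(shape), np.zeros(shape)
    for s in range(n_seeds):
        ds = simulate_coalescent(
            n_hap, length_bp, seed=int(rng.integers(1, 2**31 - 1))
        )
        for d, dens in enumerate(densities):
            sub = subsample_array_sites(
                ds, target_density=dens, seed=int(rng.integers(1, 2**31 - 1))
            )
            cfg = NeedleConfig(seed=int(rng.integers(1, 2**31 - 1)))
            inferred = build_arg_needle(
                sub.haplotypes, sub.positions, sub.genetic_map, sub.demography,
                cfg, sequence_length=ds.sequence_length,
            )
            baseline = random_topology_baseline(
                inferred, ds.demography, seed=int(rng.integers(1, 2**31 - 1))
            )
            truth = ds.true_arg
            tv_n[s, d] = arg_total_variation(truth, inferred)
            tv_b[s, d] = arg_total_variation(truth, baseline)
            rm_n[s, d] = tmrca_rmse(truth, inferred, seed=s, log10=True)
            rm_b[s, d] = tmrca_rmse(truth, baseline, seed=s, log10=True)
    return InferenceQualityResult(densities, tv_n, tv_b, rm_n, rm_b)
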