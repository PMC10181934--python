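# argstitch

Genome-wide genealogy inference by sample threading, with ARG-based
relatedness and genealogy-wide association.

Every recombining genome carries a genealogy that changes along the
sequence — an ancestral recombination graph (ARG). If that graph can be
reconstructed from genotype data, each of its branches is a candidate
variant: the set of samples below the branch is exactly the carrier set of
any mutation that fell on it, whether or not that mutation was genotyped.
`argstitch` is for statistical geneticists who want to build ARGs from
phased array or sequencing haplotypes and then use them in complex-trait
analysis: heritability estimation with ARG-derived genomic relatedness
matrices (GRMs), leave-one-out polygenic prediction, and mixed-model
association of genealogy-derived variants.

## What it implements

**Inference.** The threading builder adds one haplotype at a time to a
growing ARG in three steps: (1) word-based genotype hashing shortlists the
K samples already in the graph most related to the new one, per genomic
region; (2) a discretized-time pairwise coalescent HMM decodes posterior
TMRCA between the new sample and each candidate along the genome; (3) the
per-site minimum posterior-mean candidate becomes a piecewise-constant
threading instruction — attach to sample *j* at height *t* over this
segment. An alternative builder decodes all pairs and applies per-site
UPGMA to the N x N TMRCA matrix, stitching trees at inter-site midpoints.
Both finish with node-time normalization: a monotone quantile map onto
single-locus coalescent node times under the input demography, which fixes
the bias of posterior-mean/minimum estimation without touching topology.

**Relatedness.** The frequency-weighted genotype GRM

    K_alpha(i,j) = (1/M) sum_k (x_ik - p_k)(x_jk - p_k) [p_k(1-p_k)]^alpha

and its ARG counterparts: the exact ARG-GRM (the expected pairwise Hamming
distance given the ARG, `sum over the genome of 1 - exp(-2 mu t_ij)`), and
the Monte Carlo ARG-GRM — mutations sampled uniformly on the ARG's area at
a high rate (default mu = 1.65e-7, where it saturates against the exact
form) pushed through the genotype estimator, optionally stratified by MAF.

**Association.** Variants sampled from (or exhaustively enumerated on) an
ARG are tested by OLS or by an infinitesimal mixed model (AI-REML variance
components, GLS t-tests in the whitened space; identical to OLS when the
GRM is the identity). Multi-component REML heritability, cvBLUP
leave-one-out prediction, and resampling-based genome-wide significance
thresholds round out the toolkit.

**Comparison metrics.** Span-weighted Robinson-Foulds with random polytomy
resolution; the ARG total-variation distance between the mutation-placement
distributions of two ARGs (polytomies need no resolution), optionally
stratified by allele frequency; Kendall-Colijn distances (lambda = 0, 0.02,
1); pairwise TMRCA RMSE; and heuristics to collapse or resolve polytomies.

**Synthetic data.** Coalescent simulation (msprime) with ground-truth ARGs
at mu = 1.65e-8, rho = 1.2e-8 per bp per generation; array-like site
ascertainment matching a target density and 50-bin MAF spectrum; haploid
genotype flip errors; polygenic phenotypes with Var(beta_k) =
(p_k(1-p_k))^alpha at exactly realized heritability.

## Worked example

```python
import argstitch as ag

# simulate 64 haploid genomes over 1 Mb with a known true ARG
ds = ag.simulate_coalescent(n_hap=64, length_bp=1e6, seed=42)
array = ag.subsample_array_sites(ds, target_density=240, seed=1)
print(f"sequence sites: {ds.num_sites}, array sites: {array.num_sites}")

# infer the ARG by threading, then score it against the truth
arg = ag.build_arg_needle(
    array.haplotypes, array.positions, array.genetic_map, array.demography,
    ag.NeedleConfig(seed=7), sequence_length=ds.sequence_length,
)
tv = ag.arg_total_variation(ds.true_arg, arg)
rf = ag.robinson_foulds_avg(ds.true_arg, arg, seed=0)
print(f"ARG total variation to truth: {tv:.3f}")
print(f"rescaled Robinson-Foulds to truth: {rf:.3f}")

# a polygenic trait at realized h2 = 0.8, and REML recovery through the
# Monte Carlo ARG-GRM of the *inferred* ARG
y, g, beta = ag.simulate_phenotype(
    ds.haplotypes,
    ag.PhenotypeModel(h2=0.8, alpha=-0.5,
                      causal_sites=tuple(range(ds.num_sites)), seed=3),
)
grm = ag.monte_carlo_arg_grm(arg, seed=5)
vc = ag.estimate_h2(y, [grm])
print(f"REML h2 from the inferred-ARG GRM: {vc.h2:.3f} (s.e. {vc.h2_se:.3f})")
```

Output:

```
sequence sites: 4999, array sites: 240
ARG total variation to truth: 0.818
rescaled Robinson-Foulds to truth: 0.869
REML h2 from the inferred-ARG GRM: 0.852 (s.e. 0.124)
```

Reading it: from 240 array markers the threaded ARG predicts unobserved
mutation patterns much better than a random genealogy would (total
variation 0.82 against about 0.93 for a random-topology baseline with
coalescent times; both distances shrink as marker density grows), and a GRM
built purely from the inferred genealogy recovers the simulated
heritability of 0.8 within one standard error at this small sample size.

A command-line interface mirrors the library for shell pipelines —
`argstitch simulate | build | clust | normalize | compare | grm | assoc |
threshold | h2 | predict | power`; inputs are phased VCF, a 3-column genetic map
(chr, cM, bp) and a 2-column demography file (generation, diploid Ne);
ARGs travel as tskit tree-sequence files and GRMs in the GCTA binary
triplet format.

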