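# Methods

`argstitch` infers genome-wide genealogies — ancestral recombination graphs
(ARGs) — from phased haplotypes, and uses them for complex-trait analysis:
ARG-derived genomic relatedness matrices (GRMs), REML heritability,
leave-one-out BLUP prediction, and genealogy-wide mixed-model association.
This note records the models, the numerical choices, and what the synthetic
data used in the tests does and does not establish.

## The ARG container and threading

An ARG is a node/edge graph: nodes carry times in generations (samples at
time 0), edges carry half-open genomic spans `[left, right)` in base pairs.
At every position the edges covering that position induce a rooted marginal
coalescent tree over the samples. Coordinates are 0-based half-open
throughout; genetic-map positions are interpolated piecewise-linearly in bp.

New samples join by *threading*: a piecewise-constant instruction gives, per
genomic segment, an existing sample and an attachment height. Over each
segment the new lineage is spliced into the path from that sample toward the
marginal root at the stated height; a height above the current root creates
a new root. Implementation detail that matters for correctness: threading is
a single left-to-right sweep that maintains the marginal parent map
incrementally and defers all edge splits to the end of the instruction
(new edges never overlap later segments), which makes one threading call
linear in the number of edges rather than quadratic. If an attachment height
collides with an existing node time on the target path, it is nudged up by
2^-20 generations so node times stay strictly ordered.

Conversion to and from the tskit tree-sequence format is lossless for
topology, times, spans and mutations; tskit is also the engine used to
decode genotypes of sampled mutations at C speed. Mutation sampling itself
is area-uniform: the count is Poisson(mu x total edge area), branch and
position are chosen proportionally to edge area, and the mutation time is
uniform on the edge's time extent. Because positions are continuous, a
sampled-mutation dataset never has two hits at one position; expectations of
mismatch counts therefore follow the linear form `sum 2 mu t` rather than
the saturating `sum (1 - exp(-2 mu t))` (both are implemented for the exact
ARG-GRM; they differ by <1% whenever `2 mu t < 0.01`).

## Threading inference

Building an ARG from N haplotypes repeats three steps per sample, in a
seeded random order:

1. **Hashing.** Haplotypes are cut into non-overlapping words of S sites
   (default S = 16); hash tables map (word index, word value) to carrying
   samples. Per genomic region of genetic length L (default 0.5 cM for
   array data, 0.1 cM for sequencing), indexed samples are ranked by the
   longest run of matching words overlapping the region, tolerating up to
   T = 1 mismatched words inside the run; the score counts matching words
   only, so boundary mismatches never help. The top K = 64 per region are
   kept. Ties break by earlier threading order, then lower sample id. The
   brute-force window enumeration is the normative definition of the score;
   the hash tables only supply the per-word match indicators. An optional
   word-size schedule lets S grow as threading proceeds (the index is
   rebuilt when S changes), trading hashing cost for resolution in large
   runs; the default keeps S constant.

2. **Pairwise TMRCA decoding.** A discretized-time pairwise coalescent HMM
   (D = 30 states by default) returns posterior-mean and MAP TMRCA per site
   for the new sample against each candidate, decoded with 2.0 cM of
   burn-in context on either side of each region (1.0 cM intended for
   large-data runs). Decoding is batched across candidates — one
   forward-backward sweep per threading step.

3. **Threading instruction.** At each site the candidate with the minimum
   posterior-mean TMRCA wins (ties to the lower candidate rank). Sites are
   cut into maximal runs where the chosen candidate and its MAP state are
   both constant; each run becomes one segment whose height is the mean
   posterior mean over the run and whose start is the midpoint between the
   bounding sites.

The alternative builder decodes all N(N-1)/2 pairs and applies UPGMA to the
per-site posterior-mean TMRCA matrix. Matrix entries are already times to
common ancestry, so clusters merge at the average pairwise TMRCA (not half
of it) — this convention makes ultrametric inputs exactly recoverable, and
coalescent trees are ultrametric. Adjacent identical trees are merged into
single spans delimited by inter-site midpoints. A low-memory variant
re-decodes pairs per site chunk, trading runtime for an O(N M) footprint
while producing bit-identical trees. Merge ties take the lexicographically
smallest cluster pair (clusters identified by their smallest leaf); a merge
height that would not exceed a child's height (possible on noisy
non-ultrametric input) is lifted by 2^-20.

### The pairwise HMM is a simplified stand-in

The full sequentially-Markov decoder this step emulates conditions its
emissions on a conditional site-frequency spectrum computed from a reference
panel. This package deliberately replaces that machinery with a compact
model behind the same interface, so a faithful emission model can be dropped
in later:

- **Prior / states.** Interval boundaries sit at quantiles i/D of the
  pairwise coalescence-time distribution under the input demography
  (piecewise-constant diploid Ne; a haploid pair coalesces at rate
  1/(2 Ne)), so the prior over states is uniform by construction. The
  representative time of each interval is the conditional expected
  coalescence time, in closed form per constant-rate piece.
- **Transitions.** Between adjacent sites at genetic distance d Morgans the
  chain stays with probability exp(-2 t̄ d), where t̄ is the prior-mean
  TMRCA, and otherwise redraws from the prior. The state-independent rate is
  what makes the prior exactly stationary; the price is that transitions do
  not condition on the current TMRCA.
- **Emissions.** In array mode, P(mismatch | t, p) =
  2p(1-p) (1 - exp(-t / a(p))), where a(p) is the expected age of an allele
  at population frequency p (the classical −4N p ln p/(1−p), expressed
  through t̄): older, commoner alleles are likelier to separate deeply
  coalescing pairs, and the mismatch probability saturates at the site's
  heterozygosity. In sequence mode P(mismatch | t) = 1 - exp(-2 mu ℓ t)
  with ℓ the mean inter-site spacing, treating each variant site as
  representative of its surrounding base pairs. Missing genotypes emit 1 in
  every state.
- **Numerics.** Scaled forward-backward (no log-space needed; scaling keeps
  10^5-site inputs finite), O(D) per site thanks to the switch-to-prior
  kernel, exact agreement with path enumeration on small instances.

An *oracle mode* reads exact pairwise TMRCAs off a ground-truth ARG,
letting every downstream step (instruction assembly, threading, stitching,
metrics) be tested in isolation from decoding error.

## Normalization

Posterior-mean estimation and minimum-over-candidates selection bias node
times. Normalization applies a monotone map taking the inferred ARG's
node-time distribution onto node times pooled from 1,000 independent
single-locus coalescent trees simulated under the input demography. Ranks
are preserved (stable for ties, strictly increasing over distinct inputs),
so no marginal topology changes.

One design choice was genuinely open: whether an inferred node enters the
matched distribution once, or weighted by the genomic span it covers. This
package weights by span. The reference sample is "node times of a marginal
tree at a random position"; a threading ARG's *node set* over-represents
time strata in proportion to how many recombination-induced re-attachments
they accumulate, and matching unique nodes against per-tree references
measurably mis-calibrated pairwise times (log-scale TMRCA RMSE worse than a
topology-free baseline). Span weighting matches like with like and removed
the artifact.

## Comparison metrics

All ARG-level metrics work on the joint breakpoint refinement and weight
intervals by span; clades are bitmasks over the shared sample-label order.

- **Robinson-Foulds (rescaled)**: per interval, polytomies are randomly
  resolved (seeded), and the symmetric difference of nontrivial clade sets
  (sizes 2..N-1) is divided by the total nontrivial clades of both trees.
- **ARG total variation**: each ARG induces a probability distribution over
  (interval, clade) pairs — the distribution of where a uniformly sampled
  mutation would fall and whom it would hit; mass = branch length x span /
  total area. TV is half the L1 distance on the union of keys. Polytomies
  need no resolution; they just concentrate mass. The frequency-stratified
  variant restricts clades to a MAF bin by carrier fraction and renormalizes
  within the bin (a bin empty on both sides scores 0; empty on one side, 1).
- **Kendall-Colijn**: per leaf pair, the root-to-MRCA depth in edges
  (topology part) or in time (length part), plus pendant entries, blended
  by lambda (0 topology-only, 0.02 mixed, 1 length-aware); distance is the
  Euclidean norm of the vector difference, genome-averaged by span.
- **TMRCA RMSE**: over a seeded subsample of (pair, site) combinations;
  optionally on log10 times.
- **Polytomy heuristics**: collapse ranks the N-2 nonleaf branches of a
  binary tree by branch length divided by parent height and removes the
  smallest fraction f (ties: older parent, then node id); resolve replaces
  each polytomy by a seeded random caterpillar of zero-length edges;
  polytomy_fraction is the span-weighted mean of 1 - nonleaf/(N-2).

## GRMs and the alpha architecture

Phenotypes follow the frequency-weighted polygenic model
`g_i = sum_k beta_k x_ik`, `Var(beta_k) = (p_k (1 - p_k))^alpha`; the
noise is centred, sample-orthogonalized against g and rescaled, so the
realized Var(g)/Var(y) equals h2 exactly per replicate. Realized (rather
than expected) heritability gives recovery experiments a sharp target.

The genotype GRM is
`K_alpha(i,j) = (1/M) sum_k (x_ik - p_k)(x_jk - p_k) [p_k(1-p_k)]^alpha`,
with p_k the column mean unless supplied. Identities used as tests: the
double-centered Hamming matrix equals -2x the double-centered K_0; the
exact ARG-GRM (alpha = 0 only) is the expectation of the Hamming count
given the ARG, `sum over intervals of span x (1 - exp(-2 mu t_ij))`, with a
linear variant `span x 2 mu t_ij`. The Monte Carlo ARG-GRM samples
mutations at a high rate — 1.65e-7 per bp per generation by default, where
it saturates against the exact computation — and applies the genotype
estimator, optionally partitioned into MAF bins (default 7 log-spaced bins,
alpha = -1 within bins). Comparisons across GRM flavours are made after
double-centering, which removes the estimators' row/column-mean invariances.
Crossproducts accumulate float32 BLAS symmetric rank-k updates into float64;
the resulting GRMs can carry eigenvalues of about -1e-5, which the REML
PSD probe tolerates by a 1e-4 ridge.

## Variance components, association, prediction, thresholds

REML is average-information with an EM fallback, boundary projection at
1e-8 x Var(y), tolerance 1e-6, at most 100 iterations; every GRM is scaled
to unit mean diagonal first, so h2 = sum(sigma2_g) / (sum(sigma2_g) +
sigma2_e) regardless of alpha weighting, with a delta-method standard error
from the inverse AI matrix. A Haseman-Elston regression is available as a
fallback (far noisier at these sample sizes).

The mixed-model scan whitens the phenotype, covariates and each variant by
the Cholesky factor of the fitted covariance (normalized to unit mean
diagonal) and runs per-variant t-tests in the whitened space, re-estimating
the scalar residual variance per variant. With an identity GRM this is
*exactly* ordinary least squares, and under a polygenic background it keeps
the genomic-control lambda closer to 1 than OLS. This is an infinitesimal
mixed model; the large-cohort noninfinitesimal approximations used for
biobank-scale scans are out of scope. Variants with MAC < 5 are not tested
by default.

cvBLUP: variance components are estimated once on the full data; the
leave-one-out prediction of each sample's genetic value then follows the
kriging cross-validation identity `g_loo,i = y_i - (V^-1 r)_i / (V^-1)_ii`
on the covariate-adjusted phenotype r, verified against explicit refits.

Resampling significance thresholds scan random standard-normal phenotypes
and take the 5th percentile of the per-scan minimum p (family-wise alpha =
0.05), with an order-statistic 95% CI. ARG variants for association are
sampled at mu = 1e-5 by default, or enumerated exhaustively — one variant
per distinct branch carrier set, equivalent to testing all possible
mutations.

## Experiment designs and problem sizes

The replicated experiments keep the design ratio of 5e-3 Mb of sequence per
haploid individual for heritability work:

- **Heritability recovery** (the acceptance experiment): 20 replicates of
  N = 1,000 haploids over 5 Mb under the constant 15,000-diploid demography,
  mu = 1.65e-8, rho = 1.2e-8; fully polygenic phenotype, alpha = -0.5,
  realized h2 = 0.8. Estimators: MAF-stratified Monte Carlo ARG-GRM from
  the true ARG (the stratification stands in for not knowing alpha;
  within-bin alpha = -1) and the sequence-variant GRM at the generative
  alpha. Runs in roughly a quarter hour on one CPU.
- **Inference quality**: N = 64 haploids, 1 Mb, array-ascertained sites at
  {60, 120, 240} sites/Mb, 5 seeds. The baseline is the genealogy-valued
  null: independent random-topology coalescent trees tiled over the inferred
  ARG's breakpoints (matched marginal-tree count). Threading inference beats
  it on TV at every density and on log-TMRCA RMSE at array density, and TV
  falls monotonically with density.
- **Power**: a single causal variant on a focal chromosome plus a polygenic
  background (h2 = 0.5) from 21 chromosome-equivalents, L/N = 5.5e-3 Mb per
  individual, N = 500, 25 replicates, thresholds matched by resampling per
  variant set. At this scale the rare-causal condition maps to the rarest
  resolvable class (a singleton), the experiment's scan keeps MAC >= 1 so
  the causal branch stays testable, and scans use the linear test; the
  compared property is the ordering of genealogy-wide versus array-marker
  power.

## What the synthetic data does not show

The generator emulates neutral coalescent haplotypes under piecewise-
constant panmictic demography with uniform recombination, array-like
ascertainment via a 50-bin MAF spectrum, and symmetric per-genotype flip
errors. It does not emulate selection, population structure or relatedness,
gene conversion, mutation-rate heterogeneity, phasing or imputation error
structure, or real array ascertainment (the shipped 50-bin spectrum is a
synthetic stand-in, common-variant-enriched). Passing tests therefore show
correctness of the algorithms and calibration under the stated model, not
robustness to those real-data features. The shipped European-like bottleneck
demography is likewise a labelled generic stand-in, not a fitted model; all
demographies are user-overridable by file.

## Known limitations

- The pairwise decoder's emissions are heuristic (above); absolute TMRCA
  accuracy at sparse marker density leans on normalization.
- Exact ARG-GRMs are defined for alpha = 0 only; other alphas go through
  the Monte Carlo path.
- The mixed model is infinitesimal and dense (O(N^2) memory, O(N^3)
  factorizations); it is not a biobank-scale implementation.
- Case/control traits, conditional (COJO-style) analysis, LD-stratified
  GRMs and ARG-based imputation are out of scope.
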