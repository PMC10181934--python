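"""ARG normalization: quantile-match node times to the coalescent.

Inferred node times are biased by the pairwise posterior-mean estimator and
by taking minima over candidates.  Normalization replaces them with a
monotonically increasing transform that maps the ARG's empirical node-time
distribution onto node times sampled from single-locus coalescent trees
simulated under the input demography.  Ranks are preserved (stably for
ties), so every marginal tree's topology is unchanged.

Each internal node contributes to the ARG's node-time distribution with a
weight equal to the genomic span over which it appears in marginal trees,
which makes the matched distribution comparable to the reference (node
times of a marginal tree at a random position) rather than to the ARG's
node set, whose composition depends on how many recombinations each time
stratum accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from .arg import ARG
from .demography import DemographicModel


@dataclass(frozen=True)
class ReferenceQuantiles:
    """Pooled internal-node times from independent coalescent trees."""

    times: np.ndarray
    demography: DemographicModel
    sample_size: int
    n_trees: int
    seed: int

    def __post_init__(self):
        t = np.sort(np.asarray(self.times, float))
        if np.any(t < 0):
            raise ValueError("reference node times must be nonnegative")
        object.__setattr__(self, "times", t)


def reference_quantiles(
    demography: DemographicModel, sample_size: int, n_trees: int = 1000,
    seed: int = 1,
) -> ReferenceQuantiles:
    """Internal-node times of ``n_trees`` independent single-locus
    coalescent trees of ``sample_size`` haploid lineages."""
    if sample_size < 2:
        raise ValueError("need at least two samples")
    dem = msprime.Demography()
    dem.add_population(initial_size=demography.sizes[0])
    for start, ne in demography.epochs[1:]:
        dem.add_population_parameters_change(time=start, initial_size=ne)
    reps = msprime.sim_ancestry(
        samples=[msprime.SampleSet(sample_size, ploidy=1)],
        ploidy=2,
        demography=dem,
        num_replicates=n_trees,
        random_seed=max(int(seed), 1),
    )
    times = []
    for ts in reps:
        node_times = ts.tables.nodes.time
        times.append(node_times[node_times > 0])
    return ReferenceQuantiles(
        times=np.concatenate(times),
        demography=demography,
        sample_size=sample_size,
        n_trees=n_trees,
        seed=seed,
    )


def _monotone_quantile_map(observed: np.ndarray, reference: np.ndarray,
                           weights=None):
    """Map each observed value to the reference quantile of its (weighted)
    rank.

    Equal observed values share one output; distinct values keep a strictly
    increasing output (enforced by a cumulative-max sweep with a tiny step).
    """
    if weights is None:
        weights = np.ones_like(observed)
    uniq, inv = np.unique(observed, return_inverse=True)
    wsum = np.bincount(inv, weights=weights).astype(float)
    n = len(uniq)
    if n == 1:
        qs = np.array([0.5])
    else:
        cum = np.cumsum(wsum)
        qs = (cum - wsum / 2.0) / cum[-1]
    mapped = np.quantile(reference, qs, method="linear")
    # enforce strict increase over distinct inputs
    eps = max(np.ptp(reference), 1.0) * 1e-12
    mapped = np.maximum.accumulate(mapped)
    for k in range(1, n):
        if mapped[k] <= mapped[k - 1]:
            mapped[k] = mapped[k - 1] + eps
    return dict(zip(uniq.tolist(), mapped.tolist()))


def _node_span_weights(arg: ARG) -> dict:
    """Genomic span over which each internal node is present in the
    marginal tree (span of the edges beneath it)."""
    weights = {}
    for e in arg.edges:
        weights[e.parent] = weights.get(e.parent, 0.0) + (e.right - e.left)
    return weights


def normalize(arg: ARG, reference: ReferenceQuantiles) -> ARG:
    """Rewrite internal node times by span-weighted quantile matching;
    topology unchanged."""
    internal = [u for u, t in arg.node_time.items() if t > 0]
    if not internal:
        raise ValueError("ARG has no internal nodes to normalize")
    spans = _node_span_weights(arg)
    observed = np.array([arg.node_time[u] for u in internal])
    weights = np.array([spans.get(u, 0.0) for u in internal])
    if weights.sum() <= 0:
        weights = None
    table = _monotone_quantile_map(observed, reference.times, weights)
    new_times = {u: table[arg.node_time[u]] for u in internal}
    return arg.with_node_times(new_times)
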