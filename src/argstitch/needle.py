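"""Sample-by-sample ARG assembly by threading.

Each new haplotype is added in three steps: (1) hashing shortlists the K
most related samples already in the ARG per genomic region, (2) the pairwise
HMM decodes posterior TMRCAs between the new sample and each candidate and
(3) the per-site minimum posterior-mean candidate is converted into a
piecewise-constant threading instruction, averaging the posterior mean over
runs where the chosen candidate and its MAP state stay constant.  Node
times of the finished ARG are quantile-normalized to the demography by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .arg import ARG, ThreadingInstruction, new_arg, pairwise_tmrca_matrix
from .demography import DemographicModel, GeneticMap
from .hashing import HashIndex, HashingConfig, query_candidates, tokenize
from . import normalize as _norm
from .pairhmm import (
    BURN_IN_SIMULATION_CM,
    D_DEFAULT,
    PairwisePosterior,
    build_pair_hmm,
    decode_pairs,
    discretize_time,
    oracle_decode,
)
from .simulate import MU_DEFAULT, RHO_DEFAULT


@dataclass(frozen=True)
class NeedleConfig:
    hashing: HashingConfig = HashingConfig()
    D: int = D_DEFAULT
    burn_in_cM: float = BURN_IN_SIMULATION_CM
    mode: str = "array"
    mu: float = MU_DEFAULT
    rho: float = RHO_DEFAULT
    seed: int = 0
    normalize: bool = True
    normalize_n_trees: int = 1000
    oracle_arg: object = None  # true ARG: bypasses the HMM with exact TMRCAs
    #: optional word-size growth hook: called with the number of samples
    #: already threaded, returns the word size S to use from that point on
    #: (larger words cut hashing cost in big runs); None keeps S constant
    word_size_schedule: object = None


def threading_instruction(posteriors, candidate_ids) -> ThreadingInstruction:
    """Convert K per-candidate posteriors into a threading instruction.

    At each site the candidate with minimum posterior-mean TMRCA wins (ties
    break toward the lower candidate index).  Sites are partitioned into
    maximal runs where (chosen candidate, chosen MAP state) are constant;
    each run becomes a segment whose height is the mean posterior mean over
    the run and whose start is the midpoint between the bounding sites
    (the first segment starts at 0).
    """
    if len(posteriors) == 0 or len(posteriors) != len(candidate_ids):
        raise ValueError("need one posterior per candidate")
    positions = posteriors[0].positions
    if len(positions) == 0:
        raise ValueError("empty posterior site grid")
    for p in posteriors[1:]:
        if not np.array_equal(p.positions, positions):
            raise ValueError("posteriors must share one site grid")
    means = np.stack([p.posterior_mean for p in posteriors])   # K x M
    maps = np.stack([p.map_state for p in posteriors])         # K x M
    choice = means.argmin(axis=0)
    m = len(positions)
    sites = np.arange(m)
    chosen_map = maps[choice, sites]
    chosen_mean = means[choice, sites]
    runs = [0]
    for s in range(1, m):
        if choice[s] != choice[s - 1] or chosen_map[s] != chosen_map[s - 1]:
            runs.append(s)
    runs.append(m)
    segments = []
    for a, b in zip(runs[:-1], runs[1:]):
        start = 0.0 if a == 0 else (positions[a - 1] + positions[a]) / 2.0
        height = float(chosen_mean[a:b].mean())
        segments.append((start, candidate_ids[int(choice[a])], height))
    return ThreadingInstruction(tuple(segments))


def build_arg_needle(
    haplotypes,
    positions,
    genetic_map: GeneticMap,
    demography: DemographicModel,
    config: NeedleConfig = NeedleConfig(),
    sequence_length=None,
) -> ARG:
    """Assemble an ARG by threading samples in a seeded random order."""
    X = np.asarray(haplotypes)
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least two haplotypes")
    positions = np.asarray(positions, float)
    if sequence_length is None:
        sequence_length = float(positions[-1]) + 1.0
    freqs = X.mean(axis=0)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)

    disc = discretize_time(demography, config.D)
    model = build_pair_hmm(
        demography, config.mu, config.rho, disc, mode=config.mode,
        site_frequencies=freqs,
    )

    def posteriors(row_new, rows_old, region=None):
        if config.oracle_arg is not None:
            out = []
            for row_old in rows_old:
                post = oracle_decode(config.oracle_arg, row_new, row_old, positions)
                if region is not None:
                    keep = (post.positions >= region[0]) & (post.positions < region[1])
                    post = PairwisePosterior(
                        post.positions[keep],
                        post.posterior_mean[keep],
                        post.map_state[keep],
                    )
                out.append(post)
            return out
        return decode_pairs(
            model, X[row_new], X[list(rows_old)], positions, genetic_map,
            burn_in_cM=config.burn_in_cM, region=region,
        )

    arg = new_arg(sequence_length, label=int(order[0]))
    label_to_node = {int(order[0]): arg.samples[0]}
    S = config.hashing.S
    index = HashIndex(num_words=int(np.ceil(m / S)))
    index.add(int(order[0]), tokenize(X[order[0]], S))

    for step, row in enumerate(order[1:], start=1):
        row = int(row)
        if config.word_size_schedule is not None:
            new_S = int(config.word_size_schedule(step))
            if new_S != S and new_S >= 1:
                S = new_S
                index = HashIndex(num_words=int(np.ceil(m / S)))
                for prev in order[:step]:
                    index.add(int(prev), tokenize(X[int(prev)], S))
        try:
            if step <= config.hashing.K:
                cand_labels = [int(r) for r in order[:step]]
                posts = posteriors(row, cand_labels)
                instr = threading_instruction(
                    posts, [label_to_node[c] for c in cand_labels]
                )
            else:
                hcfg = config.hashing if S == config.hashing.S else replace(
                    config.hashing, S=S
                )
                cmat = query_candidates(
                    index, tokenize(X[row], S), hcfg,
                    genetic_map, positions, sequence_length,
                )
                site_posts = {}
                for r in range(cmat.num_regions):
                    region = (cmat.boundaries[r], cmat.boundaries[r + 1])
                    cands = [int(c) for c in cmat.candidates[r]]
                    for c, post in zip(cands, posteriors(row, cands, region=region)):
                        site_posts.setdefault(c, []).append(post)
                # assemble each candidate's posterior on the union grid;
                # sites outside a candidate's regions fall back to the prior
                cand_labels = sorted(site_posts)
                posts = []
                for c in cand_labels:
                    mean = np.full(m, np.inf)
                    mp = np.zeros(m, dtype=int)
                    for p in site_posts[c]:
                        sl = np.searchsorted(positions, p.positions)
                        mean[sl] = p.posterior_mean
                        mp[sl] = p.map_state
                    posts.append(PairwisePosterior(positions, mean, mp))
                instr = threading_instruction(
                    posts, [label_to_node[c] for c in cand_labels]
                )
            node = arg.thread(instr, label=row)
        except Exception as exc:
            raise RuntimeError(
                f"threading failed at step {step} (haplotype row {row})"
            ) from exc
        label_to_node[row] = node
        index.add(row, tokenize(X[row], S))

    if config.normalize:
        ref = _norm.reference_quantiles(
            demography, n, n_trees=config.normalize_n_trees,
            seed=int(rng.integers(1, 2**31 - 1)),
        )
        arg = _norm.normalize(arg, ref)
    return arg


def average_pairwise_over_orders(
    haplotypes, positions, genetic_map, demography,
    config: NeedleConfig = NeedleConfig(), n_orders: int = 2,
):
    """Element-wise mean of genome-averaged pairwise TMRCA matrices over
    independently seeded threading orders."""
    if n_orders < 1:
        raise ValueError("need at least one order")
    acc = None
    for k in range(n_orders):
        cfg = replace(config, seed=config.seed + k)
        arg = build_arg_needle(
            haplotypes, positions, genetic_map, demography, cfg,
        )
        mat = pairwise_tmrca_matrix(arg)
        acc = mat if acc is None else acc + mat
    return acc / n_orders
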