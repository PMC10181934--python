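"""Discretized-time pairwise coalescent HMM for posterior TMRCA decoding.

The hidden state at each variant site is the coalescence-time interval of
the haplotype pair; the prior over intervals is the pairwise coalescent
distribution under the demography, transitions between adjacent sites follow
a sequentially-Markov recombination kernel scaled by the inter-site genetic
distance, and emissions give the probability of observing an allelic
mismatch given the TMRCA.  In array mode the emission is conditioned on the
site's population frequency through a mutation-age argument: older (more
common) alleles are more likely to separate a deeply coalescing pair.

The transition kernel uses a state-independent switch rate driven by the
prior-mean TMRCA, which makes the coalescent prior its exact stationary
distribution.  An oracle decoder reads exact pairwise TMRCAs off a true ARG
for isolation testing of downstream steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arg import ARG
from .demography import DemographicModel, GeneticMap

D_DEFAULT = 30
BURN_IN_SIMULATION_CM = 2.0
BURN_IN_LARGE_DATA_CM = 1.0


@dataclass(frozen=True)
class TimeDiscretization:
    """Interval boundaries (first 0, last inf) and within-interval
    representative times (conditional expected coalescence times)."""

    boundaries: np.ndarray
    representatives: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, float)
        r = np.asarray(self.representatives, float)
        if b[0] != 0.0 or not np.isinf(b[-1]):
            raise ValueError("boundaries must run from 0 to inf")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if np.any((r <= b[:-1]) | (r >= b[1:])):
            raise ValueError("representatives must lie inside their intervals")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "representatives", r)
        object.__setattr__(self, "masses", np.asarray(self.masses, float))

    @property
    def D(self):
        return len(self.representatives)

    def interval_of(self, t):
        return np.clip(
            np.searchsorted(self.boundaries, t, side="right") - 1, 0, self.D - 1
        )


def discretize_time(demography: DemographicModel, D: int = D_DEFAULT) -> TimeDiscretization:
    """Quantile boundaries i/D of the pairwise coalescence-time distribution."""
    if D < 2:
        raise ValueError("need at least two time intervals")
    qs = np.arange(1, D) / D
    inner = demography.pair_coalescent_quantile(qs)
    boundaries = np.concatenate([[0.0], inner, [np.inf]])
    reps = np.array(
        [
            demography.pair_coalescent_interval_mean(a, b)
            for a, b in zip(boundaries[:-1], boundaries[1:])
        ]
    )
    masses = np.array(
        [
            demography.pair_coalescent_interval_mass(a, b)
            for a, b in zip(boundaries[:-1], boundaries[1:])
        ]
    )
    return TimeDiscretization(boundaries, reps, masses)


@dataclass
class PairwisePosterior:
    """Per-site posterior-mean TMRCA (generations), MAP state index and
    site positions for one haplotype pair."""

    positions: np.ndarray
    posterior_mean: np.ndarray
    map_state: np.ndarray


class PairHMM:
    """Pairwise coalescent HMM over a fixed time discretization."""

    def __init__(self, demography, mu, rho, discretization, mode="sequence",
                 site_frequencies=None):
        if mode not in ("array", "sequence"):
            raise ValueError("mode must be 'array' or 'sequence'")
        if mode == "array" and site_frequencies is None:
            raise ValueError("array mode requires site frequencies")
        self.demography = demography
        self.mu = float(mu)
        self.rho = float(rho)
        self.disc = discretization
        self.mode = mode
        self.site_frequencies = (
            None if site_frequencies is None else np.asarray(site_frequencies, float)
        )
        self.prior = self.disc.masses / self.disc.masses.sum()
        self.prior_mean = float(self.prior @ self.disc.representatives)

    # transitions: stay with prob exp(-2 tbar d), else redraw from the prior
    def stay_probability(self, d_morgans):
        return np.exp(-2.0 * self.prior_mean * np.asarray(d_morgans, float))

    def transition_matrix(self, d_morgans) -> np.ndarray:
        c = float(self.stay_probability(d_morgans))
        D = self.disc.D
        return c * np.eye(D) + (1.0 - c) * np.ones((D, 1)) @ self.prior[None, :]

    def _allele_age_scale(self, p):
        """Expected allele age given population frequency p, on the scale of
        the prior mean TMRCA (constant-size neutral approximation)."""
        p = np.clip(np.asarray(p, float), 1e-6, 1.0 - 1e-6)
        rel = -2.0 * p * np.log(p) / (1.0 - p)
        return np.maximum(rel, 1e-3) * self.prior_mean

    def mismatch_probability(self, freqs, spacing_bp) -> np.ndarray:
        """P(discordant | state) per site: D x M matrix."""
        t = self.disc.representatives[:, None]
        if self.mode == "array":
            p = np.asarray(freqs, float)[None, :]
            het = 2.0 * p * (1.0 - p)
            age = self._allele_age_scale(freqs)[None, :]
            pm = het * -np.expm1(-t / age)
        else:
            mu_eff = self.mu * float(spacing_bp)
            pm = -np.expm1(-2.0 * mu_eff * t) * np.ones((1, len(freqs)))
        return np.clip(pm, 1e-12, 1.0 - 1e-12)

    def emission_matrix(self, obs, freqs, spacing_bp) -> np.ndarray:
        """D x M emission probabilities; obs is -1 (missing), 0 (match) or
        1 (mismatch); missing sites emit 1 in every state."""
        pm = self.mismatch_probability(freqs, spacing_bp)
        obs = np.asarray(obs)
        E = np.where(obs[None, :] == 1, pm, 1.0 - pm)
        E[:, obs == -1] = 1.0
        return E


def build_pair_hmm(demography, mu, rho, discretization, mode="sequence",
                   site_frequencies=None) -> PairHMM:
    return PairHMM(demography, mu, rho, discretization, mode, site_frequencies)


def _forward_backward(prior, stay, E):
    """Scaled forward-backward for the switch-to-prior transition kernel.

    ``stay[s]`` is the stay probability between sites s and s+1 (length
    M-1).  ``E`` may be (D, M) for one sequence pair or (C, D, M) for a
    batch of C pairs sharing one site grid; returns posteriors of the same
    shape.
    """
    squeeze = E.ndim == 2
    if squeeze:
        E = E[None]
    C, D, M = E.shape
    alpha = np.empty((C, D, M))
    scale = np.empty((C, M))
    a = prior[None, :] * E[:, :, 0]
    scale[:, 0] = a.sum(axis=1)
    alpha[:, :, 0] = a / scale[:, 0, None]
    for s in range(1, M):
        pred = stay[s - 1] * alpha[:, :, s - 1] + (1.0 - stay[s - 1]) * prior
        a = pred * E[:, :, s]
        scale[:, s] = a.sum(axis=1)
        alpha[:, :, s] = a / scale[:, s, None]
    beta = np.empty((C, D, M))
    beta[:, :, -1] = 1.0
    for s in range(M - 2, -1, -1):
        nb = E[:, :, s + 1] * beta[:, :, s + 1]
        beta[:, :, s] = (
            stay[s] * nb + (1.0 - stay[s]) * (nb @ prior)[:, None]
        ) / scale[:, s + 1, None]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma[0] if squeeze else gamma


def _select_sites(positions, genetic_map, burn_in_cM, region):
    if region is None:
        sel = np.arange(len(positions))
        return sel, np.ones(len(positions), dtype=bool)
    lo, hi = region
    cm = genetic_map.bp_to_cm(positions)
    lo_cm = genetic_map.bp_to_cm(lo) - burn_in_cM
    hi_cm = genetic_map.bp_to_cm(hi) + burn_in_cM
    inside = (positions >= lo) & (positions < hi)
    keep = ((cm >= lo_cm) & (cm <= hi_cm)) | inside
    sel = np.flatnonzero(keep)
    return sel, inside[sel]


def _resolve_freqs(model, site_frequencies, m):
    freqs = site_frequencies if site_frequencies is not None else model.site_frequencies
    if model.mode == "array" and freqs is None:
        raise ValueError("array mode requires site frequencies")
    return np.zeros(m) if freqs is None else np.asarray(freqs, float)


def decode_pairs(
    model: PairHMM,
    hapA,
    others,
    positions,
    genetic_map: GeneticMap,
    burn_in_cM: float = BURN_IN_SIMULATION_CM,
    region=None,
    site_frequencies=None,
) -> list:
    """Decode one haplotype against a batch of others on a shared grid.

    Returns one :class:`PairwisePosterior` per row of ``others``; the
    forward-backward passes run batched, which is what makes threading a
    new sample against all K candidates cheap.
    """
    hapA = np.asarray(hapA)
    others = np.atleast_2d(np.asarray(others))
    positions = np.asarray(positions, float)
    if others.shape[1] != len(hapA) or len(hapA) != len(positions):
        raise ValueError("haplotypes and positions must have equal length")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    missing = (hapA[None, :] < 0) | (others < 0)
    if missing.all(axis=1).any():
        raise ValueError("all sites are missing for at least one pair")
    freqs = _resolve_freqs(model, site_frequencies, len(positions))
    sel, out_mask = _select_sites(positions, genetic_map, burn_in_cM, region)
    pos = positions[sel]
    obs = np.where(
        missing[:, sel], -1, (others[:, sel] != hapA[None, sel]).astype(int)
    )
    spacing = (pos[-1] - pos[0]) / max(len(pos) - 1, 1) if len(pos) > 1 else 1.0
    E = np.stack(
        [model.emission_matrix(o, freqs[sel], spacing) for o in obs]
    )
    d_morgans = np.diff(genetic_map.bp_to_cm(pos)) / 100.0
    stay = model.stay_probability(d_morgans)
    gamma = _forward_backward(model.prior, stay, E)
    out = []
    for c in range(others.shape[0]):
        mean = gamma[c].T @ model.disc.representatives
        out.append(
            PairwisePosterior(
                positions=pos[out_mask],
                posterior_mean=mean[out_mask],
                map_state=gamma[c].argmax(axis=0)[out_mask],
            )
        )
    return out


def decode_pair(
    model: PairHMM,
    hapA,
    hapB,
    positions,
    genetic_map: GeneticMap,
    burn_in_cM: float = BURN_IN_SIMULATION_CM,
    region=None,
    site_frequencies=None,
) -> PairwisePosterior:
    """Posterior-mean and MAP TMRCA per site by forward-backward decoding.

    ``region=(left_bp, right_bp)`` restricts the output; sites within
    ``burn_in_cM`` on either side are decoded for context but trimmed.
    """
    hapA = np.asarray(hapA)
    hapB = np.asarray(hapB)
    if hapA.shape != hapB.shape:
        raise ValueError("haplotypes and positions must have equal length")
    try:
        return decode_pairs(
            model, hapA, hapB[None, :], positions, genetic_map,
            burn_in_cM=burn_in_cM, region=region,
            site_frequencies=site_frequencies,
        )[0]
    except ValueError as exc:
        if "missing" in str(exc):
            raise ValueError("all sites are missing")
        raise


def oracle_decode(true_arg: ARG, i, j, positions,
                  discretization: TimeDiscretization | None = None) -> PairwisePosterior:
    """Exact pairwise TMRCAs read off a true ARG's marginal trees.

    The posterior mean is the exact TMRCA; the MAP state is the containing
    discretization interval (0 if no discretization is given).  ``i`` and
    ``j`` are sample labels.
    """
    labels = true_arg.labels
    if i not in labels or j not in labels:
        raise ValueError(f"samples {i}, {j} not in ARG")
    positions = np.asarray(positions, float)
    order = np.argsort(positions)
    ts = true_arg.to_tree_sequence()
    idx = {lab: k for k, lab in enumerate(sorted(labels))}
    ui, uj = ts.samples()[idx[i]], ts.samples()[idx[j]]
    tmrca = np.empty(len(positions))
    it = ts.trees()
    tree = next(it)
    cur = None
    for k in order:
        x = positions[k]
        while tree.interval.right <= x:
            tree = next(it)
            cur = None
        if cur is None:
            cur = tree.tmrca(ui, uj)
        tmrca[k] = cur
    if discretization is None:
        map_state = np.zeros(len(positions), dtype=int)
    else:
        map_state = discretization.interval_of(tmrca)
    return PairwisePosterior(
        positions=positions, posterior_mean=tmrca, map_state=map_state
    )
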