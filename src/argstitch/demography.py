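"""Piecewise-constant demographic models and genetic maps.

Times are in generations, population sizes are numbers of *diploid*
individuals, so a pair of haploid lineages coalesces at rate 1/(2*Ne) per
generation.  Genetic maps are piecewise linear in physical position, with
positions in base pairs and map positions in centimorgans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DemographicModel:
    """Single-population, piecewise-constant effective size history.

    ``epochs`` is a list of ``(start_generation, diploid_Ne)`` pairs, sorted
    by start time with the first epoch starting at generation 0.
    """

    epochs: tuple = ((0.0, 15000.0),)

    def __post_init__(self):
        epochs = tuple((float(s), float(n)) for s, n in self.epochs)
        object.__setattr__(self, "epochs", epochs)
        if not epochs:
            raise ValueError("demographic model needs at least one epoch")
        if epochs[0][0] != 0.0:
            raise ValueError(
                f"first epoch must start at generation 0, got {epochs[0][0]}"
            )
        for k, (start, ne) in enumerate(epochs):
            if ne <= 0:
                raise ValueError(f"epoch {k} has non-positive Ne = {ne}")
            if k > 0 and start <= epochs[k - 1][0]:
                raise ValueError(
                    f"epoch {k} start {start} is not after epoch {k - 1} "
                    f"start {epochs[k - 1][0]}"
                )

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.epochs])

    @property
    def sizes(self) -> np.ndarray:
        return np.array([n for _, n in self.epochs])

    def size_at(self, t: float) -> float:
        """Diploid Ne in effect at generation ``t``."""
        idx = int(np.searchsorted(self.starts, t, side="right")) - 1
        return float(self.sizes[idx])

    # -- pairwise coalescent distribution (haploid pair, rate 1/(2 Ne)) ----

    def _rates(self) -> np.ndarray:
        return 1.0 / (2.0 * self.sizes)

    def pair_coalescent_cumhazard(self, t):
        """Cumulative hazard of pairwise coalescence at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        starts, rates = self.starts, self._rates()
        ends = np.append(starts[1:], np.inf)
        dur = np.clip(t[..., None] - starts, 0.0, ends - starts)
        return (dur * rates).sum(axis=-1)

    def pair_coalescent_quantile(self, q):
        """Inverse CDF of the pairwise coalescence time."""
        q = np.asarray(q, dtype=float)
        target = -np.log1p(-q)
        starts, rates = self.starts, self._rates()
        ends = np.append(starts[1:], np.inf)
        cum = np.concatenate([[0.0], np.cumsum((ends[:-1] - starts[:-1]) * rates[:-1])])
        idx = np.clip(np.searchsorted(cum, target, side="right") - 1, 0, len(starts) - 1)
        return starts[idx] + (target - cum[idx]) / rates[idx]

    def pair_coalescent_interval_mass(self, a: float, b: float) -> float:
        """P(a <= T < b) for the pairwise coalescence time T."""
        sa = np.exp(-self.pair_coalescent_cumhazard(np.array(a)))
        sb = 0.0 if np.isinf(b) else np.exp(-self.pair_coalescent_cumhazard(np.array(b)))
        return float(sa - sb)

    def pair_coalescent_interval_mean(self, a: float, b: float) -> float:
        """E[T | a <= T < b]: closed form, summed over constant-rate pieces."""
        starts, rates = self.starts, self._rates()
        cuts = [a] + [float(s) for s in starts if a < s < b] + [b]
        total = 0.0
        for u, v in zip(cuts[:-1], cuts[1:]):
            lam = rates[int(np.searchsorted(starts, u, side="right")) - 1]
            hu = float(self.pair_coalescent_cumhazard(np.array(u)))
            # integral of t * lam * exp(-H(t)) over [u, v), H linear on the piece
            if np.isinf(v):
                total += np.exp(-hu) * (u + 1.0 / lam)
            else:
                total += np.exp(-hu) * (
                    (u + 1.0 / lam) - np.exp(-lam * (v - u)) * (v + 1.0 / lam)
                )
        mass = self.pair_coalescent_interval_mass(a, b)
        if mass <= 0:
            raise ValueError(f"empty coalescent mass on [{a}, {b})")
        return total / mass

    @property
    def pair_coalescent_mean(self) -> float:
        return self.pair_coalescent_interval_mean(0.0, np.inf)

    # -- file I/O: two whitespace-separated columns (generation, diploid Ne)

    def to_file(self, path):
        with open(path, "w") as fh:
            for start, ne in self.epochs:
                fh.write(f"{start:g}\t{ne:g}\n")

    @classmethod
    def from_file(cls, path) -> "DemographicModel":
        epochs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                start, ne = line.split()[:2]
                epochs.append((float(start), float(ne)))
        return cls(tuple(epochs))


#: Constant reference model printed in the source analyses.
CONSTANT_15K = DemographicModel(((0.0, 15000.0),))

#: Generic European-like bottleneck history: a synthetic stand-in with an
#: out-of-Africa-style bottleneck and recent growth, not a fitted model.
EUROPEAN_BOTTLENECK = DemographicModel(
    (
        (0.0, 50000.0),
        (200.0, 15000.0),
        (1500.0, 3000.0),
        (2500.0, 10000.0),
        (10000.0, 15000.0),
    )
)


@dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear map between physical (bp) and genetic (cM) position."""

    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        bp = np.asarray(self.bp, dtype=float)
        cm = np.asarray(self.cm, dtype=float)
        if bp.ndim != 1 or bp.shape != cm.shape or bp.size < 2:
            raise ValueError("map needs matching 1-d bp and cM arrays, length >= 2")
        if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) < 0):
            raise ValueError("map positions must be increasing")
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)

    @classmethod
    def constant(cls, rate_per_bp: float, length_bp: float) -> "GeneticMap":
        """Uniform recombination: ``rate_per_bp`` Morgans/bp (e.g. 1.2e-8)."""
        bp = np.array([0.0, float(length_bp)])
        return cls(bp, bp * rate_per_bp * 100.0)

    def bp_to_cm(self, pos):
        return np.interp(pos, self.bp, self.cm)

    def cm_to_bp(self, gpos):
        return np.interp(gpos, self.cm, self.bp)

    @property
    def total_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0])

    # -- 3-column text format: chromosome, cM, bp --------------------------

    def to_file(self, path, chrom: str = "1"):
        with open(path, "w") as fh:
            for b, c in zip(self.bp, self.cm):
                fh.write(f"{chrom}\t{c:.8f}\t{int(round(b))}\n")

    @classmethod
    def from_file(cls, path) -> "GeneticMap":
        cms, bps = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                _, c, b = line.split()[:3]
                cms.append(float(c))
                bps.append(float(b))
        return cls(np.array(bps), np.array(cms))
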