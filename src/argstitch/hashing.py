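"""Word-based genotype hashing: shortlist the K most related samples.

Haplotypes are cut into non-overlapping words of S sites; hash tables map
each (word index, word value) to the samples carrying that value.  For a
target haplotype, candidates are scored per genomic region by the longest
run of matching words overlapping the region, tolerating up to T mismatched
words inside the run (the score counts matching words only, so boundary
mismatches never help).  Runs may extend arbitrarily far beyond region
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import GeneticMap


@dataclass(frozen=True)
class HashingConfig:
    """S sites/word, K candidates/region, T tolerated mismatches, region
    length in cM (0.5 for array data, 0.1 for sequencing)."""

    S: int = 16
    K: int = 64
    T: int = 1
    L_region: float = 0.5

    def __post_init__(self):
        if self.S < 1 or self.K < 1 or self.T < 0 or self.L_region <= 0:
            raise ValueError("invalid hashing configuration")


@dataclass
class CandidateMatrix:
    """Per-region shortlists: ``candidates[r]`` lists up to K sample ids,
    best first; ``boundaries`` are the R+1 region edges in bp."""

    candidates: list
    boundaries: np.ndarray
    scores: list

    @property
    def num_regions(self):
        return len(self.candidates)


def tokenize(haplotype: np.ndarray, S: int) -> list:
    """Split one haplotype into ceil(M/S) words (last word may be partial)."""
    hap = np.asarray(haplotype, dtype=np.int8)
    return [hap[i : i + S].tobytes() for i in range(0, len(hap), S)]


class HashIndex:
    """Hash tables from (word position, word value) to carrying samples."""

    def __init__(self, num_words: int):
        self.num_words = num_words
        self.tables = [dict() for _ in range(num_words)]
        self.order = []  # sample ids in insertion (threading) order

    def __len__(self):
        return len(self.order)

    def add(self, sample_id, words):
        if sample_id in self.order:
            raise ValueError(f"sample {sample_id} already indexed")
        if len(words) != self.num_words:
            raise ValueError("word count mismatch")
        self.order.append(sample_id)
        for i, w in enumerate(words):
            self.tables[i].setdefault(w, []).append(sample_id)

    def query_word(self, i, value):
        return self.tables[i].get(value, [])

    def match_matrix(self, target_words) -> np.ndarray:
        """Boolean (num indexed samples) x (num words) word-match matrix,
        rows in insertion order, assembled purely from table lookups."""
        pos = {s: i for i, s in enumerate(self.order)}
        m = np.zeros((len(self.order), self.num_words), dtype=bool)
        for i, w in enumerate(target_words):
            for s in self.tables[i].get(w, ()):
                m[pos[s], i] = True
        return m


def add_to_index(index: HashIndex, sample_id, words) -> HashIndex:
    index.add(sample_id, words)
    return index


def tolerant_run_score(match: np.ndarray, T: int, lo: int, hi: int) -> int:
    """Best T-tolerant run score over word window indices in [lo, hi].

    The score of a window with at most T mismatched words is its number of
    matching words; only windows overlapping [lo, hi] count.
    """
    W = len(match)
    best = 0
    for i in range(W):
        mism = 0
        matches = 0
        for j in range(i, W):
            if match[j]:
                matches += 1
            else:
                mism += 1
                if mism > T:
                    break
            if j >= lo and i <= hi and matches > best:
                best = matches
    return best


def region_boundaries(positions, genetic_map: GeneticMap, L_region: float,
                      sequence_length: float):
    """Partition the genome into regions of genetic length ``L_region`` cM,
    snapping boundaries to inter-site midpoints.

    Returns (region index per site, bp boundaries array of length R+1).
    """
    positions = np.asarray(positions, float)
    cm = genetic_map.bp_to_cm(positions)
    rel = cm - cm[0]
    site_region = np.floor(rel / L_region).astype(int)
    # compact to consecutive region ids
    uniq = np.unique(site_region)
    remap = {u: i for i, u in enumerate(uniq)}
    site_region = np.array([remap[r] for r in site_region])
    nreg = site_region.max() + 1
    bounds = [0.0]
    for r in range(1, nreg):
        last_prev = positions[site_region == r - 1][-1]
        first_cur = positions[site_region == r][0]
        bounds.append((last_prev + first_cur) / 2.0)
    bounds.append(float(sequence_length))
    return site_region, np.array(bounds)


def query_candidates(
    index: HashIndex,
    target_words,
    config: HashingConfig,
    genetic_map: GeneticMap,
    positions,
    sequence_length: float,
) -> CandidateMatrix:
    """Rank indexed samples per region by the T-tolerant run score.

    Ties break by earlier threading (insertion) order, then lower sample id;
    if fewer than K samples are indexed, all are returned.
    """
    if len(index) == 0:
        raise ValueError("hash index is empty")
    positions = np.asarray(positions, float)
    site_region, bounds = region_boundaries(
        positions, genetic_map, config.L_region, sequence_length
    )
    S = config.S
    word_region = site_region[::S]  # region of each word's first site
    match = index.match_matrix(target_words)
    nreg = len(bounds) - 1
    cands, scores = [], []
    for r in range(nreg):
        widx = np.flatnonzero(word_region == r)
        lo, hi = int(widx[0]), int(widx[-1])
        ranked = sorted(
            range(len(index.order)),
            key=lambda row: (
                -tolerant_run_score(match[row], config.T, lo, hi),
                row,
                index.order[row],
            ),
        )[: config.K]
        cands.append([index.order[row] for row in ranked])
        scores.append(
            [tolerant_run_score(match[row], config.T, lo, hi) for row in ranked]
        )
    return CandidateMatrix(candidates=cands, boundaries=bounds, scores=scores)


def dump_scores_tsv(cmat: CandidateMatrix, path):
    """Diagnostic dump of per-region candidate scores."""
    with open(path, "w") as fh:
        fh.write("region\tleft_bp\tright_bp\trank\tsample\tscore\n")
        for r, (ids, sc) in enumerate(zip(cmat.candidates, cmat.scores)):
            for rank, (s, v) in enumerate(zip(ids, sc)):
                fh.write(
                    f"{r}\t{cmat.boundaries[r]:.1f}\t{cmat.boundaries[r + 1]:.1f}"
                    f"\t{rank}\t{s}\t{v}\n"
                )
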