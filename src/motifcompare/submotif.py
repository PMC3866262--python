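"""Separating true motifs from spurious ones via sub-motif splitting.

A motif built from n binding sites is recursively split into pairs of
sub-motifs: at the top level one uniform random bipartition of the site
multiset into sizes (k, n-k) for each k in 1..floor(n/2); the same rule is
then applied to every produced sub-motif of size >= 2, bottoming out at
size 1.  Scoring each pair of sibling sub-motifs against each other yields
the "known inner" score distribution; scoring all pairs of motifs in a
database (mostly unrelated, low-information motifs) yields the "all pairs"
distribution.  A good metric separates the two: after joint min-max
normalisation their histogram overlap (sum over shared bins of the smaller
probability mass) should be small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .alignment import ScoringStrategy, motif_similarity
from .motifs import Motif
from .retrieval import MotifDatabase

__all__ = [
    "SubMotifPair",
    "SplitForest",
    "ScoreDistribution",
    "OverlapReport",
    "split_motif",
    "expected_pair_count",
    "inner_pair_scores",
    "all_pair_scores",
    "normalize_and_overlap",
]

log = logging.getLogger(__name__)


@dataclass
class SubMotifPair:
    """Two sub-motifs from one random bipartition of a parent's sites."""

    parent_id: str
    first: Motif
    second: Motif
    depth: int

    @property
    def sizes(self) -> tuple[int, int]:
        return (self.first.n_sites, self.second.n_sites)


@dataclass
class SplitForest:
    """All sub-motif pairs produced by recursively splitting one motif."""

    motif_id: str
    pairs: list[SubMotifPair]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ScoreDistribution:
    """A bag of similarity scores from one experiment arm."""

    scores: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class OverlapReport:
    """Histogram overlap between two normalised score distributions, in [0, 1]."""

    overlap: float
    bins: int
    inner_hist: np.ndarray
    all_hist: np.ndarray


def split_motif(motif: Motif, seed: int, max_depth: int | None = None) -> SplitForest:
    """Recursively split a motif's sites into sub-motif pairs.

    The motif must carry its individual sites (counts alone cannot be
    partitioned) and have at least 3 of them for top-level inclusion.  A
    size-n (sub-)motif contributes floor(n/2) pairs, one uniform random
    bipartition per size k; recursion continues on every sub-motif of
    size >= 2 until all pieces have size 1 (or ``max_depth`` is reached).
    Reproducible for a fixed seed.
    """
    if motif.sites is None:
        raise ValueError(f"motif {motif.id!r} has no sites attached; counts cannot be split")
    if motif.n_sites < 3:
        raise ValueError(f"motif {motif.id!r} has fewer than 3 sites")
    rng = np.random.default_rng(seed)
    pairs: list[SubMotifPair] = []
    _split_into(motif.id, motif.sites, rng, pairs, depth=0, max_depth=max_depth)
    return SplitForest(motif_id=motif.id, pairs=pairs)


def _split_into(parent_id: str, sites: list[str], rng: np.random.Generator,
                out: list[SubMotifPair], depth: int, max_depth: int | None) -> None:
    n = len(sites)
    if n < 2 or (max_depth is not None and depth >= max_depth):
        return
    for k in range(1, n // 2 + 1):
        idx = rng.permutation(n)
        first_sites = [sites[i] for i in sorted(idx[:k])]
        second_sites = [sites[i] for i in sorted(idx[k:])]
        first = Motif.from_sites(f"{parent_id}|d{depth}k{k}a", first_sites)
        second = Motif.from_sites(f"{parent_id}|d{depth}k{k}b", second_sites)
        out.append(SubMotifPair(parent_id=parent_id, first=first, second=second, depth=depth))
        _split_into(first.id, first_sites, rng, out, depth + 1, max_depth)
        _split_into(second.id, second_sites, rng, out, depth + 1, max_depth)


@lru_cache(maxsize=None)
def expected_pair_count(n: int) -> int:
    """Number of sub-motif pairs the full recursion produces from n sites.

    Satisfies P(1) = 0 and
    P(n) = floor(n/2) + sum_{k=1}^{floor(n/2)} (P(k) + P(n-k)).
    """
    if n < 2:
        return 0
    return n // 2 + sum(expected_pair_count(k) + expected_pair_count(n - k)
                        for k in range(1, n // 2 + 1))


def inner_pair_scores(forest: SplitForest, strategy: ScoringStrategy) -> ScoreDistribution:
    """Score each sub-motif pair's two halves against each other ("known inner")."""
    if not forest.pairs:
        raise ValueError(f"forest for {forest.motif_id!r} is empty")
    scores = [motif_similarity(p.first, p.second, strategy).score for p in forest.pairs]
    return ScoreDistribution(scores=np.array(scores), label=f"inner:{forest.motif_id}")


def all_pair_scores(db: MotifDatabase, strategy: ScoringStrategy) -> ScoreDistribution:
    """Score all m(m-1)/2 unordered pairs of distinct database motifs ("all pairs")."""
    if len(db) == 0:
        raise ValueError("empty database")
    scores = []
    for i in range(len(db)):
        for j in range(i + 1, len(db)):
            scores.append(motif_similarity(db.motifs[i], db.motifs[j], strategy).score)
    return ScoreDistribution(scores=np.array(scores), label="all-pairs")


def normalize_and_overlap(
    inner: ScoreDistribution,
    all_pairs: ScoreDistribution,
    bins: int = 100,
) -> OverlapReport:
    """Joint min-max normalisation, shared-bin histograms, and their overlap.

    Both score sets are mapped to [0, 1] with the same affine transform
    (order-preserving), binned on a shared grid, and the overlap is the sum
    over bins of the smaller of the two probability masses: 1 for identical
    distributions, 0 for disjoint supports.
    """
    if inner.scores.size == 0 or all_pairs.scores.size == 0:
        raise ValueError("both score distributions must be non-empty")
    lo = min(inner.scores.min(), all_pairs.scores.min())
    hi = max(inner.scores.max(), all_pairs.scores.max())
    if hi == lo:
        log.warning("all scores identical across both distributions; overlap defined as 1")
        h = np.zeros(bins)
        h[0] = 1.0
        return OverlapReport(overlap=1.0, bins=bins, inner_hist=h, all_hist=h.copy())
    span = hi - lo
    inner_norm = (inner.scores - lo) / span
    all_norm = (all_pairs.scores - lo) / span
    edges = np.linspace(0.0, 1.0, bins + 1)
    inner_hist = np.histogram(inner_norm, bins=edges)[0] / inner_norm.size
    all_hist = np.histogram(all_norm, bins=edges)[0] / all_norm.size
    overlap = float(np.minimum(inner_hist, all_hist).sum())
    return OverlapReport(overlap=overlap, bins=bins, inner_hist=inner_hist, all_hist=all_hist)
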