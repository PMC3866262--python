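"""Motif-level similarity by column alignment.

Two motifs are compared by aligning their columns, exactly as two sequences
are aligned, but with the substitution score replaced by a column similarity
metric.  The score of an alignment is the sum of aligned column similarities
minus an affine gap penalty: a gap run of length g costs open + (g-1)*extend,
with extend defaulting to half of open.  Three modes are provided:

* NW  — global (Needleman-Wunsch); end gaps are penalised like internal ones.
* SW  — local (Smith-Waterman); the score is floored at 0 and an empty
        alignment is legal.
* SWU — ungapped local: the best contiguous run of column pairs over all
        relative offsets of the two motifs.

The motif similarity is the score of the best alignment, by default maximised
over both orientations (forward and reverse complement).  An empirical
p-value can be attached by scoring against column-shuffled copies of the
second motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import kfv_similarity, similarity_matrix
from .motifs import Background, Motif, MotifProfile, UNIFORM, reverse_complement

__all__ = [
    "GapPenalty",
    "ScoringStrategy",
    "GapRun",
    "AlignmentResult",
    "align_global",
    "align_local",
    "align_ungapped",
    "motif_similarity",
    "empirical_pvalue",
]

log = logging.getLogger(__name__)

_NEG = float("-inf")
MODES = ("NW", "SW", "SWU")


@dataclass(frozen=True)
class GapPenalty:
    """Affine gap cost: a run of length g costs open + (g-1)*extend."""

    open: float = 1.0
    extend: float | None = None

    def __post_init__(self) -> None:
        if self.open < 0:
            raise ValueError("gap open penalty must be non-negative")
        if self.extend is None:
            object.__setattr__(self, "extend", self.open / 2.0)
        elif self.extend < 0:
            raise ValueError("gap extension penalty must be non-negative")

    def cost(self, length: int) -> float:
        return self.open + (length - 1) * self.extend if length > 0 else 0.0


@dataclass(frozen=True)
class ScoringStrategy:
    """A named comparison configuration: metric, alignment mode, gaps, orientation.

    ``mode`` SWU ignores the gap penalty; metric ``kfv`` is alignment-free and
    ignores mode and gaps entirely.  ``pseudocount`` and ``background`` fix how
    count matrices are turned into probabilities for every metric.
    """

    metric: str = "spic"
    mode: str = "SW"
    gap: GapPenalty = field(default_factory=GapPenalty)
    both_orientations: bool = True
    min_overlap: int = 1
    pseudocount: float = 1.0
    background: Background = UNIFORM

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown alignment mode {self.mode!r}; expected one of {MODES}")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")

    def describe(self) -> str:
        if self.metric == "kfv":
            return "KFV"
        if self.mode == "SWU":
            return f"{self.metric.upper()}/SWU"
        return f"{self.metric.upper()}/{self.mode}(open={self.gap.open:g}, extend={self.gap.extend:g})"


@dataclass(frozen=True)
class GapRun:
    """A maximal run of gap characters on one side of the alignment.

    ``side`` names the motif that received the gap characters; ``after_pair``
    is the index (into the aligned-pair list, 0 = before the first pair) of
    the aligned pair preceding the run.
    """

    side: str  # "m1" or "m2"
    length: int
    after_pair: int


@dataclass
class AlignmentResult:
    """Outcome of one motif-vs-motif comparison.

    ``pairs`` holds 1-based (column of M1, column of M2) aligned index pairs,
    strictly increasing on both sides; when ``orientation`` is "revcomp" the
    M2 indices refer to the reverse-complemented M2.  ``score`` equals the sum
    of ``pair_scores`` minus the affine cost of ``gaps``.
    """

    m1_id: str
    m2_id: str
    score: float
    pairs: list[tuple[int, int]] = field(default_factory=list)
    pair_scores: list[float] = field(default_factory=list)
    gaps: list[GapRun] = field(default_factory=list)
    orientation: str = "forward"
    pvalue: float | None = None

    def recomputed_score(self, gap: GapPenalty) -> float:
        return sum(self.pair_scores) - sum(gap.cost(g.length) for g in self.gaps)


# --- dynamic programming --------------------------------------------------
# Three-state Gotoh DP.  State M ends with an aligned pair, state X with an
# M1 column against a gap (gap in M2), state Y with a gap in M1.  All
# transitions between gap states are allowed; entering a gap state from any
# other state costs `open`, staying costs `extend`.

_M, _X, _Y, _START = 0, 1, 2, 3


def _gotoh(S: np.ndarray, gap: GapPenalty, local: bool):
    L1, L2 = S.shape
    op, ex = gap.open, gap.extend
    M = np.full((L1 + 1, L2 + 1), _NEG)
    X = np.full((L1 + 1, L2 + 1), _NEG)
    Y = np.full((L1 + 1, L2 + 1), _NEG)
    ptr = np.full((3, L1 + 1, L2 + 1), -1, dtype=np.int8)
    if not local:
        M[0, 0] = 0.0
        ptr[_M, 0, 0] = _START
    for i in range(L1 + 1):
        for j in range(L2 + 1):
            if i > 0:
                # preference order on ties: continue a pair, then X, then Y
                cands = (M[i - 1, j] - op, X[i - 1, j] - ex, Y[i - 1, j] - op)
                best = int(np.argmax(cands))
                if cands[best] > _NEG:
                    X[i, j] = cands[best]
                    ptr[_X, i, j] = best
            if j > 0:
                cands = (M[i, j - 1] - op, X[i, j - 1] - op, Y[i, j - 1] - ex)
                best = int(np.argmax(cands))
                if cands[best] > _NEG:
                    Y[i, j] = cands[best]
                    ptr[_Y, i, j] = best
            if i > 0 and j > 0:
                cands = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
                if local:
                    cands.append(0.0)  # fresh start
                best = int(np.argmax(cands))
                if cands[best] > _NEG:
                    M[i, j] = S[i - 1, j - 1] + cands[best]
                    ptr[_M, i, j] = _START if (local and best == 3) else best
    return M, X, Y, ptr


def _traceback(S, ptr, state, i, j, local):
    pairs: list[tuple[int, int]] = []
    pair_scores: list[float] = []
    raw_gaps: list[tuple[str, int]] = []  # (side, position in reversed walk)
    steps: list[tuple[int, int, int]] = []
    while True:
        prev = int(ptr[state, i, j])
        if state == _M and prev == _START and (i, j) == (0, 0):
            break
        steps.append((state, i, j))
        if state == _M:
            if prev == _START:
                break
            i, j, state = i - 1, j - 1, prev
        elif state == _X:
            i, state = i - 1, prev
        else:
            j, state = j - 1, prev
    steps.reverse()
    # convert the walked path into pairs and maximal gap runs
    gaps: list[GapRun] = []
    run_side, run_len = None, 0
    for st, si, sj in steps:
        if st == _M:
            if run_side is not None:
                gaps.append(GapRun(side=run_side, length=run_len, after_pair=len(pairs)))
                run_side, run_len = None, 0
            pairs.append((si, sj))
            pair_scores.append(float(S[si - 1, sj - 1]))
        else:
            side = "m2" if st == _X else "m1"
            if side == run_side:
                run_len += 1
            else:
                if run_side is not None:
                    gaps.append(GapRun(side=run_side, length=run_len, after_pair=len(pairs)))
                run_side, run_len = side, 1
    if run_side is not None:
        gaps.append(GapRun(side=run_side, length=run_len, after_pair=len(pairs)))
    return pairs, pair_scores, gaps


def _column_sim_matrix(m1: Motif, m2: Motif, strategy: ScoringStrategy) -> np.ndarray:
    p1 = MotifProfile.from_motif(m1, strategy.background, strategy.pseudocount)
    p2 = MotifProfile.from_motif(m2, strategy.background, strategy.pseudocount)
    return similarity_matrix(p1, p2, strategy.metric)


def align_global(m1: Motif, m2: Motif, strategy: ScoringStrategy) -> AlignmentResult:
    """Best global (NW) alignment score under affine gaps; end gaps are penalised."""
    S = _column_sim_matrix(m1, m2, strategy)
    M, X, Y, ptr = _gotoh(S, strategy.gap, local=False)
    L1, L2 = S.shape
    finals = (M[L1, L2], X[L1, L2], Y[L1, L2])
    state = int(np.argmax(finals))
    pairs, pair_scores, gaps = _traceback(S, ptr, state, L1, L2, local=False)
    return AlignmentResult(m1_id=m1.id, m2_id=m2.id, score=float(finals[state]),
                           pairs=pairs, pair_scores=pair_scores, gaps=gaps)


def align_local(m1: Motif, m2: Motif, strategy: ScoringStrategy) -> AlignmentResult:
    """Best local (SW) alignment; score >= 0, empty alignment when nothing scores > 0."""
    S = _column_sim_matrix(m1, m2, strategy)
    M, X, Y, ptr = _gotoh(S, strategy.gap, local=True)
    best = float(M[1:, 1:].max(initial=0.0))
    if best <= 0.0:
        return AlignmentResult(m1_id=m1.id, m2_id=m2.id, score=0.0)
    flat = int(np.argmax(M[1:, 1:]))
    i, j = divmod(flat, S.shape[1])
    pairs, pair_scores, gaps = _traceback(S, ptr, _M, i + 1, j + 1, local=True)
    if len(pairs) < strategy.min_overlap:
        return AlignmentResult(m1_id=m1.id, m2_id=m2.id, score=0.0)
    return AlignmentResult(m1_id=m1.id, m2_id=m2.id, score=best,
                           pairs=pairs, pair_scores=pair_scores, gaps=gaps)


def align_ungapped(m1: Motif, m2: Motif, strategy: ScoringStrategy) -> AlignmentResult:
    """Best contiguous ungapped run of column pairs over all relative offsets."""
    S = _column_sim_matrix(m1, m2, strategy)
    L1, L2 = S.shape
    best_score = 0.0
    best_run: tuple[int, int, int] | None = None  # (i_start, j_start, length)
    for offset in range(-(L2 - 1), L1):
        i0, j0 = (offset, 0) if offset >= 0 else (0, -offset)
        diag = S[i0:, j0:].diagonal()
        # best contiguous run on this diagonal, via prefix sums
        prefix = np.concatenate([[0.0], np.cumsum(diag)])
        for a in range(len(diag)):
            for b in range(a + strategy.min_overlap, len(diag) + 1):
                run_sum = float(prefix[b] - prefix[a])
                if run_sum > best_score:
                    best_score = run_sum
                    best_run = (i0 + a, j0 + a, b - a)
    if best_run is None:
        return AlignmentResult(m1_id=m1.id, m2_id=m2.id, score=0.0)
    i0, j0, length = best_run
    pairs = [(i0 + t + 1, j0 + t + 1) for t in range(length)]
    pair_scores = [float(S[i0 + t, j0 + t]) for t in range(length)]
    return AlignmentResult(m1_id=m1.id, m2_id=m2.id, score=best_score,
                           pairs=pairs, pair_scores=pair_scores)


_ALIGNERS = {"NW": align_global, "SW": align_local, "SWU": align_ungapped}


def motif_similarity(m1: Motif, m2: Motif, strategy: ScoringStrategy) -> AlignmentResult:
    """Similarity of two motifs under a strategy; the score of the best alignment.

    With ``both_orientations`` (the default) the second motif is also compared
    in reverse complement and the higher-scoring orientation is returned; on a
    tie the forward orientation wins.  For the alignment-free ``kfv`` metric
    the result carries only a score.
    """
    if strategy.metric == "kfv":
        score = kfv_similarity(m1, m2, background=strategy.background,
                               pseudocount=strategy.pseudocount)
        result = AlignmentResult(m1_id=m1.id, m2_id=m2.id, score=score)
        if strategy.both_orientations:
            rc_score = kfv_similarity(m1, reverse_complement(m2),
                                      background=strategy.background,
                                      pseudocount=strategy.pseudocount)
            if rc_score > score:
                result = AlignmentResult(m1_id=m1.id, m2_id=m2.id, score=rc_score,
                                         orientation="revcomp")
        return result
    aligner = _ALIGNERS[strategy.mode]
    fwd = aligner(m1, m2, strategy)
    if not strategy.both_orientations:
        return fwd
    rev = aligner(m1, reverse_complement(m2), strategy)
    if rev.score > fwd.score:
        rev.orientation = "revcomp"
        return rev
    return fwd


def empirical_pvalue(
    m1: Motif,
    m2: Motif,
    strategy: ScoringStrategy,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical p-value of the observed similarity against a column-shuffle null.

    The null distribution is built by scoring ``m1`` against ``n_shuffles``
    copies of ``m2`` whose columns are permuted uniformly at random (which
    preserves the column IC multiset).  Returns the add-one estimator
    (1 + #{null >= observed}) / (1 + n_shuffles); reproducible for a fixed seed.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    observed = motif_similarity(m1, m2, strategy).score
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(m2.length)
        shuffled = Motif(id=m2.id, counts=m2.counts[:, perm],
                         tf_name=m2.tf_name, family_label=m2.family_label)
        if motif_similarity(m1, shuffled, strategy).score >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_shuffles)
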