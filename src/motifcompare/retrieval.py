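"""Database retrieval and ROC evaluation.

A motif database is searched with a query motif under a scoring strategy;
the ranked hit list, best-hit family-recovery accuracy, and a pairwise ROC
analysis quantify how well a metric groups motifs of the same TF family.

The ROC follows the pairwise rule: all n(n+1)/2 unordered motif pairs
(including self-pairs by default) are scored; at a threshold t a pair
scoring >= t is a "match".  A match between same-family motifs is a true
positive, a match across families a false positive, and so on; the curve is
the TP rate against the FP rate as t sweeps the observed scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import ScoringStrategy, motif_similarity
from .motifs import Motif

__all__ = [
    "MotifDatabase",
    "HitList",
    "ROCCurve",
    "AccuracyReport",
    "search_database",
    "pairwise_scores",
    "best_hit_accuracy",
    "roc_curve",
]

log = logging.getLogger(__name__)


@dataclass
class MotifDatabase:
    """A collection of motifs with unique ids; family labels may be absent (decoys)."""

    motifs: list[Motif]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.motifs]
        if len(set(ids)) != len(ids):
            raise ValueError("motif ids in a database must be unique")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    @property
    def labels(self) -> dict[str, str | None]:
        return {m.id: m.family_label for m in self.motifs}


@dataclass
class HitList:
    """Ranked search result for one query: (target id, score) descending, ties by id."""

    query_id: str
    hits: list[tuple[str, float]]


@dataclass
class ROCCurve:
    """ROC points (threshold, TPR, FPR) from the highest threshold down, plus AUC."""

    points: list[tuple[float, float, float]]
    auc: float
    n_pairs: int


@dataclass
class AccuracyReport:
    """Best-hit family recovery.

    ``overall`` counts only queries whose family has at least one other
    member (a singleton-family query can never be recovered); singletons are
    tallied separately in ``n_singletons``.
    """

    overall: float
    per_label: dict[str, float]
    n_evaluated: int
    n_singletons: int


def search_database(
    query: Motif,
    db: MotifDatabase,
    strategy: ScoringStrategy,
    exclude_self: bool = True,
) -> HitList:
    """Score the query against every database motif and rank descending.

    Ties are broken lexicographically by target id for determinism.  With
    ``exclude_self`` the query's own id is skipped.
    """
    if len(db) == 0:
        raise ValueError("cannot search an empty database")
    scored = []
    for target in db:
        if exclude_self and target.id == query.id:
            continue
        scored.append((target.id, motif_similarity(query, target, strategy).score))
    if not scored:
        log.warning("query %r: nothing to search after excluding itself", query.id)
    scored.sort(key=lambda ts: (-ts[1], ts[0]))
    return HitList(query_id=query.id, hits=scored)


def pairwise_scores(db: MotifDatabase, strategy: ScoringStrategy) -> np.ndarray:
    """Symmetric n x n matrix of motif similarities (each unordered pair scored once)."""
    n = len(db)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = motif_similarity(db.motifs[i], db.motifs[j], strategy).score
            S[i, j] = S[j, i] = s
    return S


def best_hit_accuracy(
    db: MotifDatabase,
    strategy: ScoringStrategy,
    scores: np.ndarray | None = None,
) -> AccuracyReport:
    """Fraction of queries whose top-ranked hit shares the query's family label.

    Every motif is used as a query with itself excluded.  A precomputed
    ``pairwise_scores`` matrix can be supplied to avoid re-alignment.
    """
    n = len(db)
    if n < 2:
        raise ValueError("best-hit accuracy needs at least two motifs")
    if scores is None:
        scores = pairwise_scores(db, strategy)
    labels = [m.family_label for m in db.motifs]
    ids = [m.id for m in db.motifs]
    label_sizes: dict[str, int] = {}
    for lab in labels:
        if lab is not None:
            label_sizes[lab] = label_sizes.get(lab, 0) + 1

    successes: dict[str, int] = {}
    evaluated: dict[str, int] = {}
    n_singletons = 0
    for qi in range(n):
        lab = labels[qi]
        if lab is None or label_sizes[lab] < 2:
            n_singletons += 1
            continue
        order = sorted((t for t in range(n) if t != qi),
                       key=lambda t: (-scores[qi, t], ids[t]))
        top = order[0]
        evaluated[lab] = evaluated.get(lab, 0) + 1
        if labels[top] == lab:
            successes[lab] = successes.get(lab, 0) + 1
    n_eval = sum(evaluated.values())
    if n_eval == 0:
        log.warning("best-hit accuracy: every family is a singleton; accuracy is 0")
        return AccuracyReport(overall=0.0, per_label={}, n_evaluated=0,
                              n_singletons=n_singletons)
    per_label = {lab: successes.get(lab, 0) / cnt for lab, cnt in sorted(evaluated.items())}
    overall = sum(successes.values()) / n_eval
    return AccuracyReport(overall=overall, per_label=per_label,
                          n_evaluated=n_eval, n_singletons=n_singletons)


def roc_curve(
    db: MotifDatabase,
    strategy: ScoringStrategy,
    include_self_pairs: bool = True,
    scores: np.ndarray | None = None,
) -> ROCCurve:
    """Pairwise ROC over all unordered motif pairs.

    With self-pairs included a database of n motifs yields n(n+1)/2 pairs.
    Motifs without a family label are treated as singleton families (a decoy
    never shares a family with anything else).  Raises if the labelling is
    degenerate (no cross-family pair to form a false-positive rate).
    """
    n = len(db)
    if scores is None:
        scores = pairwise_scores(db, strategy)
    labels = []
    for m in db.motifs:
        labels.append(m.family_label if m.family_label is not None else f"__decoy__{m.id}")

    pair_scores = []
    pair_same = []
    for i in range(n):
        start = i if include_self_pairs else i + 1
        for j in range(start, n):
            pair_scores.append(scores[i, j])
            pair_same.append(labels[i] == labels[j])
    pair_scores = np.asarray(pair_scores)
    pair_same = np.asarray(pair_same)
    n_pos = int(pair_same.sum())
    n_neg = int((~pair_same).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "degenerate labelling: need both same-family and cross-family pairs "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    thresholds = np.unique(pair_scores)[::-1]
    points = []
    for t in thresholds:
        match = pair_scores >= t
        tp = int((match & pair_same).sum())
        fp = int((match & ~pair_same).sum())
        points.append((float(t), tp / n_pos, fp / n_neg))
    # sentinel above the maximum score: nothing matches
    points.insert(0, (float("inf"), 0.0, 0.0))
    fpr = np.array([p[2] for p in points])  # ascending as the threshold drops
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(points=points, auc=auc, n_pairs=len(pair_scores))
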