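"""Column-to-column motif similarity metrics.

The central metric is SPIC (Similarity with Position Information Contents):
the cross-likelihood of one motif's PSSM column generating the other motif's
PFM column, weighted by the information content of the PSSM column, and
normalised by the larger of the two self-scores,

    S(P_i(A), F_j(B)) = I(A, P_i) * sum_b f_j(b, B) * log2(p_i(b, A) / q(b))

    Sim(X, Y) = min(1, max{S(P1(X), F2(Y)), S(P2(Y), F1(X))}
                        / max{S(P1(X), F1(X)), S(P2(Y), F2(Y))})

Negative values are kept (unrelated columns should score below zero so that
local alignment can terminate); when both self-scores are non-positive —
both columns carry no information — the similarity is defined as 0.

Also provided are the classical column metrics PCC, ALLR, AKL, SSD and pCS,
and the alignment-free whole-motif KFV (k-mer frequency vector) similarity.
All column metrics are symmetric.

Scalar functions operate on :class:`ColumnView`; the ``*_matrix`` forms
compute all L1 x L2 column pairs at once and are what the aligner uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .motifs import Background, Motif, MotifProfile, UNIFORM

__all__ = [
    "ColumnView",
    "METRIC_IDS",
    "spic_cross_score",
    "spic_column_similarity",
    "pcc_column",
    "allr_column",
    "akl_column",
    "ssd_column",
    "pcs_column",
    "kfv_similarity",
    "similarity_matrix",
    "column_metric",
]

log = logging.getLogger(__name__)

#: valid metric identifiers; "kfv" is alignment-free and whole-motif only
METRIC_IDS = ("spic", "pcc", "allr", "akl", "ssd", "pcs", "kfv")


@dataclass(frozen=True)
class ColumnView:
    """One motif column as the metrics see it.

    counts, probs and pssm are 4-vectors in A,C,G,T order; ``ic`` is the
    column information content in bits.
    """

    counts: np.ndarray
    probs: np.ndarray
    pssm: np.ndarray
    ic: float
    background: Background = UNIFORM

    @classmethod
    def from_profile(cls, profile: MotifProfile, column: int) -> "ColumnView":
        """Extract a 0-based column from a motif profile."""
        return cls(
            counts=profile.counts[:, column],
            probs=profile.probs[:, column],
            pssm=profile.pssm[:, column],
            ic=float(profile.ic[column]),
            background=profile.background,
        )

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def _as_profile_arrays(col: ColumnView):
    return (col.counts[:, None].astype(float), col.probs[:, None],
            col.pssm[:, None], np.array([col.ic]))


# --- SPIC -----------------------------------------------------------------

def spic_cross_score(source: ColumnView, target: ColumnView) -> float:
    """IC-weighted likelihood of the source PSSM column generating the target counts.

    Returns I(A) * sum_b f(b, B) * log2(p(b, A)/q(b)).  Zero whenever the
    source column is at background (IC = 0); negative when the target counts
    concentrate on bases the source disfavours.
    """
    if not np.isfinite(source.pssm).all():
        raise ValueError("SPIC requires finite PSSM entries; use a positive pseudocount")
    return float(source.ic * np.dot(target.counts, source.pssm))


def spic_column_similarity(x: ColumnView, y: ColumnView) -> float:
    """Normalised symmetric SPIC similarity between two columns; <= 1 always."""
    return float(_spic_matrix_from_arrays(
        x.counts[None].T.astype(float), x.pssm[None].T, np.array([x.ic]),
        y.counts[None].T.astype(float), y.pssm[None].T, np.array([y.ic]),
    )[0, 0])


def _spic_matrix_from_arrays(c1, s1, ic1, c2, s2, ic2) -> np.ndarray:
    if not (np.isfinite(s1).all() and np.isfinite(s2).all()):
        raise ValueError("SPIC requires finite PSSM entries; use a positive pseudocount")
    # cross scores: S(P1(X), F2(Y)) and S(P2(Y), F1(X)) for all column pairs
    cross12 = ic1[:, None] * (s1.T @ c2)
    cross21 = ic2[None, :] * (c1.T @ s2)
    num = np.maximum(cross12, cross21)
    self1 = ic1 * np.einsum("bi,bi->i", c1, s1)
    self2 = ic2 * np.einsum("bj,bj->j", c2, s2)
    den = np.maximum(self1[:, None], self2[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.minimum(1.0, num / den)
    # two no-information columns carry no evidence of relatedness
    return np.where(den > 0, sim, 0.0)


def spic_matrix(p1: MotifProfile, p2: MotifProfile) -> np.ndarray:
    return _spic_matrix_from_arrays(p1.counts.astype(float), p1.pssm, p1.ic,
                                    p2.counts.astype(float), p2.pssm, p2.ic)


# --- classical metrics ----------------------------------------------------

def pcc_column(x: ColumnView, y: ColumnView) -> float:
    """Pearson correlation of the two probability 4-vectors; 0 if either is uniform."""
    return float(pcc_matrix_probs(x.probs[:, None], y.probs[:, None])[0, 0])


def pcc_matrix_probs(probs1: np.ndarray, probs2: np.ndarray) -> np.ndarray:
    xc = probs1 - probs1.mean(axis=0)
    yc = probs2 - probs2.mean(axis=0)
    nx = np.linalg.norm(xc, axis=0)
    ny = np.linalg.norm(yc, axis=0)
    den = nx[:, None] * ny[None, :]
    degenerate = den == 0
    if degenerate.any():
        log.debug("PCC: uniform column (zero variance); returning 0 by convention")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / den
    return np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))


def allr_column(x: ColumnView, y: ColumnView) -> float:
    """Average log-likelihood ratio: raw counts scored against the other column's
    pseudocounted probabilities, averaged over the total count."""
    q = x.background.q
    _require_positive(x.probs, "ALLR")
    _require_positive(y.probs, "ALLR")
    num = np.dot(x.counts, np.log2(y.probs / q)) + np.dot(y.counts, np.log2(x.probs / q))
    return float(num / (x.counts.sum() + y.counts.sum()))


def allr_matrix(p1: MotifProfile, p2: MotifProfile) -> np.ndarray:
    q = p1.background.q[:, None]
    lr1 = np.log2(p1.probs / q)
    lr2 = np.log2(p2.probs / q)
    c1 = p1.counts.astype(float)
    c2 = p2.counts.astype(float)
    num = c1.T @ lr2 + lr1.T @ c2  # (L1, L2)
    den = c1.sum(axis=0)[:, None] + c2.sum(axis=0)[None, :]
    return num / den


def akl_column(x: ColumnView, y: ColumnView) -> float:
    """10 minus the symmetrised Kullback-Leibler divergence (log2); max 10 at identity."""
    _require_positive(x.probs, "AKL")
    _require_positive(y.probs, "AKL")
    kl_xy = np.dot(x.probs, np.log2(x.probs / y.probs))
    kl_yx = np.dot(y.probs, np.log2(y.probs / x.probs))
    return float(10.0 - (kl_xy + kl_yx) / 2.0)


def akl_matrix(p1: MotifProfile, p2: MotifProfile) -> np.ndarray:
    e1 = np.einsum("bi,bi->i", p1.probs, np.log2(p1.probs))
    e2 = np.einsum("bj,bj->j", p2.probs, np.log2(p2.probs))
    kl12 = e1[:, None] - p1.probs.T @ np.log2(p2.probs)
    kl21 = e2[None, :] - (p2.probs.T @ np.log2(p1.probs)).T
    return 10.0 - (kl12 + kl21) / 2.0


def ssd_column(x: ColumnView, y: ColumnView) -> float:
    """2 minus the squared Euclidean distance between probability vectors; in [0, 2]."""
    d = x.probs - y.probs
    return float(2.0 - np.dot(d, d))


def ssd_matrix(p1: MotifProfile, p2: MotifProfile) -> np.ndarray:
    sq1 = np.einsum("bi,bi->i", p1.probs, p1.probs)
    sq2 = np.einsum("bj,bj->j", p2.probs, p2.probs)
    return 2.0 - (sq1[:, None] + sq2[None, :] - 2.0 * p1.probs.T @ p2.probs)


def pcs_column(x: ColumnView, y: ColumnView) -> float:
    """Chi-square homogeneity p-value of the two count columns.

    A 2 x 4 contingency test with pooled expected counts
    E_Xb = N_X (N_Xb + N_Yb) / (N_X + N_Y); bases absent from both columns
    contribute nothing and reduce the degrees of freedom.  Identical
    compositions give similarity 1; clearly different columns approach 0.
    """
    return float(pcs_matrix_counts(x.counts[:, None], y.counts[:, None])[0, 0])


def pcs_matrix_counts(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    c1 = c1.astype(float)
    c2 = c2.astype(float)
    n1 = c1.sum(axis=0)  # (L1,)
    n2 = c2.sum(axis=0)  # (L2,)
    pooled = c1[:, :, None] + c2[:, None, :]          # (4, L1, L2)
    total = n1[:, None] + n2[None, :]                  # (L1, L2)
    e1 = n1[:, None] * pooled / total                  # expected for column X
    e2 = n2[None, :] * pooled / total
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (c1[:, :, None] - e1) ** 2 / e1
        t2 = (c2[:, None, :] - e2) ** 2 / e2
    present = pooled > 0
    stat = (np.where(present, t1, 0.0) + np.where(present, t2, 0.0)).sum(axis=0)
    df = present.sum(axis=0) - 1
    sim = np.ones_like(stat)
    ok = df > 0
    sim[ok] = chi2.sf(stat[ok], df[ok])
    return sim


def _require_positive(probs: np.ndarray, name: str) -> None:
    if np.any(probs <= 0):
        raise ValueError(f"{name} requires strictly positive probabilities; "
                         "use a positive pseudocount")


# --- KFV ------------------------------------------------------------------

def kfv_similarity(
    m1: Motif,
    m2: Motif,
    k: int = 4,
    background: Background = UNIFORM,
    pseudocount: float = 1.0,
) -> float:
    """Alignment-free k-mer frequency vector similarity.

    Each motif is converted into a 4^k-dimensional vector of expected k-mer
    frequencies under the column-independence model, summed over all
    L - k + 1 sliding windows; the similarity is the cosine of the angle
    between the two vectors, in [0, 1].  If either motif is shorter than k,
    k is reduced to the shorter length for both.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, m1.length, m2.length)
    v1 = _kmer_vector(m1, k, background, pseudocount)
    v2 = _kmer_vector(m2, k, background, pseudocount)
    return float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))


def _kmer_vector(m: Motif, k: int, background: Background, pseudocount: float) -> np.ndarray:
    probs = MotifProfile.from_motif(m, background, pseudocount).probs
    vec = np.zeros(4 ** k)
    for start in range(m.length - k + 1):
        window = np.ones(1)
        for j in range(start, start + k):
            window = np.multiply.outer(window, probs[:, j]).ravel()
        vec += window
    return vec


# --- dispatch -------------------------------------------------------------

_MATRIX_FORMS = {
    "spic": spic_matrix,
    "pcc": lambda p1, p2: pcc_matrix_probs(p1.probs, p2.probs),
    "allr": allr_matrix,
    "akl": akl_matrix,
    "ssd": ssd_matrix,
    "pcs": lambda p1, p2: pcs_matrix_counts(p1.counts, p2.counts),
}

_COLUMN_FORMS = {
    "spic": spic_column_similarity,
    "pcc": pcc_column,
    "allr": allr_column,
    "akl": akl_column,
    "ssd": ssd_column,
    "pcs": pcs_column,
}


def similarity_matrix(p1: MotifProfile, p2: MotifProfile, metric: str) -> np.ndarray:
    """All-pairs column similarity matrix (L1 x L2) for a column metric."""
    try:
        return _MATRIX_FORMS[metric](p1, p2)
    except KeyError:
        raise ValueError(
            f"{metric!r} is not a column metric; choose from {sorted(_MATRIX_FORMS)}"
        ) from None


def column_metric(metric: str):
    """The scalar column function for a metric id."""
    try:
        return _COLUMN_FORMS[metric]
    except KeyError:
        raise ValueError(
            f"{metric!r} is not a column metric; choose from {sorted(_COLUMN_FORMS)}"
        ) from None
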