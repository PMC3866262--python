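"""Motif data model.

A transcription-factor binding-site motif is represented by its position
frequency matrix (PFM): a 4 x L matrix of base counts over the alphabet
A, C, G, T, one column per aligned site position.  From the PFM and a
background base distribution we derive

* the probability matrix (pseudocounted column base probabilities),
* the position-specific scoring matrix (PSSM) of log2 probability/background
  ratios, and
* the per-column information content (IC), the Kullback-Leibler divergence
  of the column distribution from background, in bits.

All matrices use the fixed base order A, C, G, T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BASES",
    "BASE_INDEX",
    "Background",
    "Motif",
    "ProbabilityMatrix",
    "ScoringMatrix",
    "ICProfile",
    "MotifProfile",
    "build_probability_matrix",
    "build_scoring_matrix",
    "information_content",
    "column_information_content",
    "reverse_complement",
]

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# A<->T, C<->G under the fixed A,C,G,T row order
_COMPLEMENT_ROWS = np.array([3, 2, 1, 0])
_COMPLEMENT_TABLE = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Background:
    """Background base distribution q(b) over A, C, G, T."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        if q.shape != (4,):
            raise ValueError("background must have one probability per base A,C,G,T")
        if np.any(q <= 0):
            raise ValueError("background probabilities must be strictly positive")
        if abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        object.__setattr__(self, "q", q)

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))


UNIFORM = Background.uniform()


@dataclass
class Motif:
    """A motif: base-count matrix plus identity and optional raw sites.

    Parameters
    ----------
    id : unique motif identifier.
    counts : (4, L) non-negative integer matrix, rows in A,C,G,T order.
    tf_name : optional transcription factor name.
    family_label : optional family / structural-class tag used as the
        ground-truth grouping in retrieval evaluation.
    sites : optional list of equal-length DNA strings whose per-column
        tally must equal ``counts``.
    """

    id: str
    counts: np.ndarray
    tf_name: str | None = None
    family_label: str | None = None
    sites: list[str] | None = None
    n_sites: int = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"motif {self.id!r}: counts must be a 4 x L matrix with L >= 1")
        if np.any(counts < 0):
            raise ValueError(f"motif {self.id!r}: negative count")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError(f"motif {self.id!r}: counts must be integers")
            counts = np.round(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        self.counts = counts
        col_sums = counts.sum(axis=0)
        if col_sums.min() < 1:
            raise ValueError(f"motif {self.id!r}: empty column (sum 0)")
        if col_sums.min() != col_sums.max():
            log.warning(
                "motif %r: unequal column sums (%d..%d); using the maximum as n_sites",
                self.id, col_sums.min(), col_sums.max(),
            )
        self.n_sites = int(col_sums.max())
        if self.sites is not None:
            self._check_sites()

    def _check_sites(self) -> None:
        L = self.length
        tally = np.zeros((4, L), dtype=np.int64)
        for s in self.sites:
            if len(s) != L:
                raise ValueError(f"motif {self.id!r}: site length {len(s)} != motif length {L}")
            for j, b in enumerate(s.upper()):
                if b not in BASE_INDEX:
                    raise ValueError(f"motif {self.id!r}: non-ACGT base {b!r} in site")
                tally[BASE_INDEX[b], j] += 1
        if not np.array_equal(tally, self.counts):
            raise ValueError(f"motif {self.id!r}: counts do not match the site tally")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_sites(
        cls,
        id: str,
        sites: Sequence[str],
        tf_name: str | None = None,
        family_label: str | None = None,
    ) -> "Motif":
        """Build a motif by tallying equal-length ACGT site strings."""
        sites = [s.upper() for s in sites]
        if not sites:
            raise ValueError(f"motif {id!r}: no sites")
        L = len(sites[0])
        for s in sites:
            if len(s) != L:
                raise ValueError(f"motif {id!r}: ragged site lengths ({len(s)} vs {L})")
        counts = np.zeros((4, L), dtype=np.int64)
        for s in sites:
            for j, b in enumerate(s):
                if b not in BASE_INDEX:
                    raise ValueError(f"motif {id!r}: non-ACGT base {b!r} in site")
                counts[BASE_INDEX[b], j] += 1
        return cls(id=id, counts=counts, tf_name=tf_name, family_label=family_label,
                   sites=list(sites))

    def reverse_complement(self) -> "Motif":
        return reverse_complement(self)


def reverse_complement(motif: Motif) -> Motif:
    """Reverse-complement a motif: reverse the columns, swap A<->T and C<->G rows.

    An involution: applying it twice restores the input.
    """
    counts = motif.counts[_COMPLEMENT_ROWS][:, ::-1].copy()
    sites = None
    if motif.sites is not None:
        sites = [s.translate(_COMPLEMENT_TABLE)[::-1] for s in motif.sites]
    return Motif(id=motif.id, counts=counts, tf_name=motif.tf_name,
                 family_label=motif.family_label, sites=sites)


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Pseudocounted per-column base probabilities p(b, X); columns sum to 1."""

    probs: np.ndarray
    pseudocount: float


@dataclass(frozen=True)
class ScoringMatrix:
    """PSSM entries log2(p(b, X) / q(b))."""

    scores: np.ndarray


@dataclass(frozen=True)
class ICProfile:
    """Per-column information content in bits; 0 <= IC <= 2 under uniform background."""

    ic: np.ndarray


def build_probability_matrix(
    motif: Motif,
    background: Background = UNIFORM,
    pseudocount: float = 1.0,
) -> ProbabilityMatrix:
    """Turn counts into column probabilities.

    p(b, X) = (f(b, X) + c * q(b)) / (n + c) with total pseudocount mass ``c``
    spread according to the background.  With c = 0 a zero count yields a zero
    probability, which downstream log-taking operations reject.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    n = motif.counts.sum(axis=0)  # per-column totals; may differ across columns
    probs = (motif.counts + pseudocount * background.q[:, None]) / (n + pseudocount)
    if pseudocount == 0 and np.any(motif.counts == 0):
        log.debug("motif %r: zero counts with zero pseudocount; PSSM construction will fail",
                  motif.id)
    return ProbabilityMatrix(probs=probs, pseudocount=float(pseudocount))


def build_scoring_matrix(ppm: ProbabilityMatrix, background: Background = UNIFORM) -> ScoringMatrix:
    """PSSM: log2 ratio of column probability to background."""
    if np.any(ppm.probs <= 0):
        raise ValueError(
            "probability matrix contains zero entries; rebuild with a positive pseudocount"
        )
    return ScoringMatrix(scores=np.log2(ppm.probs / background.q[:, None]))


def information_content(ppm: ProbabilityMatrix, background: Background = UNIFORM) -> ICProfile:
    """Per-column IC in bits: sum_b p(b,X) log2(p(b,X)/q(b)), with 0*log(0) = 0."""
    p = ppm.probs
    terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / background.q[:, None]), 0.0)
    return ICProfile(ic=terms.sum(axis=0))


def column_information_content(ppm: ProbabilityMatrix, pssm: ScoringMatrix, column: int) -> float:
    """IC of one column (1-based index) from its probabilities and PSSM scores."""
    L = ppm.probs.shape[1]
    if not 1 <= column <= L:
        raise IndexError(f"column {column} out of range 1..{L}")
    p = ppm.probs[:, column - 1]
    s = pssm.scores[:, column - 1]
    return float(np.sum(np.where(p > 0, p * s, 0.0)))


@dataclass(frozen=True)
class MotifProfile:
    """Bundle of everything the metrics need for one motif.

    Holds the raw counts, pseudocounted probabilities, PSSM and IC profile,
    all computed against one background and pseudocount so the numbers are
    mutually consistent.
    """

    motif: Motif
    background: Background
    pseudocount: float
    counts: np.ndarray
    probs: np.ndarray
    pssm: np.ndarray
    ic: np.ndarray

    @classmethod
    def from_motif(
        cls,
        motif: Motif,
        background: Background = UNIFORM,
        pseudocount: float = 1.0,
    ) -> "MotifProfile":
        ppm = build_probability_matrix(motif, background, pseudocount)
        # lenient PSSM: zero probabilities map to -inf so that probability-only
        # metrics still work at pseudocount 0; log-based metrics must reject them
        with np.errstate(divide="ignore"):
            pssm = np.where(ppm.probs > 0,
                            np.log2(np.where(ppm.probs > 0, ppm.probs, 1.0)
                                    / background.q[:, None]),
                            -np.inf)
        icp = information_content(ppm, background)
        return cls(motif=motif, background=background, pseudocount=float(pseudocount),
                   counts=motif.counts, probs=ppm.probs, pssm=pssm, ic=icp.ic)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def reverse_complement(self) -> "MotifProfile":
        return MotifProfile.from_motif(reverse_complement(self.motif),
                                       self.background, self.pseudocount)
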