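"""Seeded synthetic motifs, families and decoy databases.

Real benchmark collections of TF motifs (curated eukaryotic motif sets with
structural-class labels; bacterial predictions dominated by spurious
low-information motifs) are emulated here with three generators:

* a single motif sampled column-independently from per-column distributions
  tuned to a target information content,
* a family of motifs derived from one ancestral site set by independent
  per-base mutation, and
* a labelled database of several such families plus unlabelled low-IC
  decoys.

Every generator is a pure function of its spec and seed.  The per-column
distribution for a target IC is a single-dominant-base mixture: the dominant
base probability is solved numerically from the IC equation and the
remaining mass is split evenly across the other three bases — simple,
monotone in IC, and invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .motifs import BASES, Motif
from .retrieval import MotifDatabase

__all__ = [
    "MotifSpec",
    "DatabaseSpec",
    "dominant_base_probability",
    "generate_motif",
    "generate_family",
    "generate_database",
]


@dataclass(frozen=True)
class MotifSpec:
    """Recipe for one random motif.

    ``column_ic`` gives the target information content per column, in bits
    (a scalar is broadcast to every column).  ``consensus`` fixes the
    dominant base of each column; otherwise dominant bases are drawn
    uniformly.  The realised IC approaches the target as n_sites grows.
    """

    length: int
    n_sites: int
    column_ic: float | tuple[float, ...] = 1.0
    consensus: str | None = None
    seed: int = 0
    id: str = "synthetic"

    def ic_vector(self) -> np.ndarray:
        ic = np.broadcast_to(np.atleast_1d(np.asarray(self.column_ic, dtype=float)),
                             (self.length,))
        if np.any(ic < 0) or np.any(ic > 2):
            raise ValueError("target column IC must lie in [0, 2] bits")
        return np.asarray(ic)


@dataclass(frozen=True)
class DatabaseSpec:
    """Recipe for a labelled family database with low-IC decoys.

    Defaults describe the desk-scale benchmark used throughout the test
    suite: 8 families of 4 members mutated at 15% per base from a common
    ancestor of 10 sites, plus 40 unlabelled decoys whose columns carry at
    most ``decoy_ic`` bits.
    """

    n_families: int = 8
    motifs_per_family: int = 4
    mutation_rate: float = 0.15
    n_decoys: int = 40
    n_sites: int = 10
    family_length_range: tuple[int, int] = (8, 16)
    family_ic_range: tuple[float, float] = (0.8, 2.0)
    decoy_length_range: tuple[int, int] = (8, 20)
    decoy_ic: float = 0.3
    seed: int = 0


def dominant_base_probability(ic: float) -> float:
    """Dominant-base probability p giving column IC ``ic`` bits (uniform background).

    Solves ic = p log2(4p) + (1-p) log2(4(1-p)/3) for p in [1/4, 1].
    """
    if not 0 <= ic <= 2:
        raise ValueError("IC must lie in [0, 2] bits")
    if ic == 0:
        return 0.25
    if ic == 2:
        return 1.0

    def f(p: float) -> float:
        rest = (1 - p) / 3
        val = p * np.log2(4 * p)
        if rest > 0:
            val += (1 - p) * np.log2(4 * rest)
        return val - ic

    return float(brentq(f, 0.25, 1 - 1e-12, xtol=1e-12))


def _column_distribution(ic: float, dominant: int) -> np.ndarray:
    p = dominant_base_probability(ic)
    dist = np.full(4, (1 - p) / 3)
    dist[dominant] = p
    return dist


def generate_motif(spec: MotifSpec) -> Motif:
    """Sample a motif (with sites attached) from a per-column IC profile."""
    rng = np.random.default_rng(spec.seed)
    ic = spec.ic_vector()
    if spec.consensus is not None:
        if len(spec.consensus) != spec.length:
            raise ValueError("consensus length must equal motif length")
        dominants = [BASES.index(b) for b in spec.consensus.upper()]
    else:
        dominants = rng.integers(0, 4, size=spec.length)
    site_matrix = np.empty((spec.n_sites, spec.length), dtype=np.int64)
    for j in range(spec.length):
        dist = _column_distribution(float(ic[j]), int(dominants[j]))
        site_matrix[:, j] = rng.choice(4, size=spec.n_sites, p=dist)
    sites = ["".join(BASES[b] for b in row) for row in site_matrix]
    return Motif.from_sites(id=spec.id, sites=sites)


def generate_family(
    ancestor: Motif,
    n_children: int,
    mutation_rate: float,
    seed: int,
) -> list[Motif]:
    """Derive a family from one ancestral site set by per-base mutation.

    Each child copies the ancestor's sites and independently replaces each
    base, with probability ``mutation_rate``, by a uniformly chosen one of
    the three other bases.  Children inherit the ancestor's family label.
    """
    if ancestor.sites is None:
        raise ValueError(f"ancestor {ancestor.id!r} has no sites to mutate")
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base_matrix = np.array([[BASES.index(b) for b in s] for s in ancestor.sites])
    children = []
    for c in range(n_children):
        mutate = rng.random(base_matrix.shape) < mutation_rate
        shifts = rng.integers(1, 4, size=base_matrix.shape)
        mutated = np.where(mutate, (base_matrix + shifts) % 4, base_matrix)
        sites = ["".join(BASES[b] for b in row) for row in mutated]
        children.append(Motif.from_sites(
            id=f"{ancestor.id}_c{c + 1}", sites=sites,
            family_label=ancestor.family_label,
        ))
    return children


def generate_database(spec: DatabaseSpec) -> MotifDatabase:
    """A labelled family database plus unlabelled low-IC decoys, order-shuffled."""
    rng = np.random.default_rng(spec.seed)
    motifs: list[Motif] = []
    for f in range(spec.n_families):
        length = int(rng.integers(spec.family_length_range[0],
                                  spec.family_length_range[1] + 1))
        ic = tuple(rng.uniform(*spec.family_ic_range, size=length))
        ancestor = generate_motif(MotifSpec(
            length=length, n_sites=spec.n_sites, column_ic=ic,
            seed=int(rng.integers(2**31)), id=f"fam{f + 1}",
        ))
        ancestor.family_label = f"fam{f + 1}"
        motifs.extend(generate_family(ancestor, spec.motifs_per_family,
                                      spec.mutation_rate, seed=int(rng.integers(2**31))))
    for d in range(spec.n_decoys):
        length = int(rng.integers(spec.decoy_length_range[0],
                                  spec.decoy_length_range[1] + 1))
        ic = tuple(rng.uniform(0.0, spec.decoy_ic, size=length))
        motifs.append(generate_motif(MotifSpec(
            length=length, n_sites=spec.n_sites, column_ic=ic,
            seed=int(rng.integers(2**31)), id=f"decoy{d + 1}",
        )))
    order = rng.permutation(len(motifs))
    return MotifDatabase(motifs=[motifs[i] for i in order])
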