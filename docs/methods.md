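# Methods

## Motif model

A motif is a 4 × L position frequency matrix (PFM) of base counts over
A, C, G, T, with `n_sites` sites per column, optionally carrying the raw
site strings. Column probabilities are pseudocounted as
p(b, X) = (f(b, X) + c·q(b)) / (n + c), where the total pseudocount mass
c (default 1) is distributed according to the background q (default
uniform 0.25). The PSSM is log₂(p/q) and the column information content
(IC) is the Kullback–Leibler divergence of p from q in bits, bounded by
2 bits under a uniform background. All logarithms are base 2: the base
only rescales scores uniformly and changes no ranking, alignment or ROC
outcome, and bits are the motif-literature convention.

With pseudocount 0 a zero count produces a zero probability;
`build_scoring_matrix` rejects such matrices, while `MotifProfile` maps
them to −∞ PSSM entries so that probability-only metrics (PCC, SSD, AKL
on positive inputs, KFV) remain usable. SPIC and ALLR require finite
log-ratios and raise with a clear message instead.

## Column metrics

* **SPIC** — cross score S(Pᵢ(A), Fⱼ(B)) = I(A)·Σ_b fⱼ(b, B)·log₂(pᵢ(b, A)/q(b));
  similarity = min(1, best cross score / best self score). Two conventions
  are fixed deliberately: (i) when both self scores are ≤ 0 (both columns at
  background) the similarity is 0 — no-information columns carry no evidence
  of relatedness, and this avoids 0/0; (ii) negative similarities are *not*
  floored, because local alignment needs an expected negative score for
  unrelated columns.
* **PCC** — Pearson correlation of the two probability 4-vectors; a uniform
  column has zero variance and returns 0 by convention (logged).
* **ALLR** — raw counts of each column scored against the *other* column's
  pseudocounted probabilities, normalised by the total count.
* **AKL** — 10 − symmetrised KL divergence / 2 (log₂); maximum 10 at identity.
* **SSD** — 2 − squared Euclidean distance between probability vectors.
* **pCS** — chi-square homogeneity p-value of the 2 × 4 count table with
  pooled expected counts E_Xb = N_X(N_Xb + N_Yb)/(N_X + N_Y); bases absent
  from both columns are dropped and the degrees of freedom reduced. The
  p-value itself is returned as the similarity (identical columns → 1):
  although the metric is traditionally *named* "1 − p-value", returning
  1 − p would score identical columns 0, which is unusable as a similarity;
  the usable direction is the one established practice follows.
* **KFV** — each motif becomes a 4^k-dimensional vector of expected k-mer
  frequencies under column independence (product of column probabilities,
  summed over all L − k + 1 windows; k reduced to the shorter length when a
  motif is shorter than k, default k = 4), compared by cosine. Strand
  handling happens at the whole-motif level, not inside the vector.

## Alignment

Three-state Gotoh dynamic programming with affine gaps: a gap run of length
g costs open + (g − 1)·extend; extend defaults to open/2. All transitions
between gap states are allowed, so a deletion run followed directly by an
insertion run pays two gap-opens, matching the enumeration semantics the
tests verify exhaustively for short motifs. Numerical choices:

* **NW end gaps** are penalised like internal gaps (true global alignment).
* **SW** floors at 0; the empty alignment is reported with empty pairs, not
  an error. Alignments start and end with an aligned pair.
* **SWU** maximises the sum of a contiguous diagonal run over all offsets
  (exact scan, no gap parameters).
* **Traceback ties** prefer the diagonal, then a gap in the second motif,
  then a gap in the first — results are deterministic.
* **Orientation**: by default both the forward and reverse-complement
  orientation of the second motif are scored and the maximum kept (forward
  wins ties); a flag disables this to reproduce strand-naive behaviour.
  When the reported orientation is `revcomp`, pair indices refer to the
  reverse-complemented second motif so they stay strictly increasing.
* **min_overlap** (default 1) discards alignments with fewer aligned pairs.

The empirical p-value scores the first motif against column-shuffled copies
of the second (shuffling preserves the column IC multiset) and reports the
add-one estimator (1 + #{null ≥ observed}) / (1 + n_shuffles), with 1000
shuffles by default.

## Retrieval and ROC evaluation

`best_hit_accuracy` queries every motif against the rest of the database and
counts a success when the top hit shares the query's family label. Queries
whose label has no second member (including unlabelled decoys) can never
succeed; they are excluded from the overall fraction and reported separately
as singletons. Ranking ties break lexicographically by id.

`roc_curve` enumerates all n(n+1)/2 unordered pairs — self-pairs included by
default, with a flag to exclude them — and sweeps thresholds over the
observed scores (score ≥ threshold is a match). Same-label matches are true
positives, cross-label matches false positives; AUC is the trapezoid rule
over the resulting step curve. Unlabelled motifs are treated as singleton
families. A labelling without any cross-family pair is rejected.

## Sub-motif splitting and overlap

A motif with n ≥ 3 sites is split, for each k in 1..⌊n/2⌋, by one uniform
random bipartition of its site multiset into sizes (k, n − k); the same rule
recurses into every sub-motif of size ≥ 2 down to size 1. The total number
of pairs follows P(n) = ⌊n/2⌋ + Σₖ (P(k) + P(n − k)), which grows roughly
geometrically — about 400 pairs at n = 10 and ~2×10⁵ by n = 20 — so the
module also exposes `expected_pair_count` and a `max_depth` cap for large
site sets; the benchmark splits motifs of 10 sites in full.

Scoring each pair's halves against each other gives the "known inner"
distribution; scoring all database pairs gives the "all pairs" distribution.
Both are mapped to [0, 1] by a *joint* min–max transform (order-preserving,
shared across the two sets so their relative placement survives), binned on
a shared 100-bin grid (configurable), and the overlap rate is Σ_bins
min(mass_inner, mass_all): 1 for identical distributions, 0 for disjoint
ones. Sub-motifs of size 1 participate and are pseudocounted like any
other motif.

## Synthetic data

The generators emulate the structure of the standard evaluation corpora:
family-labelled eukaryotic motif collections for retrieval, and a large
pool of spurious low-information motifs for the separation experiment.

* `generate_motif` samples sites column-independently from a
  single-dominant-base distribution whose dominant probability is solved
  numerically (Brent) from the IC equation, the remaining mass split evenly
  over the other three bases — simple, monotone in IC, invertible. Realised
  IC converges to the target as n_sites grows.
* `generate_family` copies an ancestral site set and mutates each base
  independently, with the given rate, to a uniformly chosen *other* base
  (at rate 1 no base survives).
* `generate_database` defaults define the benchmark: 8 families × 4 members,
  mutation rate 0.15, family lengths 8–16 with per-column IC in [0.8, 2.0]
  bits, 40 unlabelled decoys of lengths 8–20 with per-column IC ≤ 0.3 bits,
  and 10 sites per motif — site counts typical of curated bacterial motif
  collections, and small enough that the full split recursion stays
  tractable. All generators are pure functions of spec + seed.

What the generator does *not* model: positional correlation within sites,
phylogenetic relatedness between sites, variable site counts within a
family, mixed-width families, or compositional background bias. Passing
benchmarks on these data therefore demonstrates correctness of the metrics
and machinery and the expected qualitative ordering under idealised family
structure, not performance on any curated database.

## Benchmark and problem sizes

`run_benchmark` compares SPIC/SW(open 1, extend 0.5) against PCC/SWU,
SSD/SW(1, 0.5) and AKL/SW(1, 0.5) — the strongest classical combinations —
on one generated database: best-hit accuracy over the 32 labelled motifs,
ROC AUC over all 2 628 pairs, and the overlap rate from splitting one
representative per family (≈ 3 300 inner pairs against 2 556 all-pairs
scores). These sizes keep a full run around a minute on one core while
leaving every quantity statistically stable across seeds.

## Known limitations

* Best-hit accuracy and SW scores of the always-positive metrics (SSD, AKL,
  pCS) grow with motif length, so length confounds their rankings; this is
  a property of those metrics, not of the harness.
* `min_overlap` > 1 filters the single best alignment rather than
  re-optimising over constrained alignments.
* No multiple-motif alignment, familial-binding-profile construction, or
  higher-order (dinucleotide) motif models.
* The asymptotic-covariance (AC) metric is not implemented (historically
  computed by an external package).
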