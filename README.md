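# motifcompare

Compare transcription-factor binding-site (TFBS) motifs — position frequency
matrices (PFMs) — with **SPIC**, an information-content-weighted column
similarity metric, alongside the classical column metrics (PCC, ALLR, AKL,
SSD, pCS) and the alignment-free KFV k-mer score.

Motif discovery pipelines constantly need to ask whether two motifs are "the
same": to retrieve a motif from a database such as JASPAR, to merge redundant
sub-motifs of one TF, or to discard the spurious low-information motifs that
dominate genome-wide phylogenetic-footprinting predictions. That requires a
column-to-column similarity and an alignment of motif columns. `motifcompare`
implements both, plus the evaluation machinery (best-hit retrieval accuracy,
pairwise ROC, sub-motif split / distribution-overlap analysis) and seeded
synthetic motif generators so everything is testable without downloads.

## The SPIC metric

For a motif with PFM *F* = *f*(*b*, *X*) over *n* sites, the pseudocounted
column probabilities are *p*(*b*, *X*) = (*f*(*b*, *X*) + *c·q*(*b*)) / (*n* + *c*),
the PSSM is *P*(*b*, *X*) = log₂(*p*(*b*, *X*)/*q*(*b*)), and the column
information content is *I*(*X*) = Σ_b *p*(*b*, *X*)·log₂(*p*(*b*, *X*)/*q*(*b*))
(bits; *q* is the background, uniform 0.25 by default).

The cross score of a PSSM column *A* of motif 1 against a PFM column *B* of
motif 2 is the IC-weighted log-likelihood

> S(P₁(A), F₂(B)) = I(A, P₁) · Σ_b f₂(b, B) · log₂(p₁(b, A)/q(b))

and the symmetric column similarity normalises the better of the two cross
scores by the better self score:

> Sim(X, Y) = min(1, max{S(P₁(X), F₂(Y)), S(P₂(Y), F₁(X))} / max{S(P₁(X), F₁(X)), S(P₂(Y), F₂(Y))})

High-information columns dominate; uninformative columns contribute nothing
(two background columns score 0 by convention), and mismatched columns score
*negative*, which is exactly what local alignment needs to terminate.

Motif-level similarity is the best column alignment under an affine gap
penalty (a gap run of length *g* costs open + (*g*−1)·extend, extend
defaulting to open/2): global (NW), local (SW), or ungapped local (SWU),
optionally maximised over both strands, with an empirical p-value from a
column-shuffle null.

## Worked example

```python
from motifcompare import (Motif, ScoringStrategy, GapPenalty,
                          motif_similarity, empirical_pvalue)

crp_like = Motif.from_sites("crpA", [
    "TGTGATCTAGATCACA", "TGTGATTTAGATCACG", "TTTGATCGAGTTCACA",
    "TGTGACGTAGGTCACA", "TGCGATCTAGCTCACA", "TGTGATCTGGATCACT",
])
# the same sites shifted left by two columns
shifted = Motif.from_sites("crpB", [s[2:] + "AT" for s in crp_like.sites])

strategy = ScoringStrategy(metric="spic", mode="SW", gap=GapPenalty(1.0, 0.5))
res = motif_similarity(crp_like, shifted, strategy)
print(f"score={res.score:.3f} orientation={res.orientation}")
print("aligned pairs:", res.pairs)
print(f"empirical p-value: "
      f"{empirical_pvalue(crp_like, shifted, strategy, 1000, seed=7):.4f}")
```

prints

```
score=14.000 orientation=forward
aligned pairs: [(3, 1), (4, 2), (5, 3), (6, 4), (7, 5), (8, 6), (9, 7), (10, 8), (11, 9), (12, 10), (13, 11), (14, 12), (15, 13), (16, 14)]
empirical p-value: 0.0010
```

The local alignment recovers the two-column shift exactly: 14 informative
column pairs each scoring ≈ 1 give a score of 14, and only 1 of 1000
column-shuffled nulls matches it (the add-one p-value floor).

A CLI mirrors the library:

```
motifcompare synth --preset families --seed 3 --out bench/
motifcompare score  --query bench/motifs.jaspar --target bench/motifs.jaspar
motifcompare search --db bench/motifs.jaspar --query my_motif.jaspar --top 5
motifcompare roc    --db bench/motifs.jaspar --labels bench/labels.tsv
motifcompare split-eval --db bench/motifs.jaspar --sites bench/sites --seed 1
```

JASPAR-style and TRANSFAC-style matrix files and site FASTA are supported.

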