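"""Independent brute-force oracles used by the test suite.

Everything here is written from the defining formulas with plain Python
arithmetic (or exhaustive enumeration), deliberately sharing no code with
the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import chi2 as chi2_dist

Q = 0.25  # uniform background


# --- column-level formulas -------------------------------------------------

def probs(counts, pseudo: float):
    counts = [float(c) for c in counts]
    n = sum(counts)
    return [(c + pseudo * Q) / (n + pseudo) for c in counts]


def ic_bits(p):
    return sum(pi * math.log2(pi / Q) for pi in p if pi > 0)


def spic_cross(counts_src, counts_tgt, pseudo: float) -> float:
    ps = probs(counts_src, pseudo)
    weight = ic_bits(ps)
    return weight * sum(counts_tgt[b] * math.log2(ps[b] / Q) for b in range(4))


def spic_sim(cx, cy, pseudo: float) -> float:
    num = max(spic_cross(cx, cy, pseudo), spic_cross(cy, cx, pseudo))
    den = max(spic_cross(cx, cx, pseudo), spic_cross(cy, cy, pseudo))
    if den <= 0:
        return 0.0
    return min(1.0, num / den)


def pcc(px, py) -> float:
    mx = sum(px) / 4
    my = sum(py) / 4
    sx = [p - mx for p in px]
    sy = [p - my for p in py]
    den = math.sqrt(sum(v * v for v in sx)) * math.sqrt(sum(v * v for v in sy))
    if den == 0:
        return 0.0
    return sum(a * b for a, b in zip(sx, sy)) / den


def allr(cx, cy, pseudo: float) -> float:
    px = probs(cx, pseudo)
    py = probs(cy, pseudo)
    num = sum(cx[b] * math.log2(py[b] / Q) for b in range(4))
    num += sum(cy[b] * math.log2(px[b] / Q) for b in range(4))
    return num / (sum(cx) + sum(cy))


def akl(px, py) -> float:
    kl_xy = sum(a * math.log2(a / b) for a, b in zip(px, py))
    kl_yx = sum(b * math.log2(b / a) for a, b in zip(px, py))
    return 10.0 - (kl_xy + kl_yx) / 2.0


def ssd(px, py) -> float:
    return 2.0 - sum((a - b) ** 2 for a, b in zip(px, py))


def pcs(cx, cy) -> float:
    nx = sum(cx)
    ny = sum(cy)
    stat = 0.0
    df = -1
    for b in range(4):
        pooled = cx[b] + cy[b]
        if pooled == 0:
            continue
        df += 1
        ex = nx * pooled / (nx + ny)
        ey = ny * pooled / (nx + ny)
        stat += (cx[b] - ex) ** 2 / ex + (cy[b] - ey) ** 2 / ey
    if df <= 0:
        return 1.0
    return float(chi2_dist.sf(stat, df))


def kfv(counts1, counts2, k: int, pseudo: float) -> float:
    """Cosine of expected k-mer frequency vectors, by exhaustive k-mer enumeration."""
    def vector(counts):
        L = len(counts[0])
        p = [probs([counts[b][j] for b in range(4)], pseudo) for j in range(L)]
        vec = {}
        for start in range(L - k + 1):
            for kmer in itertools.product(range(4), repeat=k):
                w = 1.0
                for off, b in enumerate(kmer):
                    w *= p[start + off][b]
                vec[kmer] = vec.get(kmer, 0.0) + w
        return vec

    v1 = vector(counts1)
    v2 = vector(counts2)
    keys = set(v1) | set(v2)
    dot = sum(v1.get(kk, 0.0) * v2.get(kk, 0.0) for kk in keys)
    n1 = math.sqrt(sum(v * v for v in v1.values()))
    n2 = math.sqrt(sum(v * v for v in v2.values()))
    return dot / (n1 * n2)


# --- alignment enumeration -------------------------------------------------

def monotone_matchings(L1: int, L2: int):
    """All matchings of columns, strictly increasing on both sides (incl. empty)."""
    def rec(i, j):
        yield []
        for a in range(i, L1):
            for b in range(j, L2):
                for rest in rec(a + 1, b + 1):
                    yield [(a, b)] + rest
    yield from rec(0, 0)


def _gap_cost(g: int, open_: float, ext: float) -> float:
    return 0.0 if g == 0 else open_ + (g - 1) * ext


def global_best(S: np.ndarray, open_: float, ext: float) -> float:
    """Best global alignment score: every unmatched stretch, ends included, is a gap run."""
    L1, L2 = S.shape
    best = -math.inf
    for m in monotone_matchings(L1, L2):
        sc = sum(S[i, j] for i, j in m)
        prev = (-1, -1)
        for i, j in m + [(L1, L2)]:
            sc -= _gap_cost(i - prev[0] - 1, open_, ext)
            sc -= _gap_cost(j - prev[1] - 1, open_, ext)
            prev = (i, j)
        best = max(best, sc)
    return best


def local_best(S: np.ndarray, open_: float, ext: float, min_overlap: int = 1) -> float:
    """Best local alignment score: only gaps strictly between aligned pairs count."""
    L1, L2 = S.shape
    best = 0.0
    for m in monotone_matchings(L1, L2):
        if len(m) < min_overlap or not m:
            continue
        sc = sum(S[i, j] for i, j in m)
        for (i1, j1), (i2, j2) in zip(m, m[1:]):
            sc -= _gap_cost(i2 - i1 - 1, open_, ext)
            sc -= _gap_cost(j2 - j1 - 1, open_, ext)
        best = max(best, sc)
    return best


def ungapped_best(S: np.ndarray, min_overlap: int = 1) -> float:
    """Best contiguous run of column pairs over all offsets (exhaustive scan)."""
    L1, L2 = S.shape
    best = 0.0
    for i0 in range(L1):
        for j0 in range(L2):
            run = 0.0
            t = 0
            while i0 + t < L1 and j0 + t < L2:
                run += S[i0 + t, j0 + t]
                if t + 1 >= min_overlap:
                    best = max(best, run)
                t += 1
    return best


def split_pair_count(n: int) -> int:
    """Independent recurrence for the number of sub-motif pairs from n sites."""
    memo = {0: 0, 1: 0}

    def rec(m):
        if m not in memo:
            memo[m] = m // 2 + sum(rec(k) + rec(m - k) for k in range(1, m // 2 + 1))
        return memo[m]

    return rec(n)
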