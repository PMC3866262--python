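"""Column metrics against independently coded formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp_st

from motifcompare import (
    Motif,
    column_metric,
    kfv_similarity,
    pcc_column,
    pcs_column,
    spic_column_similarity,
    spic_cross_score,
    ssd_column,
    akl_column,
    allr_column,
)

import oracles
from conftest import column_view, random_counts, random_motif


class TestSpic:
    def test_uniform_source_scores_zero(self):
        src = column_view([1, 1, 1, 1])  # IC = 0
        tgt = column_view([9, 0, 1, 0])
        assert spic_cross_score(src, tgt) == pytest.approx(0.0)

    def test_matching_columns_score_positive(self):
        c = column_view([4, 0, 0, 0])
        got = spic_cross_score(c, c)
        assert got == pytest.approx(oracles.spic_cross([4, 0, 0, 0], [4, 0, 0, 0], 1.0))
        assert got > 0

    def test_anti_matching_columns_score_negative(self):
        src = column_view([4, 0, 0, 0])
        tgt = column_view([0, 4, 0, 0])
        got = spic_cross_score(src, tgt)
        assert got == pytest.approx(oracles.spic_cross([4, 0, 0, 0], [0, 4, 0, 0], 1.0))
        assert got < 0

    def test_identical_informative_columns_similarity_one(self):
        c = column_view([7, 1, 1, 1])
        assert spic_column_similarity(c, c) == pytest.approx(1.0)

    def test_both_uniform_columns_similarity_zero(self):
        u = column_view([1, 1, 1, 1])
        assert spic_column_similarity(u, u) == 0.0

    def test_swapped_columns_match_formula_oracle(self):
        x = column_view([7, 1, 1, 1])
        y = column_view([1, 7, 1, 1])
        assert spic_column_similarity(x, y) == pytest.approx(
            oracles.spic_sim([7, 1, 1, 1], [1, 7, 1, 1], 1.0), abs=1e-12)

    def test_similarity_decreases_toward_background(self):
        """Mixing one column toward uniform lowers its similarity to the sharp one."""
        sharp = [16, 0, 0, 0]
        sims = []
        for mix in range(5):
            other = [16 - 3 * mix, mix, mix, mix]
            sims.append(spic_column_similarity(column_view(sharp), column_view(other)))
        assert all(a >= b - 1e-12 for a, b in zip(sims, sims[1:]))


class TestClassicalMetrics:
    def test_identity_values(self):
        c = column_view([7, 1, 1, 1])
        assert pcc_column(c, c) == pytest.approx(1.0)
        assert ssd_column(c, c) == pytest.approx(2.0)
        assert akl_column(c, c) == pytest.approx(10.0)
        assert pcs_column(c, c) == pytest.approx(1.0)

    def test_pcc_disjoint_deterministic_columns(self):
        # probability vectors (1,0,0,0) vs (0,1,0,0) correlate at -1/3
        x = column_view([4, 0, 0, 0], pseudocount=0.0)
        y = column_view([0, 4, 0, 0], pseudocount=0.0)
        assert pcc_column(x, y) == pytest.approx(-1 / 3)

    def test_pcc_uniform_column_convention(self):
        u = column_view([1, 1, 1, 1])
        x = column_view([4, 0, 0, 0])
        assert pcc_column(u, x) == 0.0

    def test_allr_at_background_is_zero(self):
        u = column_view([1, 1, 1, 1], pseudocount=0.0)
        assert allr_column(u, u) == pytest.approx(0.0)

    def test_allr_signs(self):
        same = column_view([4, 0, 0, 0])
        anti = column_view([0, 4, 0, 0])
        assert allr_column(same, same) == pytest.approx(
            oracles.allr([4, 0, 0, 0], [4, 0, 0, 0], 1.0))
        assert allr_column(same, same) > 0
        assert allr_column(same, anti) == pytest.approx(
            oracles.allr([4, 0, 0, 0], [0, 4, 0, 0], 1.0))
        assert allr_column(same, anti) < 0

    def test_ssd_extremes(self):
        x = column_view([4, 0, 0, 0], pseudocount=0.0)
        y = column_view([0, 4, 0, 0], pseudocount=0.0)
        assert ssd_column(x, y) == pytest.approx(0.0)
        half_ac = column_view([2, 2, 0, 0], pseudocount=0.0)
        half_ag = column_view([2, 0, 2, 0], pseudocount=0.0)
        assert ssd_column(half_ac, half_ag) == pytest.approx(1.5)

    def test_pcs_disjoint_counts_near_zero(self):
        x = column_view([8, 0, 0, 0])
        y = column_view([0, 8, 0, 0])
        got = pcs_column(x, y)
        assert got == pytest.approx(oracles.pcs([8, 0, 0, 0], [0, 8, 0, 0]), abs=1e-12)
        assert got < 0.01

    def test_pcs_absent_bases_reduce_degrees_of_freedom(self):
        x = column_view([5, 3, 0, 0])
        y = column_view([3, 5, 0, 0])
        assert pcs_column(x, y) == pytest.approx(oracles.pcs([5, 3, 0, 0], [3, 5, 0, 0]),
                                                 abs=1e-12)


@pytest.mark.parametrize("metric,oracle", [
    ("spic", lambda cx, cy: oracles.spic_sim(cx, cy, 1.0)),
    ("pcc", lambda cx, cy: oracles.pcc(oracles.probs(cx, 1.0), oracles.probs(cy, 1.0))),
    ("allr", lambda cx, cy: oracles.allr(cx, cy, 1.0)),
    ("akl", lambda cx, cy: oracles.akl(oracles.probs(cx, 1.0), oracles.probs(cy, 1.0))),
    ("ssd", lambda cx, cy: oracles.ssd(oracles.probs(cx, 1.0), oracles.probs(cy, 1.0))),
    ("pcs", oracles.pcs),
])
def test_metric_matches_oracle_on_random_columns(rng, metric, oracle):
    f = column_metric(metric)
    for _ in range(60):
        cx = random_counts(rng)
        cy = random_counts(rng)
        x = column_view(cx)
        y = column_view(cy)
        assert f(x, y) == pytest.approx(oracle(list(cx), list(cy)), abs=1e-9)
        # symmetry
        assert f(x, y) == pytest.approx(f(y, x), abs=1e-12)


_count_vec = hyp_st.lists(hyp_st.integers(0, 20), min_size=4, max_size=4).filter(
    lambda v: sum(v) > 0)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(cx=_count_vec, cy=_count_vec)
def test_metric_symmetry_property(cx, cy):
    """Every column metric is symmetric and respects its range, for arbitrary
    count vectors."""
    x = column_view(np.array(cx))
    y = column_view(np.array(cy))
    for f in (spic_column_similarity, pcc_column, allr_column, akl_column,
              ssd_column, pcs_column):
        assert f(x, y) == pytest.approx(f(y, x), abs=1e-9)
    assert spic_column_similarity(x, y) <= 1 + 1e-12
    assert 0 - 1e-12 <= pcs_column(x, y) <= 1 + 1e-12
    assert 0 - 1e-12 <= ssd_column(x, y) <= 2 + 1e-12


def test_metric_ranges_on_random_columns(rng):
    for _ in range(50):
        x = column_view(random_counts(rng))
        y = column_view(random_counts(rng))
        assert spic_column_similarity(x, y) <= 1.0 + 1e-12
        assert -1 - 1e-12 <= pcc_column(x, y) <= 1 + 1e-12
        assert -1e-12 <= ssd_column(x, y) <= 2 + 1e-12
        assert akl_column(x, y) <= 10 + 1e-12
        assert -1e-12 <= pcs_column(x, y) <= 1 + 1e-12


class TestKfv:
    def test_identical_motifs_give_one(self, rng):
        m = random_motif(rng)
        assert kfv_similarity(m, m) == pytest.approx(1.0)

    def test_disjoint_deterministic_motifs_give_zero(self):
        m1 = Motif.from_sites("a", ["AAAA"] * 3)
        m2 = Motif.from_sites("c", ["CCCC"] * 3)
        assert kfv_similarity(m1, m2, pseudocount=0.0) == pytest.approx(0.0)

    def test_matches_exhaustive_kmer_enumeration(self, rng):
        for k in (2, 3):
            m1 = random_motif(rng, length=5)
            m2 = random_motif(rng, length=5)
            got = kfv_similarity(m1, m2, k=k)
            want = oracles.kfv(m1.counts.tolist(), m2.counts.tolist(), k, 1.0)
            assert got == pytest.approx(want, abs=1e-9)

    def test_short_motif_reduces_k(self):
        m1 = Motif.from_sites("a", ["AC", "AC"])
        m2 = Motif.from_sites("b", ["AC", "AG"])
        got = kfv_similarity(m1, m2, k=4)
        want = oracles.kfv(m1.counts.tolist(), m2.counts.tolist(), 2, 1.0)
        assert got == pytest.approx(want, abs=1e-9)
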