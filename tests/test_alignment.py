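"""Alignment DP against exhaustive enumeration; orientation, symmetry, p-values."""

import pytest

from motifcompare import (
    GapPenalty,
    Motif,
    MotifProfile,
    ScoringStrategy,
    align_global,
    align_local,
    align_ungapped,
    empirical_pvalue,
    motif_similarity,
    reverse_complement,
    similarity_matrix,
)

import oracles
from conftest import random_motif

GAPS = [GapPenalty(1.0, 0.5), GapPenalty(0.5, 0.25), GapPenalty(2.0, 1.0)]


def _strategy(metric="spic", mode="SW", gap=GapPenalty(1.0, 0.5), **kw):
    return ScoringStrategy(metric=metric, mode=mode, gap=gap,
                           both_orientations=False, **kw)


def _sim(m1, m2, strategy):
    p1 = MotifProfile.from_motif(m1, strategy.background, strategy.pseudocount)
    p2 = MotifProfile.from_motif(m2, strategy.background, strategy.pseudocount)
    return similarity_matrix(p1, p2, strategy.metric)


def informative_motif(length=5):
    sites = ["ACGTA"[:length]] * 6 + ["ACGTT"[:length]] * 2
    return Motif.from_sites(f"inf{length}", sites)


class TestDpAgainstEnumeration:
    """DP score equals brute force over all alignments for short motifs."""

    @pytest.mark.parametrize("gap", GAPS, ids=["1-0.5", "0.5-0.25", "2-1"])
    @pytest.mark.parametrize("metric", ["spic", "allr", "ssd"])
    def test_all_modes_match_brute_force(self, rng, gap, metric):
        for _ in range(15):
            m1 = random_motif(rng, length=rng.integers(1, 5), id="a")
            m2 = random_motif(rng, length=rng.integers(1, 5), id="b")
            st = _strategy(metric=metric, gap=gap)
            S = _sim(m1, m2, st)
            got_g = align_global(m1, m2, _strategy(metric=metric, mode="NW", gap=gap))
            assert got_g.score == pytest.approx(
                oracles.global_best(S, gap.open, gap.extend), abs=1e-9)
            got_l = align_local(m1, m2, st)
            assert got_l.score == pytest.approx(
                oracles.local_best(S, gap.open, gap.extend), abs=1e-9)
            got_u = align_ungapped(m1, m2, _strategy(metric=metric, mode="SWU", gap=gap))
            assert got_u.score == pytest.approx(oracles.ungapped_best(S), abs=1e-9)

    def test_length_one_pair(self, rng):
        m1 = random_motif(rng, length=1, id="a")
        m2 = random_motif(rng, length=1, id="b")
        gap = GapPenalty(1.0, 0.5)
        S = _sim(m1, m2, _strategy())
        res = align_global(m1, m2, _strategy(mode="NW"))
        assert res.score == pytest.approx(oracles.global_best(S, gap.open, gap.extend))


class TestAlignmentProperties:
    def test_self_alignment_scores_length(self):
        m = informative_motif(5)
        res = align_local(m, m, _strategy())
        assert res.score == pytest.approx(5.0)
        assert res.pairs == [(i, i) for i in range(1, 6)]
        assert not res.gaps

    def test_disjoint_consensi_give_empty_local_alignment(self):
        m1 = Motif.from_sites("a", ["AAAA"] * 8)
        m2 = Motif.from_sites("c", ["CCCC"] * 8)
        res = align_local(m1, m2, _strategy())
        assert res.score == 0.0
        assert res.pairs == []

    def test_shifted_motif_recovered_ungapped(self):
        m1 = Motif.from_sites("a", ["ACGTA"] * 6)
        m2 = Motif.from_sites("b", ["CGTAT"] * 6)  # m1 shifted left by one
        res = align_ungapped(m1, m2, _strategy(mode="SWU"))
        assert len(res.pairs) == 4
        assert res.pairs[0] == (2, 1)

    def test_sw_dominates_swu_dominates_zero(self, rng):
        for _ in range(20):
            m1 = random_motif(rng, id="a")
            m2 = random_motif(rng, id="b")
            sw = align_local(m1, m2, _strategy()).score
            swu = align_ungapped(m1, m2, _strategy(mode="SWU")).score
            best_pair = _sim(m1, m2, _strategy()).max()
            assert sw >= swu - 1e-12 >= -1e-12
            assert sw >= max(0.0, best_pair) - 1e-12

    @pytest.mark.parametrize("metric", ["spic", "pcc", "allr", "akl", "ssd", "pcs", "kfv"])
    @pytest.mark.parametrize("mode", ["NW", "SW", "SWU"])
    def test_score_symmetry(self, rng, metric, mode):
        for _ in range(5):
            m1 = random_motif(rng, id="a")
            m2 = random_motif(rng, id="b")
            st = ScoringStrategy(metric=metric, mode=mode, gap=GapPenalty(1.0, 0.5))
            assert motif_similarity(m1, m2, st).score == pytest.approx(
                motif_similarity(m2, m1, st).score, abs=1e-9)

    def test_score_recomputable_from_pairs_and_gaps(self, rng):
        st = _strategy()
        for _ in range(20):
            m1 = random_motif(rng, id="a")
            m2 = random_motif(rng, id="b")
            for aligner, mode in [(align_global, "NW"), (align_local, "SW"),
                                  (align_ungapped, "SWU")]:
                res = aligner(m1, m2, _strategy(mode=mode))
                if res.pairs:
                    assert res.score == pytest.approx(
                        res.recomputed_score(st.gap), abs=1e-9)

    def test_pairs_strictly_increasing(self, rng):
        for _ in range(10):
            m1 = random_motif(rng, id="a")
            m2 = random_motif(rng, id="b")
            res = align_global(m1, m2, _strategy(mode="NW"))
            for (i1, j1), (i2, j2) in zip(res.pairs, res.pairs[1:]):
                assert i2 > i1 and j2 > j1


class TestOrientation:
    def test_revcomp_target_matches_self_score(self):
        m = informative_motif(5)
        rc = reverse_complement(m)
        st = ScoringStrategy(metric="spic", mode="SW", both_orientations=True)
        self_res = motif_similarity(m, m, st)
        rc_res = motif_similarity(m, rc, st)
        assert rc_res.score == pytest.approx(self_res.score)
        assert rc_res.orientation == "revcomp"

    def test_single_orientation_never_beats_both(self, rng):
        for _ in range(10):
            m1 = random_motif(rng, id="a")
            m2 = random_motif(rng, id="b")
            both = motif_similarity(m1, m2, ScoringStrategy(both_orientations=True))
            fwd = motif_similarity(m1, m2, ScoringStrategy(both_orientations=False))
            assert both.score >= fwd.score - 1e-12

    def test_self_similarity_dominates_shuffles(self, rng):
        m = informative_motif(5)
        st = ScoringStrategy(metric="spic", mode="SW")
        self_score = motif_similarity(m, m, st).score
        for _ in range(10):
            perm = rng.permutation(m.length)
            shuffled = Motif(id="s", counts=m.counts[:, perm])
            assert motif_similarity(m, shuffled, st).score <= self_score + 1e-12


class TestEmpiricalPvalue:
    def test_single_column_self_pvalue_is_one(self):
        m = Motif.from_sites("a", ["A", "A", "A"])
        st = ScoringStrategy(metric="spic", mode="SW")
        assert empirical_pvalue(m, m, st, n_shuffles=50, seed=3) == pytest.approx(1.0)

    def test_identical_informative_motifs_rank_top(self):
        m = Motif.from_sites("a", ["ACGTAC"] * 5 + ["ACGTAT"] * 3)
        st = ScoringStrategy(metric="spic", mode="SW")
        p = empirical_pvalue(m, m, st, n_shuffles=200, seed=11)
        # observed score should rarely be beaten by column shuffles
        assert p <= 10 / 201

    def test_fixed_seed_is_deterministic(self, rng):
        m1 = random_motif(rng, id="a")
        m2 = random_motif(rng, id="b")
        st = ScoringStrategy()
        p1 = empirical_pvalue(m1, m2, st, n_shuffles=100, seed=5)
        p2 = empirical_pvalue(m1, m2, st, n_shuffles=100, seed=5)
        assert p1 == p2


def test_unknown_mode_and_metric_rejected():
    with pytest.raises(ValueError):
        ScoringStrategy(mode="banana")
    m = Motif.from_sites("a", ["AC", "AC"])
    with pytest.raises(ValueError, match="not a column metric"):
        align_local(m, m, ScoringStrategy(metric="kfv"))
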