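"""Signature statistics: area enrichment, resampling null, rank overlap."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dermsig.genesets import GeneSet
from dermsig.signatures import (
    RankedList,
    area_enrichment,
    area_from_ranks,
    cumulative_overlap_curve,
    fc_spearman,
    fisher_overlap,
    mean_fc_resampling,
    rank_by_fc,
    rank_overlap,
    select_top_signature,
    slope_ranking,
)


def ranked(n, prefix="g"):
    return RankedList(genes=tuple(f"{prefix}{i}" for i in range(1, n + 1)))


def brute_force_area(rank_positions, N):
    """Independent curve-based area computation by enumeration."""
    member = set(rank_positions)
    m = len(member)
    hits = 0
    area = 0.0
    for k in range(1, N + 1):
        if k in member:
            hits += 1
        area += hits / m - k / N
    return area / N


class TestRanking:
    def test_up_ranking_by_fc(self, simple_de_table):
        r = rank_by_fc(simple_de_table.loc[["g1", "g2", "g3"]], "up")
        assert r.genes == ("g1", "g3", "g2")

    def test_up_is_reverse_of_down_when_fc_distinct(self, simple_de_table):
        table = simple_de_table.loc[["g1", "g2", "g3", "g4"]]
        up = rank_by_fc(table, "up")
        down = rank_by_fc(table, "down")
        assert up.genes == down.genes[::-1]

    def test_fc_ties_broken_by_p(self):
        de = pd.DataFrame(
            {"fc": [1.5, 1.5], "p": [0.2, 0.01], "tested": [True, True]},
            index=pd.Index(["a", "b"], name="gene"),
        )
        assert rank_by_fc(de, "up").genes == ("b", "a")

    def test_empty_table_rejected(self):
        de = pd.DataFrame({"fc": [], "p": [], "tested": []})
        with pytest.raises(ValueError):
            rank_by_fc(de, "up")


class TestCumulativeCurve:
    def test_full_universe_set_gives_diagonal(self):
        r = ranked(6)
        C = cumulative_overlap_curve(r, GeneSet("all", r.genes))
        assert np.allclose(C, np.arange(1, 7) / 6)

    def test_worked_micro_curve(self):
        C = cumulative_overlap_curve(ranked(4), GeneSet("s", ("g1", "g2")))
        assert np.allclose(C, [0.5, 1, 1, 1])

    def test_curve_ends_at_one_and_is_monotone(self):
        rng = np.random.default_rng(1)
        r = ranked(30)
        genes = tuple(rng.choice(r.genes, size=7, replace=False))
        C = cumulative_overlap_curve(r, GeneSet("s", genes))
        assert C[-1] == pytest.approx(1.0)
        assert (np.diff(C) >= 0).all()

    def test_absent_genes_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            C = cumulative_overlap_curve(ranked(4), GeneSet("s", ("g1", "zzz")))
        assert np.allclose(C, [1, 1, 1, 1])


class TestAreaEnrichment:
    def test_top_placement_area(self):
        res = area_enrichment(ranked(4), GeneSet("s", ("g1", "g2")), n_perm=100, seed=0)
        assert res.area == pytest.approx(0.25)

    def test_bottom_placement_area(self):
        res = area_enrichment(ranked(4), GeneSet("s", ("g3", "g4")), n_perm=100, seed=0)
        assert res.area == pytest.approx(-0.25)

    def test_curve_sum_equals_rank_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            N = int(rng.integers(5, 60))
            m = int(rng.integers(1, N))
            positions = rng.choice(N, size=m, replace=False) + 1
            genes = tuple(f"g{i}" for i in sorted(positions))
            res = area_enrichment(ranked(N), GeneSet("s", genes), n_perm=10, seed=0)
            assert abs(res.area - area_from_ranks(positions, N)) < 1e-12
            assert abs(res.area - brute_force_area(positions, N)) < 1e-12

    def test_reversal_negates_area_exactly(self):
        rng = np.random.default_rng(3)
        r = ranked(40)
        genes = tuple(rng.choice(r.genes, size=11, replace=False))
        a = area_enrichment(r, GeneSet("s", genes), n_perm=10, seed=0).area
        b = area_enrichment(r.reversed(), GeneSet("s", genes), n_perm=10, seed=0).area
        assert a == -b

    def test_exhaustive_one_sided_p_micro_example(self):
        # all C(4,2)=6 placements; one-sided P(A >= 0.25) = 1/6
        areas = [brute_force_area(c, 4) for c in itertools.combinations(range(1, 5), 2)]
        assert sum(a >= 0.25 for a in areas) / len(areas) == pytest.approx(1 / 6)
        res = area_enrichment(
            ranked(4), GeneSet("s", ("g1", "g2")), n_perm=20000, seed=5, alternative="greater"
        )
        se = np.sqrt((1 / 6) * (5 / 6) / 20000)
        assert abs(res.p_perm - 1 / 6) < 3 * se + 1 / 20001

    def test_normal_approximation_tracks_permutation(self):
        rng = np.random.default_rng(9)
        r = ranked(300)
        genes = tuple(rng.choice(r.genes, size=30, replace=False))
        res = area_enrichment(r, GeneSet("s", genes), n_perm=4000, seed=2)
        assert res.p_normal == pytest.approx(res.p_perm, abs=0.08)

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            area_enrichment(ranked(4), GeneSet("s", ("g1",)), n_perm=0)


class TestMeanFCResampling:
    def test_degenerate_null_all_unit_fc(self):
        fc = pd.Series(1.0, index=[f"g{i}" for i in range(6)])
        res = mean_fc_resampling(fc, GeneSet("s", ("g0", "g1")), n_resamples=200, seed=0)
        assert res.observed_mean_fc == 1.0
        assert res.p == 1.0
        assert res.percent_shift == 0.0

    def test_worked_six_gene_example(self):
        fc = pd.Series([2, 2, 0.5, 0.5, 1, 1], index=[f"g{i}" for i in range(1, 7)], dtype=float)
        # exhaustive null over all 15 pairs (independent oracle)
        null = [np.mean(pair) for pair in itertools.combinations(fc.to_numpy(), 2)]
        exact = sum(x >= 2.0 for x in null) / len(null)
        assert exact == pytest.approx(1 / 15)
        res = mean_fc_resampling(
            fc, GeneSet("s", ("g1", "g2")), n_resamples=20000, seed=3, alternative="greater"
        )
        assert res.observed_mean_fc == pytest.approx(2.0)
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(res.p - exact) < 3 * se + 1 / 20001

    def test_set_with_no_members_in_universe_rejected(self):
        fc = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.warns(UserWarning, match="absent"), pytest.raises(ValueError):
            mean_fc_resampling(fc, GeneSet("s", ("c", "d")), n_resamples=10)

    def test_geometric_mode(self):
        fc = pd.Series([4.0, 1.0, 1.0, 1.0, 0.25, 1.0], index=[f"g{i}" for i in range(6)])
        res = mean_fc_resampling(
            fc, GeneSet("s", ("g0", "g4")), n_resamples=100, seed=0, mode="geometric"
        )
        assert res.observed_mean_fc == pytest.approx(1.0)


class TestSelectTopSignature:
    def test_zero_k_gives_empty_set(self, simple_de_table):
        assert len(select_top_signature(simple_de_table, 0)) == 0

    def test_lowest_p_qualifying_genes(self):
        de = pd.DataFrame(
            {
                "fc": [1.5, 1.2, 2.0, 0.5, 0.8],
                "p": [0.001, 0.01, 0.2, 1e-6, 0.03],
                "tested": [True] * 5,
            },
            index=pd.Index(["a", "b", "c", "d", "e"], name="gene"),
        )
        top = select_top_signature(de, 2, "up")
        assert set(top.genes) == {"a", "b"}

    def test_no_qualifying_genes_warns(self):
        de = pd.DataFrame(
            {"fc": [0.5, 0.8], "p": [0.01, 0.02], "tested": [True, True]},
            index=pd.Index(["a", "b"], name="gene"),
        )
        with pytest.warns(UserWarning, match="qualify"):
            top = select_top_signature(de, 2, "up")
        assert len(top) == 0

    def test_negative_k_rejected(self, simple_de_table):
        with pytest.raises(ValueError):
            select_top_signature(simple_de_table, -1)


class TestSlopeRanking:
    def _tables(self, profiles):
        out = []
        for d in range(profiles.shape[1]):
            out.append(
                pd.DataFrame(
                    {"log2fc": profiles[:, d], "p": 0.5, "tested": True},
                    index=pd.Index([f"g{i}" for i in range(profiles.shape[0])], name="gene"),
                )
            )
        return out

    def test_constant_profile_has_zero_slope(self):
        _, slopes = slope_ranking(self._tables(np.full((3, 7), 2.0)))
        assert np.allclose(slopes, 0.0)

    def test_unit_ramp_has_unit_slope(self):
        profiles = np.vstack([np.arange(7.0)])
        _, slopes = slope_ranking(self._tables(profiles))
        assert slopes.iloc[0] == pytest.approx(1.0)

    def test_steeper_gene_ranks_first(self):
        days = np.arange(1, 8, dtype=float)
        profiles = np.vstack([1.0 * days, 0.5 * days])
        ranking, _ = slope_ranking(self._tables(profiles))
        assert ranking.genes[0] == "g0"

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            slope_ranking(self._tables(np.zeros((2, 1))))


class TestFisherOverlap:
    def test_minimum_overlap_gives_p_one(self):
        assert fisher_overlap(0, 5, 4, 10) == 1.0

    def test_toy_case(self):
        assert fisher_overlap(4, 5, 4, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_exact_rational_enumeration(self):
        for N in range(2, 9):
            for m1 in range(1, N + 1):
                for m2 in range(1, N + 1):
                    lo = max(0, m1 + m2 - N)
                    for k in range(lo, min(m1, m2) + 1):
                        exact = sum(
                            Fraction(comb(m1, i) * comb(N - m1, m2 - i), comb(N, m2))
                            for i in range(k, min(m1, m2) + 1)
                        )
                        assert fisher_overlap(k, m1, m2, N) == pytest.approx(
                            float(exact), rel=1e-10
                        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_overlap(5, 4, 4, 10)
        with pytest.raises(ValueError):
            fisher_overlap(0, 8, 8, 10)  # below the minimum possible overlap

    def test_extreme_tail_stays_finite_and_positive(self):
        p = fisher_overlap(317, 1000, 1000, 14578)
        assert 0 < p < 1e-50


class TestRankOverlap:
    def test_identical_rankings(self):
        r = ranked(5)
        res = rank_overlap(r, r, 3)
        assert list(res.overlap) == [1, 2, 3]

    def test_reversed_rankings_have_empty_top_half_overlap(self):
        r = ranked(10)
        res = rank_overlap(r, r.reversed(), 5)
        assert res.overlap[-1] == 0

    def test_fisher_at_cutoff(self):
        # N=10, K=4, complete overlap in top-4: p = 1/C(10,4)
        r = ranked(10)
        res = rank_overlap(r, r, 4)
        assert res.fisher_p == pytest.approx(1 / 210, rel=1e-10)
        assert res.contingency[0, 0] == 4

    def test_cutoff_beyond_universe_rejected(self):
        with pytest.raises(ValueError):
            rank_overlap(ranked(4), ranked(4), 5)

    def test_overlap_is_monotone(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        a = RankedList(tuple(rng.permutation(genes)))
        b = RankedList(tuple(rng.permutation(genes)))
        res = rank_overlap(a, b, 40)
        assert (np.diff(res.overlap) >= 0).all()


class TestFCSpearman:
    def _table(self, fc):
        return pd.DataFrame(
            {"fc": fc, "tested": True},
            index=pd.Index([f"g{i}" for i in range(len(fc))], name="gene"),
        )

    def test_self_correlation_is_one(self):
        t = self._table([0.5, 1.2, 2.0, 0.9])
        assert fc_spearman(t, t).r == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        a = self._table([1.0, 2.0, 3.0])
        b = self._table([3.0, 2.0, 1.0])
        assert fc_spearman(a, b).r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        a = self._table([1.0, 2.0, 3.0])
        b = self._table([1.0, 3.0, 2.0])
        assert fc_spearman(a, b).r == pytest.approx(0.5)

    def test_too_few_shared_genes_rejected(self):
        a = self._table([1.0, 2.0])
        with pytest.raises(ValueError):
            fc_spearman(a, a)
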