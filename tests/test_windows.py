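"""Sliding-window tracks, correlation and enrichment statistics vs oracles."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from plastid_rnaproc.windows import (
    WindowTrack,
    category_association_test,
    correlate_tracks,
    region_enrichment_test,
    window_conservation_track,
    window_editing_track,
)


class TestEditingTrack:
    def test_no_events_all_zero(self):
        track = window_editing_track([], 300, 60, 3)
        assert set(track.values) == {0.0}

    def test_every_position_edited_all_one(self):
        track = window_editing_track(list(range(300)), 300, 60, 3)
        assert set(track.values) == {1.0}

    def test_counts_match_direct_window_counting(self):
        rng = random.Random(3)
        cds_length = 402
        positions = sorted(rng.sample(range(cds_length), 37))
        track = window_editing_track(positions, cds_length, 60, 3)
        for s, v in zip(track.starts, track.values):
            direct = sum(1 for p in positions if s <= p < s + 60)
            assert v == direct / 60

    def test_short_gene_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            window_editing_track([], 45, 60, 3)

    def test_event_order_invariance(self):
        positions = [5, 100, 200, 33, 150]
        a = window_editing_track(positions, 300, 60, 3)
        b = window_editing_track(positions[::-1], 300, 60, 3)
        assert a.values == b.values

    def test_values_bounded(self):
        track = window_editing_track([0, 1, 2, 59], 120, 60, 1)
        assert all(0.0 <= v <= 1.0 for v in track.values)


class TestConservationTrack:
    def test_identical_proteins_fully_conserved(self):
        protein = "MKLVNNPQRSTACDEFGHIW" * 3
        track = window_conservation_track(protein, protein, 60, 3)
        assert set(track.values) == {1.0}

    def test_hand_computed_window_score(self):
        # 20 codons: 12 identities, 4 positives, 4 non-positives
        # -> (12 + 0.5 * 4) / 20 = 0.70
        query = "AAAAAAAAAAAA" + "ILVF" + "GGGG"
        orth = "AAAAAAAAAAAA" + "VLIY" + "PPPP"
        # I~V, L=L identity... build carefully: make the 4 "positives"
        # substitutions with positive BLOSUM62 score and no identity
        query = "AAAAAAAAAAAA" + "IKDF" + "GGGG"
        orth = "AAAAAAAAAAAA" + "VREY" + "PPPP"
        # BLOSUM62: I/V=3, K/R=2, D/E=2, F/Y=3 (positives);
        # G/P=-2 x4 (non-positives); 12 A/A identities
        track = window_conservation_track(query, orth, 60, 60)
        assert track.values[0] == pytest.approx(0.70)

    def test_ortholog_gap_scores_zero(self):
        # ortholog missing the whole C-terminal half: those windows score 0
        query = "MKLVNNPQRSTACDEFGHIW" + "WYFHKRDE" * 5
        orth = "MKLVNNPQRSTACDEFGHIW"
        track = window_conservation_track(query, orth, 60, 3)
        assert track.values[-1] == 0.0
        assert track.values[0] == 1.0

    def test_window_must_be_codon_sized(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            window_conservation_track("MKLV" * 10, "MKLV" * 10, 50, 3)

    def test_empty_ortholog_rejected(self):
        with pytest.raises(ValueError, match="empty ortholog"):
            window_conservation_track("MKLV" * 10, "", 60, 3)


class TestCorrelation:
    def test_negated_track_perfectly_anticorrelated(self):
        a = WindowTrack("g", 60, 3, [0, 3, 6, 9], [0.1, 0.4, 0.2, 0.8])
        b = WindowTrack("g", 60, 3, [0, 3, 6, 9], [-v for v in a.values])
        res = correlate_tracks(a, b)
        assert res.r == pytest.approx(-1.0)

    def test_closed_form_pearson(self):
        a = WindowTrack("g", 60, 3, [0, 3, 6], [1, 2, 3])
        b = WindowTrack("g", 60, 3, [0, 3, 6], [1, 2, 4])
        res = correlate_tracks(a, b)
        # closed form: r = cov / (sd_x sd_y)
        x, y = np.array([1, 2, 3.0]), np.array([1, 2, 4.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert res.r == pytest.approx(expected, abs=1e-12)
        assert res.r == pytest.approx(0.98198, abs=1e-5)

    def test_p_value_from_t_distribution(self):
        rng = np.random.default_rng(5)
        x = rng.random(40)
        y = 0.3 * x + rng.random(40)
        starts = list(range(0, 120, 3))
        res = correlate_tracks(
            WindowTrack("g", 60, 3, starts, list(x)),
            WindowTrack("g", 60, 3, starts, list(y)),
        )
        from scipy import stats

        t = res.r * math.sqrt((res.n - 2) / (1 - res.r**2))
        p = 2 * stats.t.sf(abs(t), res.n - 2)
        assert res.t_stat == pytest.approx(t)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_self_correlation_is_one(self):
        a = WindowTrack("g", 60, 3, [0, 3, 6, 9], [0.1, 0.4, 0.2, 0.8])
        assert correlate_tracks(a, a).r == pytest.approx(1.0)

    def test_constant_track_rejected(self):
        a = WindowTrack("g", 60, 3, [0, 3, 6], [1.0, 1.0, 1.0])
        b = WindowTrack("g", 60, 3, [0, 3, 6], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            correlate_tracks(a, b)

    def test_mismatched_starts_rejected(self):
        a = WindowTrack("g", 60, 3, [0, 3, 6], [1.0, 2.0, 3.0])
        b = WindowTrack("g", 60, 3, [0, 3, 9], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="different window starts"):
            correlate_tracks(a, b)

    def test_hotspot_coupled_divergence_negative_correlation(self, default_run):
        # with hotspot-coupled ortholog divergence the editing and
        # conservation tracks must be negatively correlated
        correlations = default_run["correlations"]
        hot = default_run["truth"].hotspots
        checked = 0
        for gene_id, res in correlations.items():
            if gene_id in hot:
                assert res.r < 0
                assert res.p_value < 1e-3
                checked += 1
        assert checked >= 5


def binomial_sf_oracle(k: int, n: int, p: float) -> float:
    """Exact upper tail P(X >= k) by direct enumeration."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestEnrichment:
    def test_null_region_not_enriched(self):
        # region rate equals the background rate
        res = region_enrichment_test(k=5, n=100, total_k=50, total_n=1000)
        assert 0.4 < res.binomial_p < 0.7
        assert res.chisq_p > 0.9

    def test_binomial_matches_enumeration(self):
        res = region_enrichment_test(
            k=3, n=10, total_k=3 + 45, total_n=10 + 900, background="exclusive"
        )
        assert res.background_rate == pytest.approx(0.05)
        assert res.binomial_p == pytest.approx(
            binomial_sf_oracle(3, 10, 0.05), abs=1e-12
        )
        assert res.binomial_p == pytest.approx(0.0115, abs=5e-4)

    def test_monotone_in_k(self):
        previous = 1.1
        for k in range(0, 8):
            res = region_enrichment_test(k, 50, k + 40, 50 + 800)
            assert res.binomial_p < previous
            previous = res.binomial_p

    def test_dense_region_significant_chisq(self):
        # a region holding over a third of events in one-twelfth of the gene
        total_n, n = 1008, 84
        total_k, k = 45, 16
        res = region_enrichment_test(k, n, total_k, total_n)
        assert res.chisq_p < 0.05
        assert res.binomial_p < 0.05

    def test_region_must_fit_in_gene(self):
        with pytest.raises(ValueError):
            region_enrichment_test(5, 100, 4, 1000)


class TestCategoryAssociation:
    def test_balanced_table_statistic_zero(self):
        stat, p, _ = category_association_test([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # n(ad - bc)^2 / (row and column products) = 20
        stat, p, _ = category_association_test([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0, abs=1e-12)

    def test_transpose_symmetry(self):
        t = [[7, 2], [11, 19]]
        tt = [[7, 11], [2, 19]]
        assert category_association_test(t)[1] == pytest.approx(
            category_association_test(tt)[1]
        )

    def test_low_expected_count_flagged(self):
        _, _, low = category_association_test([[2, 1], [3, 50]])
        assert low

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="zero marginal"):
            category_association_test([[0, 0], [5, 5]])


@given(
    st.lists(st.integers(min_value=0, max_value=400), min_size=0, max_size=40),
)
def test_track_values_always_fractions(positions):
    track = window_editing_track(positions, 402, 60, 3)
    assert all(0.0 <= v <= 1.0 for v in track.values)
    assert track.starts == sorted(track.starts)
    steps = {b - a for a, b in zip(track.starts, track.starts[1:])}
    assert steps <= {3}
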