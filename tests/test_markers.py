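"""Marker-efficiency indices: published worked examples, brute-force
oracles, and algebraic invariants."""

import numpy as np
import pytest

from issrpop import (
    aggregate_metrics,
    count_bands,
    discriminating_power,
    emr,
    expected_heterozygosity,
    havp,
    marker_index,
    panel_metrics,
    pic,
    pic_multiallelic,
    pooled_band_frequency,
    primer_metrics,
    resolving_power,
)
from conftest import make_matrix


def block_with_counts(n_loci, n_poly, n_ind=44, seed=0):
    """Matrix with exactly n_poly polymorphic and n_loci - n_poly fixed loci."""
    rng = np.random.default_rng(seed)
    data = np.ones((n_ind, n_loci))
    for j in range(n_poly):
        col = rng.integers(0, 2, n_ind).astype(float)
        while col.min() == col.max():
            col = rng.integers(0, 2, n_ind).astype(float)
        data[:, j] = col
    return make_matrix(data)


class TestBandCounts:
    @pytest.mark.parametrize(
        "tsb,pb,ppb",
        [(13, 11, 84.62), (19, 18, 94.74), (6, 6, 100.0)],
    )
    def test_ppb_bookkeeping(self, tsb, pb, ppb):
        m = block_with_counts(tsb, pb)
        TSB, PB, PPB = count_bands(m, "P1")
        assert (TSB, PB) == (tsb, pb)
        assert PPB == pytest.approx(ppb, abs=0.005)

    def test_unknown_primer_rejected(self, tiny_matrix):
        with pytest.raises(KeyError):
            count_bands(tiny_matrix, "nope")


class TestPooledFrequencyAndH:
    def test_half_ones_gives_half(self):
        m = make_matrix([[1, 0], [0, 1], [1, 0], [0, 1]])
        assert pooled_band_frequency(m, "P1") == pytest.approx(0.5)

    def test_monomorphic_primer_rejected(self):
        m = make_matrix(np.ones((4, 3)))
        with pytest.raises(ValueError, match="polymorphic"):
            pooled_band_frequency(m, "P1")

    @pytest.mark.parametrize("p,h", [(0.5, 0.5), (0.0, 0.0), (1.0, 0.0)])
    def test_heterozygosity_extremes(self, p, h):
        assert expected_heterozygosity(p) == pytest.approx(h)

    def test_published_reconstruction_issr842(self):
        # 11 fully polymorphic loci with EMR 3.886 imply pooled p = 0.3533,
        # H = 2p(1-p) = 0.457 and PIC = H - H^2/2 = 0.353
        p_bar = 3.886 / 11
        assert expected_heterozygosity(p_bar) == pytest.approx(0.457, abs=5e-4)
        assert pic(p_bar) == pytest.approx(0.353, abs=5e-4)

    def test_published_reconstruction_issr11(self):
        # printed H = 0.304 -> PIC = H - H^2/2 = 0.258, printed 0.257
        h = 0.304
        assert h - h * h / 2 == pytest.approx(0.257, abs=2e-3)

    def test_pic_identity_and_multiallelic_agreement(self):
        for p in np.linspace(0.01, 0.99, 23):
            h = expected_heterozygosity(p)
            assert pic(p) == pytest.approx(h - h * h / 2, abs=1e-12)
            assert pic(p) == pytest.approx(
                pic_multiallelic(np.array([p, 1 - p])), abs=1e-12
            )


class TestEMR:
    def test_fully_polymorphic_counts(self):
        # 4 bands seen per individual over 5 polymorphic loci: n = 4, beta = 1
        data = np.array(
            [[1, 1, 1, 1, 0], [0, 1, 1, 1, 1], [1, 0, 1, 1, 1], [1, 1, 0, 1, 1],
             [1, 1, 1, 0, 1], [1, 1, 1, 1, 0]]
        )
        m = make_matrix(data)
        assert emr(m, "P1") == pytest.approx(4.0)

    def test_monomorphic_primer_zero(self):
        m = make_matrix(np.ones((4, 3)))
        assert emr(m, "P1") == 0.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 2, (20, 9)).astype(float)
        m = make_matrix(data)
        TSB, PB, _ = count_bands(m, "P1")
        n_hand = np.mean([row.sum() for row in data])
        assert emr(m, "P1") == pytest.approx(n_hand * PB / TSB, abs=1e-12)


class TestResolvingPower:
    def test_half_frequency_band_contributes_one(self):
        m = make_matrix([[1], [1], [0], [0]])
        assert resolving_power(m, "P1") == pytest.approx(1.0)

    def test_fixed_bands_contribute_zero(self):
        m = make_matrix(np.hstack([np.ones((4, 2)), np.zeros((4, 2))]))
        assert resolving_power(m, "P1") == pytest.approx(0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        data = rng.integers(0, 2, (44, 22)).astype(float)
        m = make_matrix(data)
        hand = sum(
            1 - 2 * abs(0.5 - data[:, j].mean()) for j in range(22)
        )
        assert resolving_power(m, "P1") == pytest.approx(hand, abs=1e-12)


class TestDiscriminatingPower:
    def test_single_shared_pattern_zero(self):
        m = make_matrix(np.ones((6, 4)))
        assert discriminating_power(m, "P1") == pytest.approx(0.0)

    def test_all_distinct_patterns_one(self):
        m = make_matrix(np.eye(5))
        assert discriminating_power(m, "P1") == pytest.approx(1.0)

    def test_hand_enumeration_aabc(self):
        # patterns {A, A, B, C}: C = 0.5*(2-1)/3 = 1/6, D = 5/6
        data = np.array([[1, 1], [1, 1], [0, 1], [1, 0]], dtype=float)
        m = make_matrix(data)
        assert discriminating_power(m, "P1") == pytest.approx(5 / 6)

    def test_needs_two_individuals(self):
        data = np.array([[1.0], [0.0]])
        m = make_matrix(data)
        assert discriminating_power(m, "P1") == pytest.approx(1.0)


class TestHavp:
    def test_single_locus_half(self):
        m = make_matrix([[1], [1], [0], [0]])
        assert havp(m, "P1") == pytest.approx(0.5)

    def test_mean_invariance(self):
        m = make_matrix([[1, 1], [1, 1], [0, 0], [0, 0]])
        assert havp(m, "P1") == pytest.approx(0.5)

    def test_matches_brute_force_mean_of_2pq(self):
        rng = np.random.default_rng(5)
        data = rng.integers(0, 2, (30, 12)).astype(float)
        m = make_matrix(data)
        ps = [data[:, j].mean() for j in range(12)]
        hand = np.mean([2 * p * (1 - p) for p in ps if 0 < p < 1])
        assert havp(m, "P1") == pytest.approx(hand, abs=1e-12)

    def test_monomorphic_warns_and_zero(self):
        m = make_matrix(np.ones((4, 2)))
        with pytest.warns(UserWarning):
            assert havp(m, "P1") == 0.0


class TestMarkerIndexAndAggregate:
    @pytest.mark.parametrize("p,e,mi", [(0.0, 3.0, 0.0), (0.5, 2.0, 1.0)])
    def test_product(self, p, e, mi):
        assert marker_index(p, e) == pytest.approx(mi)

    def test_single_primer_summary_is_itself(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.integers(0, 2, (10, 8)).astype(float))
        table = panel_metrics(m)
        agg = aggregate_metrics(table)
        for col in ("H", "PIC", "EMR", "MI", "D", "RP"):
            assert agg.loc["mean", col] == pytest.approx(table.iloc[0][col])


class TestInvariants:
    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        data = rng.integers(0, 2, (15, 10)).astype(float)
        m = make_matrix(data)
        perm_ind = rng.permutation(15)
        perm_loc = rng.permutation(10)
        m_shuffled = make_matrix(data[perm_ind][:, perm_loc])
        a, b = primer_metrics(m, "P1"), primer_metrics(m_shuffled, "P1")
        for fld in ("H", "PIC", "EMR", "Havp", "MI", "D", "RP"):
            assert getattr(a, fld) == pytest.approx(getattr(b, fld), abs=1e-12)

    def test_adding_monomorphic_locus_lowers_ppb_keeps_rp(self):
        rng = np.random.default_rng(8)
        data = rng.integers(0, 2, (15, 6)).astype(float)
        m = make_matrix(data)
        m_plus = make_matrix(np.hstack([data, np.ones((15, 1))]))
        assert count_bands(m_plus, "P1")[2] < count_bands(m, "P1")[2]
        assert emr(m_plus, "P1") < emr(m, "P1") + 1  # beta shrinks
        assert resolving_power(m_plus, "P1") == pytest.approx(
            resolving_power(m, "P1")
        )
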