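"""Length-distribution analytics: conversions, histograms, kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifsim import (
    LengthDistribution,
    SimulationParams,
    elongation_constant,
    fold_reduction,
    length_to_ulfs,
    lp_normalized_fractions,
    mass_concentration,
    mass_weighted_histogram,
    normalized_sweeps,
    number_histogram,
    summarize,
    ulfs_for_concentration,
    ulfs_to_length,
)


class TestUlfConversion:
    @pytest.mark.parametrize(
        "length_nm, ulfs",
        [(60.0, 1.0), (353.0, 7.862), (1500.0, 34.72), (2100.0, 48.775)],
    )
    def test_forward(self, length_nm, ulfs):
        assert length_to_ulfs(length_nm) == pytest.approx(ulfs, abs=0.005)

    @pytest.mark.parametrize("i, length_nm", [(1.0, 60.0), (2.0, 102.7)])
    def test_inverse(self, i, length_nm):
        assert ulfs_to_length(i) == pytest.approx(length_nm)

    @given(st.floats(min_value=1.0, max_value=1e4))
    @settings(deadline=None)
    def test_round_trip_identity(self, i):
        assert length_to_ulfs(ulfs_to_length(i)) == pytest.approx(i, abs=1e-9)

    def test_strictly_increasing(self):
        L = np.linspace(60.0, 5000.0, 100)
        assert np.all(np.diff(length_to_ulfs(L)) > 0)
        assert np.all(np.diff(ulfs_to_length(np.linspace(1, 100, 50))) > 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            length_to_ulfs(59.0)
        with pytest.raises(ValueError):
            ulfs_to_length(0.5)


class TestSummarize:
    def test_two_filaments(self):
        d = LengthDistribution([60.0, 102.7])
        s = summarize(d)
        assert s.n == 2
        assert s.mean_ulf == pytest.approx(1.5)

    def test_constant_lengths_zero_sd(self):
        s = summarize(LengthDistribution([500.0] * 10))
        assert s.sd_ulf == pytest.approx(0.0, abs=1e-12)

    def test_matches_first_principles(self, rng):
        lengths = rng.uniform(60.0, 4000.0, 500)
        s = summarize(LengthDistribution(lengths))
        u = (lengths - 60.0) / 42.7 + 1.0
        assert s.mean_length_nm == pytest.approx(lengths.mean())
        assert s.mean_ulf == pytest.approx(u.mean())
        assert s.sd_ulf == pytest.approx(u.std())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            LengthDistribution([])


class TestHistograms:
    def test_single_bin(self):
        d = LengthDistribution([60.0, 70.0, 80.0])
        _, frac = number_histogram(d, 1.0)
        assert frac.tolist() == [1.0]

    def test_number_fractions(self):
        d = LengthDistribution.from_ulf_counts([1, 1, 2, 2])
        _, frac = number_histogram(d, 1.0)
        assert np.allclose(frac, [0.5, 0.5])

    def test_mass_equals_number_for_equal_lengths(self):
        d = LengthDistribution([500.0] * 8)
        _, nf = number_histogram(d, 5.0)
        _, mf = mass_weighted_histogram(d, 5.0)
        assert np.allclose(nf, mf)

    def test_mass_weighting_favours_long(self):
        # 100 nm and 300 nm filaments: number 50/50, mass 25/75
        d = LengthDistribution([100.0, 300.0])
        _, nf = number_histogram(d, 5.0)
        _, mf = mass_weighted_histogram(d, 5.0)
        assert np.allclose(nf, [0.5, 0.5])
        assert np.allclose(mf, [0.25, 0.75])

    @pytest.mark.parametrize("width", [1.0, 5.0])
    def test_matches_brute_force(self, rng, width):
        lengths = rng.uniform(60.0, 3000.0, 400)
        d = LengthDistribution(lengths)
        edges, nf = number_histogram(d, width)
        _, mf = mass_weighted_histogram(d, width)
        u = (lengths - 60.0) / 42.7 + 1.0
        for k in range(len(edges) - 1):
            sel = (u >= edges[k]) & (u < edges[k + 1])
            if k == len(edges) - 2:  # top edge closes the last bin
                sel |= u == edges[k + 1]
            assert nf[k] == pytest.approx(sel.sum() / 400)
            assert mf[k] == pytest.approx(lengths[sel].sum() / lengths.sum())
        assert nf.sum() == pytest.approx(1.0, abs=1e-12)
        assert mf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_lp_normalized_all_short(self):
        d = LengthDistribution([100.0, 500.0, 900.0])
        frac = lp_normalized_fractions(d, 1000.0)
        assert frac.tolist() == [1.0]

    def test_lp_normalized_arithmetic(self):
        d = LengthDistribution([500.0, 1500.0, 3500.0])
        frac = lp_normalized_fractions(d, 1000.0)
        assert frac[0] == pytest.approx(0.5 / 5.5)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)

    def test_lp_normalized_matches_brute_force(self, rng):
        lengths = rng.uniform(60.0, 5000.0, 300)
        d = LengthDistribution(lengths)
        frac = lp_normalized_fractions(d, 750.0)
        for k in range(len(frac)):
            sel = (lengths >= k * 750.0) & (lengths < (k + 1) * 750.0)
            assert frac[k] == pytest.approx(lengths[sel].sum() / lengths.sum())


class TestKinetics:
    def test_no_elongation(self):
        assert elongation_constant(1.0, 0.1, 100.0) == 0.0

    @pytest.mark.parametrize(
        "mean_ulf, c, t, expected",
        [
            (35.0, 0.1, 7200.0, 0.0472),
            (3.7, 0.0025, 60.0, 18.0),
        ],
    )
    def test_published_style_values(self, mean_ulf, c, t, expected):
        assert elongation_constant(mean_ulf, c, t) == pytest.approx(expected, rel=1e-2)

    @given(
        st.floats(min_value=1.01, max_value=100.0),
        st.floats(min_value=1e-3, max_value=100.0),
        st.floats(min_value=1e-2, max_value=1e5),
        st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(deadline=None)
    def test_scaling_invariance(self, mean_ulf, c, t, k):
        a = elongation_constant(mean_ulf, c, t)
        b = elongation_constant(mean_ulf, k * c, t / k)
        assert b == pytest.approx(a, rel=1e-9)


class TestConcentration:
    # (c g/l, volume um^3, n0) bookkeeping triples of the simulation runs
    TRIPLES = [
        (0.10, 28.0, 1000),
        (2.19, 7.63, 5832),
        (7.46, 2.24, 5832),
        (17.8, 0.94, 5832),
        (17.5, 7.63, 46656),
    ]

    @pytest.mark.parametrize("c, volume, n0", TRIPLES)
    def test_single_mass_constant_reproduces_triples(self, c, volume, n0):
        assert mass_concentration(n0, volume) == pytest.approx(c, rel=0.03)

    def test_zero_ulfs(self):
        assert mass_concentration(0, 1.0) == 0.0

    @pytest.mark.parametrize("c, volume, n0", TRIPLES)
    def test_inverse(self, c, volume, n0):
        assert ulfs_for_concentration(c, volume) == pytest.approx(n0, rel=0.03)

    def test_custom_params_mass(self):
        p = SimulationParams(ulf_mass_g=1e-18)
        assert mass_concentration(1000, 1.0, p) == pytest.approx(1.0)


class TestNormalizedSweeps:
    def test_identity_at_unit_concentration(self):
        assert normalized_sweeps(1.0, 12345.0) == 12345.0

    def test_published_style_products(self):
        assert normalized_sweeps(17.8, 4.30e6) == pytest.approx(76.5e6, rel=1e-3)
        assert normalized_sweeps(0.10, 750e6) == pytest.approx(75e6, rel=1e-3)


class TestFoldReduction:
    def test_trivial(self):
        assert fold_reduction(100, 100) == 1.0

    def test_published_style_aggregate(self):
        assert fold_reduction(300_000, 9000) == pytest.approx(33.3, abs=0.1)
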