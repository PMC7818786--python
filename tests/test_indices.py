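"""Index algebra: exact identities, bounds, oracle equivalence, Hurst fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fractalconn import (BivariateFractalSpec, ConnectivityProfile, ScaleBand,
                         band_average, bivariate_realizations, dtcwt_forward,
                         estimate_hurst, w_coh, w_icoh, w_wpli,
                         wavelet_cross_spectrum, wavelet_indices)


@pytest.fixture(scope="module")
def pair_coeffs(bank):
    rng = np.random.default_rng(2)
    spec = BivariateFractalSpec(H1=0.7, H2=0.8, rho=0.6, delta=4, n=2 ** 10,
                                seed=2)
    data = next(bivariate_realizations(spec, 1, rng))
    a = dtcwt_forward(data[0], 6, bank)
    b = dtcwt_forward(data[1], 6, bank)
    return a, b


class TestCrossSpectrum:
    def test_self_spectrum_real_nonnegative(self, pair_coeffs):
        a, _ = pair_coeffs
        S = wavelet_cross_spectrum(a, a)
        assert np.all(np.abs(S.values.imag) < 1e-12 * np.abs(S.values))
        assert np.all(S.values.real >= 0.0)

    def test_hermitian_symmetry_exact(self, pair_coeffs):
        a, b = pair_coeffs
        Sab = wavelet_cross_spectrum(a, b)
        Sba = wavelet_cross_spectrum(b, a)
        assert np.allclose(Sab.values, np.conj(Sba.values), rtol=1e-13, atol=0)

    def test_white_noise_diagonal_flat(self, bank):
        rng = np.random.default_rng(11)
        J = 7
        acc = np.zeros(J)
        N = 100
        for _ in range(N):
            c = dtcwt_forward(rng.standard_normal(2 ** 11), J, bank)
            acc += wavelet_cross_spectrum(c, c).values.real
        inner = (acc / N)[1: J - 1]
        assert inner.max() / inner.min() < 1.5

    def test_mismatched_inputs_rejected(self, bank, pair_coeffs):
        a, _ = pair_coeffs
        other = dtcwt_forward(np.zeros(2 ** 9), 5, bank)
        with pytest.raises(ValueError):
            wavelet_cross_spectrum(a, other)


class TestIndexIdentities:
    def test_self_channel(self, pair_coeffs):
        a, _ = pair_coeffs
        S = wavelet_cross_spectrum(a, a)
        coh = w_coh(S, S, S)
        icoh = w_icoh(S, S, S)
        wpli = w_wpli(a, a)
        assert np.allclose(coh.values, 1.0, atol=1e-12)
        assert np.allclose(icoh.values, 0.0, atol=1e-12)
        assert np.all(wpli.values == 0.0)
        assert np.all(wpli.flagged)      # 0/0 convention: value 0, flagged

    def test_antisymmetry_under_swap(self, pair_coeffs):
        a, b = pair_coeffs
        Saa = wavelet_cross_spectrum(a, a)
        Sbb = wavelet_cross_spectrum(b, b)
        Sab = wavelet_cross_spectrum(a, b)
        Sba = wavelet_cross_spectrum(b, a)
        icoh_ab = w_icoh(Saa, Sbb, Sab).values
        icoh_ba = w_icoh(Sbb, Saa, Sba).values
        assert np.allclose(icoh_ab, -icoh_ba, atol=1e-14)
        wpli_ab = w_wpli(a, b).values
        wpli_ba = w_wpli(b, a).values
        assert np.allclose(wpli_ab, -wpli_ba, atol=1e-14)
        coh_ab = np.abs(w_coh(Saa, Sbb, Sab).values)
        coh_ba = np.abs(w_coh(Sbb, Saa, Sba).values)
        assert np.allclose(coh_ab, coh_ba, atol=1e-14)

    def test_bounds(self, pair_coeffs):
        a, b = pair_coeffs
        Saa = wavelet_cross_spectrum(a, a)
        Sbb = wavelet_cross_spectrum(b, b)
        Sab = wavelet_cross_spectrum(a, b)
        assert np.all(np.abs(w_coh(Saa, Sbb, Sab).values) <= 1 + 1e-10)
        assert np.all(np.abs(w_icoh(Saa, Sbb, Sab).values) <= 1 + 1e-10)
        assert np.all(np.abs(w_wpli(a, b).values) <= 1.0)

    def test_wpli_saturates_for_consistent_sign(self, bank):
        # Delay one channel so the per-coefficient imaginary parts share a
        # sign at some octave: |wPLI| = 1 there by construction of the ratio.
        n = 2 ** 11
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.standard_normal(n))
        y = np.roll(x, 3)
        a = dtcwt_forward(x, 6, bank)
        b = dtcwt_forward(y, 6, bank)
        im2 = np.imag(a.interior(2) * np.conj(b.interior(2)))
        if np.all(im2 > 0) or np.all(im2 < 0):
            assert abs(w_wpli(a, b).values[1]) == pytest.approx(1.0)
        # regardless, the identity |sum| <= sum|.| is tight iff signs agree
        prof = w_wpli(a, b)
        tight = np.isclose(np.abs(prof.values), 1.0)
        for j in np.flatnonzero(tight) + 1:
            im = np.imag(a.interior(j) * np.conj(b.interior(j)))
            assert np.all(im >= 0) or np.all(im <= 0)


class TestOracleEquivalence:
    def test_naive_double_loop_recomputation(self, bank):
        # On a 64-sample pair, the vectorized spectrum and wPLI must equal a
        # literal per-coefficient recomputation to 1e-12 relative error.
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 64))
        a = dtcwt_forward(x, 3, bank)
        b = dtcwt_forward(y, 3, bank)
        Sab = wavelet_cross_spectrum(a, b)
        wpli = w_wpli(a, b)
        for j in range(1, 4):
            da, db = a.interior(j), b.interior(j)
            acc = 0.0 + 0.0j
            num = den = 0.0
            for k in range(len(da)):
                prod = da[k] * np.conj(db[k])
                acc += prod
                num += prod.imag
                den += abs(prod.imag)
            acc /= len(da)
            assert abs(Sab.values[j - 1] - acc) <= 1e-12 * abs(acc)
            assert abs(wpli.values[j - 1] - num / den) <= 1e-12


class TestBandAverage:
    def test_hand_computed_mean_of_absolute_values(self):
        p = ConnectivityProfile(index="ICOH", basis="wavelet",
                                values=np.array([-0.2, 0.4, -0.6]),
                                flagged=np.zeros(3, bool),
                                octaves=np.array([3, 4, 5]))
        assert band_average(p, ScaleBand(3, 5)) == pytest.approx(0.4)

    def test_zero_profile(self):
        p = ConnectivityProfile(index="ICOH", basis="wavelet",
                                values=np.zeros(4), flagged=np.zeros(4, bool),
                                octaves=np.arange(1, 5))
        assert band_average(p, ScaleBand(1, 4)) == 0.0

    def test_flagged_octaves_are_excluded(self):
        p = ConnectivityProfile(index="ICOH", basis="wavelet",
                                values=np.array([0.5, 99.0, 0.1]),
                                flagged=np.array([False, True, False]),
                                octaves=np.array([3, 4, 5]))
        assert band_average(p, ScaleBand(3, 5)) == pytest.approx(0.3)
        with pytest.raises(ValueError, match="no unflagged"):
            band_average(ConnectivityProfile(
                index="ICOH", basis="wavelet", values=np.array([1.0]),
                flagged=np.array([True]), octaves=np.array([3])),
                ScaleBand(3, 3))

    def test_band_exceeding_support_rejected(self):
        p = ConnectivityProfile(index="ICOH", basis="wavelet",
                                values=np.zeros(3), flagged=np.zeros(3, bool),
                                octaves=np.array([1, 2, 3]))
        with pytest.raises(ValueError, match="exceeds"):
            band_average(p, ScaleBand(2, 5))

    @given(vals=st.lists(st.floats(-1.0, 1.0), min_size=2, max_size=8))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_result_in_unit_interval(self, vals):
        v = np.asarray(vals)
        p = ConnectivityProfile(index="wPLI", basis="wavelet", values=v,
                                flagged=np.zeros(len(v), bool),
                                octaves=np.arange(1, len(v) + 1))
        ba = band_average(p, ScaleBand(1, len(v)))
        assert 0.0 <= ba <= 1.0

    def test_fourier_profile_band_selection(self):
        freqs = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        p = ConnectivityProfile(index="ICOH", basis="fourier",
                                values=np.array([9.0, 0.2, -0.4, 9.0, 9.0]),
                                flagged=np.zeros(5, bool), frequencies=freqs)
        band = ScaleBand(5, 6, fs=100.0, f0=0.64)   # maps to [1.0, 2.0] Hz
        assert band_average(p, band) == pytest.approx(0.3)


class TestHurstEstimation:
    def test_white_noise_recovers_half(self, bank):
        rng = np.random.default_rng(19)
        ests = []
        for _ in range(10):
            c = dtcwt_forward(rng.standard_normal(2 ** 14), 9, bank)
            S = wavelet_cross_spectrum(c, c)
            ests.append(estimate_hurst(S, ScaleBand(3, 9), "fGn").H)
        assert abs(np.mean(ests) - 0.5) < 0.05

    def test_fgn_recovery(self, bank):
        spec = BivariateFractalSpec(H1=0.8, H2=0.8, rho=0.0, n=2 ** 14, seed=23)
        ests = []
        for data in bivariate_realizations(spec, 30):
            c = dtcwt_forward(data[0], 9, bank)
            S = wavelet_cross_spectrum(c, c)
            ests.append(estimate_hurst(S, ScaleBand(3, 9), "fGn").H)
        assert abs(np.mean(ests) - 0.8) < 0.05

    def test_fbm_class_mapping(self, bank):
        from fractalconn import integrate_to_fbm
        spec = BivariateFractalSpec(H1=0.7, H2=0.7, rho=0.0, n=2 ** 14, seed=29)
        slopes, ests = [], []
        for data in bivariate_realizations(spec, 30):
            c = dtcwt_forward(integrate_to_fbm(data[0]), 9, bank)
            S = wavelet_cross_spectrum(c, c)
            h = estimate_hurst(S, ScaleBand(3, 9), "fBm")
            slopes.append(h.slope)
            ests.append(h.H)
        assert abs(np.mean(slopes) - 2.4) < 0.1
        assert abs(np.mean(ests) - 0.7) < 0.05

    def test_error_paths(self, bank):
        c = dtcwt_forward(np.random.default_rng(0).standard_normal(2 ** 10),
                          6, bank)
        S = wavelet_cross_spectrum(c, c)
        with pytest.raises(ValueError, match="3 octaves"):
            estimate_hurst(S, ScaleBand(3, 4), "fGn")
        with pytest.raises(ValueError):
            estimate_hurst(S, ScaleBand(3, 6), "white")


class TestNoiseFloor:
    def test_coherence_floor_decreases_with_sample_size(self, bank):
        # Independent channels: |W-COH| at a fixed octave reflects the
        # number of coefficients averaged, so it shrinks as n grows.
        means = {}
        for n in (2 ** 12, 2 ** 14):
            spec = BivariateFractalSpec(H1=0.7, H2=0.7, rho=0.0, n=n, seed=31)
            vals = []
            for data in bivariate_realizations(spec, 60):
                prof = wavelet_indices(data[0], data[1], 4, bank)["COH"]
                vals.append(abs(prof.value(3)))
            means[n] = np.mean(vals)
        assert means[2 ** 14] < means[2 ** 12]
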