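"""Simulator: exact covariance structure, delays, fBm integration, trends."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fractalconn import (BivariateFractalSpec, SynthesisError, TimeSeriesSet,
                         TrendSpec, add_trend, bivariate_realizations,
                         fgn_covariance, generate_network_dataset,
                         integrate_to_fbm, synthesize_bivariate,
                         wavelet_indices)
from fractalconn.transform import dtcwt_forward


class TestFgnCovariance:
    def test_closed_form_values(self):
        assert fgn_covariance(0.5, 3) == pytest.approx(0.0)
        assert fgn_covariance(0.5, 1) == pytest.approx(0.0)
        assert fgn_covariance(0.31, 0) == pytest.approx(1.0)
        assert fgn_covariance(0.8, 1) == pytest.approx(0.5 * (2 ** 1.6 - 2), abs=1e-12)

    @given(H=st.floats(0.05, 0.95), lag=st.integers(-64, 64))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_symmetric_in_lag(self, H, lag):
        assert fgn_covariance(H, lag) == pytest.approx(fgn_covariance(H, -lag))

    def test_domain_error(self):
        for H in (0.0, 1.0, -0.2, 1.4):
            with pytest.raises(ValueError):
                fgn_covariance(H, 1)


class TestBivariateSynthesis:
    def test_autocovariance_matches_theory(self):
        # 500 realizations of n=2^12 fGn; sample autocovariance at lags <= 16
        # within 3 Monte-Carlo standard errors of the closed form.
        H, n, N = 0.7, 2 ** 12, 500
        spec = BivariateFractalSpec(H1=H, H2=H, rho=0.0, n=n, seed=4)
        lags = np.arange(17)
        est = np.zeros((N, len(lags)))
        for i, data in enumerate(bivariate_realizations(spec, N)):
            x = data[0]
            for k in lags:
                est[i, k] = np.mean(x[: n - k] * x[k:])
        mean = est.mean(axis=0)
        se = est.std(axis=0, ddof=1) / np.sqrt(N)
        theory = fgn_covariance(H, lags)
        assert np.all(np.abs(mean - theory) < 3 * se + 1e-12)

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6, 0.9])
    def test_lag0_cross_correlation_equals_rho(self, rho):
        spec = BivariateFractalSpec(H1=0.7, H2=0.8, rho=rho, n=2 ** 12, seed=5)
        N = 200
        vals = np.empty(N)
        for i, data in enumerate(bivariate_realizations(spec, N)):
            vals[i] = np.mean(data[0] * data[1])
        se = vals.std(ddof=1) / np.sqrt(N)
        assert abs(vals.mean() - rho) < 3 * se + 1e-12

    def test_cross_correlation_peaks_at_delay(self):
        delta, N = 8, 100
        spec = BivariateFractalSpec(H1=0.7, H2=0.8, rho=0.6, delta=delta,
                                    n=2 ** 12, seed=6)
        hits = 0
        lags = np.arange(-32, 33)
        for data in bivariate_realizations(spec, N):
            x1, x2 = data
            cc = [np.mean(x1[: len(x1) - abs(k)] * x2[abs(k):]) if k >= 0
                  else np.mean(x2[: len(x2) - abs(k)] * x1[abs(k):])
                  for k in lags]
            if lags[int(np.argmax(cc))] == delta:
                hits += 1
        assert hits > N // 2

    def test_seed_reproducibility_and_independence(self):
        spec = BivariateFractalSpec(H1=0.6, H2=0.6, rho=0.5, n=2 ** 8, seed=9)
        a = synthesize_bivariate(spec)
        b = synthesize_bivariate(spec)
        assert np.array_equal(a.data, b.data)
        from dataclasses import replace
        c = synthesize_bivariate(replace(spec, seed=10))
        assert not np.allclose(a.data, c.data)

    def test_non_psd_triple_is_rejected(self):
        # Strongly mismatched exponents admit only limited correlation.
        with pytest.raises(SynthesisError, match="rho"):
            next(bivariate_realizations(
                BivariateFractalSpec(H1=0.05, H2=0.95, rho=0.99, n=2 ** 10), 1))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BivariateFractalSpec(H1=1.2, H2=0.5, rho=0.0)
        with pytest.raises(ValueError):
            BivariateFractalSpec(H1=0.5, H2=0.5, rho=1.5)
        with pytest.raises(ValueError):
            BivariateFractalSpec(H1=0.5, H2=0.5, rho=0.0, delta=-1)
        with pytest.raises(ValueError):
            BivariateFractalSpec(H1=0.5, H2=0.5, rho=0.0, n=32)


class TestFbmIntegration:
    def test_trivial_sequences(self):
        assert np.array_equal(integrate_to_fbm(np.zeros(5)), np.zeros(5))
        assert np.array_equal(integrate_to_fbm(np.ones(5)),
                              np.array([1, 2, 3, 4, 5.0]))
        with pytest.raises(ValueError):
            integrate_to_fbm(np.array([]))

    def test_differences_invert_integration(self, rng):
        x = rng.standard_normal(256)
        b = integrate_to_fbm(x)
        assert np.allclose(np.diff(np.concatenate([[0.0], b])), x)

    def test_fbm_variance_growth_exponent(self):
        # var B_H(t) ~ t^{2H}: log-log slope 1.4 +- 0.1 for H=0.7.
        H, n, N = 0.7, 2 ** 10, 400
        spec = BivariateFractalSpec(H1=H, H2=H, rho=0.0, n=n, seed=13)
        paths = np.empty((N, n))
        for i, data in enumerate(bivariate_realizations(spec, N)):
            paths[i] = integrate_to_fbm(data[0])
        t = np.unique(np.logspace(1, np.log10(n - 1), 20).astype(int))
        var = paths[:, t].var(axis=0)
        slope = np.polyfit(np.log(t), np.log(var), 1)[0]
        assert abs(slope - 2 * H) < 0.1


class TestTrends:
    def _base(self, n=2 ** 10):
        return synthesize_bivariate(
            BivariateFractalSpec(H1=0.8, H2=0.8, rho=0.0, n=n, seed=3))

    def test_zero_amplitude_is_identity(self):
        ts = self._base()
        out = add_trend(ts, TrendSpec(trend_kind="polynomial", amplitude=0.0))
        assert np.array_equal(out.data, ts.data)
        assert out.data is not ts.data

    def test_linear_trend_difference_is_affine(self):
        ts = self._base()
        out = add_trend(ts, TrendSpec(trend_kind="polynomial", amplitude=1.0,
                                      order=1, seed=2))
        for c in range(2):
            diff = out.data[c] - ts.data[c]
            resid = diff - np.polyval(np.polyfit(np.arange(len(diff)), diff, 1),
                                      np.arange(len(diff)))
            assert np.max(np.abs(resid)) < 1e-8 * max(1.0, np.max(np.abs(diff)))
            assert diff.std() == pytest.approx(ts.data[c].std(), rel=1e-9)

    def test_input_unmodified_and_unknown_kind_rejected(self):
        ts = self._base()
        before = ts.data.copy()
        add_trend(ts, TrendSpec(trend_kind="sinusoid", amplitude=2.0, period=64))
        assert np.array_equal(ts.data, before)
        with pytest.raises(ValueError):
            TrendSpec(trend_kind="steps", amplitude=1.0)

    def test_fbm_trend_perturbs_coarsest_octaves_most(self, bank):
        # Wavelet log-spectra with/without an added slow fBm trend deviate
        # most at the coarsest octave.
        J, N = 8, 50
        spec = BivariateFractalSpec(H1=0.8, H2=0.8, rho=0.0, n=2 ** 12, seed=17)
        trend = TrendSpec(trend_kind="fbm", amplitude=1.0, hurst=0.2, seed=1)
        dev = np.zeros(J)
        for i, data in enumerate(bivariate_realizations(spec, N)):
            ts = TimeSeriesSet(data=data, fs=1.0)
            tr = add_trend(ts, TrendSpec(trend_kind="fbm", amplitude=1.0,
                                         hurst=0.2, seed=1000 + i))
            c0 = dtcwt_forward(ts.data[0], J, bank)
            c1 = dtcwt_forward(tr.data[0], J, bank)
            for j in range(1, J + 1):
                e0 = np.mean(np.abs(c0.interior(j)) ** 2)
                e1 = np.mean(np.abs(c1.interior(j)) ** 2)
                dev[j - 1] += np.log2(e1) - np.log2(e0)
        assert int(np.argmax(np.abs(dev))) + 1 == J


class TestNetworkDataset:
    def test_independent_channels_have_no_phase_coupling(self, bank):
        from fractalconn import ScaleBand, band_average
        band = ScaleBand(3, 6)
        N = 30
        vals = []
        for s in range(N):
            ts = generate_network_dataset(M=4, edges=[], H=0.7, n=2 ** 11, seed=s)
            prof = wavelet_indices(ts.data[0], ts.data[1], 6, bank)["wPLI"]
            vals.append(np.mean(prof.values[2:6]))
        se = np.std(vals, ddof=1) / np.sqrt(N)
        assert abs(np.mean(vals)) < 3 * se + 1e-12

    def test_connected_pair_ranks_first_for_wpli(self, bank):
        from fractalconn import ScaleBand, pairwise_band_indices
        band = ScaleBand(3, 6)
        hits, N = 0, 40
        for s in range(N):
            ts = generate_network_dataset(
                M=4, edges=[(0, 1, 0.8, 8)], H=0.7, n=2 ** 13, seed=s)
            cm = pairwise_band_indices(ts, "wPLI", "wavelet", band, bank)
            iu = np.triu_indices(4, k=1)
            flat = cm.values[iu]
            assert len(flat) == 6
            if np.argmax(flat) == 0:      # pair (0, 1) listed first
                hits += 1
        assert hits >= int(0.9 * N)

    def test_correlated_but_undelayed_pair_shows_no_wpli(self, bank):
        # rho=0.8 at zero delay: instantaneous mixing only, wPLI stays 0.
        N = 40
        vals = []
        for s in range(N):
            ts = generate_network_dataset(
                M=2, edges=[(0, 1, 0.8, 0)], H=0.7, n=2 ** 12, seed=100 + s)
            prof = wavelet_indices(ts.data[0], ts.data[1], 6, bank)["wPLI"]
            vals.append(np.mean(prof.values[2:6]))
        se = np.std(vals, ddof=1) / np.sqrt(N)
        assert abs(np.mean(vals)) < 3 * se + 1e-12

    def test_overlapping_edges_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            generate_network_dataset(
                M=3, edges=[(0, 1, 0.5, 0), (1, 2, 0.5, 0)], H=0.7, n=2 ** 8)


class TestTimeSeriesSet:
    def test_validation(self):
        with pytest.raises(ValueError, match="unique"):
            TimeSeriesSet(data=np.zeros((2, 8)), fs=1.0, labels=["a", "a"])
        with pytest.raises(ValueError, match="non-finite"):
            TimeSeriesSet(data=np.array([[np.inf, 0.0]]), fs=1.0)
        with pytest.raises(ValueError):
            TimeSeriesSet(data=np.zeros((1, 4)), fs=-1.0)
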