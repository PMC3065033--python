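"""Synchronization estimators: coherence, nonlinear interdependence, PDC."""

import numpy as np
import pytest

from neurosync import (
    ComputationError,
    EmbeddingParams,
    TimeSeriesSet,
    VARModel,
    WelchParams,
    band_reduce,
    connectivity_matrix,
    estimate_tau,
    fit_var,
    gen_coupled_henon,
    gen_sinusoid_pair,
    gen_var,
    msc,
    pdc,
    rim,
)


class TestMsc:
    def test_self_coherence_is_exactly_one(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((2048, 2)))
        f, gamma = msc(ts, 0, 0)
        assert np.all(gamma == 1.0)

    def test_independent_white_noise_band_mean_small(self):
        # 64 averaged half-overlapping 256-sample windows need ~8320 samples;
        # the coherence bias of K independent windows is about 1/K
        ts = gen_sinusoid_pair(10.0, 128.0, snr=0.0, n_samples=256 * 33, seed=7)
        f, gamma = msc(ts, 0, 1)
        assert band_reduce(f, gamma, None) < 0.1

    def test_pure_delay_preserves_coherence(self, rng):
        x = rng.standard_normal(6 * 4096)
        y = np.roll(x, 5)
        ts = TimeSeriesSet(np.column_stack([x, y]))
        f, gamma = msc(ts, 0, 1)
        # |e^{-i 5 w}| = 1, so a pure delay leaves the magnitude coherence at 1
        # (up to segment-boundary leakage)
        assert gamma.mean() > 0.95
        assert gamma.min() > 0.8

    def test_symmetric_in_channel_order(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((1024, 2)))
        _, g_ij = msc(ts, 0, 1)
        _, g_ji = msc(ts, 1, 0)
        assert np.allclose(g_ij, g_ji)

    def test_constant_channel_rejected(self):
        data = np.column_stack([np.ones(512), np.random.default_rng(0).standard_normal(512)])
        ts = TimeSeriesSet(data)
        with pytest.raises(ComputationError, match="constant"):
            msc(ts, 0, 1)

    def test_snr_increases_band_coherence(self):
        vals = []
        for snr in (0.1, 1.0, 10.0):
            ts = gen_sinusoid_pair(10.0, 128.0, snr=snr, n_samples=4096, seed=3)
            f, gamma = msc(ts, 0, 1)
            vals.append(band_reduce(f, gamma, (8.0, 13.0)))
        assert vals[0] < vals[1] < vals[2]


class TestEstimateTau:
    def test_sinusoid_quarter_period(self):
        t = np.arange(500)
        assert estimate_tau(np.sin(2 * np.pi * t / 20)) == 5
        assert estimate_tau(np.sin(2 * np.pi * t / 40)) == 10

    def test_white_noise_gives_lag_one(self, rng):
        assert estimate_tau(rng.standard_normal(2000)) == 1

    def test_constant_series_rejected(self):
        with pytest.raises(ComputationError, match="constant"):
            estimate_tau(np.ones(100))


class TestRim:
    def test_identical_channels_near_maximum(self):
        h = gen_coupled_henon(0.0, 2000, seed=1)
        x = h.data[:, 0]
        ts = TimeSeriesSet(np.column_stack([x, x]))
        res = rim(ts, 0, 1, EmbeddingParams(m=5, tau=1, k=10))
        assert res.symmetric >= 0.95

    def test_independent_realizations_near_zero(self):
        for seed in (1, 2, 3):
            ts = gen_coupled_henon(0.0, 2000, seed=seed)
            res = rim(ts, 0, 1, EmbeddingParams(m=5, tau=1, k=10))
            assert abs(res.symmetric) < 0.05

    def test_synchronization_value_clipped_to_unit_interval(self):
        ts = gen_coupled_henon(0.0, 1500, seed=4)
        res = rim(ts, 0, 1)
        assert 0.0 <= res.synchronization <= 1.0

    def test_too_short_series_rejected(self):
        ts = TimeSeriesSet(np.random.default_rng(0).standard_normal((30, 2)))
        with pytest.raises(ComputationError, match="too short"):
            rim(ts, 0, 1, EmbeddingParams(m=5, tau=2, k=10))

    def test_coupling_increases_index(self):
        lo = rim(gen_coupled_henon(0.2, 2000, seed=11), 0, 1).symmetric
        hi = rim(gen_coupled_henon(0.8, 2000, seed=11), 0, 1).symmetric
        assert hi > lo


class TestVarFit:
    def test_parameter_recovery(self):
        A = np.array([[[0.5, 0.1], [0.0, -0.3]]])
        sim = gen_var(A, None, n_samples=5000, seed=5)
        model = fit_var(sim.ts, 1)
        assert np.all(np.abs(model.coefs - A) < 0.05)

    def test_white_noise_coefficients_near_zero(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((5000, 3)))
        model = fit_var(ts, 1)
        assert np.all(np.abs(model.coefs) < 0.05)

    def test_duplicated_channel_rejected(self, rng):
        x = rng.standard_normal(500)
        ts = TimeSeriesSet(np.column_stack([x, x]))
        with pytest.raises(ComputationError, match="rank deficient"):
            fit_var(ts, 1)

    def test_aic_selects_generating_order(self):
        A = np.zeros((2, 2, 2))
        A[0] = [[0.4, 0.0], [0.3, 0.2]]
        A[1] = [[-0.3, 0.0], [0.0, -0.3]]
        sim = gen_var(A, None, n_samples=4000, seed=9)
        model = fit_var(sim.ts, "aic", p_max=5)
        assert model.order == 2

    def test_matches_statsmodels_ols(self):
        statsmodels = pytest.importorskip("statsmodels.tsa.api")
        A = np.array([[[0.5, 0.2], [0.1, -0.4]]])
        sim = gen_var(A, None, n_samples=2000, seed=2)
        ours = fit_var(sim.ts, 1)
        ref = statsmodels.VAR(np.asarray(sim.ts.data)).fit(1, trend="c")
        assert np.allclose(ours.coefs, ref.coefs, atol=1e-6)


class TestPdc:
    def diag_model(self):
        return VARModel(order=1, coefs=np.array([np.diag([0.5, 0.3])]), sigma=np.eye(2))

    def test_diagonal_var_has_zero_cross_pdc(self):
        vals = pdc(self.diag_model(), np.linspace(0, 0.5, 64))
        assert np.all(vals[:, 0, 1] == 0.0)
        assert np.all(vals[:, 1, 0] == 0.0)

    def test_standard_columns_unit_sum_of_squares(self, rng):
        coefs = 0.2 * rng.standard_normal((2, 3, 3))
        model = VARModel(order=2, coefs=coefs, sigma=np.eye(3))
        vals = pdc(model, np.linspace(0, 0.5, 33))
        ssq = (vals**2).sum(axis=1)
        assert np.all(np.abs(ssq - 1.0) < 1e-10)

    def test_one_way_coupling_direction(self):
        coefs = np.array([[[0.5, 0.0], [0.5, 0.3]]])  # A_21 = 0.5, A_12 = 0
        model = VARModel(order=1, coefs=coefs, sigma=np.eye(2))
        vals = pdc(model, np.linspace(0, 0.5, 64))
        assert np.all(vals[:, 1, 0] > 0)
        assert np.all(vals[:, 0, 1] == 0)

    def test_as_printed_variant_lacks_root(self):
        model = self.diag_model()
        freqs = np.linspace(0, 0.5, 16)
        std = pdc(model, freqs, "standard")
        printed = pdc(model, freqs, "as_printed")
        # diagonal model: single nonzero entry per column, so the printed
        # normalization gives 1/|Abar_jj| instead of 1
        assert np.allclose(std[:, 0, 0], 1.0)
        assert not np.allclose(printed[:, 0, 0], 1.0)


class TestBandReduce:
    def test_constant_spectrum(self):
        f = np.linspace(0, 64, 65)
        assert band_reduce(f, np.full(65, 0.7), (8, 13)) == pytest.approx(0.7)

    def test_half_band_occupancy(self):
        f = np.arange(10.0)
        v = np.array([1.0] * 5 + [0.0] * 5)
        assert band_reduce(f, v, (0, 9)) == pytest.approx(0.5)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ComputationError, match="band"):
            band_reduce(np.arange(5.0), np.ones(5), (10, 20))


class TestConnectivityMatrix:
    def test_msc_small_set_symmetric_zero_diagonal(self, rng):
        ts = TimeSeriesSet(rng.standard_normal((1024, 3)))
        res = connectivity_matrix(ts, "msc")
        assert res.matrix.shape == (3, 3)
        assert np.allclose(res.matrix, res.matrix.T)
        assert np.all(np.diag(res.matrix) == 0)
        assert res.params["n_pair_evaluations"] == 3

    def test_pdc_matrix_directional(self):
        coefs = np.array([[[0.5, 0.0], [0.5, 0.3]]])
        sim = gen_var(coefs, None, n_samples=4000, seed=3)
        res = connectivity_matrix(sim.ts, "pdc", order=1)
        assert res.directed
        assert res.matrix[1, 0] > res.matrix[0, 1]

    def test_rim_matrix_symmetric(self):
        ts = gen_coupled_henon(0.5, 600, seed=0)
        res = connectivity_matrix(ts, "rim", emb=EmbeddingParams(m=3, tau=1, k=5))
        assert np.allclose(res.matrix, res.matrix.T)
        assert res.params["n_pair_evaluations"] == 1

    def test_band_restriction_changes_msc_values(self):
        ts = gen_sinusoid_pair(10.0, 128.0, snr=2.0, n_samples=4096, seed=1)
        alpha = connectivity_matrix(ts, "msc", band=(8.0, 13.0)).matrix[0, 1]
        gamma_band = connectivity_matrix(ts, "msc", band=(30.0, 45.0)).matrix[0, 1]
        assert alpha > gamma_band
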