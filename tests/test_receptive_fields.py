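import numpy as np
import pytest

from rgcdegen import receptive_fields as rf


class TestClippedGradient:
    def test_decreasing_trace_clips_to_zero(self):
        out = rf.clipped_gradient(np.linspace(10, 0, 50), sample_rate=10.0)
        assert np.all(out == 0)

    def test_ramp_gives_constant_slope(self):
        fs = 10.0
        trace = 3.0 * np.arange(50) / fs
        out = rf.clipped_gradient(trace, sample_rate=fs)
        assert np.allclose(out, 3.0)

    def test_sine_matches_clipped_cosine(self):
        fs = 200.0
        t = np.arange(0, 10, 1 / fs)
        out = rf.clipped_gradient(np.sin(t), sample_rate=fs)
        expected = np.maximum(0, np.cos(t + 0.5 / fs))  # midpoint convention
        assert np.max(np.abs(out[:-1] - expected[:-1])) < 2 / fs


class TestUpsamplePair:
    def test_frame_expansion_factor(self):
        idx, cdot, trimmed = rf.upsample_pair(1500, np.zeros(3000), trigger_s=0.0)
        assert len(idx) == 15000
        assert trimmed == 0

    def test_constant_gradient_stays_constant(self):
        idx, cdot, _ = rf.upsample_pair(50, np.full(200, 2.5), trigger_s=0.0)
        assert np.allclose(cdot, 2.5)

    def test_zero_order_hold_inverse(self):
        idx, _, _ = rf.upsample_pair(100, np.zeros(300), trigger_s=0.0)
        assert np.array_equal(idx[::10], np.arange(100))

    def test_short_trace_trims_with_warning(self):
        with pytest.warns(UserWarning, match="trimmed"):
            _, _, trimmed = rf.upsample_pair(100, np.zeros(50), trigger_s=0.0)
        assert trimmed > 0


class TestBuildDesign:
    def test_identity_basis_reproduces_lagged_stimulus(self, rng):
        frames = rng.integers(0, 2, size=(40, 3, 3)).astype(float)
        basis = rf.SplineBasis.identity((3, 3, 2))
        lags = np.array([0.0, 0.02])  # 0 and 1 sample at 50 Hz
        idx = np.arange(40)
        X, valid = rf.build_design(frames, idx, basis, lags_s=lags, up_rate=50.0)
        t = valid[5]
        row = X[5].reshape(3, 3, 2)
        assert np.array_equal(row[:, :, 0], frames[t])
        assert np.array_equal(row[:, :, 1], frames[t - 1])

    def test_time_shift_moves_lag_block(self, rng):
        frames = rng.normal(size=(30, 3, 3))
        basis = rf.SplineBasis.identity((3, 3, 2))
        lags = np.array([0.0, 0.02])
        idx = np.arange(30)
        X, valid = rf.build_design(frames, idx, basis, lags_s=lags, up_rate=50.0)
        a = X[4].reshape(3, 3, 2)[:, :, 1]
        b = X[3].reshape(3, 3, 2)[:, :, 0]
        assert np.array_equal(a, b)

    def test_default_feature_count(self):
        basis = rf.SplineBasis.make()
        assert basis.n_features == 10 * 12 * 9 == 1080


def small_instance(rng, T=2500, noise=0.0):
    basis = rf.SplineBasis.make(grid_shape=(6, 4, 5), n_knots=(4, 4, 4))
    frames = rng.integers(0, 2, size=(T // 2, 6, 4)).astype(float)
    idx = np.repeat(np.arange(T // 2), 2)
    lags = np.linspace(-0.04, 0.2, 5)
    X, valid = rf.build_design(frames, idx, basis, lags_s=lags, up_rate=50.0)
    b_true = rng.normal(size=basis.n_features)
    y = 0.3 + X @ b_true + (rng.normal(0, noise, size=len(X)) if noise else 0.0)
    return basis, X, y, b_true


class TestFitRF:
    def test_noiseless_recovery_matches_truth(self, rng):
        _, X, y, b_true = small_instance(rng)
        fit = rf.fit_rf(X, y, beta=0.0)
        assert np.max(np.abs(fit.b - b_true)) < 1e-2
        # spline bases nearly sum to one, so the intercept is only weakly
        # identified against the coefficients
        assert fit.y0 == pytest.approx(0.3, abs=0.02)

    def test_beta_zero_near_least_squares_optimum(self, rng):
        _, X, y, _ = small_instance(rng, noise=0.5)
        fit = rf.fit_rf(X, y, beta=0.0)
        y0_ref, b_ref = rf.closed_form_lstsq(X, y)
        ref = np.concatenate([[y0_ref], b_ref])
        got = np.concatenate([[fit.y0], fit.b])
        assert np.linalg.norm(got - ref) / np.linalg.norm(ref) < 1e-2
        resid_fit = y - fit.y0 - X @ fit.b
        resid_ref = y - y0_ref - X @ b_ref
        gap = (resid_fit @ resid_fit - resid_ref @ resid_ref) / (resid_ref @ resid_ref)
        assert 0 <= gap < 1e-5  # early stopping leaves a tiny optimality gap

    def test_l1_penalty_shrinks_coefficients_on_noise(self, rng):
        _, X, _, _ = small_instance(rng)
        y = rng.normal(size=X.shape[0])
        l1_free = np.abs(rf.fit_rf(X, y, beta=0.0).b).sum()
        l1_pen = np.abs(rf.fit_rf(X, y, beta=0.01).b).sum()
        assert l1_pen < l1_free

    def test_large_beta_drives_weights_to_zero(self, rng):
        _, X, y, _ = small_instance(rng)
        fit = rf.fit_rf(X, y, beta=10.0)
        assert np.max(np.abs(fit.b)) < 1e-6
        assert fit.y0 == pytest.approx(y.mean(), rel=1e-6)

    def test_mismatched_lengths_raise(self, rng):
        with pytest.raises(ValueError):
            rf.fit_rf(rng.normal(size=(10, 3)), np.zeros(11))


class TestAssembleSmooth:
    def test_zero_coefficients_give_zero_rf(self):
        basis = rf.SplineBasis.make()
        assert not rf.assemble_rf(np.zeros(basis.n_features), basis).any()

    def test_impulse_smoothing_matches_kernel(self):
        F = np.zeros((15, 15, 1))
        F[7, 7, 0] = 1.0
        out = rf.smooth_rf(F)
        from scipy.ndimage import gaussian_filter
        expected = gaussian_filter(F[:, :, 0], 1.0, mode="reflect", truncate=2.0)
        assert np.allclose(out[:, :, 0], expected)
        assert out[:, :, 0].sum() == pytest.approx(1.0, abs=1e-6)

    def test_smoothing_preserves_interior_mass(self, rng):
        F = np.zeros((20, 20, 3))
        F[8:12, 8:12, :] = rng.random((4, 4, 3))
        out = rf.smooth_rf(F)
        for k in range(3):
            assert out[:, :, k].sum() == pytest.approx(F[:, :, k].sum(), abs=1e-6)


class TestSvdSplit:
    @staticmethod
    def separable(dx=32, dy=20, dt=15):
        x = np.arange(dx)[:, None]
        y = np.arange(dy)[None, :]
        g = np.exp(-((x - 15) ** 2 + (y - 10) ** 2) / 30.0) - 0.05
        h = np.sin(np.linspace(0, np.pi, dt)) - 0.2
        return g[:, :, None] * h[None, None, :]

    def test_separable_input_gives_qi_one(self):
        Ft, Fs, qi = rf.svd_split(self.separable())
        assert qi == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_contamination_reduces_qi_by_its_share(self):
        F = self.separable()
        dx, dy, dt = F.shape
        M = F.reshape(dx * dy, dt)
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        contam = np.outer(u[:, 1], vt[1]).reshape(F.shape)
        contam *= np.sqrt(0.1 / 0.9) * np.linalg.norm(F) / np.linalg.norm(contam)
        Ft, Fs, qi = rf.svd_split(F + contam)
        assert qi == pytest.approx(0.9, abs=0.03)

    def test_scaling_contract(self):
        F = 3.7 * self.separable()
        Ft, Fs, _ = rf.svd_split(F)
        assert np.max(np.abs(Ft)) == pytest.approx(1.0, abs=1e-9)
        assert np.max(np.abs(Fs)) == pytest.approx(np.max(np.abs(F)), rel=1e-9)

    def test_qi_invariant_to_scaling(self):
        F = self.separable() + 0.01
        _, _, qi1 = rf.svd_split(F)
        _, _, qi2 = rf.svd_split(-42.0 * F)
        assert qi1 == pytest.approx(qi2, abs=1e-12)

    def test_zero_rf_degenerates(self):
        Ft, Fs, qi = rf.svd_split(np.zeros((4, 4, 3)))
        assert qi == 0.0 and not Ft.any() and not Fs.any()


class TestSpatialGaussian:
    @staticmethod
    def gaussian(sx=2.5, sy=1.8, x0=14.0, y0=9.0, dx=32, dy=20):
        xx, yy = np.meshgrid(np.arange(dx), np.arange(dy), indexing="ij")
        return np.exp(-0.5 * (((xx - x0) / sx) ** 2 + ((yy - y0) / sy) ** 2))

    def test_exact_gaussian_self_fit(self):
        fit, qi = rf.fit_spatial_gaussian(self.gaussian())
        assert qi >= 0.999
        assert fit.sigma_x_px == pytest.approx(2.5, rel=0.01)
        assert fit.sigma_y_px == pytest.approx(1.8, rel=0.01)
        assert fit.x0_px == pytest.approx(14.0, abs=0.05)

    def test_white_noise_fails_gate(self, rng):
        _, qi = rf.fit_spatial_gaussian(rng.normal(size=(32, 20)))
        assert qi < 0.5

    def test_noise_share_sets_qi(self, rng):
        G = self.gaussian()
        noise = rng.normal(size=G.shape)
        noise *= np.sqrt(0.25) * G.std() / noise.std()  # 20% of total variance
        _, qi = rf.fit_spatial_gaussian(G + noise)
        assert qi == pytest.approx(0.8, abs=0.05)

    def test_constant_input_degenerates(self):
        fit, qi = rf.fit_spatial_gaussian(np.ones((8, 8)))
        assert fit is None and qi == 0.0


class TestRFSize:
    def test_closed_form_circular(self):
        area, d = rf.rf_size(25.0, 25.0)
        assert d == pytest.approx(100.0)
        assert area == pytest.approx(np.pi * 50 * 50)

    def test_diameter_is_four_sigma_for_circular(self):
        _, d = rf.rf_size(10.0, 10.0)
        assert d == pytest.approx(40.0)

    def test_scaling_law(self):
        a1, d1 = rf.rf_size(10.0, 20.0)
        a2, d2 = rf.rf_size(20.0, 40.0)
        assert a2 == pytest.approx(4 * a1)
        assert d2 == pytest.approx(2 * d1)

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError):
            rf.rf_size(0.0, 10.0)


class TestTemporalPeaks:
    def test_single_peak(self):
        Ft = np.zeros(15)
        i = int(np.argmin(np.abs(rf.LAGS_S - 0.10)))
        Ft[i] = 1.0
        assert rf.temporal_peaks(Ft) == pytest.approx(rf.LAGS_S[i])

    def test_smallest_lag_wins_with_two_peaks(self):
        Ft = np.zeros(15)
        i1, i2 = 3, 5  # separated local maxima at 0.13 s and 0.35 s
        Ft[i1] = 0.8
        Ft[i2] = 1.0
        assert rf.temporal_peaks(Ft) == pytest.approx(rf.LAGS_S[i1])

    def test_subthreshold_gives_none(self):
        assert rf.temporal_peaks(np.full(15, 0.3)) is None


class TestQualityGate:
    @pytest.mark.parametrize(
        "qi_svd,qi_srf,lag,expected",
        [
            (0.6, 0.6, 0.1, True),
            (0.5, 0.9, 0.1, False),   # boundary excluded, strict >
            (0.9, 0.9, 0.35, False),  # lag outside the causal window
            (0.9, 0.9, None, False),
        ],
    )
    def test_gate(self, qi_svd, qi_srf, lag, expected):
        assert rf.rf_quality_gate(qi_svd, qi_srf, lag) is expected
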