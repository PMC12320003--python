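import numpy as np
import pytest
from scipy import stats

from laminapipe import denoise
from laminapipe.denoise import (
    CasoratiMatrix,
    build_casorati,
    clean_signal_components,
    denoise_series,
    estimate_noise_edge,
    mp_median,
    residual_gaussianity,
)
from laminapipe.images import Image3D, Image4D, ImageKind


def _img4d(data):
    return Image4D(data, np.eye(4))


class TestCasorati:
    def test_window_and_frame_dimensions(self, rng):
        series = _img4d(rng.normal(size=(12, 10, 2, 310)))
        m = build_casorati(series, (3, 4, 1), (3, 3))
        assert m.values.shape == (9, 310)

    def test_single_voxel_window(self, rng):
        series = _img4d(rng.normal(size=(6, 6, 1, 20)))
        m = build_casorati(series, (2, 3, 0), (1, 1))
        np.testing.assert_array_equal(m.values, series.data[2, 3, 0][None, :])

    def test_entries_match_direct_indexing(self, rng):
        # brute-force index-mapping oracle over every entry
        series = _img4d(rng.normal(size=(8, 7, 2, 15)))
        x0, y0, z0, (wx, wy) = 2, 1, 1, (3, 5)
        m = build_casorati(series, (x0, y0, z0), (wx, wy))
        for k in range(wx * wy):
            dx, dy = divmod(k, wy)
            np.testing.assert_array_equal(
                m.values[k], series.data[x0 + dx, y0 + dy, z0, :]
            )

    def test_out_of_bounds_errors(self, rng):
        series = _img4d(rng.normal(size=(6, 6, 1, 5)))
        with pytest.raises(ValueError, match="bounds"):
            build_casorati(series, (5, 0, 0), (3, 3))


class TestNoiseEdge:
    def test_mp_median_against_direct_simulation(self):
        # Monte-Carlo oracle for the MP bulk median at gamma = 9/300
        gamma = 9 / 300
        rng = np.random.default_rng(1)
        meds = []
        for _ in range(300):
            X = rng.normal(size=(9, 300))
            ev = np.linalg.eigvalsh(X @ X.T / 300)
            meds.append(np.median(ev))
        assert mp_median(gamma) == pytest.approx(np.mean(meds), rel=0.03)

    def test_null_false_signal_rate(self):
        # direct simulation of the null largest singular value
        hits = 0
        n_rep = 400
        for i in range(n_rep):
            X = np.random.default_rng(10_000 + i).normal(0.0, 3.0, (9, 310))
            sp = estimate_noise_edge(
                CasoratiMatrix(X, (0, 0, 0), (3, 3)), "tw_quantile", 0.95
            )
            hits += sp.n_signal > 0
        assert hits / n_rep <= 0.05 + 0.02  # binomial slack at 400 replicates

    def test_planted_spike_detected(self):
        for i in range(60):
            r = np.random.default_rng(20_000 + i)
            u = r.normal(size=9)
            v = r.normal(size=310)
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            edge_sv = np.sqrt(9) + np.sqrt(310)  # unscaled MP edge at sigma=1
            X = 10 * edge_sv * np.outer(u, v) + r.normal(size=(9, 310))
            sp = estimate_noise_edge(CasoratiMatrix(X, (0, 0, 0), (3, 3)))
            assert sp.n_signal >= 1
            assert sp.singular_values[0] > sp.noise_edge

    def test_sigma_estimate_accuracy(self):
        sigmas = []
        for i in range(100):
            X = np.random.default_rng(i).normal(0.0, 2.5, (9, 310))
            sp = estimate_noise_edge(CasoratiMatrix(X, (0, 0, 0), (3, 3)))
            sigmas.append(sp.sigma_hat)
        assert np.mean(sigmas) == pytest.approx(2.5, rel=0.05)

    def test_zero_matrix(self):
        with pytest.warns(UserWarning, match="constant"):
            sp = estimate_noise_edge(
                CasoratiMatrix(np.zeros((9, 30)), (0, 0, 0), (3, 3))
            )
        assert sp.n_signal == 0
        assert sp.sigma_hat == 0.0


class TestCleanComponents:
    def test_zero_signal_returns_temporal_means(self, rng):
        X = rng.normal(5.0, 1.0, (9, 200))
        sp = estimate_noise_edge(CasoratiMatrix(X, (0, 0, 0), (3, 3)))
        sp.n_signal = 0
        out = clean_signal_components(CasoratiMatrix(X, (0, 0, 0), (3, 3)), sp)
        np.testing.assert_allclose(
            out.values, np.tile(X.mean(axis=1, keepdims=True), (1, 200)), atol=1e-10
        )

    def test_noiseless_low_rank_passthrough(self, rng):
        X = (
            np.outer(rng.normal(size=9), rng.normal(size=240))
            + np.outer(rng.normal(size=9), rng.normal(size=240))
            + 3.0
        )
        cm = CasoratiMatrix(X, (0, 0, 0), (3, 3))
        out = clean_signal_components(cm, estimate_noise_edge(cm))
        np.testing.assert_allclose(out.values, X, atol=1e-9 * np.abs(X).max())

    def test_shrinkage_beats_hard_truncation(self):
        # simulation oracle comparing the two estimators on planted rank-3
        mse_shrunk, mse_trunc = [], []
        P, T = 9, 150
        for i in range(150):
            r = np.random.default_rng(30_000 + i)
            U = np.linalg.qr(r.normal(size=(P, 3)))[0]
            V = np.linalg.qr(r.normal(size=(T, 3)))[0]
            s_true = np.array([4.0, 3.0, 2.5]) * np.sqrt(T)
            S = (U * s_true) @ V.T
            X = S + r.normal(size=(P, T))
            cm = CasoratiMatrix(X, (0, 0, 0), (3, 3))
            sp = estimate_noise_edge(cm)
            out = clean_signal_components(cm, sp)
            mse_shrunk.append(((out.values - S) ** 2).mean())
            # hard truncation: keep observed singular values unshrunk
            mean = X.mean(axis=1, keepdims=True)
            Uo, so, Vo = np.linalg.svd(X - mean, full_matrices=False)
            so[sp.n_signal :] = 0.0
            hard = (Uo * so) @ Vo + mean
            mse_trunc.append(((hard - S) ** 2).mean())
        assert np.mean(mse_shrunk) < np.mean(mse_trunc)

    def test_mismatched_split_rejected(self, rng):
        X = rng.normal(size=(9, 100))
        sp = estimate_noise_edge(CasoratiMatrix(X, (0, 0, 0), (3, 3)))
        other = CasoratiMatrix(rng.normal(size=(9, 100)), (0, 0, 0), (3, 3))
        with pytest.raises(ValueError):
            clean_signal_components(other, sp)


class TestDenoiseSeries:
    def test_conservation_exact(self, rng):
        series = _img4d(rng.normal(100, 5, (10, 10, 2, 60)))
        den, res, _ = denoise_series(series)
        np.testing.assert_array_equal(den.data + res.data, series.data)

    def test_scale_equivariance(self, rng):
        series = _img4d(rng.normal(100, 5, (10, 10, 1, 60)))
        den1, _, _ = denoise_series(series)
        scaled = _img4d(series.data * 7.5)
        den2, _, _ = denoise_series(scaled)
        np.testing.assert_allclose(den2.data, 7.5 * den1.data, rtol=1e-10)

    def test_pure_noise_variance_nearly_removed(self, rng):
        series = _img4d(rng.normal(0, 1, (16, 16, 1, 200)))
        den, _, _ = denoise_series(series)
        fluct = den.data - den.data.mean(axis=3, keepdims=True)
        assert fluct.var() <= 0.10 * series.data.var()

    def test_zero_noise_input_preserved(self, rng):
        # band-limited smooth signals, no noise
        t = np.arange(120)
        base = np.stack(
            [np.sin(2 * np.pi * (0.02 + 0.001 * k) * t) for k in range(25)]
        ).reshape(5, 5, 1, 120)
        series = _img4d(100 + base)
        den, _, _ = denoise_series(series)
        rms = np.sqrt(((den.data - series.data) ** 2).mean())
        assert rms / np.sqrt((series.data**2).mean()) < 1e-3

    def test_tsnr_gain_on_noisy_phantom(self, quiet_phantom):
        from laminapipe.phantom import apply_acquisition
        from laminapipe.qc import tsnr_map

        truth = quiet_phantom
        acq = apply_acquisition(truth.clean_series, truth, truth.acq, seed=3)
        den, _, _ = denoise_series(acq)
        mask = truth.atlas.labels.data > 0
        t_raw = tsnr_map(acq).data[mask]
        t_den = tsnr_map(den).data[mask]
        assert np.median(t_den) / np.median(t_raw) > 1.5

    def test_sigma_map_matches_true_noise(self, rng):
        series = _img4d(rng.normal(50, 4.0, (12, 12, 1, 150)))
        _, _, smap = denoise_series(series)
        assert np.median(smap.data) == pytest.approx(4.0, rel=0.05)

    def test_stride_too_large_errors(self, rng):
        series = _img4d(rng.normal(size=(12, 12, 1, 30)))
        mask = Image3D(np.ones((12, 12, 1)), np.eye(4), ImageKind.mask)
        with pytest.raises(ValueError, match="stride|covered"):
            denoise_series(series, window=(3, 3), stride=11, mask=mask)

    def test_even_window_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            denoise_series(_img4d(rng.normal(size=(8, 8, 1, 20))), window=(2, 3))


class TestResidualGaussianity:
    def _mask(self, shape):
        return Image3D(np.ones(shape), np.eye(4), ImageKind.mask)

    def test_pvalues_roughly_uniform_under_null(self):
        # oracle: p-values of a calibrated test are U(0,1) under H0
        ps = []
        for i in range(120):
            res = _img4d(np.random.default_rng(i).normal(0, 2, (8, 8, 1, 40)))
            _, p, _ = residual_gaussianity(res, self._mask((8, 8, 1)))
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 1e-3

    def test_heavy_tails_rejected(self):
        rej = 0
        for i in range(60):
            res = _img4d(stats.t.rvs(3, size=(8, 8, 1, 40), random_state=i))
            _, p, _ = residual_gaussianity(res, self._mask((8, 8, 1)))
            rej += p < 0.05
        assert rej / 60 > 0.9

    def test_fit_recovers_moments(self):
        res = _img4d(np.random.default_rng(5).normal(1.5, 3.0, (10, 10, 1, 50)))
        _, _, (mu, sd) = residual_gaussianity(res, self._mask((10, 10, 1)))
        assert mu == pytest.approx(1.5, abs=0.1)
        assert sd == pytest.approx(3.0, rel=0.05)

    def test_constant_input_errors(self):
        res = _img4d(np.full((10, 10, 1, 20), 3.0))
        with pytest.raises(ValueError, match="variance"):
            residual_gaussianity(res, self._mask((10, 10, 1)))

    def test_too_few_samples_errors(self, rng):
        res = _img4d(rng.normal(size=(4, 4, 1, 10)))
        with pytest.raises(ValueError, match="1000"):
            residual_gaussianity(res, self._mask((4, 4, 1)))
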