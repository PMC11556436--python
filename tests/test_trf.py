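"""Lagged designs, ridge TRF estimation, nested cross-validation."""

import numpy as np
import pytest

from syntrf import trf
from syntrf.features import FeatureTrack


def augmented_lstsq(X, Y, lam):
    """Independent oracle: ridge via least squares on the augmented system
    [X; sqrt(lam) I] against [Y; 0]."""
    d = X.shape[1]
    Xa = np.vstack([X, np.sqrt(lam) * np.eye(d)])
    Ya = np.vstack([Y, np.zeros((d, Y.shape[1]))])
    beta, *_ = np.linalg.lstsq(Xa, Ya, rcond=None)
    return beta


class TestLagDesign:
    def test_lag_count(self):
        assert len(trf.lag_times(-0.2, 1.0, 200)) == 241

    def test_zero_lag_single_track_is_identity(self, rng):
        x = rng.normal(size=100)
        d = trf.build_lagged([x], 0.0, 0.0, 100.0)
        assert d.matrix.shape == (100, 1)
        assert np.allclose(d.matrix[:, 0], x)

    def test_impulse_shift(self):
        x = np.zeros(50)
        x[10] = 1.0
        d = trf.build_lagged([x], 0.0, 0.05, 100.0)  # lags 0..5 samples
        for k in range(6):
            col = d.matrix[:, k]
            assert col[10 + k] == 1.0
            assert col.sum() == 1.0

    def test_negative_lags_advance(self):
        x = np.zeros(50)
        x[10] = 1.0
        d = trf.build_lagged([x], -0.02, 0.0, 100.0)  # lags -2..0
        assert d.matrix[8, 0] == 1.0

    def test_excessive_lags_rejected(self):
        with pytest.raises(ValueError):
            trf.build_lagged([np.zeros(10)], 0.0, 1.0, 100.0)


class TestRidge:
    def test_orthonormal_design_lambda0(self, rng):
        Q = np.linalg.qr(rng.normal(size=(200, 8)))[0]
        Y = rng.normal(size=(200, 3))
        d = trf.LagDesign(matrix=Q, lag_min=0, lag_max=7 / 100, fs=100.0,
                          K=8, feature_names=["f"])
        m = trf.fit_ridge(d, Y, 0.0)
        assert np.allclose(m.beta2d(), Q.T @ Y, atol=1e-10)

    def test_heavy_shrinkage(self, rng):
        x = rng.normal(size=500)
        d = trf.build_lagged([x], 0.0, 0.05, 100.0)
        m = trf.fit_ridge(d, rng.normal(size=(500, 2)), 1e12)
        assert np.abs(m.beta).max() < 1e-6

    def test_rank_deficient_lambda0_rejected(self, rng):
        x = rng.normal(size=100)
        d = trf.build_lagged([x, x], 0.0, 0.03, 100.0)  # duplicated feature
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            trf.fit_ridge(d, rng.normal(size=(100, 1)), 0.0)

    def test_matches_augmented_system_oracle(self, rng):
        for _ in range(20):
            N = int(rng.integers(300, 700))
            F = int(rng.integers(1, 4))
            K = int(rng.integers(3, 8))
            lam = float(10 ** rng.uniform(-2, 3))
            tracks = rng.normal(size=(F, N))
            d = trf.build_lagged(tracks, 0.0, (K - 1) / 100, 100.0)
            Y = rng.normal(size=(N, 2))
            m = trf.fit_ridge(d, Y, lam)
            oracle = augmented_lstsq(d.matrix, Y, lam)
            assert np.abs(m.beta2d() - oracle).max() < 1e-8

    def test_beta_reshape_round_trip(self, rng):
        tracks = rng.normal(size=(3, 400))
        d = trf.build_lagged(tracks, 0.0, 0.04, 100.0)
        m = trf.fit_ridge(d, rng.normal(size=(400, 2)), 1.0)
        flat = m.beta2d()
        K = d.K
        for f in range(3):
            assert np.allclose(m.beta[:, f, :], flat[f * K:(f + 1) * K, :])


class TestPredictScore:
    def test_zero_design_zero_prediction(self, rng):
        d = trf.build_lagged([np.zeros(100)], 0.0, 0.03, 100.0)
        m = trf.fit_ridge(d, rng.normal(size=(100, 2)), 1.0)
        assert not trf.predict(m, d).any()

    def test_residual_orthogonality_ols(self, rng):
        tracks = rng.normal(size=(2, 500))
        d = trf.build_lagged(tracks, 0.0, 0.03, 100.0)
        Y = rng.normal(size=(500, 1))
        m = trf.fit_ridge(d, Y, 0.0)
        r = Y - trf.predict(m, d)
        assert np.abs(d.matrix.T @ r).max() < 1e-6

    def test_linearity(self, rng):
        tracks = rng.normal(size=(1, 300))
        d = trf.build_lagged(tracks, 0.0, 0.02, 100.0)
        m = trf.fit_ridge(d, rng.normal(size=(300, 1)), 1.0)
        d2 = trf.LagDesign(matrix=2 * d.matrix, lag_min=d.lag_min,
                           lag_max=d.lag_max, fs=d.fs, K=d.K,
                           feature_names=d.feature_names)
        assert np.allclose(trf.predict(m, d2), 2 * trf.predict(m, d))

    def test_score_extremes_and_noise(self, rng):
        Y = rng.normal(size=(10000, 2))
        assert np.allclose(trf.score(Y, Y.copy()), 1.0)
        assert np.allclose(trf.score(Y, -Y), -1.0)
        r = trf.score(Y, rng.normal(size=(10000, 2)))
        assert np.all(np.abs(r) < 0.05)

    def test_constant_column_warns_nan(self, rng):
        Y = rng.normal(size=(100, 2))
        Yh = Y.copy()
        Yh[:, 1] = 3.0
        with pytest.warns(UserWarning):
            r = trf.score(Y, Yh)
        assert np.isnan(r[1]) and np.isfinite(r[0])


def _smooth_tracks(rng, F, N):
    from scipy.ndimage import gaussian_filter1d

    return gaussian_filter1d(rng.normal(size=(F, N)), 3.0, axis=-1)


class TestNestedCV:
    fs = 100.0

    def _simulated(self, rng, snr=np.inf, N=5400, F=2, K=6):
        tracks = rng.normal(size=(F, N))
        beta = rng.normal(size=(K * F, 2))
        d = trf.build_lagged(tracks, 0.0, (K - 1) / self.fs, self.fs)
        Y = d.matrix @ beta
        if np.isfinite(snr):
            noise = rng.normal(size=Y.shape) * Y.std() / np.sqrt(snr)
            Y = Y + noise
        return tracks, Y

    def test_noiseless_recovery_picks_minimal_lambda(self, rng):
        tracks, Y = self._simulated(rng)
        grid = [1e-4, 1e0, 1e4]
        res, models = trf.nested_cv(tracks, Y, grid, k_outer=9, k_inner=3,
                                    lag_min=0.0, lag_max=0.05, fs=self.fs)
        assert np.nanmean(res.mean_r) > 0.99
        assert res.modal_lambda[0] == 1e-4
        assert models[0].beta.shape == (6, 2, 2)

    def test_permuted_signal_scores_nil(self, rng):
        tracks, Y = self._simulated(rng)
        Yp = Y[rng.permutation(len(Y))]
        res, _ = trf.nested_cv(tracks, Yp, [1.0], k_outer=9, k_inner=3,
                               lag_min=0.0, lag_max=0.05, fs=self.fs)
        assert abs(np.nanmean(res.mean_r)) < 0.05

    def test_deterministic(self, rng):
        tracks, Y = self._simulated(rng, snr=2.0)
        a, _ = trf.nested_cv(tracks, Y, [0.1, 10], k_outer=6, k_inner=2,
                             lag_min=0.0, lag_max=0.05, fs=self.fs)
        b, _ = trf.nested_cv(tracks, Y, [0.1, 10], k_outer=6, k_inner=2,
                             lag_min=0.0, lag_max=0.05, fs=self.fs)
        assert np.array_equal(a.fold_r, b.fold_r)
        assert np.array_equal(a.chosen_lambda, b.chosen_lambda)

    def test_fold_shorter_than_lags_rejected(self, rng):
        tracks = _smooth_tracks(rng, 1, 200)
        with pytest.raises(ValueError):
            trf.nested_cv(tracks, np.zeros((200, 1)), [1.0], k_outer=9,
                          k_inner=2, lag_min=0.0, lag_max=0.3, fs=self.fs)

    def test_group_mode_matches_single(self, rng):
        tracks, Y = self._simulated(rng, snr=5.0)
        res1, _ = trf.nested_cv(tracks, Y, [1.0], k_outer=6, k_inner=2,
                                lag_min=0.0, lag_max=0.05, fs=self.fs)
        resg, _ = trf.nested_cv(tracks, np.stack([Y, Y]), [1.0], k_outer=6,
                                k_inner=2, lag_min=0.0, lag_max=0.05,
                                fs=self.fs)
        assert np.allclose(res1.fold_r[0], resg.fold_r[0])
        assert np.allclose(resg.fold_r[0], resg.fold_r[1])


class TestModelGrid:
    def test_table1_has_16_models(self):
        sets = trf.table1_feature_sets()
        assert len(sets) == 16
        assert sets["main_null"] == ["envelope", "word_onset",
                                     "word_frequency"]
        assert "surprisal" in sets["main_distributional_topdown_bottomup"]
        base_count = sum(
            1 for fs_ in sets.values()
            if {"envelope", "word_onset", "word_frequency"} <= set(fs_)
        )
        assert base_count == 16
        with_bu = [m for m, fs_ in sets.items() if "bottomup" in fs_]
        assert len(with_bu) == 8

    def test_table2_has_4_models(self):
        sets = trf.table2_feature_sets()
        assert len(sets) == 4
        assert sets["bottomup_split_surprisal"][-2:] == [
            "bottomup_low", "bottomup_high",
        ]

    def test_unknown_feature_rejected(self, rng):
        tracks = {"envelope": FeatureTrack("envelope", 100, rng.normal(size=600))}
        with pytest.raises(ValueError, match="unknown"):
            trf.model_grid({"m": ["envelope", "nope"]}, tracks,
                           rng.normal(size=(600, 1)), [1.0])

    def test_pure_noise_feature_adds_nothing(self, rng):
        sig = _smooth_tracks(rng, 1, 4800)[0]
        noisef = rng.normal(size=4800)
        K = 4
        d = trf.build_lagged([sig], 0.0, (K - 1) / 100, 100.0)
        Y = d.matrix @ rng.normal(size=(K, 1))
        Y += 0.3 * Y.std() * rng.normal(size=Y.shape)
        tr_d = {
            "sig": FeatureTrack("sig", 100.0, sig),
            "noise": FeatureTrack("noise", 100.0, noisef),
        }
        df = trf.model_grid(
            {"without": ["sig"], "with": ["sig", "noise"]}, tr_d, Y[None],
            [1.0], k_outer=6, k_inner=2, lag_min=0.0,
            lag_max=(K - 1) / 100, fs=100.0,
        )
        gain = (df[df.model == "with"].r.mean()
                - df[df.model == "without"].r.mean())
        assert gain <= 0.005

    def test_superset_scores_at_least_subset_noiseless(self, rng):
        tracks = _smooth_tracks(rng, 2, 3600)
        K = 4
        beta = rng.normal(size=(K * 2, 1))
        d = trf.build_lagged(tracks, 0.0, (K - 1) / 100, 100.0)
        Y = d.matrix @ beta
        tr_d = {
            "a": FeatureTrack("a", 100.0, tracks[0]),
            "b": FeatureTrack("b", 100.0, tracks[1]),
        }
        df = trf.model_grid(
            {"sub": ["a"], "super": ["a", "b"]}, tr_d, Y[None], [1e-6],
            k_outer=6, k_inner=2, lag_min=0.0, lag_max=(K - 1) / 100,
            fs=100.0,
        )
        r_sub = df[df.model == "sub"].r.mean()
        r_super = df[df.model == "super"].r.mean()
        assert r_super >= r_sub - 1e-6
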