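"""Toy-grammar corpus, event generation, kernels, forward simulation."""

import numpy as np
import pytest
import scipy.stats

from syntrf import simulate as sim
from syntrf import trees as tr
from syntrf.ngram import train_kn
from syntrf.trf import lag_times


class TestCorpus:
    def test_deterministic(self):
        a, _ = sim.gen_grammar_corpus(50, seed=4)
        b, _ = sim.gen_grammar_corpus(50, seed=4)
        assert a == b

    def test_trees_satisfy_count_invariant(self):
        _, trees = sim.gen_grammar_corpus(200, seed=8)
        for t in trees:
            assert sum(tr.count_topdown(t)) == t.n_internal()

    def test_mean_length_near_ten_words(self):
        sents, _ = sim.gen_grammar_corpus(791, seed=11)
        total = sum(len(s) for s in sents)
        assert abs(total - 791 * 10) < 0.2 * 791 * 10

    def test_traces_occur_but_are_minority(self):
        _, trees = sim.gen_grammar_corpus(300, seed=2)
        n_traces = sum(sum(tr.trace_flags(t)) for t in trees)
        n_words = sum(len(t.leaves()) for t in trees)
        assert 0 < n_traces < 0.1 * n_words


class TestEvents:
    def _events(self, coupling, seed=0, n_seg=6):
        cfg = sim.SimConfig(n_subjects=2, n_channels=4,
                            segment_duration=60.0, n_segments=n_seg,
                            duration_coupling=coupling, seed=seed)
        sents, trees = sim.gen_grammar_corpus(400, seed=seed)
        lm = train_kn(sents)
        return sim.gen_events(trees, lm, cfg, seed=seed), cfg

    def test_positive_coupling_shows_in_durations(self):
        ev, _ = self._events(0.10)
        assert len(ev) >= 500
        rho = scipy.stats.spearmanr(ev.duration, ev.surprisal_trigram).statistic
        assert rho > 0.2

    def test_zero_coupling_near_independent(self):
        ev, _ = self._events(0.0)
        rho = scipy.stats.spearmanr(ev.duration, ev.surprisal_trigram).statistic
        assert abs(rho) < 0.1

    def test_onsets_strictly_increasing_within_recording(self):
        ev, cfg = self._events(0.10)
        assert (np.diff(ev.onset) > 0).all()
        assert ev.onset.iloc[-1] < cfg.n_samples / cfg.fs

    def test_required_columns_present(self):
        ev, _ = self._events(0.10)
        for col in ("onset", "duration", "token", "sentence_id", "segment",
                    "logfreq", "surprisal_trigram", "entropy_trigram",
                    "topdown", "bottomup", "leftcorner"):
            assert col in ev.columns
        assert (ev.logfreq >= 0.301).all()


class TestKernels:
    cfg = sim.SimConfig(n_subjects=2, n_channels=6, segment_duration=20.0)

    def test_shift_invariant_sample_exact(self):
        truth = sim.make_kernels(self.cfg, seed=0)
        low, high = truth.node_count_kernel_low, truth.node_count_kernel_high
        s = int(round(self.cfg.planted_shift * self.cfg.fs))
        assert np.array_equal(high[s:], low[:-s])
        assert not high[:s].any()

    def test_kernels_vanish_outside_window(self):
        truth = sim.make_kernels(self.cfg, seed=1)
        lags = truth.lags
        for name, k in truth.kernels.items():
            support = (0.0, 0.6 + (self.cfg.planted_shift
                                   if name == "bottomup_high" else 0.0))
            outside = (lags < support[0] - 1e-9) | (lags > support[1] + 1e-9)
            assert not k[outside].any(), name

    def test_seeds_give_distinct_kernels(self):
        a = sim.make_kernels(self.cfg, seed=0).kernels["surprisal"]
        b = sim.make_kernels(self.cfg, seed=1).kernels["surprisal"]
        r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert abs(r) < 0.99

    def test_off_grid_shift_rejected(self):
        with pytest.raises(ValueError):
            sim.SimConfig(planted_shift=0.1501)


class TestSignal:
    def _small(self, snr=1.0, seed=0):
        cfg = sim.SimConfig(n_subjects=2, n_channels=4,
                            segment_duration=40.0, n_segments=3, snr=snr,
                            seed=seed)
        rng = np.random.default_rng(seed)
        truth = sim.make_kernels(cfg, seed=rng)
        env = sim.gen_envelope(cfg.n_samples, cfg.fs, seed=rng)
        x = np.zeros(cfg.n_samples)
        x[np.arange(100, cfg.n_samples - 300, 80)] = 1.0
        from syntrf.features import FeatureTrack

        tracks = {
            "envelope": env,
            "word_onset": FeatureTrack("word_onset", cfg.fs, x),
            "bottomup_low": FeatureTrack("bottomup_low", cfg.fs, x * 0.5),
            "bottomup_high": FeatureTrack("bottomup_high", cfg.fs,
                                          np.roll(x, 37) * 0.5),
        }
        return cfg, truth, tracks

    def test_deterministic_per_seed(self):
        cfg, truth, tracks = self._small()
        a = sim.simulate(tracks, truth, cfg, seed=5)
        b = sim.simulate(tracks, truth, cfg, seed=5)
        assert np.array_equal(a, b)
        assert a.shape == (2, 4, cfg.n_samples)

    def test_snr_scales_noise(self):
        cfg1, truth, tracks = self._small(snr=1.0)
        cfg4, _, _ = self._small(snr=4.0)
        y1 = sim.simulate(tracks, truth, cfg1, seed=3)
        y4 = sim.simulate(tracks, truth, cfg4, seed=3)
        resid1 = y1 - y4  # noise difference dominates
        assert y1.var() > y4.var()

    def test_band_limited(self):
        cfg, truth, tracks = self._small()
        y = sim.simulate(tracks, truth, cfg, seed=1)
        f, pxx = scipy.signal.welch(y[0, 0], fs=cfg.fs, nperseg=2048)
        band = pxx[(f >= 0.5) & (f <= 4.0)].sum()
        out = pxx[f >= 8.0].sum()
        assert out < 0.01 * band

    def test_unknown_track_rejected(self):
        cfg, truth, tracks = self._small()
        from syntrf.features import FeatureTrack

        tracks["mystery"] = FeatureTrack("mystery", cfg.fs,
                                         np.zeros(cfg.n_samples))
        with pytest.raises(ValueError):
            sim.simulate(tracks, truth, cfg, seed=0)


import scipy.signal  # noqa: E402  (used in TestSignal)


def test_pink_noise_spectrum_slopes_down():
    x = sim.pink_noise((4, 60000), fs=200.0, seed=0)
    f, pxx = scipy.signal.welch(x, fs=200.0, nperseg=4096, axis=-1)
    lowband = pxx[:, (f > 0.3) & (f < 1.0)].mean()
    highband = pxx[:, (f > 10) & (f < 30)].mean()
    assert lowband > 5 * highband
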