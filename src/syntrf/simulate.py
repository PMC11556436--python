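"""Forward simulation with known ground truth.

The simulator emulates the study conditions of a naturalistic-listening
MEG experiment: a toy probabilistic grammar generates sentences with
parses (including occasional traces), word durations are coupled to
trigram surprisal (longer words when surprisal is high), word frequencies
are drawn from a Zipf-like distribution, and multi-channel delta-band
signals are produced by convolving the feature tracks with smooth
per-channel response kernels plus 1/f background noise, band-passed to
0.5-4 Hz.

The planted effect mirrors the hypothesis under test: the response kernel
for the bottom-up node-count feature of *high-surprisal* words is an
exact sample-grid-shifted copy of the low-surprisal kernel (default
+150 ms), while the word-frequency kernel is shared by both surprisal
conditions.  A correct analysis should therefore recover the latency
shift on the node-count split and a null shift on the frequency split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as feat
from . import trees as tr
from .ngram import KneserNeyLM, score_events, train_kn
from .trf import lag_times

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gen_grammar_corpus",
    "gen_events",
    "make_kernels",
    "gen_envelope",
    "simulate",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic twin."""

    fs: float = 200.0
    n_channels: int = 32
    n_subjects: int = 24
    segment_duration: float = 60.0      # seconds per segment
    n_segments: int = 9
    snr: float = 1.0                    # clean/noise band power ratio
    planted_shift: float = 0.150        # seconds, node-count kernel delay
    duration_coupling: float = 0.10     # log-duration per bit of surprisal
    duration_noise_sd: float = 0.25     # SD of log-duration noise
    kernel_jitter: float = 0.05         # per-subject kernel gain jitter
    lag_min: float = -0.2
    lag_max: float = 1.0
    band: tuple[float, float] = (0.5, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.band[1]:
            raise ValueError("fs too low for the analysis band")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        shift_samples = self.planted_shift * self.fs
        if abs(shift_samples - round(shift_samples)) > 1e-9:
            raise ValueError("planted_shift must be a multiple of 1/fs")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.segment_duration * self.n_segments))


@dataclass
class GroundTruth:
    """Planted kernels and noise model."""

    kernels: dict[str, np.ndarray]      # name -> (K, C)
    lags: np.ndarray
    planted_shift: float
    noise_exponent: float = 1.0

    @property
    def node_count_kernel_low(self) -> np.ndarray:
        return self.kernels["bottomup_low"]

    @property
    def node_count_kernel_high(self) -> np.ndarray:
        return self.kernels["bottomup_high"]


# ---------------------------------------------------------------------------
# toy grammar

TRACE_TOKEN = "*t*"

_LEXICON: dict[str, list[str]] = {
    "Det": ["the", "a", "this", "every", "some"],
    "N": ["train", "king", "garden", "story", "child", "bird", "castle",
          "road", "apple", "teacher", "river", "dog", "letter", "queen",
          "village"],
    "PRO": ["she", "he", "they", "someone"],
    "V": ["arrived", "saw", "followed", "liked", "found", "told", "made",
          "heard", "took", "left", "watched", "feared"],
    "Adj": ["old", "small", "quiet", "bright", "strange", "happy", "tall",
            "green"],
    "Adv": ["often", "quietly", "suddenly", "never"],
    "P": ["in", "near", "behind", "with", "over"],
    "RP": ["that", "who"],
    "C": ["that", "whether"],
}

_RULES: dict[str, list[tuple[float, tuple[str, ...]]]] = {
    "S": [(1.0, ("NP", "VP"))],
    "NP": [
        (0.42, ("Det", "N")),
        (0.18, ("Det", "AP", "N")),
        (0.16, ("Det", "N", "PP")),
        (0.10, ("Det", "N", "RC")),
        (0.14, ("PRO",)),
    ],
    "AP": [(0.72, ("Adj",)), (0.28, ("Adj", "AP"))],
    "VP": [
        (0.38, ("V", "NP")),
        (0.14, ("V",)),
        (0.18, ("V", "NP", "PP")),
        (0.12, ("V", "PP")),
        (0.10, ("V", "CP")),
        (0.08, ("Adv", "VP")),
    ],
    "PP": [(1.0, ("P", "NP"))],
    "RC": [(1.0, ("RP", "Srel"))],
    "Srel": [(1.0, ("NPt", "VP"))],
    "CP": [(1.0, ("C", "S"))],
}

# non-recursive escapes used past the depth limit
_ESCAPE: dict[str, tuple[str, ...]] = {
    "S": ("NP", "VP"),
    "NP": ("PRO",),
    "AP": ("Adj",),
    "VP": ("V",),
    "PP": ("P", "NP"),
    "RC": ("RP", "Srel"),
    "Srel": ("NPt", "VP"),
    "CP": ("C", "S"),
}


def _word_probs(n: int) -> np.ndarray:
    p = 1.0 / (np.arange(n) + 1.0)
    return p / p.sum()


def _sample_tree(rng: np.random.Generator, symbol: str = "S",
                 depth: int = 0) -> tr.Tree:
    if symbol == "NPt":
        return tr.Tree("NPt", [tr.Tree(TRACE_TOKEN)])
    if symbol in _LEXICON:
        words = _LEXICON[symbol]
        w = words[rng.choice(len(words), p=_word_probs(len(words)))]
        return tr.Tree(symbol, [tr.Tree(w)])
    rules = _RULES[symbol]
    if depth > 24:
        rhs = _ESCAPE[symbol]
    else:
        probs = np.array([p for p, _ in rules])
        rhs = rules[rng.choice(len(rules), p=probs)][1]
    return tr.Tree(symbol, [_sample_tree(rng, s, depth + 1) for s in rhs])


def gen_grammar_corpus(
    n_sentences: int,
    seed: int | np.random.Generator = 0,
    max_words: int = 35,
) -> tuple[list[list[str]], list[tr.Tree]]:
    """Sample sentences with parses from the toy grammar.

    Returns (overt token lists, trees); trees may contain trace terminals.
    Sentences longer than ``max_words`` overt words are resampled.
    """
    rng = np.random.default_rng(seed)
    sentences: list[list[str]] = []
    trees: list[tr.Tree] = []
    while len(trees) < n_sentences:
        t = _sample_tree(rng)
        toks = [
            w for w, f in zip(t.terminals(), tr.trace_flags(t)) if not f
        ]
        if 1 <= len(toks) <= max_words:
            trees.append(t)
            sentences.append(toks)
    return sentences, trees


def zipf_logfreq(tokens: list[str], seed: int | np.random.Generator = 0
                 ) -> dict[str, float]:
    """Log10 occurrences-per-million per word type, Zipf-like draw."""
    rng = np.random.default_rng(seed)
    types = sorted(set(tokens))
    vals = np.clip(rng.normal(2.0, 1.0, size=len(types)), 0.301, 4.5)
    return dict(zip(types, vals))


# ---------------------------------------------------------------------------
# events


def gen_events(
    trees: list[tr.Tree],
    lm: KneserNeyLM,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Word-event table over the whole recording.

    Sentences are laid down segment by segment; word durations follow
    ``log dur = base + duration_coupling * surprisal + noise`` so duration
    and surprisal are positively coupled by default.  Node counts (traces
    folded) and log frequency are attached per word.
    """
    rng = np.random.default_rng(seed)
    counts = tr.node_count_table(trees)
    counts = counts.rename(columns={"sentence_id": "tree_id"})
    scored = score_events(lm, counts.rename(columns={"tree_id": "sentence_id"}))
    scored["tree_id"] = counts["tree_id"].to_numpy()
    logfreq_map = zipf_logfreq(scored["token"].tolist(), rng)
    scored["logfreq"] = scored["token"].map(logfreq_map)

    surp = scored["surprisal_trigram"].to_numpy()
    base = np.log(0.16)
    dur = np.exp(
        base
        + config.duration_coupling * surp
        + rng.normal(0.0, config.duration_noise_sd, size=len(scored))
    )
    dur = np.clip(dur, 0.05, 1.2)
    scored["duration"] = dur

    rows: list[pd.DataFrame] = []
    seg, t = 0, 0.5
    seg_end = config.segment_duration
    margin = config.lag_max + 0.2
    for tid, grp in scored.groupby("tree_id", sort=True):
        need = grp["duration"].sum() + 0.03 * len(grp) + 0.4
        if t + need > seg_end - margin:
            seg += 1
            if seg >= config.n_segments:
                break
            seg_end = (seg + 1) * config.segment_duration
            t = seg * config.segment_duration + 0.5
        onsets = []
        for d in grp["duration"]:
            onsets.append(t)
            t += d + rng.uniform(0.01, 0.05)
        g = grp.copy()
        g["onset"] = onsets
        g["segment"] = seg
        rows.append(g)
        t += rng.uniform(0.25, 0.55)  # sentence pause
    if not rows:
        raise ValueError("no sentences fit into the recording")
    out = pd.concat(rows, ignore_index=True)
    out["sentence_id"] = out["tree_id"]
    return out.drop(columns=["tree_id"])


# ---------------------------------------------------------------------------
# kernels and signal


def _gabor_kernel(
    lags: np.ndarray,
    n_channels: int,
    rng: np.random.Generator,
    support: tuple[float, float] = (0.0, 0.6),
) -> np.ndarray:
    """Smooth bimodal kernel: 2-3 Gabor atoms with channel topographies."""
    K = len(lags)
    out = np.zeros((K, n_channels))
    n_atoms = rng.integers(2, 4)
    for _ in range(n_atoms):
        mu = rng.uniform(support[0] + 0.06, support[1] - 0.06)
        w = rng.uniform(0.04, 0.09)
        f = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
        wave = amp * np.exp(-0.5 * ((lags - mu) / w) ** 2) * np.cos(
            2 * np.pi * f * (lags - mu) + phase
        )
        topo = rng.normal(0.4, 1.0, size=n_channels)
        out += wave[:, None] * topo[None, :]
    # hard-limit the support so the shifted copy stays inside the window
    mask = ((lags >= support[0]) & (lags <= support[1])).astype(float)
    edge = (lags - support[0]) / 0.04
    mask *= np.clip(edge, 0, 1) * np.clip((support[1] - lags) / 0.04, 0, 1)
    out *= mask[:, None]
    rms = np.sqrt((out**2).mean())
    if rms > 0:
        out /= rms
    return out


def make_kernels(
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    feature_names: tuple[str, ...] = (
        "envelope", "word_onset", "word_frequency", "surprisal",
    ),
) -> GroundTruth:
    """Draw ground-truth kernels; the high-surprisal node-count kernel is
    the low-surprisal one delayed by ``config.planted_shift`` exactly."""
    rng = np.random.default_rng(seed)
    lags = lag_times(config.lag_min, config.lag_max, config.fs)
    shift = config.planted_shift * config.fs
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError("planted_shift is not on the sample grid")
    shift = int(round(shift))
    kernels = {
        name: _gabor_kernel(lags, config.n_channels, rng)
        for name in feature_names
    }
    low = _gabor_kernel(lags, config.n_channels, rng)
    high = np.zeros_like(low)
    if shift >= 0:
        high[shift:] = low[: len(lags) - shift]
    else:
        high[:shift] = low[-shift:]
    kernels["bottomup_low"] = low
    kernels["bottomup_high"] = high
    return GroundTruth(
        kernels=kernels, lags=lags, planted_shift=config.planted_shift
    )


def gen_envelope(
    n_samples: int, fs: float, seed: int | np.random.Generator = 0
) -> feat.FeatureTrack:
    """Surrogate speech envelope: positive, 1-8 Hz noise-modulated."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n_samples)
    y = np.abs(feat.bandpass(x, fs, lo=1.0, hi=8.0, transition=1.0))
    y = feat.scale_by_sd(y)
    return feat.FeatureTrack(name="envelope", fs=fs, samples=y)


def pink_noise(
    shape: tuple[int, ...],
    fs: float,
    exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum along the last axis."""
    rng = np.random.default_rng(seed)
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = rng.normal(size=shape[:-1] + (len(freqs),)) + 1j * rng.normal(
        size=shape[:-1] + (len(freqs),)
    )
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def simulate(
    tracks: dict[str, feat.FeatureTrack],
    truth: GroundTruth,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Forward-simulate band-passed signals: (subjects, channels, samples).

    Per subject the clean signal is the sum over features of the track
    convolved with its kernel (scaled by a small per-subject gain jitter),
    plus 1/f noise scaled so that the clean/noise power ratio within the
    analysis band equals ``config.snr``; the sum is band-passed 0.5-4 Hz.
    """
    if config.snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    names = [n for n in truth.kernels if n in tracks]
    missing = set(tracks) - set(truth.kernels)
    if missing:
        raise ValueError(f"tracks without kernels: {sorted(missing)}")
    n = len(tracks[names[0]].samples)
    fs = config.fs
    k0 = int(round(config.lag_min * fs))
    S, C = config.n_subjects, config.n_channels

    from scipy.signal import fftconvolve

    # shared clean signal; per-subject gain jitter per feature.  Every
    # feature's contribution is equalized in overall RMS so that sparse
    # impulse-train features are not drowned by the continuous envelope —
    # each modeled response is assumed to be measurable at the stated SNR.
    contribs = {}
    for name in names:
        x = tracks[name].samples
        kern = truth.kernels[name]          # K x C
        full = fftconvolve(x[:, None], kern, axes=0)   # (n+K-1) x C
        start = -k0  # lag_min < 0 shifts the kernel origin forward
        contrib = full[start:start + n].T              # C x n
        rms = np.sqrt((contrib**2).mean())
        if rms > 0:
            contrib = contrib / rms
        contribs[name] = contrib

    out = np.empty((S, C, n))
    lo, hi = config.band
    for s in range(S):
        gains = 1.0 + config.kernel_jitter * rng.normal(size=len(names))
        clean = np.zeros((C, n))
        for g, name in zip(gains, names):
            clean += g * contribs[name]
        clean_f = feat.bandpass(clean, fs, lo, hi)
        noise = pink_noise((C, n), fs, truth.noise_exponent, rng)
        noise_f = feat.bandpass(noise, fs, lo, hi)
        p_clean = (clean_f**2).mean()
        p_noise = (noise_f**2).mean()
        noise_f *= np.sqrt(p_clean / (config.snr * p_noise))
        out[s] = clean_f + noise_f
    return out
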