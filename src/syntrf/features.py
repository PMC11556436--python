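"""Regressor construction: smoothed impulse trains, envelope, VIF, filtering.

Word-level predictors enter the encoding model as impulse trains — zero
everywhere except at word-onset samples, where the impulse height is the
predictor value (1 for the plain word-onset feature).  Trains are smoothed
with a unit-sum Gaussian kernel (sigma = 15 ms by default) so that
impulse-like features occupy a frequency band comparable to the continuous
speech envelope and all regressors need a similar degree of ridge
regularization.  Predictor values are scaled by their pooled standard
deviation across all stimuli (no centering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FeatureTrack",
    "Kernel",
    "gaussian_kernel",
    "spectral_sd",
    "impulse_train",
    "smooth",
    "scale_by_sd",
    "envelope",
    "vif",
    "bandpass",
]


@dataclass
class FeatureTrack:
    """A named regressor sampled on the signal's time grid."""

    name: str
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class Kernel:
    """Discrete smoothing kernel: odd length, symmetric, unit sum."""

    sigma: float
    fs: float
    taps: np.ndarray


def gaussian_kernel(sigma: float = 0.015, fs: float = 200.0) -> Kernel:
    """Unit-sum discrete Gaussian, truncated at +/- 4 sigma.

    Length is 2*ceil(4*sigma*fs) + 1 taps.  Warns when sigma*fs < 0.5
    (kernel close to a single sample).
    """
    if sigma <= 0 or fs <= 0:
        raise ValueError("sigma and fs must be positive")
    if sigma * fs < 0.5:
        warnings.warn("sigma*fs < 0.5: smoothing kernel is near-degenerate")
    half = int(np.ceil(4 * sigma * fs))
    k = np.arange(-half, half + 1)
    taps = np.exp(-0.5 * (k / (sigma * fs)) ** 2)
    taps /= taps.sum()
    return Kernel(sigma=sigma, fs=fs, taps=taps)


def spectral_sd(sigma: float, convention: str = "reciprocal") -> float:
    """Spectral width (Hz) of a Gaussian with temporal SD ``sigma`` (s).

    ``"reciprocal"`` uses sigma_f = 1/(pi*sigma) — 21.22 Hz for 15 ms;
    ``"fourier"`` uses the textbook Fourier pair sigma_f = 1/(2*pi*sigma).
    """
    if convention == "reciprocal":
        return 1.0 / (np.pi * sigma)
    if convention == "fourier":
        return 1.0 / (2.0 * np.pi * sigma)
    raise ValueError(f"unknown convention {convention!r}")


def impulse_train(
    onsets: np.ndarray,
    values: np.ndarray,
    fs: float,
    n_samples: int,
    name: str = "",
) -> FeatureTrack:
    """Impulse train: ``values`` added at samples ``round(onset * fs)``.

    Events landing on the same sample accumulate.  Raises if any onset
    rounds to a sample at or beyond ``n_samples``.
    """
    onsets = np.asarray(onsets, dtype=float)
    values = np.broadcast_to(np.asarray(values, dtype=float), onsets.shape)
    idx = np.rint(onsets * fs).astype(int)
    bad = (idx < 0) | (idx >= n_samples)
    if bad.any():
        raise ValueError(
            f"onsets beyond track end (n_samples={n_samples}): "
            f"{onsets[bad].tolist()}"
        )
    x = np.zeros(n_samples)
    np.add.at(x, idx, values)
    return FeatureTrack(name=name, fs=fs, samples=x)


def smooth(track: FeatureTrack, kernel: Kernel) -> FeatureTrack:
    """Same-length centered convolution with a unit-sum kernel."""
    if kernel.fs != track.fs:
        raise ValueError("kernel and track sampling rates differ")
    y = sps.fftconvolve(track.samples, kernel.taps, mode="same")
    return FeatureTrack(name=track.name, fs=track.fs, samples=y)


def scale_by_sd(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Divide by the pooled standard deviation (no centering)."""
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=ddof))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("zero or undefined standard deviation")
    return values / sd


def envelope(audio, fs_in: float | None = None,
             fs_out: float = 200.0) -> FeatureTrack:
    """Amplitude envelope: |Hilbert transform|, resampled to ``fs_out``.

    ``audio`` may be a sample array (with ``fs_in`` given) or a path to a
    mono WAV file (``fs_in`` then read from the file).
    """
    if isinstance(audio, (str, bytes)) or hasattr(audio, "__fspath__"):
        from scipy.io import wavfile

        fs_in, audio = wavfile.read(audio)
        if np.ndim(audio) > 1:
            raise ValueError("expected mono audio")
    if fs_in is None:
        raise ValueError("fs_in required for array input")
    if fs_in < 2 * fs_out:
        raise ValueError("fs_in must be at least 2*fs_out")
    env = np.abs(sps.hilbert(np.asarray(audio, dtype=float)))
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    env = sps.resample_poly(env, frac.numerator, frac.denominator)
    return FeatureTrack(name="envelope", fs=fs_out, samples=env)


def vif(value_matrix: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Variance inflation factors: diagonal of the inverted correlation matrix.

    Columns are z-scored first.  A singular correlation matrix raises,
    naming the offending (near-perfectly correlated) column pairs.
    """
    X = np.asarray(value_matrix, dtype=float)
    n, p = X.shape
    if n < p + 1:
        raise ValueError("need at least features+1 rows")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"constant columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    if np.linalg.matrix_rank(R, tol=1e-10) < p:
        pairs = [
            (names[i] if names else i, names[j] if names else j)
            for i in range(p)
            for j in range(i + 1, p)
            if abs(R[i, j]) > 1 - 1e-9
        ]
        raise ValueError(f"singular correlation matrix; collinear set: {pairs}")
    return np.diag(np.linalg.inv(R)).copy()


def design_bandpass_fir(
    fs: float, lo: float, hi: float, transition: float | None = None
) -> np.ndarray:
    """Symmetric (zero-phase when centered) band-pass FIR taps.

    Hamming-window design; the DC gain is nulled exactly so constant
    offsets are removed.  Default transition width is lo/2.
    """
    if transition is None:
        transition = lo / 2.0
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs,
                      window="hamming")
    taps = taps - taps.mean()  # exact DC null
    return taps


def bandpass(
    x: np.ndarray,
    fs: float,
    lo: float = 0.5,
    hi: float = 4.0,
    transition: float | None = None,
) -> np.ndarray:
    """Zero-phase FIR band-pass along the last axis.

    The symmetric FIR applied with a centered convolution has zero phase;
    the signal is demeaned first (the passband excludes DC).  Raises when
    the signal is shorter than three filter lengths.
    """
    x = np.asarray(x, dtype=float)
    if hi >= fs / 2:
        raise ValueError("hi must be below the Nyquist frequency")
    taps = design_bandpass_fir(fs, lo, hi, transition)
    if x.shape[-1] < 3 * len(taps):
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than 3x filter length "
            f"{len(taps)}"
        )
    x = x - x.mean(axis=-1, keepdims=True)
    y = sps.fftconvolve(x, taps[(np.newaxis,) * (x.ndim - 1) + (slice(None),)],
                        mode="same", axes=-1)
    return y
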