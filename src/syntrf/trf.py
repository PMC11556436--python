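"""Temporal response functions by closed-form ridge regression.

The encoding model is y_c(t) = sum_f sum_k x_f(t - tau_k) beta_f(tau_k, c)
+ noise: each feature track contributes through a coefficient waveform
(the TRF) over lags tau_k.  Stacking lagged copies of all features into a
design matrix X (N samples x K*F columns, feature-major blocks), the ridge
solution is beta = (X'X + lambda I)^-1 X'Y.

Model selection and scoring use nested cross-validation over contiguous
segments: outer folds score a model whose lambda was chosen on inner folds
of the training portion only, and the final TRF is refit on all data at
the modal chosen lambda.  Because all subjects hear the same stimulus the
design matrix — and hence each fold's Gram matrix X'X — is shared across
subjects; Grams are accumulated once per segment and reused for every
fold, subject and lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .features import FeatureTrack

__all__ = [
    "LagDesign",
    "TRFModel",
    "CVResult",
    "lag_times",
    "build_lagged",
    "fit_ridge",
    "predict",
    "score",
    "nested_cv",
    "model_grid",
    "table1_feature_sets",
    "table2_feature_sets",
]


def lag_times(lag_min: float, lag_max: float, fs: float) -> np.ndarray:
    """Lag grid in seconds; K = round((lag_max - lag_min) * fs) + 1."""
    if lag_min > lag_max:
        raise ValueError("lag_min must not exceed lag_max")
    K = int(round((lag_max - lag_min) * fs)) + 1
    k0 = int(round(lag_min * fs))
    return (k0 + np.arange(K)) / fs


@dataclass
class LagDesign:
    """Lagged design matrix over F feature tracks."""

    matrix: np.ndarray          # N x (K*F), feature-major column blocks
    lag_min: float
    lag_max: float
    fs: float
    K: int
    feature_names: list[str]

    @property
    def F(self) -> int:
        return len(self.feature_names)


@dataclass
class TRFModel:
    """Estimated TRF coefficients (lags x features x channels)."""

    beta: np.ndarray
    lam: float
    lag_times: np.ndarray
    feature_names: list[str]

    @property
    def channel_count(self) -> int:
        return self.beta.shape[2]

    def beta2d(self) -> np.ndarray:
        K, F, C = self.beta.shape
        return self.beta.reshape(K * F, C, order="F").copy()

    @classmethod
    def from_flat(
        cls,
        beta_flat: np.ndarray,
        K: int,
        lam: float,
        lags: np.ndarray,
        names: list[str],
    ) -> "TRFModel":
        d, C = beta_flat.shape
        F = d // K
        beta = beta_flat.reshape(K * F, C).reshape(K, F, C, order="F")
        return cls(beta=beta, lam=lam, lag_times=lags, feature_names=names)


@dataclass
class CVResult:
    """Nested-CV bookkeeping: held-out accuracy and chosen lambdas."""

    fold_r: np.ndarray          # subjects x outer folds x channels
    chosen_lambda: np.ndarray   # subjects x outer folds
    modal_lambda: np.ndarray    # per subject
    mean_r: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_r = np.nanmean(self.fold_r, axis=1)


def _as_track_matrix(tracks) -> tuple[np.ndarray, list[str]]:
    if isinstance(tracks, np.ndarray):
        mat = np.atleast_2d(np.asarray(tracks, dtype=float))
        return mat, [f"f{i}" for i in range(mat.shape[0])]
    mats, names = [], []
    for i, t in enumerate(tracks):
        if isinstance(t, FeatureTrack):
            mats.append(t.samples)
            names.append(t.name or f"f{i}")
        else:
            mats.append(np.asarray(t, dtype=float))
            names.append(f"f{i}")
    lengths = {len(m) for m in mats}
    if len(lengths) != 1:
        raise ValueError("tracks must share a common length")
    return np.vstack(mats), names


def build_lagged(
    tracks, lag_min: float, lag_max: float, fs: float
) -> LagDesign:
    """Build the N x (K*F) lagged design matrix.

    Column (f, k) holds track f delayed by ``lag_times[k]`` (negative lags
    advance), zero-padded at the edges; row t aligns with signal sample t.
    """
    mat, names = _as_track_matrix(tracks)
    F, N = mat.shape
    lags = lag_times(lag_min, lag_max, fs)
    K = len(lags)
    if K > N:
        raise ValueError("lag window exceeds track length")
    shifts = np.rint(lags * fs).astype(int)
    X = np.zeros((N, K * F))
    for f in range(F):
        for k, s in enumerate(shifts):
            col = f * K + k
            if s >= 0:
                X[s:, col] = mat[f, : N - s]
            else:
                X[:s, col] = mat[f, -s:]
    return LagDesign(
        matrix=X, lag_min=lag_min, lag_max=lag_max, fs=fs, K=K,
        feature_names=names,
    )


def _solve_ridge(G: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    d = G.shape[0]
    A = G + lam * np.eye(d)
    try:
        cf = sla.cho_factor(A, check_finite=False)
    except sla.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "ridge system not positive definite (rank-deficient design); "
            "use lambda > 0"
        ) from exc
    return sla.cho_solve(cf, b, check_finite=False)


def fit_ridge(design: LagDesign, Y: np.ndarray, lam: float) -> TRFModel:
    """Closed-form ridge solution beta = (X'X + lambda I)^-1 X'Y."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X = design.matrix
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y row counts differ")
    beta_flat = _solve_ridge(X.T @ X, X.T @ Y, lam)
    return TRFModel.from_flat(
        beta_flat, design.K, lam,
        lag_times(design.lag_min, design.lag_max, design.fs),
        design.feature_names,
    )


def predict(model: TRFModel, design: LagDesign) -> np.ndarray:
    """Reconstruct the signal: X @ beta."""
    B = model.beta2d()
    if design.matrix.shape[1] != B.shape[0]:
        raise ValueError("design shape does not match the model")
    return design.matrix @ B


def score(Y: np.ndarray, Yhat: np.ndarray) -> np.ndarray:
    """Per-channel Pearson correlation between data and reconstruction."""
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise ValueError("shape mismatch")
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    yc = Y - Y.mean(axis=0)
    hc = Yhat - Yhat.mean(axis=0)
    denom = np.sqrt((yc**2).sum(axis=0) * (hc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc * hc).sum(axis=0) / denom
    if np.any(denom == 0):
        warnings.warn("constant column: correlation undefined, reported NaN")
        r = np.where(denom == 0, np.nan, r)
    return r


class SegmentedDesign:
    """Per-segment lagged designs with cached Gram matrices.

    Lagging is done within each contiguous fold block, so fold training
    and validation sets share no samples through the lags.
    """

    def __init__(self, tracks, n_blocks: int, lag_min: float,
                 lag_max: float, fs: float):
        mat, self.names = _as_track_matrix(tracks)
        N = mat.shape[1]
        bounds = np.linspace(0, N, n_blocks + 1).astype(int)
        self.slices = [slice(bounds[i], bounds[i + 1]) for i in range(n_blocks)]
        self.designs: list[LagDesign] = []
        self.grams: list[np.ndarray] = []
        K = len(lag_times(lag_min, lag_max, fs))
        for sl in self.slices:
            if sl.stop - sl.start < K:
                raise ValueError("fold shorter than the number of lags")
            d = build_lagged(mat[:, sl], lag_min, lag_max, fs)
            self.designs.append(d)
            self.grams.append(d.matrix.T @ d.matrix)
        self.K = K
        self.lags = lag_times(lag_min, lag_max, fs)
        self.d = self.designs[0].matrix.shape[1]

    def gram(self, blocks: list[int]) -> np.ndarray:
        G = np.zeros((self.d, self.d))
        for b in blocks:
            G += self.grams[b]
        return G

    def xty(self, blocks: list[int], Y: np.ndarray) -> np.ndarray:
        """X'Y accumulated over blocks; Y is (S, N, C) -> returns d x (S*C)."""
        S, _, C = Y.shape
        out = np.zeros((self.d, S * C))
        for b in blocks:
            sl = self.slices[b]
            Yb = np.moveaxis(Y[:, sl, :], 1, 0).reshape(sl.stop - sl.start, S * C)
            out += self.designs[b].matrix.T @ Yb
        return out

    def stacked_y(self, blocks: list[int], Y: np.ndarray) -> np.ndarray:
        S, _, C = Y.shape
        parts = [
            np.moveaxis(Y[:, self.slices[b], :], 1, 0).reshape(-1, S * C)
            for b in blocks
        ]
        return np.vstack(parts)

    def predict_flat(self, blocks: list[int], beta: np.ndarray) -> np.ndarray:
        return np.vstack([self.designs[b].matrix @ beta for b in blocks])


def _score_cols(Y: np.ndarray, Yhat: np.ndarray) -> np.ndarray:
    yc = Y - Y.mean(axis=0)
    hc = Yhat - Yhat.mean(axis=0)
    denom = np.sqrt((yc**2).sum(axis=0) * (hc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom == 0, np.nan, (yc * hc).sum(axis=0) / denom)


def nested_cv(
    tracks,
    Y: np.ndarray,
    lambda_grid,
    k_outer: int = 9,
    k_inner: int = 4,
    lag_min: float = -0.2,
    lag_max: float = 1.0,
    fs: float = 200.0,
    seed: int | None = None,
) -> tuple[CVResult, list[TRFModel]]:
    """Nested CV over contiguous segments; returns scores and final TRFs.

    ``Y`` may be (N, C) for one subject or (S, N, C) for a group sharing
    the stimulus.  Lambda is tuned per subject on inner folds of each outer
    training set (highest mean validation r across channels); the final
    model per subject is refit on all data at the modal chosen lambda
    (ties broken toward the smaller lambda).  The procedure is
    deterministic; ``seed`` is accepted for interface symmetry.
    """
    lambda_grid = sorted(float(l) for l in lambda_grid)
    if not lambda_grid:
        raise ValueError("empty lambda grid")
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 2
    if squeeze:
        Y = Y[None]
    S, N, C = Y.shape

    sd = SegmentedDesign(tracks, k_outer, lag_min, lag_max, fs)
    all_blocks = list(range(k_outer))
    fold_r = np.full((S, k_outer, C), np.nan)
    chosen = np.zeros((S, k_outer))

    for o in all_blocks:
        train_blocks = [b for b in all_blocks if b != o]
        groups = [list(g) for g in np.array_split(train_blocks, k_inner)]
        # inner score per subject per lambda
        inner_r = np.zeros((S, len(lambda_grid)))
        for g in groups:
            fit_blocks = [b for b in train_blocks if b not in g]
            G = sd.gram(fit_blocks)
            b = sd.xty(fit_blocks, Y)
            Yval = sd.stacked_y(g, Y)
            for li, lam in enumerate(lambda_grid):
                beta = _solve_ridge(G, b, lam)
                Yhat = sd.predict_flat(g, beta)
                r = _score_cols(Yval, Yhat).reshape(S, C)
                inner_r[:, li] += np.nanmean(r, axis=1)
        lam_idx = np.argmax(inner_r, axis=1)
        chosen[:, o] = np.asarray(lambda_grid)[lam_idx]
        # outer fit per distinct chosen lambda
        G = sd.gram(train_blocks)
        b = sd.xty(train_blocks, Y)
        Yval = sd.stacked_y([o], Y)
        for li in np.unique(lam_idx):
            beta = _solve_ridge(G, b, lambda_grid[li])
            Yhat = sd.predict_flat([o], beta)
            r = _score_cols(Yval, Yhat).reshape(S, C)
            fold_r[lam_idx == li, o, :] = r[lam_idx == li]

    # modal lambda per subject, ties toward smaller lambda
    modal = np.empty(S)
    for s in range(S):
        vals, cnts = np.unique(chosen[s], return_counts=True)
        modal[s] = vals[np.argmax(cnts)]  # unique() is sorted ascending

    G = sd.gram(all_blocks)
    b_all = sd.xty(all_blocks, Y)
    models: list[TRFModel] = []
    for lam in np.unique(modal):
        beta = _solve_ridge(G, b_all, lam)
        beta = beta.reshape(sd.d, S, C)
        for s in np.flatnonzero(modal == lam):
            models.append(
                TRFModel.from_flat(beta[:, s, :], sd.K, float(lam), sd.lags,
                                   sd.names)
            )
    # restore subject order
    order = np.argsort(np.argsort(modal, kind="stable"), kind="stable")
    models = [models[i] for i in order]

    res = CVResult(fold_r=fold_r, chosen_lambda=chosen, modal_lambda=modal)
    return res, (models if not squeeze else models[:1])


def table1_feature_sets(
    base: tuple[str, ...] = ("envelope", "word_onset", "word_frequency"),
) -> dict[str, list[str]]:
    """The 16-model main-effects grid over 4 binary experimental features."""
    sets: dict[str, list[str]] = {}
    for s in (0, 1):
        for e in (0, 1):
            for td in (0, 1):
                for bu in (0, 1):
                    parts = []
                    if s and e:
                        parts.append("distributional")
                    elif s:
                        parts.append("surprisal")
                    elif e:
                        parts.append("entropy")
                    if td:
                        parts.append("topdown")
                    if bu:
                        parts.append("bottomup")
                    name = "main_" + ("_".join(parts) if parts else "null")
                    feats = list(base)
                    if s:
                        feats.append("surprisal")
                    if e:
                        feats.append("entropy")
                    if bu:
                        feats.append("bottomup")
                    if td:
                        feats.append("topdown")
                    sets[name] = feats
    return sets


def table2_feature_sets(
    base: tuple[str, ...] = ("envelope", "word_onset", "word_frequency"),
) -> dict[str, list[str]]:
    """The 4-model interaction grid: surprisal-split vs random-split."""
    b = list(base) + ["surprisal"]
    return {
        "bottomup_low_surprisal": b + ["bottomup_low"],
        "bottomup_high_surprisal": b + ["bottomup_high"],
        "bottomup_split_surprisal": b + ["bottomup_low", "bottomup_high"],
        "bottomup_split_random": b + ["bottomup_rand1", "bottomup_rand2"],
    }


def model_grid(
    feature_sets: dict[str, list[str]],
    tracks: dict[str, FeatureTrack],
    Y: np.ndarray,
    lambda_grid,
    **cv_kwargs,
) -> pd.DataFrame:
    """Fit every named feature set and tabulate held-out accuracy.

    Returns one row per (model, subject, channel) with the mean held-out
    Pearson r across outer folds.
    """
    for name, feats in feature_sets.items():
        missing = [f for f in feats if f not in tracks]
        if missing:
            raise ValueError(f"model {name}: unknown features {missing}")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 2:
        Y = Y[None]
    rows = []
    for name, feats in feature_sets.items():
        res, _ = nested_cv([tracks[f] for f in feats], Y, lambda_grid,
                           **cv_kwargs)
        S, C = res.mean_r.shape
        for s in range(S):
            for c in range(C):
                rows.append(dict(model=name, subject=s, channel=c,
                                 r=res.mean_r[s, c]))
    return pd.DataFrame(rows)
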