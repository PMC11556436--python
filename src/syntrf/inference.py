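"""Split-based interaction analyses and nonparametric inference.

Three pieces of machinery:

* word-set splits — median split on a covariate (e.g. trigram surprisal),
  random halves as the matched control, and duration matching by
  histogram overlap (per duration bin, keep min(count_low, count_high)
  words from each condition so the matched histograms are identical);
* spatio-temporal cluster-based permutation tests on paired subject maps,
  with signed summed-t cluster masses, sensor adjacency, and a sign-flip
  randomization null with add-one Monte-Carlo p-values;
* cross-correlation latency estimation between two grand-average TRF
  waveforms: per-sensor peak lags, the modal lag, shifted-waveform
  correlations, and a Monte-Carlo null over random channel subsets and
  lags.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats
from scipy.sparse import csgraph

__all__ = [
    "Adjacency",
    "ClusterResult",
    "LatencyResult",
    "median_split",
    "random_split",
    "duration_match",
    "cluster_perm",
    "xcorr_latency",
]


@dataclass
class Adjacency:
    """Symmetric sensor neighborhood structure."""

    channels: list[str]
    neighbors: dict[str, set[str]]

    def __post_init__(self) -> None:
        for ch, ns in self.neighbors.items():
            if ch in ns:
                raise ValueError(f"self-loop at channel {ch}")
            for n in ns:
                if ch not in self.neighbors.get(n, set()):
                    raise ValueError(f"asymmetric adjacency: {ch} -> {n}")

    @classmethod
    def from_json(cls, text: str) -> "Adjacency":
        d = json.loads(text)
        return cls(channels=list(d), neighbors={k: set(v) for k, v in d.items()})

    def to_json(self) -> str:
        return json.dumps({c: sorted(self.neighbors[c]) for c in self.channels})

    @classmethod
    def grid(cls, n_channels: int) -> "Adjacency":
        """Rook-adjacency on the most square grid holding n_channels."""
        rows = int(np.floor(np.sqrt(n_channels)))
        while n_channels % rows:
            rows -= 1
        cols = n_channels // rows
        names = [f"ch{i:02d}" for i in range(n_channels)]
        nb: dict[str, set[str]] = {n: set() for n in names}
        for i in range(n_channels):
            r, c = divmod(i, cols)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    nb[names[i]].add(names[rr * cols + cc])
        return cls(channels=names, neighbors=nb)

    def matrix(self) -> sparse.csr_matrix:
        idx = {c: i for i, c in enumerate(self.channels)}
        rows, cols = [], []
        for c, ns in self.neighbors.items():
            for n in ns:
                rows.append(idx[c])
                cols.append(idx[n])
        n = len(self.channels)
        return sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )


@dataclass
class ClusterResult:
    """Observed clusters with signed masses, p-values, and the null."""

    clusters: list[np.ndarray]          # arrays of flat (channel,time) indices
    masses: np.ndarray                  # signed summed t per cluster
    p_values: np.ndarray
    t_map: np.ndarray                   # channels x time
    null_max_mass: np.ndarray

    def significant_channels(self, alpha: float = 0.05) -> np.ndarray:
        """Channels belonging to any cluster with p < alpha."""
        T = self.t_map.shape[1] if self.t_map.ndim == 2 else 1
        chans: set[int] = set()
        for cl, p in zip(self.clusters, self.p_values):
            if p < alpha:
                chans.update((cl // T).tolist())
        return np.array(sorted(chans), dtype=int)


@dataclass
class LatencyResult:
    """Cross-correlation latency estimate with its Monte-Carlo null."""

    peak_lags: np.ndarray               # seconds, per retained channel
    channels: np.ndarray                # retained channel indices
    modal_lag: float                    # seconds
    shifted_corr: np.ndarray            # per-channel Pearson r after shift
    mean_corr: float
    sd_corr: float
    null_means: np.ndarray
    p_value: float


# ---------------------------------------------------------------------------
# splits


def median_split(
    events: pd.DataFrame, key: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split events at the global median of ``key`` (<= median goes low)."""
    vals = events[key].to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        raise ValueError(f"degenerate split: all {key} values identical")
    med = float(np.median(vals))
    low = events[events[key] <= med]
    high = events[events[key] > med]
    return low, high


def random_split(
    events: pd.DataFrame, seed: int | np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniformly random partition into halves differing in size by <= 1."""
    if len(events) < 2:
        raise ValueError("need at least 2 events")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(events))
    half = len(events) // 2
    a = events.iloc[np.sort(perm[:half])]
    b = events.iloc[np.sort(perm[half:])]
    return a, b


def duration_match(
    low: pd.DataFrame,
    high: pd.DataFrame,
    n_bins: int = 100,
    range_s: tuple[float, float] = (0.0, 1.25),
    seed: int | np.random.Generator = 0,
    key: str = "duration",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram-overlap subsampling so duration histograms match exactly.

    Per duration bin the kept count is min(count_low, count_high); kept
    events are drawn uniformly at random within the bin for each condition.
    Out-of-range events are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    edges = np.linspace(range_s[0], range_s[1], n_bins + 1)

    def binned(df: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
        d = df[key].to_numpy(dtype=float)
        inside = (d >= range_s[0]) & (d <= range_s[1])
        if not inside.all():
            warnings.warn(
                f"dropping {int((~inside).sum())} events outside the "
                f"duration range {range_s}"
            )
        df = df[inside]
        b = np.clip(
            np.digitize(df[key].to_numpy(dtype=float), edges) - 1, 0,
            n_bins - 1,
        )
        return df, b

    low, bl = binned(low)
    high, bh = binned(high)
    keep_l: list[np.ndarray] = []
    keep_h: list[np.ndarray] = []
    for b in range(n_bins):
        il = np.flatnonzero(bl == b)
        ih = np.flatnonzero(bh == b)
        k = min(len(il), len(ih))
        if k:
            keep_l.append(rng.choice(il, size=k, replace=False))
            keep_h.append(rng.choice(ih, size=k, replace=False))
    if not keep_l:
        raise ValueError("empty histogram overlap between conditions")
    out_l = low.iloc[np.sort(np.concatenate(keep_l))]
    out_h = high.iloc[np.sort(np.concatenate(keep_h))]
    return out_l, out_h


# ---------------------------------------------------------------------------
# cluster-based permutation test


def _spatiotemporal_graph(adj: sparse.csr_matrix, T: int) -> sparse.csr_matrix:
    """Adjacency over (channel, time) nodes, flat index = c * T + t."""
    C = adj.shape[0]
    eyeT = sparse.identity(T, format="csr")
    spatial = sparse.kron(adj, eyeT, format="csr")
    if T > 1:
        off = sparse.diags([np.ones(T - 1), np.ones(T - 1)], [1, -1],
                           format="csr")
        temporal = sparse.kron(sparse.identity(C, format="csr"), off,
                               format="csr")
        return (spatial + temporal).tocsr()
    return spatial


def _clusters_from_mask(
    graph: sparse.csr_matrix, mask: np.ndarray, t_flat: np.ndarray
) -> tuple[list[np.ndarray], list[float]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return [], []
    sub = graph[idx][:, idx]
    n, labels = csgraph.connected_components(sub, directed=False)
    masses = np.bincount(labels, weights=t_flat[idx], minlength=n)
    return [idx[labels == i] for i in range(n)], masses.tolist()


def _paired_t(mean: np.ndarray, msq: np.ndarray, n: int) -> np.ndarray:
    var = (msq - mean**2) * n / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def cluster_perm(
    A: np.ndarray,
    B: np.ndarray,
    adjacency: Adjacency,
    t_thresh: float = 1.714,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> ClusterResult:
    """Paired spatio-temporal cluster permutation test between A and B.

    ``A`` and ``B`` are (subjects, channels, time) — or (subjects,
    channels) for time-free maps such as accuracy topographies.  The
    statistic is the paired t map of A - B; clusters form separately from
    t > +t_thresh and t < -t_thresh under channel (and time) adjacency,
    with mass = sum of t inside the cluster.  The null permutes condition
    labels by sign-flipping subject difference maps; each cluster's
    p-value is (1 + #{perm max |mass| >= |mass|}) / (1 + n_perm).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("A and B must have identical shapes")
    if A.ndim == 2:
        A = A[..., None]
        B = B[..., None]
    S, C, T = A.shape
    if S < 2:
        raise ValueError("need at least 2 subjects")
    if C != len(adjacency.channels):
        raise ValueError("adjacency channel count does not match the data")
    rng = np.random.default_rng(seed)

    D = (A - B).reshape(S, C * T)
    msq = (D**2).mean(axis=0)
    t_obs = _paired_t(D.mean(axis=0), msq, S)

    graph = _spatiotemporal_graph(adjacency.matrix(), T)
    clusters: list[np.ndarray] = []
    masses: list[float] = []
    cl, ms = _clusters_from_mask(graph, t_obs > t_thresh, t_obs)
    clusters += cl
    masses += ms
    cl, ms = _clusters_from_mask(graph, t_obs < -t_thresh, t_obs)
    clusters += cl
    masses += ms

    signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
    perm_means = signs @ D / S
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        t_p = _paired_t(perm_means[i], msq, S)
        best = 0.0
        for mask in (t_p > t_thresh, t_p < -t_thresh):
            _, ms = _clusters_from_mask(graph, mask, t_p)
            if ms:
                best = max(best, np.abs(ms).max())
        null_max[i] = best

    masses_arr = np.asarray(masses)
    p = np.array(
        [
            (1 + np.sum(null_max >= abs(m))) / (1 + n_perm)
            for m in masses_arr
        ]
    )
    order = np.argsort(-np.abs(masses_arr)) if len(masses_arr) else np.array([], int)
    return ClusterResult(
        clusters=[clusters[i] for i in order],
        masses=masses_arr[order],
        p_values=p[order],
        t_map=t_obs.reshape(C, T),
        null_max_mass=null_max,
    )


# ---------------------------------------------------------------------------
# cross-correlation latency


def _pearson_by_lag(low: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Pearson r between high[t] and low[t - L] over the overlap, per lag L.

    Returns an array over lags L = -(T-1) .. T-1 (length 2T-1); positive L
    means the high waveform is delayed relative to the low one.
    """
    T = low.shape[-1]
    lags = np.arange(-(T - 1), T)
    out = np.empty(len(lags))
    for i, L in enumerate(lags):
        if L >= 0:
            x, y = high[L:], low[: T - L]
        else:
            x, y = high[: T + L], low[-L:]
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            out[i] = np.nan
            continue
        out[i] = np.corrcoef(x, y)[0, 1]
    return out


def _raw_xcorr(low: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Unnormalized cross-correlation sum_t low[t] * high[t + L]."""
    return np.correlate(high, low, mode="full")


def xcorr_latency(
    trf_low: np.ndarray,
    trf_high: np.ndarray,
    channel_subset,
    fs: float,
    n_null: int = 10000,
    seed: int | np.random.Generator = 0,
) -> LatencyResult:
    """Latency shift between two grand-average TRFs by cross-correlation.

    Per channel in ``channel_subset`` the full cross-correlation of the
    low- and high-condition waveforms is normalized by its maximum, and
    the lag of the maximal positive peak recorded; a positive lag means
    the high-condition response is delayed.  The low waveform is then
    shifted by the modal peak lag (ties toward the smaller absolute lag)
    and correlated with the high waveform per channel.  The null repeats
    the mean shifted correlation for random channel subsets of the same
    size and a random lag, n_null times.
    """
    trf_low = np.atleast_2d(np.asarray(trf_low, dtype=float))
    trf_high = np.atleast_2d(np.asarray(trf_high, dtype=float))
    if trf_low.shape != trf_high.shape:
        raise ValueError("waveform shapes differ")
    C, T = trf_low.shape
    subset = np.asarray(list(channel_subset), dtype=int)
    if subset.size == 0:
        raise ValueError("empty channel subset")
    rng = np.random.default_rng(seed)
    lags = np.arange(-(T - 1), T)

    keep: list[int] = []
    peak_lags: list[int] = []
    for c in subset:
        lo, hi = trf_low[c], trf_high[c]
        if not lo.any() or not hi.any():
            warnings.warn(f"all-zero waveform on channel {c}; dropped")
            continue
        xc = _raw_xcorr(lo, hi)
        xc = xc / np.abs(xc).max()
        pos = np.flatnonzero(xc > 0)
        if pos.size == 0:
            warnings.warn(f"no positive cross-correlation on channel {c}; dropped")
            continue
        peak = pos[np.argmax(xc[pos])]
        keep.append(int(c))
        peak_lags.append(int(lags[peak]))
    if not keep:
        raise ValueError("no usable channels in the subset")

    vals, cnts = np.unique(peak_lags, return_counts=True)
    best = cnts.max()
    cand = vals[cnts == best]
    modal = int(cand[np.lexsort((cand, np.abs(cand)))[0]])

    # Pearson-by-lag table for every channel (used for observed and null)
    table = np.full((C, len(lags)), np.nan)
    for c in range(C):
        if trf_low[c].any() and trf_high[c].any():
            table[c] = _pearson_by_lag(trf_low[c], trf_high[c])
    li = modal + (T - 1)
    shifted = table[np.asarray(keep), li]
    mean_corr = float(np.nanmean(shifted))
    sd_corr = float(np.nanstd(shifted))

    usable = np.flatnonzero(~np.all(np.isnan(table), axis=1))
    # valid lags: overlap long enough that some channel has a defined r
    valid_lags = np.flatnonzero(~np.all(np.isnan(table[usable]), axis=0))
    null_means = np.empty(n_null)
    for i in range(n_null):
        ch = rng.choice(usable, size=min(len(keep), len(usable)),
                        replace=False)
        li_n = valid_lags[rng.integers(len(valid_lags))]
        null_means[i] = np.nanmean(table[ch, li_n])
    p = float((1 + np.sum(null_means >= mean_corr)) / (1 + n_null))

    return LatencyResult(
        peak_lags=np.asarray(peak_lags) / fs,
        channels=np.asarray(keep),
        modal_lag=modal / fs,
        shifted_corr=shifted,
        mean_corr=mean_corr,
        sd_corr=sd_corr,
        null_means=null_means,
        p_value=p,
    )
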