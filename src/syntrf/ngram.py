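"""Interpolated Kneser–Ney trigram language model: surprisal and entropy.

Surprisal of a word is I(w) = -log2 P(w | h) in bits, where h is the two
preceding tokens; lexical entropy is H(h) = -sum_k P(k | h) log2 P(k | h)
over the full prediction vocabulary (end-of-sentence and unknown symbols
included).  Both are the short-context distributional predictors used in
the encoding models.

The estimator is single-discount interpolated Kneser–Ney: the highest
order uses raw counts, lower orders use continuation (distinct-history)
counts, and each order's discount is D = n1 / (n1 + 2 n2) from that
order's count-of-counts, clamped to [0, 0.999].  The unigram level
interpolates with a uniform distribution over the vocabulary plus an
explicit unknown symbol, so every token receives non-zero mass and
surprisal is finite even for unseen words.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["KneserNeyLM", "train_kn", "score_events", "BOS", "EOS", "UNK"]

BOS = "<s>"
EOS = "</s>"
UNK = "<unk>"


def _discount(counts: Counter) -> float:
    """Absolute discount D = n1/(n1 + 2 n2) from count-of-counts."""
    n1 = sum(1 for c in counts.values() if c == 1)
    n2 = sum(1 for c in counts.values() if c == 2)
    if n1 + 2 * n2 == 0:
        return 0.0
    return float(np.clip(n1 / (n1 + 2 * n2), 0.0, 0.999))


@dataclass
class KneserNeyLM:
    """Interpolated Kneser–Ney model of order 1–3.

    Built with :func:`train_kn`; query with :meth:`prob`,
    :meth:`surprisal`, :meth:`entropy` or :meth:`prob_dist`.
    """

    order: int
    vocab: list[str]                       # prediction space incl. EOS, UNK
    c3: dict[tuple[str, str], Counter] = field(default_factory=dict)
    cc2: dict[str, Counter] = field(default_factory=dict)
    cc1: Counter = field(default_factory=Counter)
    discounts: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {w: i for i, w in enumerate(self.vocab)}
        self._c3_tot = {h: sum(c.values()) for h, c in self.c3.items()}
        self._cc2_tot = {h: sum(c.values()) for h, c in self.cc2.items()}
        self._cc1_tot = sum(self.cc1.values())
        V = len(self.vocab)
        D1 = self.discounts.get(1, 0.0)
        p1 = np.zeros(V)
        if self._cc1_tot > 0:
            n_types = sum(1 for c in self.cc1.values() if c > 0)
            lam1 = D1 * n_types / self._cc1_tot
            for w, c in self.cc1.items():
                p1[self._index[w]] = max(c - D1, 0.0) / self._cc1_tot
            p1 += lam1 / V
        else:
            p1[:] = 1.0 / V
        self._p1 = p1

    # -- vocabulary handling ------------------------------------------------

    def map_token(self, token: str) -> str:
        """Map out-of-vocabulary tokens to the unknown symbol."""
        return token if token in self._index else UNK

    def _map_history(self, history: tuple[str, ...]) -> tuple[str, ...]:
        hist = tuple(history)[-(self.order - 1):] if self.order > 1 else ()
        return tuple(
            t if (t == BOS or t in self._index) else UNK for t in hist
        )

    # -- probabilities ------------------------------------------------------

    def _p2_vec(self, v: str) -> np.ndarray:
        """Bigram-level continuation distribution P(. | v)."""
        D2 = self.discounts.get(2, 0.0)
        tot = self._cc2_tot.get(v, 0)
        if tot == 0 or self.order < 2:
            return self._p1
        cnt = self.cc2[v]
        p = np.zeros(len(self.vocab))
        for w, c in cnt.items():
            p[self._index[w]] = max(c - D2, 0.0) / tot
        lam = D2 * len(cnt) / tot
        return p + lam * self._p1

    def prob_dist(self, history: tuple[str, ...]) -> np.ndarray:
        """P(. | history) over ``self.vocab``; sums to 1."""
        hist = self._map_history(history)
        if self.order == 1 or not hist:
            return self._p1
        v = hist[-1]
        p2 = self._p2_vec(v)
        if self.order == 2 or len(hist) < 2:
            return p2
        u = hist[-2]
        D3 = self.discounts.get(3, 0.0)
        tot = self._c3_tot.get((u, v), 0)
        if tot == 0:
            return p2
        cnt = self.c3[(u, v)]
        p = np.zeros(len(self.vocab))
        for w, c in cnt.items():
            p[self._index[w]] = max(c - D3, 0.0) / tot
        lam = D3 * len(cnt) / tot
        return p + lam * p2

    def prob(self, word: str, history: tuple[str, ...]) -> float:
        dist = self.prob_dist(history)
        return float(dist[self._index[self.map_token(word)]])

    def surprisal(self, word: str, history: tuple[str, ...]) -> float:
        """-log2 P(word | history), in bits."""
        p = self.prob(word, history)
        if p <= 0.0:
            return float("inf")
        return float(-np.log2(p))

    def entropy(self, history: tuple[str, ...]) -> float:
        """Shannon entropy of the next-word distribution, in bits."""
        p = self.prob_dist(history)
        nz = p[p > 0]
        return float(-(nz * np.log2(nz)).sum())

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "order": self.order,
            "vocab": self.vocab,
            "discounts": {str(k): v for k, v in self.discounts.items()},
            "c3": [[list(h), dict(c)] for h, c in self.c3.items()],
            "cc2": [[h, dict(c)] for h, c in self.cc2.items()],
            "cc1": dict(self.cc1),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "KneserNeyLM":
        d = json.loads(text)
        return cls(
            order=d["order"],
            vocab=d["vocab"],
            c3={tuple(h): Counter(c) for h, c in d["c3"]},
            cc2={h: Counter(c) for h, c in d["cc2"]},
            cc1=Counter(d["cc1"]),
            discounts={int(k): v for k, v in d["discounts"].items()},
        )


def train_kn(sentences: list[list[str]], order: int = 3) -> KneserNeyLM:
    """Train an interpolated KN model on tokenized sentences.

    Each sentence is padded with ``order - 1`` start symbols and one end
    symbol; start symbols are never predicted.  Supported orders: 1–3.
    """
    if not sentences:
        raise ValueError("empty corpus")
    if order not in (1, 2, 3):
        raise ValueError(f"order must be 1, 2 or 3, got {order}")

    tokens = sorted({t for s in sentences for t in s})
    vocab = tokens + [EOS, UNK]

    c3: dict[tuple[str, str], Counter] = defaultdict(Counter)
    raw2: Counter = Counter()
    raw1: Counter = Counter()
    for s in sentences:
        padded = [BOS] * max(order - 1, 1) + list(s) + [EOS]
        for i in range(max(order - 1, 1), len(padded)):
            w = padded[i]
            raw1[w] += 1
            if order >= 2:
                raw2[(padded[i - 1], w)] += 1
            if order >= 3:
                c3[(padded[i - 2], padded[i - 1])][w] += 1

    discounts: dict[int, float] = {}
    cc2: dict[str, Counter] = defaultdict(Counter)
    cc1: Counter = Counter()

    if order == 3:
        tri_counts = Counter(
            {(h + (w,)): c for h, cnt in c3.items() for w, c in cnt.items()}
        )
        discounts[3] = _discount(tri_counts)
        # continuation counts: distinct left contexts per bigram
        for (u, v), cnt in c3.items():
            for w in cnt:
                cc2[v][w] += 1
        discounts[2] = _discount(
            Counter({(v, w): c for v, cnt in cc2.items() for w, c in cnt.items()})
        )
        for v, cnt in cc2.items():
            for w in cnt:
                cc1[w] += 1
        discounts[1] = _discount(cc1)
    elif order == 2:
        discounts[2] = _discount(raw2)
        for (v, w), c in raw2.items():
            cc2[v][w] += c
        for (v, w) in raw2:
            cc1[w] += 1
        discounts[1] = _discount(cc1)
    else:
        cc1 = raw1
        discounts[1] = _discount(raw1)

    return KneserNeyLM(
        order=order,
        vocab=vocab,
        c3=dict(c3),
        cc2=dict(cc2),
        cc1=cc1,
        discounts=discounts,
    )


def score_events(model: KneserNeyLM, events: pd.DataFrame) -> pd.DataFrame:
    """Attach per-word surprisal and entropy columns to a word-event table.

    ``events`` must carry ``token`` and ``sentence_id`` columns; per word,
    the history is the two preceding tokens within the sentence, padded
    with start symbols at sentence beginnings.  Returns a copy with
    ``surprisal_trigram`` and ``entropy_trigram`` columns.
    """
    if "sentence_id" not in events.columns:
        raise ValueError("events lack sentence grouping (column sentence_id)")
    out = events.copy()
    surp = np.empty(len(out))
    ent = np.empty(len(out))
    pos = 0
    n_hist = max(model.order - 1, 0)
    for _, grp in out.groupby("sentence_id", sort=False):
        hist: list[str] = [BOS] * n_hist
        for tok in grp["token"]:
            h = tuple(hist[-n_hist:]) if n_hist else ()
            surp[pos] = model.surprisal(tok, h)
            ent[pos] = model.entropy(h)
            hist.append(model.map_token(tok))
            pos += 1
    out["surprisal_trigram"] = surp
    out["entropy_trigram"] = ent
    return out
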