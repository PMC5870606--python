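"""Word embeddings for CRF features: a CBOW trainer and a token->vector table.

The continuous-bag-of-words model predicts a token from the mean of its
context vectors inside a symmetric window, trained by negative sampling.
Defaults mirror the tagger's operating point: window = 10, dimension
D = 100, tokens normalized to lowercase with every digit mapped to ``0``.
Training is single-threaded and fully deterministic given the seed.

The persisted format is a plain-text table: a header line ``D window``
followed by one ``token v_0 ... v_{D-1}`` line per vocabulary entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .tokenizer import token_surfaces


def normalize_for_embedding(surface: str) -> str:
    """Embedding lookup key: lowercase, every digit mapped to 0."""
    return "".join("0" if c.isdigit() else c.lower() for c in surface)


@dataclass
class EmbeddingModel:
    dim: int
    window: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for token, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise ValueError(f"vector for {token!r} has shape {vec.shape}")

    def lookup(self, normalized_token: str) -> np.ndarray | None:
        return self.vectors.get(normalized_token)

    def similarity(self, a: str, b: str) -> float:
        va = self.lookup(normalize_for_embedding(a))
        vb = self.lookup(normalize_for_embedding(b))
        if va is None or vb is None:
            return float("nan")
        denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
        return float(va @ vb) / denom if denom else 0.0

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.dim} {self.window}\n")
            for token in sorted(self.vectors):
                vals = " ".join(f"{v:.8g}" for v in self.vectors[token])
                fh.write(f"{token} {vals}\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        with open(path) as fh:
            dim, window = map(int, fh.readline().split())
            vectors: dict[str, np.ndarray] = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vectors[parts[0]] = np.array([float(v) for v in parts[1:]])
        return cls(dim=dim, window=window, vectors=vectors)


def train_cbow(
    texts: Iterable[str],
    window: int = 10,
    dim: int = 100,
    seed: int = 0,
    epochs: int = 5,
    negative: int = 5,
    learning_rate: float = 0.05,
    min_count: int = 1,
) -> EmbeddingModel:
    """Train CBOW vectors on raw texts (tokenized and normalized in here)."""
    sentences = [
        [normalize_for_embedding(s) for s in token_surfaces(text)]
        for text in texts
    ]
    sentences = [s for s in sentences if s]
    if not sentences:
        raise ValueError("cannot train embeddings on an empty corpus")

    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(tok for tok, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("no vocabulary above min_count")
    index = {tok: i for i, tok in enumerate(vocab)}
    V = len(vocab)

    # unigram^0.75 negative-sampling distribution
    freqs = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    neg_probs = freqs / freqs.sum()

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    encoded = [np.array([index[t] for t in sent if t in index]) for sent in sentences]
    encoded = [s for s in encoded if len(s) >= 2]
    total_steps = max(1, epochs * sum(len(s) for s in encoded))
    step = 0
    for _epoch in range(epochs):
        for sent in encoded:
            n = len(sent)
            reduced = rng.integers(1, window + 1, size=n)
            for pos in range(n):
                lr = learning_rate * max(1e-4, 1.0 - step / total_steps)
                step += 1
                b = reduced[pos]
                lo, hi = max(0, pos - b), min(n, pos + b + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1 : hi]])
                if len(ctx) == 0:
                    continue
                h = W_in[ctx].mean(axis=0)
                center = sent[pos]
                negs = rng.choice(V, size=negative, p=neg_probs)
                targets = np.concatenate([[center], negs])
                labels = np.zeros(len(targets))
                labels[0] = 1.0
                out = W_out[targets]
                scores = 1.0 / (1.0 + np.exp(-out @ h))
                g = (labels - scores) * lr
                grad_h = g @ out
                W_out[targets] += np.outer(g, h)
                W_in[ctx] += grad_h / len(ctx)
    return EmbeddingModel(
        dim=dim, window=window,
        vectors={tok: W_in[i].copy() for tok, i in index.items()},
    )
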