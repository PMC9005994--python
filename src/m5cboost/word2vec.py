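"""Deterministic CBOW word embeddings for nucleotide k-mer tokens.

RNA segments are treated as sentences of overlapping k-mer tokens (stride 1,
k=3 by default) and a continuous-bag-of-words model with negative sampling
is trained by mini-batch SGD in numpy.  The trainer is single-threaded and
fully driven by one seed, so the same corpus and seed always reproduce the
same vectors — a property the surrounding pipeline relies on for
reproducible feature matrices.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Sequence

import numpy as np


def tokenize(sequence: str, k: int = 3) -> list[str]:
    """Overlapping k-mers with stride 1 (a 41-mer yields 39 3-mer tokens)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


@dataclasses.dataclass
class Word2VecModel:
    """A trained token -> vector map plus the tokenization contract."""

    vocab: dict[str, int]
    vectors: np.ndarray  # (V, dim) input embeddings
    token_k: int
    config: dict

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def vector(self, token: str) -> np.ndarray:
        """The token's vector, or zeros if out of vocabulary."""
        idx = self.vocab.get(token)
        if idx is None:
            return np.zeros(self.dim)
        return self.vectors[idx]

    def encode(self, sequence: str) -> np.ndarray:
        """Mean of token vectors; OOV tokens contribute zero vectors."""
        tokens = tokenize(sequence, self.token_k)
        if not tokens:
            raise ValueError("sequence shorter than token size")
        acc = np.zeros(self.dim)
        for tok in tokens:
            acc += self.vector(tok)
        return acc / len(tokens)


def train_cbow(
    sentences: Sequence[Sequence[str]],
    dim: int = 100,
    window: int = 5,
    epochs: int = 20,
    negative: int = 5,
    seed: int = 0,
    lr: float = 0.025,
    min_lr: float = 1e-4,
    min_count: int = 1,
    batch_size: int = 512,
    token_k: int = 3,
) -> Word2VecModel:
    """Train CBOW with negative sampling on tokenized sentences.

    The context is the symmetric fixed window around each center token; the
    prediction input is the mean of the context vectors; ``negative`` noise
    tokens per example are drawn from the unigram^0.75 distribution.  The
    learning rate decays linearly from ``lr`` to ``min_lr`` over all batches.
    """
    counts = Counter(tok for sent in sentences for tok in sent)
    vocab_tokens = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    if not vocab_tokens:
        raise ValueError("empty corpus (or everything below min_count)")
    vocab = {t: i for i, t in enumerate(vocab_tokens)}
    nvocab = len(vocab)

    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-0.5 / dim, 0.5 / dim, size=(nvocab, dim))
    w_out = np.zeros((nvocab, dim))

    # flatten (center, padded context) examples once, in corpus order
    centers, contexts, ctx_len = [], [], []
    width = 2 * window
    for sent in sentences:
        idx = [vocab[t] for t in sent if t in vocab]
        for t, center in enumerate(idx):
            ctx = idx[max(0, t - window) : t] + idx[t + 1 : t + 1 + window]
            if not ctx:
                continue
            centers.append(center)
            contexts.append(ctx + [-1] * (width - len(ctx)))
            ctx_len.append(len(ctx))
    if not centers:
        raise ValueError("corpus sentences shorter than the context window")
    centers = np.array(centers)
    contexts = np.array(contexts)
    ctx_len = np.array(ctx_len, dtype=float)
    mask = (contexts >= 0).astype(float)
    contexts_safe = np.where(contexts >= 0, contexts, 0)

    freq = np.array([counts[t] for t in vocab_tokens], dtype=float) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())

    n = len(centers)
    n_batches = int(np.ceil(n / batch_size))
    total_steps = epochs * n_batches
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n)
        for b in range(n_batches):
            sel = order[b * batch_size : (b + 1) * batch_size]
            alpha = max(min_lr, lr * (1 - step / total_steps))
            step += 1
            ctx = contexts_safe[sel]
            m = mask[sel]
            h = (w_in[ctx] * m[:, :, None]).sum(axis=1) / ctx_len[sel][:, None]

            negs = np.searchsorted(
                noise_cdf, rng.random((len(sel), negative))
            )
            out_idx = np.concatenate([centers[sel][:, None], negs], axis=1)
            labels = np.zeros(out_idx.shape)
            labels[:, 0] = 1.0

            emb_out = w_out[out_idx]  # (B, 1+neg, dim)
            scores = np.einsum("bd,bkd->bk", h, emb_out)
            sig = 1.0 / (1.0 + np.exp(-np.clip(scores, -30, 30)))
            g = (labels - sig) * alpha  # (B, 1+neg)

            grad_h = np.einsum("bk,bkd->bd", g, emb_out)
            np.add.at(w_out, out_idx, g[:, :, None] * h[:, None, :])
            ctx_grad = (grad_h / ctx_len[sel][:, None])[:, None, :] * m[:, :, None]
            np.add.at(w_in, ctx, ctx_grad)

    return Word2VecModel(
        vocab=vocab,
        vectors=w_in,
        token_k=token_k,
        config={
            "dim": dim,
            "window": window,
            "epochs": epochs,
            "negative": negative,
            "seed": seed,
            "lr": lr,
            "min_lr": min_lr,
            "min_count": min_count,
            "batch_size": batch_size,
        },
    )
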