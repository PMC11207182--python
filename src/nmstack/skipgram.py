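"""Minimal deterministic skip-gram with negative sampling (SGNS).

Trains token embeddings over k-mer "sentences" derived from RNA sequences.
The vocabulary for overlapping 3-mers over {A,C,G,U} is at most 64 tokens,
so a vectorised numpy SGD is entirely adequate; training is deterministic
for a fixed seed (single worker, fixed shuffling).

The objective is the standard SGNS logistic loss: for a (center, context)
pair with label 1 and ``negative`` noise tokens with label 0,

    L = -log sigma(u_c . v_o) - sum_neg log sigma(-u_c . v_n)

Noise tokens are drawn from the unigram distribution raised to 3/4.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_skipgram(
    sentences: list[list[str]],
    dim: int = 64,
    window: int = 5,
    epochs: int = 3,
    negative: int = 5,
    lr: float = 0.025,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Train SGNS embeddings; returns token -> dim-length vector.

    The returned vectors are the input (center) embeddings, the standard
    word2vec convention.
    """
    if not sentences or all(len(s) == 0 for s in sentences):
        raise ValueError("empty corpus")
    vocab = sorted({tok for sent in sentences for tok in sent})
    index = {tok: i for i, tok in enumerate(vocab)}
    V = len(vocab)
    rng = np.random.default_rng(seed)

    counts = np.zeros(V)
    for sent in sentences:
        for tok in sent:
            counts[index[tok]] += 1
    noise = counts**0.75
    noise /= noise.sum()

    # (center, context) pairs from all sentences, fixed enumeration order
    centers, contexts = [], []
    for sent in sentences:
        ids = [index[t] for t in sent]
        n = len(ids)
        for i in range(n):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(ids[i])
                    contexts.append(ids[j])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)
    n_pairs = centers.size
    if n_pairs == 0:
        # degenerate corpus of single-token sentences: return random vectors
        U = (rng.random((V, dim)) - 0.5) / dim
        return {tok: U[index[tok]].copy() for tok in vocab}

    U = (rng.random((V, dim)) - 0.5) / dim  # center vectors
    W = np.zeros((V, dim))  # context vectors
    batch = 1024
    for epoch in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch):
            sel = order[start : start + batch]
            c = centers[sel]
            o = contexts[sel]
            neg = rng.choice(V, size=(sel.size, negative), p=noise)

            uc = U[c]  # (b, d)
            # positive context
            g_pos = _sigmoid(np.einsum("bd,bd->b", uc, W[o])) - 1.0  # (b,)
            # negatives
            wn = W[neg]  # (b, k, d)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", uc, wn))  # (b, k)

            grad_u = g_pos[:, None] * W[o] + np.einsum("bk,bkd->bd", g_neg, wn)
            grad_o = g_pos[:, None] * uc
            grad_n = g_neg[..., None] * uc[:, None, :]

            np.add.at(U, c, -lr * grad_u)
            np.add.at(W, o, -lr * grad_o)
            np.add.at(W, neg.ravel(), -lr * grad_n.reshape(-1, dim))

    return {tok: U[index[tok]].copy() for tok in vocab}
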