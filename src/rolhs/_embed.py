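"""Vectorized numpy trainers for the four embedding kinds.

All trainers share a skip-gram-with-negative-sampling core (word2vec and
fasttext differ only in how the input vector is composed; doc2vec/PV-DBOW
replaces the centre word with a document id).  The glove kind factorizes a
distance-weighted co-occurrence matrix under the weighted least-squares
objective f(x)*(w.w~ + b + b~ - log x)^2 with AdaGrad.

Everything is seeded through a numpy Generator and runs single-threaded
numpy element-wise ops, so identical seeds give identical tables.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Vocab",
    "build_vocab",
    "skipgram_pairs",
    "train_sgns",
    "train_pvdbow",
    "train_glove",
    "train_fasttext",
]

_SIGMOID_CLAMP = 8.0
_MAX_ROW_UPDATE = 0.5  # L2 cap per aggregated row update; tames batch collisions


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_SIGMOID_CLAMP, _SIGMOID_CLAMP)))


def _scatter_sub(target: np.ndarray, idx: np.ndarray, grads: np.ndarray) -> None:
    """target[idx] -= grads with duplicate indices summed then norm-capped.

    The sum over duplicates is a one-hot sparse matmul (much faster than
    ufunc.at); the cap keeps frequent rows stable when a mini-batch
    aggregates many colliding updates.
    """
    from scipy import sparse

    n = len(idx)
    onehot = sparse.csr_matrix(
        (np.ones(n, dtype=grads.dtype), idx, np.arange(n + 1, dtype=np.int64)),
        shape=(n, target.shape[0]))
    update = np.asarray(onehot.T @ grads)
    norms = np.linalg.norm(update, axis=1, keepdims=True)
    np.divide(update * _MAX_ROW_UPDATE, norms, out=update,
              where=norms > _MAX_ROW_UPDATE)
    target -= update


class Vocab:
    def __init__(self, tokens: list[str], counts: np.ndarray):
        self.tokens = tokens
        self.index = {t: i for i, t in enumerate(tokens)}
        self.counts = counts

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, sentence: list[str]) -> np.ndarray:
        return np.array([self.index[t] for t in sentence], dtype=np.int64)

    def noise_distribution(self, power: float = 0.75) -> np.ndarray:
        p = self.counts.astype(float) ** power
        return p / p.sum()


def build_vocab(sentences: list[list[str]]) -> Vocab:
    counts: dict[str, int] = {}
    for sentence in sentences:
        for token in sentence:
            counts[token] = counts.get(token, 0) + 1
    tokens = sorted(counts)  # deterministic token order
    return Vocab(tokens, np.array([counts[t] for t in tokens], dtype=np.int64))


def skipgram_pairs(
    sentences: list[list[str]], vocab: Vocab, window: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(centre, context) index pairs with word2vec-style dynamic windows."""
    centres, contexts = [], []
    for sentence in sentences:
        ids = vocab.encode(sentence)
        n = len(ids)
        if n < 2:
            continue
        spans = rng.integers(1, window + 1, size=n)
        for i in range(n):
            lo, hi = max(0, i - spans[i]), min(n, i + spans[i] + 1)
            for j in range(lo, hi):
                if j != i:
                    centres.append(ids[i])
                    contexts.append(ids[j])
    if not centres:
        return np.empty((0, 2), dtype=np.int64)
    return np.stack([np.array(centres), np.array(contexts)], axis=1)


def _sample_negatives(
    rng: np.random.Generator, cdf: np.ndarray, shape: tuple[int, ...]
) -> np.ndarray:
    return np.searchsorted(cdf, rng.random(shape), side="right")


def _lr_schedule(step: int, total: int, lr0: float, lr_min: float = 1e-4) -> float:
    return max(lr_min, lr0 * (1.0 - step / max(1, total)))


def train_sgns(
    pairs: np.ndarray,
    n_vocab: int,
    noise: np.ndarray,
    dim: int,
    epochs: int,
    negative: int,
    lr: float,
    rng: np.random.Generator,
    batch: int = 4096,
) -> np.ndarray:
    """Plain skip-gram negative sampling; returns the input vector table."""
    w_in = ((rng.random((n_vocab, dim)) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((n_vocab, dim), dtype=np.float32)
    if len(pairs) == 0:
        return w_in
    cdf = np.cumsum(noise)
    n_batches = int(np.ceil(len(pairs) / batch))
    total = epochs * n_batches
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for b in range(n_batches):
            sel = pairs[order[b * batch:(b + 1) * batch]]
            centres, positives = sel[:, 0], sel[:, 1]
            negatives = _sample_negatives(rng, cdf, (len(sel), negative))
            eta = _lr_schedule(step, total, lr)
            step += 1
            _sgns_step(w_in, w_out, centres, positives, negatives, eta,
                       gather=lambda idx: w_in[idx],
                       scatter=lambda idx, g: _scatter_sub(w_in, idx, g))
    return w_in


def _sgns_step(w_in, w_out, centres, positives, negatives, eta, gather, scatter):
    v = gather(centres)                                   # (B, d)
    u_pos = w_out[positives]                              # (B, d)
    u_neg = w_out[negatives]                              # (B, k, d)
    g_pos = _sigmoid(np.einsum("bd,bd->b", v, u_pos)) - 1.0
    g_neg = _sigmoid(np.einsum("bkd,bd->bk", u_neg, v))
    grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
    d = v.shape[1]
    out_idx = np.concatenate([positives, negatives.reshape(-1)])
    out_grads = np.concatenate([
        eta * g_pos[:, None] * v,
        eta * (g_neg[:, :, None] * v[:, None, :]).reshape(-1, d),
    ])
    _scatter_sub(w_out, out_idx, out_grads)
    scatter(centres, eta * grad_v)


def train_pvdbow(
    doc_tokens: list[np.ndarray],
    n_vocab: int,
    noise: np.ndarray,
    dim: int,
    epochs: int,
    negative: int,
    lr: float,
    rng: np.random.Generator,
    batch: int = 4096,
) -> np.ndarray:
    """PV-DBOW: document vectors predict their tokens; returns doc table."""
    n_docs = len(doc_tokens)
    d_in = ((rng.random((n_docs, dim)) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((n_vocab, dim), dtype=np.float32)
    pairs = np.concatenate([
        np.stack([np.full(len(toks), i, dtype=np.int64), toks], axis=1)
        for i, toks in enumerate(doc_tokens) if len(toks)
    ]) if any(len(t) for t in doc_tokens) else np.empty((0, 2), dtype=np.int64)
    if len(pairs) == 0:
        return d_in
    cdf = np.cumsum(noise)
    n_batches = int(np.ceil(len(pairs) / batch))
    total = epochs * n_batches
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for b in range(n_batches):
            sel = pairs[order[b * batch:(b + 1) * batch]]
            docs, positives = sel[:, 0], sel[:, 1]
            negatives = _sample_negatives(rng, cdf, (len(sel), negative))
            eta = _lr_schedule(step, total, lr)
            step += 1
            _sgns_step(d_in, w_out, docs, positives, negatives, eta,
                       gather=lambda idx: d_in[idx],
                       scatter=lambda idx, g: _scatter_sub(d_in, idx, g))
    return d_in


def cooccurrence(
    sentences: list[list[str]], vocab: Vocab, window: int
) -> np.ndarray:
    """Symmetric distance-weighted co-occurrence counts (dense; small vocab)."""
    x = np.zeros((len(vocab), len(vocab)))
    for sentence in sentences:
        ids = vocab.encode(sentence)
        for i in range(len(ids)):
            for off in range(1, window + 1):
                j = i + off
                if j >= len(ids):
                    break
                x[ids[i], ids[j]] += 1.0 / off
                x[ids[j], ids[i]] += 1.0 / off
    return x


def train_glove(
    sentences: list[list[str]],
    vocab: Vocab,
    dim: int,
    epochs: int,
    window: int,
    rng: np.random.Generator,
    lr: float = 0.05,
    x_max: float = 100.0,
    alpha: float = 0.75,
) -> np.ndarray:
    """AdaGrad on the weighted least-squares co-occurrence objective."""
    x = cooccurrence(sentences, vocab, window)
    rows, cols = np.nonzero(x)
    if len(rows) == 0:
        return (rng.random((len(vocab), dim)) - 0.5) / dim
    xs = x[rows, cols]
    weights = np.minimum(1.0, (xs / x_max) ** alpha)
    logx = np.log(xs)

    n = len(vocab)
    w = (rng.random((n, dim)) - 0.5) / dim
    wt = (rng.random((n, dim)) - 0.5) / dim
    b = np.zeros(n)
    bt = np.zeros(n)
    gw = np.ones((n, dim))
    gwt = np.ones((n, dim))
    gb = np.ones(n)
    gbt = np.ones(n)

    for _ in range(epochs):
        order = rng.permutation(len(rows))
        r, c = rows[order], cols[order]
        fw, lx = weights[order], logx[order]
        diff = np.einsum("nd,nd->n", w[r], wt[c]) + b[r] + bt[c] - lx
        g = fw * diff  # (nnz,)
        grad_w = g[:, None] * wt[c]
        grad_wt = g[:, None] * w[r]
        np.add.at(gw, r, grad_w ** 2)
        np.add.at(gwt, c, grad_wt ** 2)
        np.add.at(gb, r, g ** 2)
        np.add.at(gbt, c, g ** 2)
        np.subtract.at(w, r, lr * grad_w / np.sqrt(gw[r]))
        np.subtract.at(wt, c, lr * grad_wt / np.sqrt(gwt[c]))
        np.subtract.at(b, r, lr * g / np.sqrt(gb[r]))
        np.subtract.at(bt, c, lr * g / np.sqrt(gbt[c]))
    return w + wt  # standard glove vector = sum of both roles


# -- fasttext ---------------------------------------------------------------

def _char_ngrams(token: str, nmin: int = 3, nmax: int = 5) -> list[str]:
    wrapped = f"<{token}>"
    grams = []
    for n in range(nmin, nmax + 1):
        for i in range(len(wrapped) - n + 1):
            grams.append(wrapped[i:i + n])
    return grams


def _hash_ngram(gram: str, buckets: int) -> int:
    h = 2166136261  # FNV-1a, 32-bit
    for byte in gram.encode("utf-8"):
        h = ((h ^ byte) * 16777619) & 0xFFFFFFFF
    return h % buckets


def subword_ids(vocab: Vocab, buckets: int) -> tuple[np.ndarray, np.ndarray]:
    """Padded (V, max_ngrams+1) id matrix into [vocab | ngram buckets] rows.

    Column 0 is the word's own id; remaining columns are hashed n-gram ids
    offset by the vocab size; -1 pads.
    """
    lists = []
    for i, token in enumerate(vocab.tokens):
        ids = [i] + [len(vocab) + _hash_ngram(g, buckets)
                     for g in _char_ngrams(token)]
        lists.append(ids)
    width = max(len(ids) for ids in lists)
    mat = np.full((len(vocab), width), -1, dtype=np.int64)
    for i, ids in enumerate(lists):
        mat[i, :len(ids)] = ids
    lengths = np.array([len(ids) for ids in lists], dtype=np.int64)
    return mat, lengths


def _composition_matrix(vocab: Vocab, buckets: int):
    """Sparse (V, V + buckets) matrix averaging a word's subword rows."""
    from scipy import sparse

    rows, cols, data = [], [], []
    for i, token in enumerate(vocab.tokens):
        ids = [i] + [len(vocab) + _hash_ngram(g, buckets)
                     for g in _char_ngrams(token)]
        weight = 1.0 / len(ids)
        for sid in ids:
            rows.append(i)
            cols.append(sid)
            data.append(weight)
    return sparse.csr_matrix(
        (np.array(data, dtype=np.float32), (rows, cols)),
        shape=(len(vocab), len(vocab) + buckets))


def train_fasttext(
    pairs: np.ndarray,
    vocab: Vocab,
    noise: np.ndarray,
    dim: int,
    epochs: int,
    negative: int,
    lr: float,
    rng: np.random.Generator,
    buckets: int = 1 << 14,
    batch: int = 4096,
) -> np.ndarray:
    """SGNS where each input vector averages word + hashed n-gram rows."""
    comp = _composition_matrix(vocab, buckets)
    n_rows = len(vocab) + buckets
    w_sub = ((rng.random((n_rows, dim)) - 0.5) / dim).astype(np.float32)
    w_out = np.zeros((len(vocab), dim), dtype=np.float32)
    if len(pairs) == 0:
        return np.asarray(comp @ w_sub)
    cdf = np.cumsum(noise)
    n_batches = int(np.ceil(len(pairs) / batch))
    total = epochs * n_batches
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(pairs))
        for b in range(n_batches):
            sel = pairs[order[b * batch:(b + 1) * batch]]
            centres, positives = sel[:, 0], sel[:, 1]
            negatives = _sample_negatives(rng, cdf, (len(sel), negative))
            eta = _lr_schedule(step, total, lr)
            step += 1
            comp_batch = comp[centres]                    # (B, V+buckets) sparse
            v = np.asarray(comp_batch @ w_sub)            # composed inputs
            u_pos = w_out[positives]
            u_neg = w_out[negatives]
            g_pos = _sigmoid(np.einsum("bd,bd->b", v, u_pos)) - 1.0
            g_neg = _sigmoid(np.einsum("bkd,bd->bk", u_neg, v))
            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg)
            d = v.shape[1]
            out_idx = np.concatenate([positives, negatives.reshape(-1)])
            out_grads = np.concatenate([
                eta * g_pos[:, None] * v,
                eta * (g_neg[:, :, None] * v[:, None, :]).reshape(-1, d),
            ])
            _scatter_sub(w_out, out_idx, out_grads)
            update = np.asarray(comp_batch.T @ (eta * grad_v))
            norms = np.linalg.norm(update, axis=1, keepdims=True)
            np.divide(update * _MAX_ROW_UPDATE, norms, out=update,
                      where=norms > _MAX_ROW_UPDATE)
            w_sub -= update
    return np.asarray(comp @ w_sub)
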