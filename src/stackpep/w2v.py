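"""Seeded skip-gram k-mer embeddings.

Peptide sequences are tokenised into overlapping k-mers and a
skip-gram-with-negative-sampling embedding is trained over them, treating
each sequence as a sentence. With the default window of 40 — far longer
than typical peptides — every token in a sequence is context for every
other, so the embedding captures k-mer co-occurrence at the whole-peptide
scale. Training is single-threaded numpy and fully deterministic for a
given seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["W2VModel", "train_w2v", "encode_w2v", "tokenize"]


def tokenize(seq: str, k: int) -> list[str]:
    """Overlapping k-mer tokens of a sequence (L - k + 1 of them)."""
    return [seq[i:i + k] for i in range(len(seq) - k + 1)]


def _scatter_mean(param: np.ndarray, rows: np.ndarray,
                  grads: np.ndarray) -> None:
    """Add the mean of ``grads`` per distinct row index to ``param``."""
    uniq, inv, cnt = np.unique(rows, return_inverse=True, return_counts=True)
    acc = np.zeros((uniq.size, param.shape[1]))
    np.add.at(acc, inv, grads)
    param[uniq] += acc / cnt[:, None]


@dataclass
class W2VModel:
    """Trained k-mer embedding: token -> dim-vector lookup."""

    k: int
    dim: int
    vocab: dict[str, int]
    vectors: np.ndarray  # |vocab| x dim input embeddings

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[self.vocab[token]]

    def __contains__(self, token: str) -> bool:
        return token in self.vocab


def train_w2v(corpus, k: int, dim: int = 128, window: int = 40,
              epochs: int = 100, sg: int = 1, seed: int = 0,
              negatives: int = 5, lr: float = 0.025,
              batch_size: int = 1024) -> W2VModel:
    """Train a skip-gram embedding over k-mer tokens.

    Only the skip-gram objective (``sg=1``) is implemented; negative
    sampling draws from the unigram^(3/4) token distribution. The learning
    rate decays linearly to 1e-4 over training. Deterministic per seed.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty corpus")
    if not 1 <= k <= 4:
        raise ValueError("k must be in 1..4")
    if sg != 1:
        raise NotImplementedError("only skip-gram (sg=1) is implemented")

    sentences = [tokenize(s, k) for s in corpus if len(s) >= k]
    if not sentences:
        raise ValueError(f"no sequence of length >= k={k} in corpus")
    vocab: dict[str, int] = {}
    counts: list[int] = []
    for sent in sentences:
        for tok in sent:
            if tok not in vocab:
                vocab[tok] = len(vocab)
                counts.append(0)
            counts[vocab[tok]] += 1

    rng = np.random.default_rng(seed)
    n_vocab = len(vocab)
    # standard word2vec init: uniform input vectors, zero output vectors
    vin = (rng.random((n_vocab, dim)) - 0.5) / dim
    vout = np.zeros((n_vocab, dim))

    centers, contexts = [], []
    for sent in sentences:
        idx = [vocab[t] for t in sent]
        for i, c in enumerate(idx):
            lo, hi = max(0, i - window), min(len(idx), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(idx[j])
    centers = np.asarray(centers, dtype=np.intp)
    contexts = np.asarray(contexts, dtype=np.intp)
    if centers.size == 0:  # all single-token sentences: nothing to train on
        return W2VModel(k, dim, vocab, vin)

    noise = np.asarray(counts, dtype=float) ** 0.75
    noise /= noise.sum()
    n_pairs = centers.size
    total_steps = epochs * n_pairs
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            sel = order[start:start + batch_size]
            b = sel.size
            alpha = max(lr * (1 - step / total_steps), 1e-4)
            step += b
            c, o = centers[sel], contexts[sel]
            neg = rng.choice(n_vocab, size=(b, negatives), p=noise)
            vc = vin[c]                                   # b x d
            targets = np.concatenate([o[:, None], neg], axis=1)  # b x (1+neg)
            ut = vout[targets]                            # b x (1+neg) x d
            score = np.einsum("bd,bnd->bn", vc, ut)
            sig = 1.0 / (1.0 + np.exp(-np.clip(score, -30, 30)))
            label = np.zeros_like(sig)
            label[:, 0] = 1.0
            g = alpha * (label - sig)                     # b x (1+neg)
            grad_vc = np.einsum("bn,bnd->bd", g, ut)
            grad_ut = g[..., None] * vc[:, None, :]
            # average (not sum) gradients hitting the same row within a
            # batch: with small vocabularies summed stale-parameter updates
            # overshoot and diverge
            _scatter_mean(vout, targets.ravel(),
                          grad_ut.reshape(-1, dim))
            _scatter_mean(vin, c, grad_vc)
    return W2VModel(k, dim, vocab, vin)


def encode_w2v(seq: str, model: W2VModel, k: int | None = None) -> np.ndarray:
    """Mean of token vectors over the sequence's overlapping k-mers.

    Out-of-vocabulary k-mers are skipped; if every k-mer is unseen the
    zero vector is returned with a warning.
    """
    import warnings

    k = model.k if k is None else k
    toks = [t for t in tokenize(seq, k) if t in model]
    if not toks:
        warnings.warn(f"all {k}-mers out of vocabulary; zero vector",
                      stacklevel=2)
        return np.zeros(model.dim)
    return np.mean([model[t] for t in toks], axis=0)
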