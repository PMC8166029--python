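"""Skip-gram word embeddings with negative sampling, trained from scratch.

For each (center, context) pair within a sampled window the objective is

    log sigma(u_ctx . v_cen) + sum_{i=1..k} log sigma(-u_neg_i . v_cen),

negatives drawn from the unigram distribution raised to 3/4. Training is
plain SGD with a linearly decaying learning rate, per-pair updates in corpus
order, and the usual frequent-word subsampling; with a fixed seed the run is
bit-reproducible. The inner loop is compiled with numba;
:func:`sgns_pair_loss_grad` is the plain-numpy per-pair loss/gradient kept
as the analytic reference for finite-difference checks.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from numba import njit
from scipy.special import expit

__all__ = ["SkipGramParams", "EmbeddingModel", "train_skipgram", "sgns_pair_loss_grad"]


@dataclass(frozen=True)
class SkipGramParams:
    """Training hyperparameters.

    Embedding size 100 and seed 0 follow common reporting for this kind of
    corpus; window/epochs/negative/min_count/subsample/learning-rate follow
    standard word2vec conventions. ``workers`` is recorded for provenance
    but training always runs sequentially, so results are reproducible for
    any value (asynchronous multi-worker updates are deliberately not
    implemented).
    """

    dim: int = 100
    seed: int = 0
    workers: int = 1
    window: int = 5
    epochs: int = 5
    negative: int = 5
    start_lr: float = 0.025
    end_lr: float = 1e-4
    min_count: int = 1
    subsample_t: float = 1e-3

    def validate(self) -> None:
        if self.dim <= 0:
            raise ValueError(f"dim must be > 0, got {self.dim}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.negative < 1:
            raise ValueError(f"negative must be >= 1, got {self.negative}")
        if not (self.start_lr > self.end_lr > 0):
            raise ValueError(
                f"require start_lr > end_lr > 0, got {self.start_lr}, {self.end_lr}"
            )
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.workers < 1:
            raise ValueError(f"workers must be >= 1, got {self.workers}")


@dataclass
class EmbeddingModel:
    """Trained vocabulary with input (center) and output (context) vectors."""

    vocabulary: list[str]
    input_vectors: np.ndarray
    output_vectors: np.ndarray
    params: SkipGramParams | None = None
    epoch_losses: list[float] | None = None

    def __post_init__(self) -> None:
        if self.input_vectors.shape[0] != len(self.vocabulary):
            raise ValueError("input_vectors row count != vocabulary size")
        if self.output_vectors.shape != self.input_vectors.shape:
            raise ValueError("output_vectors shape != input_vectors shape")
        if not np.isfinite(self.input_vectors).all() or not np.isfinite(
            self.output_vectors
        ).all():
            raise ValueError("non-finite entries in embedding vectors")
        self._index = {t: i for i, t in enumerate(self.vocabulary)}

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.input_vectors[self._index[token]]
        except KeyError:
            raise KeyError(f"token not in vocabulary: {token!r}") from None

    def save(self, vectors_path: str | Path, meta_path: str | Path) -> None:
        """TSV of token + input-vector floats, plus JSON metadata."""
        with open(vectors_path, "w", encoding="utf-8") as fh:
            for tok, row in zip(self.vocabulary, self.input_vectors):
                fh.write(tok + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
        meta = {
            "params": asdict(self.params) if self.params else None,
            "vocabulary_size": len(self.vocabulary),
            "epoch_losses": self.epoch_losses,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, vectors_path: str | Path, meta_path: str | Path | None = None) -> "EmbeddingModel":
        vocab: list[str] = []
        rows: list[list[float]] = []
        for line in Path(vectors_path).read_text(encoding="utf-8").splitlines():
            parts = line.split("\t")
            vocab.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        vecs = np.asarray(rows, dtype=np.float64)
        params = None
        if meta_path is not None:
            meta = json.loads(Path(meta_path).read_text(encoding="utf-8"))
            if meta.get("params"):
                params = SkipGramParams(**meta["params"])
        return cls(vocabulary=vocab, input_vectors=vecs,
                   output_vectors=np.zeros_like(vecs), params=params)


def sgns_pair_loss_grad(
    center: np.ndarray, context: np.ndarray, negatives: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss and analytic gradients for one (center, context, negatives) triple.

    loss = -log sigma(u_ctx.v) - sum_i log sigma(-u_neg_i.v). Returns
    (loss, d/d_center, d/d_context, d/d_negatives).
    """
    center = np.asarray(center, dtype=float)
    context = np.asarray(context, dtype=float)
    negatives = np.atleast_2d(np.asarray(negatives, dtype=float))

    s_pos = float(context @ center)
    s_neg = negatives @ center
    # -log sigma(x) = log(1 + exp(-x)), computed stably
    loss = float(np.logaddexp(0.0, -s_pos) + np.logaddexp(0.0, s_neg).sum())

    g_pos = expit(s_pos) - 1.0          # d loss / d s_pos
    g_neg = expit(s_neg)                # d loss / d s_neg_i
    grad_center = g_pos * context + g_neg @ negatives
    grad_context = g_pos * center
    grad_negatives = g_neg[:, None] * center[None, :]
    return loss, grad_center, grad_context, grad_negatives


@njit(cache=True)
def _train_kernel(data, offsets, w_in, w_out, keep_prob, neg_cdf,
                  window, k, epochs, lr_start, lr_end, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    d = w_in.shape[1]
    n_sent = offsets.shape[0] - 1
    total = data.shape[0] * epochs
    processed = 0
    losses = np.zeros(epochs)
    kept = np.empty(data.shape[0], dtype=np.int64)
    neu1e = np.empty(d)
    for epoch in range(epochs):
        loss = 0.0
        n_pairs = 0
        for s in range(n_sent):
            m = 0
            for idx in range(offsets[s], offsets[s + 1]):
                w = data[idx]
                processed += 1
                if keep_prob[w] >= 1.0 or np.random.random() < keep_prob[w]:
                    kept[m] = w
                    m += 1
            for i in range(m):
                c = kept[i]
                lr = lr_start - (lr_start - lr_end) * (processed / total)
                if lr < lr_end:
                    lr = lr_end
                b = np.random.randint(1, window + 1)
                lo = i - b if i - b > 0 else 0
                hi = i + b + 1 if i + b + 1 < m else m
                for j in range(lo, hi):
                    if j == i:
                        continue
                    ctx = kept[j]
                    for q in range(d):
                        neu1e[q] = 0.0
                    for neg in range(k + 1):
                        if neg == 0:
                            target = ctx
                            label = 1.0
                        else:
                            target = np.searchsorted(neg_cdf, np.random.random())
                            if target == ctx:
                                continue
                            label = 0.0
                        f = 0.0
                        for q in range(d):
                            f += w_in[c, q] * w_out[target, q]
                        if f > 30.0:
                            sig = 1.0
                        elif f < -30.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + np.exp(-f))
                        p = sig if label == 1.0 else 1.0 - sig
                        if p < 1e-12:
                            p = 1e-12
                        loss += -np.log(p)
                        g = (label - sig) * lr
                        for q in range(d):
                            neu1e[q] += g * w_out[target, q]
                            w_out[target, q] += g * w_in[c, q]
                    n_pairs += 1
                    for q in range(d):
                        w_in[c, q] += neu1e[q]
        losses[epoch] = loss / n_pairs if n_pairs > 0 else 0.0
    return losses


def _build_vocab(documents: list[list[str]], min_count: int) -> tuple[list[str], np.ndarray]:
    counts = Counter(tok for doc in documents for tok in doc)
    items = [(t, c) for t, c in counts.items() if c >= min_count]
    items.sort(key=lambda tc: (-tc[1], tc[0]))
    vocab = [t for t, _ in items]
    return vocab, np.asarray([c for _, c in items], dtype=np.float64)


def train_skipgram(corpus, params: SkipGramParams = SkipGramParams()) -> EmbeddingModel:
    """Train an embedding model on a tokenized corpus.

    ``corpus`` is a list of token lists or any object with a ``documents``
    attribute (e.g. :class:`~zjscreen.syndata.TokenizedCorpus`).
    """
    params.validate()
    documents = getattr(corpus, "documents", corpus)
    if not documents:
        raise ValueError("corpus is empty")

    vocab, counts = _build_vocab(documents, params.min_count)
    if not vocab:
        raise ValueError(
            f"vocabulary is empty after min_count={params.min_count} filtering"
        )
    index = {t: i for i, t in enumerate(vocab)}

    flat: list[int] = []
    offsets = [0]
    for doc in documents:
        flat.extend(index[t] for t in doc if t in index)
        offsets.append(len(flat))
    data = np.asarray(flat, dtype=np.int64)
    offs = np.asarray(offsets, dtype=np.int64)

    total = counts.sum()
    if params.subsample_t > 0:
        z = counts / total
        keep = (np.sqrt(z / params.subsample_t) + 1) * (params.subsample_t / z)
        keep_prob = np.minimum(keep, 1.0)
    else:
        keep_prob = np.ones_like(counts)

    pow_counts = counts**0.75
    neg_cdf = np.cumsum(pow_counts) / pow_counts.sum()
    neg_cdf[-1] = 1.0

    rng = np.random.default_rng(params.seed)
    w_in = (rng.random((len(vocab), params.dim)) - 0.5) / params.dim
    w_out = np.zeros((len(vocab), params.dim))

    losses = _train_kernel(
        data, offs, w_in, w_out, keep_prob, neg_cdf,
        params.window, params.negative, params.epochs,
        params.start_lr, params.end_lr, params.seed,
    )
    if not np.isfinite(losses).all():
        bad = int(np.flatnonzero(~np.isfinite(losses))[0])
        raise FloatingPointError(
            f"non-finite training loss at epoch {bad}: losses={losses.tolist()}"
        )
    return EmbeddingModel(
        vocabulary=vocab,
        input_vectors=w_in,
        output_vectors=w_out,
        params=params,
        epoch_losses=[float(x) for x in losses],
    )
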