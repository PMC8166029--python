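"""Cosine-similarity association ranking and bidirectional validation.

Associations between query terms (disease/symptom names) and candidate
terms (formula names) are scored by the cosine of their embedding vectors;
a bidirectional check then asks whether top-ranked formulae point back to
the querying symptom when the retrieval direction is reversed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skipgram import EmbeddingModel

__all__ = [
    "cosine",
    "RankedAssociation",
    "rank_associations",
    "aggregate_ranking",
    "bidirectional_validate",
    "embed_2d",
]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); raises on zero-norm input rather than returning 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


@dataclass(frozen=True)
class RankedAssociation:
    query: str
    candidate: str
    score: float
    rank: int  # 1-based


def _check_vocabulary(model: EmbeddingModel, tokens: list[str]) -> None:
    missing = [t for t in tokens if t not in model]
    if missing:
        raise KeyError(f"tokens not in vocabulary: {missing}")


def _scores(model: EmbeddingModel, query: str, candidates: list[str]) -> list[tuple[str, float]]:
    qv = model.vector(query)
    scored = [(c, cosine(qv, model.vector(c))) for c in candidates]
    scored.sort(key=lambda cs: (-cs[1], cs[0]))  # ties broken lexicographically
    return scored


def rank_associations(
    model: EmbeddingModel,
    queries: list[str],
    candidates: list[str],
    k: int | None = None,
) -> list[RankedAssociation]:
    """Per-query candidate rankings by cosine, truncated to the top k."""
    _check_vocabulary(model, list(queries) + list(candidates))
    out: list[RankedAssociation] = []
    for q in queries:
        scored = _scores(model, q, list(candidates))
        if k is not None:
            scored = scored[:k]
        out.extend(
            RankedAssociation(query=q, candidate=c, score=s, rank=r + 1)
            for r, (c, s) in enumerate(scored)
        )
    return out


def aggregate_ranking(
    model: EmbeddingModel,
    queries: list[str],
    candidates: list[str],
    k: int | None = None,
    combine: str = "mean",
) -> list[RankedAssociation]:
    """Rank candidates by their cosine combined over several queries.

    ``combine`` is "mean" (default) or "max". The combined list mirrors how
    a candidate formula is scored against a panel of disease terms.
    """
    _check_vocabulary(model, list(queries) + list(candidates))
    if combine not in ("mean", "max"):
        raise ValueError(f"combine must be 'mean' or 'max', got {combine!r}")
    agg = np.mean if combine == "mean" else np.max
    scored = [
        (c, float(agg([cosine(model.vector(q), model.vector(c)) for q in queries])))
        for c in candidates
    ]
    scored.sort(key=lambda cs: (-cs[1], cs[0]))
    if k is not None:
        scored = scored[:k]
    label = "|".join(queries)
    return [
        RankedAssociation(query=label, candidate=c, score=s, rank=r + 1)
        for r, (c, s) in enumerate(scored)
    ]


def bidirectional_validate(
    model: EmbeddingModel,
    formulae: list[str],
    symptoms: list[str],
    k: int = 3,
) -> tuple[pd.DataFrame, float | None]:
    """Reverse-retrieval consistency of symptom->formula rankings.

    For every symptom, take its top-k formulae; for each such formula look
    up the rank of that symptom in the formula's own symptom ranking.
    Consistency is the fraction of (symptom, formula) pairs whose reverse
    rank is <= k; ``None`` when there are no pairs to check.
    """
    _check_vocabulary(model, list(formulae) + list(symptoms))
    rows = []
    for s in symptoms:
        forward = _scores(model, s, list(formulae))[:k]
        for fwd_rank, (f, score) in enumerate(forward, start=1):
            reverse = _scores(model, f, list(symptoms))
            rev_rank = next(i for i, (cand, _) in enumerate(reverse, start=1) if cand == s)
            rows.append(
                {
                    "symptom": s,
                    "formula": f,
                    "forward_rank": fwd_rank,
                    "cosine": score,
                    "reverse_rank": rev_rank,
                    "consistent": rev_rank <= k,
                }
            )
    table = pd.DataFrame(rows)
    consistency = float(table["consistent"].mean()) if len(table) else None
    return table, consistency


def embed_2d(model: EmbeddingModel, perplexity: float = 5.0, seed: int = 0) -> np.ndarray:
    """t-SNE layout of the input vectors, one (x, y) row per vocabulary token."""
    n = len(model.vocabulary)
    if n < 5:
        raise ValueError(f"need at least 5 tokens for a 2-D layout, got {n}")
    if perplexity >= n:
        raise ValueError(f"perplexity ({perplexity}) must be < number of points ({n})")
    from sklearn.manifold import TSNE

    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    )
    return tsne.fit_transform(model.input_vectors)
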