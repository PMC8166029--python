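"""Synthetic tokenized corpus with planted formula-symptom associations.

The generator emulates the statistical skeleton of a biomedical literature
corpus: every sentence mentions exactly one prescription formula; a symptom
token co-occurs with its planted partner formula with probability
``p_assoc`` and with any formula at the background rate ``p_bg``; the rest
of each sentence is filled with background vocabulary. Token identity
carries all semantics — the corpus is generated pre-tokenized, so
orthography and real segmentation are exercised separately (see
:mod:`zjscreen.textmine.segment`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["CorpusSpec", "TokenizedCorpus", "generate_corpus"]


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of the planted-association corpus.

    Defaults give a small desk-scale corpus: 10 formulae, 10 symptoms,
    30 background tokens, one planted pair, strong association (0.9) over a
    weak background rate (0.02), 2000 sentences of 12 tokens.
    """

    n_formulae: int = 10
    n_symptoms: int = 10
    n_filler: int = 30
    planted_pairs: tuple[tuple[int, int], ...] = ((0, 0),)
    p_assoc: float = 0.9
    p_bg: float = 0.02
    n_sentences: int = 2000
    sentence_len: int = 12
    topic_weight: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_formulae", "n_symptoms", "n_filler", "n_sentences",
                     "sentence_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not (0.0 <= self.p_bg < self.p_assoc <= 1.0):
            raise ValueError(
                f"require 0 <= p_bg < p_assoc <= 1, got p_bg={self.p_bg}, "
                f"p_assoc={self.p_assoc}"
            )
        for f, s in self.planted_pairs:
            if not (0 <= f < self.n_formulae):
                raise ValueError(f"planted_pairs: formula id {f} out of range")
            if not (0 <= s < self.n_symptoms):
                raise ValueError(f"planted_pairs: symptom id {s} out of range")
        if self.sentence_len < 3:
            raise ValueError("sentence_len must be >= 3 to hold formula + symptom")
        if not (0.0 <= self.topic_weight <= 1.0):
            raise ValueError(f"topic_weight must be in [0, 1], got {self.topic_weight}")


@dataclass
class TokenizedCorpus:
    """Documents as token sequences plus a category dictionary.

    ``dictionary`` maps each token to its category (formula / disease /
    other); ``planted_pairs`` records the ground-truth associated
    (formula token, symptom token) pairs.
    """

    documents: list[list[str]]
    dictionary: dict[str, str]
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def formulae(self) -> list[str]:
        return [t for t, c in self.dictionary.items() if c == "formula"]

    @property
    def symptoms(self) -> list[str]:
        return [t for t, c in self.dictionary.items() if c == "disease"]

    def save(self, corpus_path: str | Path, dict_path: str | Path) -> None:
        """Write one whitespace-joined document per line, plus a TSV dictionary."""
        Path(corpus_path).write_text(
            "\n".join(" ".join(doc) for doc in self.documents) + "\n",
            encoding="utf-8",
        )
        Path(dict_path).write_text(
            "".join(f"{t}\t{c}\n" for t, c in self.dictionary.items()),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, corpus_path: str | Path, dict_path: str | Path) -> "TokenizedCorpus":
        docs = [
            line.split()
            for line in Path(corpus_path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        dictionary: dict[str, str] = {}
        for line in Path(dict_path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            phrase, category = line.split("\t")
            dictionary[phrase] = category
        return cls(documents=docs, dictionary=dictionary)


def _token_names(spec: CorpusSpec) -> tuple[list[str], list[str], list[str]]:
    formulae = [f"formula_{i:02d}" for i in range(spec.n_formulae)]
    symptoms = [f"symptom_{i:02d}" for i in range(spec.n_symptoms)]
    filler = [f"filler_{i:02d}" for i in range(spec.n_filler)]
    return formulae, symptoms, filler


def generate_corpus(spec: CorpusSpec) -> TokenizedCorpus:
    """Generate a corpus with planted formula-symptom co-occurrences.

    Every sentence contains exactly one formula token at a random position.
    For a planted pair (f, s), sentences whose formula is f additionally
    contain s with probability ``p_assoc``; every other (formula, symptom)
    combination co-occurs at the background rate ``p_bg``.

    Background slots mix a shared filler vocabulary with a formula-specific
    topic: each background slot draws from the formula's own filler subset
    with probability ``topic_weight`` and uniformly from all fillers
    otherwise. This emulates the topical structure of real literature (texts
    about a prescription share vocabulary about its indication domain) and
    is what gives distributional word embeddings second-order signal beyond
    raw co-occurrence counts.
    """
    spec.validate()
    formulae, symptoms, filler = _token_names(spec)
    planted_by_formula: dict[int, list[int]] = {}
    for f, s in spec.planted_pairs:
        planted_by_formula.setdefault(f, []).append(s)
    # formula f's topic: fillers with index = f (mod n_formulae)
    topics = [
        [j for j in range(spec.n_filler) if j % spec.n_formulae == f]
        for f in range(spec.n_formulae)
    ]

    rng = np.random.default_rng(spec.seed)
    documents: list[list[str]] = []
    for _ in range(spec.n_sentences):
        f_id = int(rng.integers(0, spec.n_formulae))
        topic = topics[f_id]
        sent = []
        for _slot in range(spec.sentence_len):
            if topic and rng.random() < spec.topic_weight:
                sent.append(filler[topic[rng.integers(0, len(topic))]])
            else:
                sent.append(filler[rng.integers(0, spec.n_filler)])
        include: list[str] = []
        planted = set(planted_by_formula.get(f_id, []))
        for s_id in planted:
            if rng.random() < spec.p_assoc:
                include.append(symptoms[s_id])
        for s_id in range(spec.n_symptoms):
            if s_id in planted:
                continue
            if rng.random() < spec.p_bg:
                include.append(symptoms[s_id])
        # formula plus included symptoms overwrite distinct random slots
        n_special = 1 + len(include)
        if n_special > spec.sentence_len:
            include = include[: spec.sentence_len - 1]
            n_special = spec.sentence_len
        slots = rng.choice(spec.sentence_len, size=n_special, replace=False)
        sent[slots[0]] = formulae[f_id]
        for slot, tok in zip(slots[1:], include):
            sent[slot] = tok
        documents.append(sent)

    dictionary = (
        {t: "formula" for t in formulae}
        | {t: "disease" for t in symptoms}
        | {t: "other" for t in filler}
    )
    pairs = [(formulae[f], symptoms[s]) for f, s in spec.planted_pairs]
    return TokenizedCorpus(documents=documents, dictionary=dictionary,
                           planted_pairs=pairs)
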