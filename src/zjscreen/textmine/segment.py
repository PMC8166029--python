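"""Dictionary-based segmentation and category word frequencies.

Segmentation uses forward maximum matching: scanning left to right, the
longest dictionary phrase starting at the current position is consumed as
one token; characters matching no phrase become single-character tokens.
The scheme is lossless — concatenating the tokens reproduces the input —
which keeps frequency counts auditable against the raw text.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

CATEGORIES = ("formula", "herb", "syndrome", "disease", "other")

__all__ = ["CATEGORIES", "PhraseDictionary", "segment", "frequencies", "top_k"]


@dataclass
class PhraseDictionary:
    """Phrase -> category map (categories: formula, herb, syndrome, disease, other)."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for phrase, category in self.entries.items():
            if not phrase:
                raise ValueError("empty phrase in dictionary")
            if category not in CATEGORIES:
                raise ValueError(
                    f"unknown category {category!r} for phrase {phrase!r}; "
                    f"expected one of {CATEGORIES}"
                )

    @property
    def max_len(self) -> int:
        return max((len(p) for p in self.entries), default=0)

    def phrases_of(self, category: str) -> set[str]:
        if category == "all":
            return set(self.entries)
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return {p for p, c in self.entries.items() if c == category}

    @classmethod
    def load(cls, path: str | Path) -> "PhraseDictionary":
        entries: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            phrase, category = line.split("\t")
            entries[phrase] = category
        return cls(entries=entries)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{p}\t{c}\n" for p, c in self.entries.items()), encoding="utf-8"
        )


def segment(text: str, dictionary: PhraseDictionary) -> list[str]:
    """Forward-maximum-matching tokenization; total on any string."""
    tokens: list[str] = []
    n = len(text)
    max_len = dictionary.max_len
    i = 0
    while i < n:
        match = None
        for length in range(min(max_len, n - i), 0, -1):
            cand = text[i : i + length]
            if cand in dictionary.entries:
                match = cand
                break
        if match is None:
            match = text[i]
        tokens.append(match)
        i += len(match)
    return tokens


def frequencies(
    documents: list[list[str]],
    dictionary: PhraseDictionary,
    category: str = "all",
) -> dict[str, int]:
    """Occurrence counts of dictionary phrases of one category (or "all")."""
    wanted = dictionary.phrases_of(category)
    counts: Counter[str] = Counter()
    for doc in documents:
        for tok in doc:
            if tok in wanted:
                counts[tok] += 1
    return dict(counts)


def top_k(table: dict[str, int], k: int = 100) -> list[tuple[str, int]]:
    """Most frequent entries, count descending then token ascending."""
    return sorted(table.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
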