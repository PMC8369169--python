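"""Lexicon-driven word segmentation and word-character alignment.

Segmentation here feeds only the representation side (which word's
semantics get fused into each character); tags remain character-level.
The segmenter is greedy forward maximum matching: at each position take
the longest lexicon word starting there, else a singleton character.
Deterministic, dependency-free, and exact on the synthetic corpus whose
lexicon contains every gold entity surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class Lexicon:
    """A set of known words; ``max_len`` bounds the matcher's lookahead."""

    words: frozenset[str]

    def __post_init__(self) -> None:
        if any(not w for w in self.words):
            raise ValueError("lexicon words must be non-empty")

    @property
    def max_len(self) -> int:
        return max((len(w) for w in self.words), default=0)

    @classmethod
    def from_words(cls, words: Iterable[str]) -> "Lexicon":
        return cls(frozenset(words))

    @classmethod
    def from_file(cls, path: str | Path) -> "Lexicon":
        words = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                w = line.rstrip("\n")
                if w:
                    words.append(w)
        return cls.from_words(words)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for w in sorted(self.words):
                fh.write(w + "\n")

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class Segmentation:
    """A partition of a character sequence into word spans."""

    spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pos = 0
        for s, e in self.spans:
            if s != pos or e <= s:
                raise ValueError(
                    f"spans must partition the sequence; bad span ({s}, {e}) "
                    f"at position {pos}"
                )
            pos = e

    @property
    def n_chars(self) -> int:
        return self.spans[-1][1] if self.spans else 0

    @property
    def word_of_char(self) -> list[int]:
        return broadcast_word_ids(self)

    def surfaces(self, chars: str) -> list[str]:
        return [chars[s:e] for s, e in self.spans]


def segment(chars: str, lexicon: Lexicon) -> Segmentation:
    """Greedy forward maximum matching over ``lexicon``.

    Total: an empty lexicon yields all singleton spans.  Longest match
    wins; matching proceeds left to right so the tie-break is
    leftmost-first by construction.
    """
    spans: list[tuple[int, int]] = []
    n = len(chars)
    i = 0
    cap = lexicon.max_len
    while i < n:
        match_end = i + 1
        for length in range(min(cap, n - i), 1, -1):
            if chars[i : i + length] in lexicon:
                match_end = i + length
                break
        spans.append((i, match_end))
        i = match_end
    return Segmentation(tuple(spans))


def broadcast_word_ids(seg: Segmentation) -> list[int]:
    """Per-character word index: constant within a span, non-decreasing."""
    out: list[int] = []
    for w, (s, e) in enumerate(seg.spans):
        out.extend([w] * (e - s))
    return out
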