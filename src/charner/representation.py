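"""Word-semantics-integrated character representations.

Character-level tagging keeps long clinical phrases intact, but raw
character embeddings carry no word/phrase semantics.  This module fuses
the two: for each word span produced by the segmenter, an attention
weight is computed for every character of the word from a bilinear score

    s_i = R_word · W_attn · R_char_i + b_attn,      e = softmax(s),

where ``R_word = E_word[x_word] · W_word`` and
``R_char_i = E_char[x_char_i] · W_character``.  Each character's fused
vector is its gated concatenation ``e_i · [R_char_i, R_word]`` — one
vector per character, as character-level tagging requires.  A literal
"collapse" variant that sums the gated vectors over the word (yielding
one vector per word, broadcast back) is available behind a flag for
comparison.

The multihead variant replaces the bilinear score with standard
scaled-dot-product multihead attention restricted to each word's span:
the word representation is the query, the word's character
representations are keys and values; the attended output is concatenated
with the character's own representation.

Both variants expose the same (sample, segmentation, parameters) ->
FusedSequence signature, so a downstream tagger can consume either — or
plain character embeddings — interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .schema import LabeledSample
from .segmentation import Segmentation

#: Reserved vocabulary ids.
UNK_ID = 0
PAD_ID = 1
N_RESERVED = 2


class Vocabulary:
    """Token -> id mapping with reserved UNK (0) and PAD (1) slots."""

    def __init__(self, tokens: Iterable[str] = ()) -> None:
        self._ids: dict[str, int] = {}
        for t in tokens:
            self.add(t)

    def add(self, token: str) -> int:
        if token not in self._ids:
            self._ids[token] = N_RESERVED + len(self._ids)
        return self._ids[token]

    def id(self, token: str) -> int:
        return self._ids.get(token, UNK_ID)

    @property
    def size(self) -> int:
        """Table size including the reserved slots."""
        return N_RESERVED + len(self._ids)

    def tokens(self) -> list[str]:
        return list(self._ids)

    def to_dict(self) -> dict[str, int]:
        return dict(self._ids)

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "Vocabulary":
        v = cls()
        for tok, i in sorted(d.items(), key=lambda kv: kv[1]):
            got = v.add(tok)
            if got != i:
                raise ValueError(f"non-contiguous vocabulary ids at {tok!r}")
        return v


@dataclass
class FusionParameters:
    """Embedding tables and attention parameters of the fusion module.

    ``char_embedding``: (V_c, d_c); ``word_embedding``: (V_w, d_w);
    ``W_word``: (d_w, d_w); ``W_character``: (d_c, d_c);
    ``W_attn``: (d_w, d_c); ``b_attn``: scalar.  The multihead variant
    projects words (queries) and characters (keys/values) to a shared
    ``d_model`` divisible by ``n_heads``.
    """

    char_embedding: np.ndarray
    word_embedding: np.ndarray
    W_word: np.ndarray
    W_character: np.ndarray
    W_attn: np.ndarray
    b_attn: float
    char_vocab: Vocabulary
    word_vocab: Vocabulary
    n_heads: int = 1
    W_q: Optional[np.ndarray] = None
    W_k: Optional[np.ndarray] = None
    W_v: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        d_c = self.char_embedding.shape[1]
        d_w = self.word_embedding.shape[1]
        if self.W_word.shape != (d_w, d_w):
            raise ValueError(f"W_word shape {self.W_word.shape}, expected {(d_w, d_w)}")
        if self.W_character.shape != (d_c, d_c):
            raise ValueError(
                f"W_character shape {self.W_character.shape}, expected {(d_c, d_c)}"
            )
        if self.W_attn.shape != (d_w, d_c):
            raise ValueError(f"W_attn shape {self.W_attn.shape}, expected {(d_w, d_c)}")
        if self.W_q is not None:
            d_model = self.W_q.shape[1]
            if d_model % self.n_heads != 0:
                raise ValueError(
                    f"model dimension {d_model} not divisible by {self.n_heads} heads"
                )

    @property
    def d_char(self) -> int:
        return self.char_embedding.shape[1]

    @property
    def d_word(self) -> int:
        return self.word_embedding.shape[1]

    @property
    def d_model(self) -> int:
        if self.W_q is None:
            raise ValueError("multihead projections not initialized")
        return self.W_q.shape[1]

    @classmethod
    def init(
        cls,
        char_vocab: Vocabulary,
        word_vocab: Vocabulary,
        d_char: int = 16,
        d_word: int = 16,
        n_heads: int = 1,
        d_model: Optional[int] = None,
        seed: int = 0,
    ) -> "FusionParameters":
        """Uniform(-0.1, 0.1) initialization with an explicit seed."""
        rng = np.random.default_rng(seed)

        def u(*shape: int) -> np.ndarray:
            return rng.uniform(-0.1, 0.1, size=shape)

        if d_model is None:
            d_model = d_char
        if d_model % n_heads != 0:
            raise ValueError(f"model dimension {d_model} not divisible by {n_heads} heads")
        return cls(
            char_embedding=u(char_vocab.size, d_char),
            word_embedding=u(word_vocab.size, d_word),
            W_word=u(d_word, d_word),
            W_character=u(d_char, d_char),
            W_attn=u(d_word, d_char),
            b_attn=float(rng.uniform(-0.1, 0.1)),
            char_vocab=char_vocab,
            word_vocab=word_vocab,
            n_heads=n_heads,
            W_q=u(d_word, d_model),
            W_k=u(d_char, d_model),
            W_v=u(d_char, d_model),
            seed=seed,
        )


@dataclass
class FusedSequence:
    """Per-character fused vectors and the attention weight of each
    character within its word span (positive; sums to 1 per span)."""

    vectors: np.ndarray  # (L, d_out)
    attention: np.ndarray  # (L,)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def attention_weights(
    word_vec: np.ndarray,
    char_vecs: np.ndarray,
    W_attn: np.ndarray,
    b_attn: float,
) -> np.ndarray:
    """Softmax over bilinear scores word·W_attn·char_i + b for one word.

    ``char_vecs`` is (l, d_c) with l >= 1; returns l positive weights
    summing to 1 — the importance of each character within the word.
    """
    word_vec = np.asarray(word_vec, dtype=float)
    char_vecs = np.atleast_2d(np.asarray(char_vecs, dtype=float))
    if word_vec.ndim != 1:
        raise ValueError(f"word_vec must be 1-D, got shape {word_vec.shape}")
    if char_vecs.shape[0] < 1:
        raise ValueError("need at least one character vector")
    d_w, d_c = W_attn.shape
    if word_vec.shape[0] != d_w or char_vecs.shape[1] != d_c:
        raise ValueError(
            f"dimension mismatch: word {word_vec.shape}, chars {char_vecs.shape}, "
            f"W_attn {W_attn.shape}"
        )
    scores = word_vec @ W_attn @ char_vecs.T + b_attn
    return softmax(scores)


def _lookup(sample: LabeledSample, seg: Segmentation, params: FusionParameters):
    """Map a segmented sample to (R_char (L,d_c), per-word R_word rows)."""
    if seg.n_chars != len(sample.chars):
        raise ValueError(
            f"segmentation covers {seg.n_chars} characters, sample has "
            f"{len(sample.chars)}"
        )
    char_ids = np.array([params.char_vocab.id(c) for c in sample.chars], dtype=int)
    word_ids = np.array(
        [params.word_vocab.id(sample.chars[s:e]) for s, e in seg.spans], dtype=int
    )
    r_char = params.char_embedding[char_ids] @ params.W_character  # (L, d_c)
    r_word = params.word_embedding[word_ids] @ params.W_word  # (n_words, d_w)
    return r_char, r_word


def fuse_bilinear(
    sample: LabeledSample,
    seg: Segmentation,
    params: FusionParameters,
    collapse: bool = False,
) -> FusedSequence:
    """Bilinear-attention fusion; one (d_c + d_w) vector per character.

    With ``collapse=True`` the gated vectors are summed over each word
    span and the sum broadcast to every character of the word (the
    word-collapsing reading; reduces to the default for length-1 words).

    Unknown characters/words map to the reserved UNK embedding.
    """
    r_char, r_word = _lookup(sample, seg, params)
    L = len(sample.chars)
    out = np.empty((L, params.d_char + params.d_word))
    attn = np.empty(L)
    for w, (s, e) in enumerate(seg.spans):
        weights = attention_weights(r_word[w], r_char[s:e], params.W_attn, params.b_attn)
        attn[s:e] = weights
        gated = weights[:, None] * np.concatenate(
            [r_char[s:e], np.tile(r_word[w], (e - s, 1))], axis=1
        )
        out[s:e] = gated.sum(axis=0) if collapse else gated
    return FusedSequence(vectors=out, attention=attn)


def fuse_multihead(
    sample: LabeledSample,
    seg: Segmentation,
    params: FusionParameters,
) -> FusedSequence:
    """Multihead self-attention fusion, masked to each word's span.

    Per word: query = projected word representation; keys/values =
    projected character representations of that word.  Scores use the
    standard 1/sqrt(d_k) scaling.  Each character's output is the
    attended value vector concatenated after its own (projected)
    character representation; the reported per-character attention is the
    head-averaged weight, which sums to 1 within every span.
    """
    if params.W_q is None or params.W_k is None or params.W_v is None:
        raise ValueError("multihead projections not initialized")
    d_model, H = params.d_model, params.n_heads
    if d_model % H != 0:
        raise ValueError(f"model dimension {d_model} not divisible by {H} heads")
    d_k = d_model // H
    r_char, r_word = _lookup(sample, seg, params)
    L = len(sample.chars)
    out = np.empty((L, params.d_char + d_model))
    attn = np.empty(L)
    for w, (s, e) in enumerate(seg.spans):
        l = e - s
        q = (r_word[w] @ params.W_q).reshape(H, d_k)  # (H, d_k)
        k = (r_char[s:e] @ params.W_k).reshape(l, H, d_k)
        v = (r_char[s:e] @ params.W_v).reshape(l, H, d_k)
        scores = np.einsum("hd,lhd->hl", q, k) / np.sqrt(d_k)  # (H, l)
        weights = softmax(scores, axis=-1)
        o = np.einsum("hl,lhd->hd", weights, v).reshape(d_model)
        out[s:e, : params.d_char] = r_char[s:e]
        out[s:e, params.d_char :] = o
        attn[s:e] = weights.mean(axis=0)
    return FusedSequence(vectors=out, attention=attn)
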