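"""Character-level sequence tagger: (fusion) -> encoder -> CRF/softmax.

The model embeds each character, optionally fuses word semantics into
the character vectors (bilinear or multihead word-character attention),
runs an identity/LSTM/BiLSTM encoder, projects to per-tag emission
scores, and trains either a linear-chain CRF (exact NLL) or a
per-position softmax head.  All gradients are derived by hand and
checked against finite differences in the test suite.

Training is exactly reproducible: one master seed fans out (via numpy
``SeedSequence``) to parameter initialization, shuffling and dropout,
and is recorded in the checkpoint sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import crf as crf_mod
from . import nn
from .crf import CrfParameters, apply_mask
from .representation import (
    PAD_ID,
    FusionParameters,
    Vocabulary,
    softmax,
)
from .schema import DEFAULT_SCHEMA, LabeledSample, TagSchema, decode_tags
from .segmentation import Lexicon, Segmentation, segment

FUSION_VARIANTS = ("none", "bilinear", "multihead")
ENCODER_KINDS = ("identity", "lstm", "bilstm")
HEADS = ("crf", "softmax")


@dataclass
class EncoderConfig:
    """Sequence encoder over the (fused) character vectors."""

    kind: str = "bilstm"
    hidden_dim: int = 32
    n_layers: int = 1
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ENCODER_KINDS:
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def bidirectional(self) -> bool:
        return self.kind == "bilstm"


@dataclass
class ModelConfig:
    fusion: str = "none"
    head: str = "crf"
    d_char: int = 16
    d_word: int = 16
    d_model: int = 16  # multihead projection dim
    n_heads: int = 2
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self) -> None:
        if self.fusion not in FUSION_VARIANTS:
            raise ValueError(f"unknown fusion variant {self.fusion!r}")
        if self.head not in HEADS:
            raise ValueError(f"unknown head {self.head!r}")
        if self.fusion == "multihead" and self.d_model % self.n_heads != 0:
            raise ValueError(
                f"model dimension {self.d_model} not divisible by {self.n_heads} heads"
            )

    @property
    def encoder_input_dim(self) -> int:
        if self.fusion == "none":
            return self.d_char
        if self.fusion == "bilinear":
            return self.d_char + self.d_word
        return self.d_char + self.d_model

    @property
    def encoder_output_dim(self) -> int:
        if self.encoder.kind == "identity":
            return self.encoder_input_dim
        return self.encoder.hidden_dim * (2 if self.encoder.bidirectional else 1)


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0
    shuffle: bool = True


class Tagger:
    """A trainable character-level tagger; see the module docstring."""

    def __init__(
        self,
        config: ModelConfig,
        char_vocab: Vocabulary,
        word_vocab: Vocabulary,
        params: dict[str, np.ndarray],
        lexicon: Lexicon,
        schema: TagSchema = DEFAULT_SCHEMA,
        seed: int = 0,
    ) -> None:
        self.config = config
        self.char_vocab = char_vocab
        self.word_vocab = word_vocab
        self.params = params
        self.lexicon = lexicon
        self.schema = schema
        self.seed = seed
        self.history: list[dict] = []

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def build(
        cls,
        corpus: Sequence[LabeledSample],
        lexicon: Lexicon,
        config: ModelConfig,
        seed: int = 0,
        schema: TagSchema = DEFAULT_SCHEMA,
    ) -> "Tagger":
        if not corpus:
            raise ValueError("cannot build a tagger from an empty corpus")
        for k, sample in enumerate(corpus):
            for t in sample.tags:
                if t not in schema.index_of:
                    raise ValueError(f"sample {k} has tag {t!r} outside the schema")
        char_vocab = Vocabulary()
        for sample in corpus:
            for ch in sample.chars:
                char_vocab.add(ch)
        word_vocab = Vocabulary(sorted(lexicon.words))
        ss = np.random.SeedSequence(seed)
        init_rng = np.random.default_rng(ss.spawn(1)[0])
        params = cls._init_params(config, char_vocab, word_vocab, schema, init_rng)
        return cls(config, char_vocab, word_vocab, params, lexicon, schema, seed)

    @staticmethod
    def _init_params(
        config: ModelConfig,
        char_vocab: Vocabulary,
        word_vocab: Vocabulary,
        schema: TagSchema,
        rng: np.random.Generator,
    ) -> dict[str, np.ndarray]:
        p: dict[str, np.ndarray] = {}
        p["char_emb"] = nn.uniform_init(rng, char_vocab.size, config.d_char)
        if config.fusion != "none":
            p["word_emb"] = nn.uniform_init(rng, word_vocab.size, config.d_word)
            p["W_word"] = nn.uniform_init(rng, config.d_word, config.d_word)
            p["W_char"] = nn.uniform_init(rng, config.d_char, config.d_char)
            if config.fusion == "bilinear":
                p["W_attn"] = nn.uniform_init(rng, config.d_word, config.d_char)
                p["b_attn"] = nn.uniform_init(rng, 1)
            else:
                p["W_q"] = nn.uniform_init(rng, config.d_word, config.d_model)
                p["W_k"] = nn.uniform_init(rng, config.d_char, config.d_model)
                p["W_v"] = nn.uniform_init(rng, config.d_char, config.d_model)
        d_in = config.encoder_input_dim
        enc = config.encoder
        if enc.kind != "identity":
            for layer in range(enc.n_layers):
                for direction in ("f", "b") if enc.bidirectional else ("f",):
                    lp = nn.lstm_params(rng, d_in, enc.hidden_dim)
                    for k, v in lp.items():
                        p[f"lstm{layer}{direction}_{k}"] = v
                d_in = enc.hidden_dim * (2 if enc.bidirectional else 1)
        T = schema.n_tags
        p["W_out"] = nn.uniform_init(rng, config.encoder_output_dim, T)
        p["b_out"] = np.zeros(T)
        if config.head == "crf":
            p["transitions"] = apply_mask(
                nn.uniform_init(rng, T + 2, T + 2), T
            )
        return p

    # ------------------------------------------------------------------
    # fusion parameter view (plug-and-play with the representation module)
    # ------------------------------------------------------------------
    def fusion_parameters(self) -> FusionParameters:
        if self.config.fusion == "none":
            raise ValueError("tagger was built without a fusion module")
        p = self.params
        bilinear = self.config.fusion == "bilinear"
        return FusionParameters(
            char_embedding=p["char_emb"],
            word_embedding=p["word_emb"],
            W_word=p["W_word"],
            W_character=p["W_char"],
            W_attn=p["W_attn"] if bilinear else np.zeros((self.config.d_word, self.config.d_char)),
            b_attn=float(p["b_attn"][0]) if bilinear else 0.0,
            char_vocab=self.char_vocab,
            word_vocab=self.word_vocab,
            n_heads=self.config.n_heads,
            W_q=None if bilinear else p["W_q"],
            W_k=None if bilinear else p["W_k"],
            W_v=None if bilinear else p["W_v"],
            seed=self.seed,
        )

    # ------------------------------------------------------------------
    # forward / backward
    # ------------------------------------------------------------------
    def _segment(self, chars: str) -> Segmentation:
        return segment(chars, self.lexicon)

    def _batch_arrays(self, batch: Sequence[LabeledSample]):
        B = len(batch)
        lengths = np.array([len(s) for s in batch], dtype=int)
        L = int(lengths.max())
        char_ids = np.full((B, L), PAD_ID, dtype=int)
        for b, s in enumerate(batch):
            for i, ch in enumerate(s.chars):
                char_ids[b, i] = self.char_vocab.id(ch)
        mask = (np.arange(L)[None, :] < lengths[:, None]).astype(float)
        return char_ids, lengths, mask

    def _fusion_forward(self, batch, char_ids, lengths):
        """Build encoder input X (B, L, d_in); returns X and fusion caches."""
        cfg = self.config
        B, L = char_ids.shape
        E = self.params["char_emb"][char_ids]  # (B, L, d_char)
        if cfg.fusion == "none":
            X = E * (char_ids != PAD_ID)[:, :, None]
            return X, None
        p = self.params
        X = np.zeros((B, L, cfg.encoder_input_dim))
        caches = []
        for b, sample in enumerate(batch):
            n = lengths[b]
            seg = sample.words
            spans = seg if seg is not None else self._segment(sample.chars).spans
            Rc = E[b, :n] @ p["W_char"]  # (n, d_char)
            words = []
            for (s, e) in spans:
                wid = self.word_vocab.id(sample.chars[s:e])
                Rw = p["word_emb"][wid] @ p["W_word"]
                if cfg.fusion == "bilinear":
                    scores = Rw @ p["W_attn"] @ Rc[s:e].T + p["b_attn"][0]
                    w8 = softmax(scores)
                    X[b, s:e, : cfg.d_char] = w8[:, None] * Rc[s:e]
                    X[b, s:e, cfg.d_char :] = w8[:, None] * Rw[None, :]
                    words.append((s, e, wid, Rw, w8))
                else:
                    H, dk = cfg.n_heads, cfg.d_model // cfg.n_heads
                    l = e - s
                    q = (Rw @ p["W_q"]).reshape(H, dk)
                    k = (Rc[s:e] @ p["W_k"]).reshape(l, H, dk)
                    v = (Rc[s:e] @ p["W_v"]).reshape(l, H, dk)
                    att = softmax(np.einsum("hd,lhd->hl", q, k) / np.sqrt(dk), axis=-1)
                    o = np.einsum("hl,lhd->hd", att, v).reshape(cfg.d_model)
                    X[b, s:e, : cfg.d_char] = Rc[s:e]
                    X[b, s:e, cfg.d_char :] = o[None, :]
                    words.append((s, e, wid, Rw, q, k, v, att))
            caches.append((Rc, words))
        return X, caches

    def _fusion_backward(self, batch, char_ids, lengths, dX, caches, grads):
        cfg = self.config
        p = self.params
        E = p["char_emb"]
        if cfg.fusion == "none":
            np.add.at(grads["char_emb"], char_ids.ravel(), dX.reshape(-1, cfg.d_char))
            grads["char_emb"][PAD_ID] = 0.0
            return
        for b, sample in enumerate(batch):
            n = lengths[b]
            Rc, words = caches[b]
            dRc = np.zeros_like(Rc)
            for word in words:
                if cfg.fusion == "bilinear":
                    s, e, wid, Rw, w8 = word
                    g = dX[b, s:e]
                    g_c = g[:, : cfg.d_char]
                    g_w = g[:, cfg.d_char :]
                    de = (g_c * Rc[s:e]).sum(axis=1) + g_w @ Rw
                    dRc[s:e] += w8[:, None] * g_c
                    dRw = (w8[:, None] * g_w).sum(axis=0)
                    ds = w8 * (de - float(w8 @ de))
                    dRw += p["W_attn"] @ Rc[s:e].T @ ds
                    dRc[s:e] += ds[:, None] * (Rw @ p["W_attn"])[None, :]
                    grads["W_attn"] += np.outer(Rw, Rc[s:e].T @ ds)
                    grads["b_attn"][0] += ds.sum()
                else:
                    s, e, wid, Rw, q, k, v, att = word
                    H, dk = cfg.n_heads, cfg.d_model // cfg.n_heads
                    l = e - s
                    g = dX[b, s:e]
                    dRc[s:e] += g[:, : cfg.d_char]
                    do = g[:, cfg.d_char :].sum(axis=0).reshape(H, dk)
                    dv = np.einsum("hl,hd->lhd", att, do)
                    da = np.einsum("lhd,hd->hl", v, do)
                    dscore = att * (da - (att * da).sum(axis=1, keepdims=True))
                    dq = np.einsum("hl,lhd->hd", dscore, k) / np.sqrt(dk)
                    dkk = np.einsum("hl,hd->lhd", dscore, q) / np.sqrt(dk)
                    dQ = dq.reshape(cfg.d_model)
                    dK = dkk.reshape(l, cfg.d_model)
                    dV = dv.reshape(l, cfg.d_model)
                    dRw = dQ @ p["W_q"].T
                    grads["W_q"] += np.outer(Rw, dQ)
                    grads["W_k"] += Rc[s:e].T @ dK
                    grads["W_v"] += Rc[s:e].T @ dV
                    dRc[s:e] += dK @ p["W_k"].T + dV @ p["W_v"].T
                # shared word-side backprop
                w_emb_row = p["word_emb"][wid]
                grads["W_word"] += np.outer(w_emb_row, dRw)
                grads["word_emb"][wid] += dRw @ p["W_word"].T
            # char side: Rc = E_span @ W_char
            E_span = E[char_ids[b, :n]]
            grads["W_char"] += E_span.T @ dRc
            np.add.at(grads["char_emb"], char_ids[b, :n], dRc @ p["W_char"].T)
        grads["char_emb"][PAD_ID] = 0.0

    def _encoder_forward(self, X, mask, lengths, train, drop_rng):
        enc = self.config.encoder
        caches = []
        H_cur = X
        if enc.kind != "identity":
            for layer in range(enc.n_layers):
                if enc.bidirectional:
                    pf = self._lstm_p(layer, "f")
                    pb = self._lstm_p(layer, "b")
                    hf, cf = nn.lstm_forward(H_cur, mask, pf)
                    rev = nn.reverse_padded(H_cur, lengths)
                    hb_r, cb = nn.lstm_forward(rev, mask, pb)
                    hb = nn.reverse_padded(hb_r, lengths)
                    caches.append(("bi", cf, cb))
                    H_cur = np.concatenate([hf, hb], axis=2)
                else:
                    pf = self._lstm_p(layer, "f")
                    hf, cf = nn.lstm_forward(H_cur, mask, pf)
                    caches.append(("uni", cf, None))
                    H_cur = hf
        drop_mask = None
        if train and enc.dropout > 0.0:
            keep = 1.0 - enc.dropout
            drop_mask = (drop_rng.random(H_cur.shape) < keep) / keep
            H_cur = H_cur * drop_mask
        return H_cur, caches, drop_mask

    def _lstm_p(self, layer: int, direction: str) -> dict[str, np.ndarray]:
        pre = f"lstm{layer}{direction}_"
        return {k[len(pre):]: v for k, v in self.params.items() if k.startswith(pre)}

    def _encoder_backward(self, dH, caches, lengths, drop_mask, grads):
        enc = self.config.encoder
        if drop_mask is not None:
            dH = dH * drop_mask
        if enc.kind == "identity":
            return dH
        hdim = enc.hidden_dim
        for layer in range(enc.n_layers - 1, -1, -1):
            kind, cf, cb = caches[layer]
            if kind == "bi":
                pf = self._lstm_p(layer, "f")
                pb = self._lstm_p(layer, "b")
                dxf, gf = nn.lstm_backward(dH[:, :, :hdim], pf, cf)
                dhb_r = nn.reverse_padded(dH[:, :, hdim:], lengths)
                dxb_r, gb = nn.lstm_backward(dhb_r, pb, cb)
                dxb = nn.reverse_padded(dxb_r, lengths)
                dH = dxf + dxb
                for k, v in gf.items():
                    grads[f"lstm{layer}f_{k}"] += v
                for k, v in gb.items():
                    grads[f"lstm{layer}b_{k}"] += v
            else:
                pf = self._lstm_p(layer, "f")
                dxf, gf = nn.lstm_backward(dH, pf, cf)
                dH = dxf
                for k, v in gf.items():
                    grads[f"lstm{layer}f_{k}"] += v
        return dH

    def loss_and_grads(
        self,
        batch: Sequence[LabeledSample],
        train: bool = True,
        drop_rng: Optional[np.random.Generator] = None,
    ) -> tuple[float, dict[str, np.ndarray], float]:
        """Mean per-token loss, parameter gradients, and token accuracy."""
        cfg = self.config
        char_ids, lengths, mask = self._batch_arrays(batch)
        X, fcaches = self._fusion_forward(batch, char_ids, lengths)
        Henc, ecaches, drop_mask = self._encoder_forward(
            X, mask, lengths, train, drop_rng
        )
        emissions = Henc @ self.params["W_out"] + self.params["b_out"]
        T = self.schema.n_tags
        n_tokens = int(lengths.sum())
        gold = [self.schema.to_indices(s.tags) for s in batch]

        d_em = np.zeros_like(emissions)
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        total_loss = 0.0
        correct = 0
        if cfg.head == "crf":
            crf = CrfParameters(self.params["transitions"])
            for b, tags in enumerate(gold):
                n = lengths[b]
                nll, dem_b, dtr_b = crf_mod.nll_and_grad(emissions[b, :n], tags, crf)
                total_loss += nll
                d_em[b, :n] = dem_b / n_tokens
                grads["transitions"] += dtr_b / n_tokens
                # d_em + one-hot(gold) recovers the unary marginals; their
                # argmax is the posterior decode, used only for monitoring.
                marg = dem_b.copy()
                marg[np.arange(n), tags] += 1.0
                correct += int((marg.argmax(axis=1) == np.array(tags)).sum())
            apply_mask(grads["transitions"], T)
            grads["transitions"][:, crf.start] = 0.0
            grads["transitions"][crf.stop, :] = 0.0
        else:
            for b, tags in enumerate(gold):
                n = lengths[b]
                probs = softmax(emissions[b, :n], axis=-1)
                idx = np.arange(n)
                total_loss += -np.log(probs[idx, tags] + 1e-300).sum()
                d_em[b, :n] = probs / n_tokens
                d_em[b, idx, tags] -= 1.0 / n_tokens
                correct += int((probs.argmax(axis=1) == np.array(tags)).sum())
        loss = total_loss / n_tokens

        # emission projection backward
        flat_h = Henc.reshape(-1, Henc.shape[-1])
        flat_d = d_em.reshape(-1, T)
        grads["W_out"] += flat_h.T @ flat_d
        grads["b_out"] += flat_d.sum(axis=0)
        dHenc = d_em @ self.params["W_out"].T
        dX = self._encoder_backward(dHenc, ecaches, lengths, drop_mask, grads)
        self._fusion_backward(batch, char_ids, lengths, dX, fcaches, grads)
        return float(loss), grads, correct / n_tokens

    # ------------------------------------------------------------------
    # training / prediction
    # ------------------------------------------------------------------
    def fit(
        self,
        corpus: Sequence[LabeledSample],
        train_cfg: TrainConfig,
        dev: Optional[Sequence[LabeledSample]] = None,
    ) -> list[dict]:
        if not corpus:
            raise ValueError("cannot train on an empty corpus")
        ss = np.random.SeedSequence(train_cfg.seed)
        shuffle_seed, drop_seed = ss.spawn(2)
        shuffle_rng = np.random.default_rng(shuffle_seed)
        drop_rng = np.random.default_rng(drop_seed)
        opt = nn.Adam(self.params, lr=train_cfg.lr)
        order = np.arange(len(corpus))
        for epoch in range(train_cfg.epochs):
            if train_cfg.shuffle:
                shuffle_rng.shuffle(order)
            ep_loss, ep_acc, n_batches = 0.0, 0.0, 0
            for start in range(0, len(order), train_cfg.batch_size):
                batch = [corpus[i] for i in order[start : start + train_cfg.batch_size]]
                loss, grads, acc = self.loss_and_grads(batch, train=True, drop_rng=drop_rng)
                opt.step(grads)
                if self.config.head == "crf":
                    apply_mask(self.params["transitions"], self.schema.n_tags)
                ep_loss += loss
                ep_acc += acc
                n_batches += 1
            entry = {
                "epoch": epoch,
                "split": "train",
                "loss": ep_loss / n_batches,
                "token_accuracy": ep_acc / n_batches,
            }
            self.history.append(entry)
            if dev:
                self.history.append(
                    {
                        "epoch": epoch,
                        "split": "dev",
                        "token_accuracy": self.token_accuracy(dev),
                    }
                )
        return self.history

    def emissions_for(self, sample: LabeledSample) -> np.ndarray:
        char_ids, lengths, mask = self._batch_arrays([sample])
        X, _ = self._fusion_forward([sample], char_ids, lengths)
        Henc, _, _ = self._encoder_forward(X, mask, lengths, False, None)
        return Henc[0] @ self.params["W_out"] + self.params["b_out"]

    def predict_tags(self, samples: Sequence[LabeledSample]) -> list[list[str]]:
        """One tag per character for each sample; CRF uses Viterbi."""
        out: list[list[str]] = []
        if not samples:
            return out
        crf = CrfParameters(self.params["transitions"]) if self.config.head == "crf" else None
        for sample in samples:
            if len(sample) == 0:
                out.append([])
                continue
            em = self.emissions_for(sample)
            if crf is not None:
                idx, _ = crf_mod.viterbi_decode(em, crf)
            else:
                idx = em.argmax(axis=1).tolist()
            out.append([self.schema.tags[i] for i in idx])
        return out

    def predict_texts(self, texts: Sequence[str]) -> list[LabeledSample]:
        samples = [
            LabeledSample(t, ["O"] * len(t), schema=self.schema) for t in texts
        ]
        tag_seqs = self.predict_tags(samples)
        return [
            LabeledSample(t, tags, schema=self.schema)
            for t, tags in zip(texts, tag_seqs)
        ]

    def token_accuracy(self, samples: Sequence[LabeledSample]) -> float:
        pred = self.predict_tags(samples)
        total = sum(len(s) for s in samples)
        correct = sum(
            int(p == g) for s, ps in zip(samples, pred) for p, g in zip(ps, s.tags)
        )
        return correct / total if total else 0.0

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    CHECKPOINT_VERSION = 1

    def save(self, path: str | Path) -> None:
        """Binary parameter checkpoint (.npz) + JSON sidecar (.json)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {
            "version": self.CHECKPOINT_VERSION,
            "seed": self.seed,
            "config": {
                "fusion": self.config.fusion,
                "head": self.config.head,
                "d_char": self.config.d_char,
                "d_word": self.config.d_word,
                "d_model": self.config.d_model,
                "n_heads": self.config.n_heads,
                "encoder": asdict(self.config.encoder),
            },
            "schema_tags": list(self.schema.tags),
            "char_vocab": self.char_vocab.to_dict(),
            "word_vocab": self.word_vocab.to_dict(),
            "lexicon": sorted(self.lexicon.words),
        }
        with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, ensure_ascii=False)

    @classmethod
    def load(cls, path: str | Path, schema: TagSchema = DEFAULT_SCHEMA) -> "Tagger":
        path = Path(path)
        with open(path.with_suffix(".json"), encoding="utf-8") as fh:
            sidecar = json.load(fh)
        if sidecar.get("version") != cls.CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {sidecar.get('version')!r}"
            )
        if list(schema.tags) != sidecar["schema_tags"]:
            raise ValueError("checkpoint tag schema does not match the current schema")
        cfg_d = sidecar["config"]
        config = ModelConfig(
            fusion=cfg_d["fusion"],
            head=cfg_d["head"],
            d_char=cfg_d["d_char"],
            d_word=cfg_d["d_word"],
            d_model=cfg_d["d_model"],
            n_heads=cfg_d["n_heads"],
            encoder=EncoderConfig(**cfg_d["encoder"]),
        )
        with np.load(path.with_suffix(".npz")) as data:
            params = {k: data[k] for k in data.files}
        return cls(
            config,
            Vocabulary.from_dict(sidecar["char_vocab"]),
            Vocabulary.from_dict(sidecar["word_vocab"]),
            params,
            Lexicon.from_words(sidecar["lexicon"]),
            schema,
            seed=sidecar["seed"],
        )


def train(
    corpus: Sequence[LabeledSample],
    lexicon: Lexicon,
    model_config: ModelConfig,
    train_config: TrainConfig,
    dev: Optional[Sequence[LabeledSample]] = None,
    schema: TagSchema = DEFAULT_SCHEMA,
) -> Tagger:
    """Build and fit a tagger; the per-epoch loss log is ``tagger.history``."""
    tagger = Tagger.build(corpus, lexicon, model_config, seed=train_config.seed, schema=schema)
    tagger.fit(corpus, train_config, dev=dev)
    return tagger
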