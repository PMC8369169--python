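"""Precision / recall / F1 in three protocols.

* ``classification`` — token-level micro scores over all 11 tags at every
  position, O included (the "traditional" protocol; micro P = R = F1 =
  token accuracy for single-label tagging, so a model is also rewarded
  for calling non-entities O).
* ``identification`` — the stricter protocol: both tag sequences are
  restricted to the positions where the *gold* tag is an entity tag, and
  micro scores are computed over the 10 entity tags at those positions.
  O-position behaviour of the model is invisible here by construction.
* ``entity_strict`` — CoNLL-style strict span matching: both sequences
  are decoded to entities and a predicted entity counts only if class,
  start and end all match a gold entity.

F1 is the harmonic mean 2PR/(P+R), defined as 0 when P + R = 0.
Reported percentages round half away from zero to one decimal.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .schema import DEFAULT_SCHEMA, OUTSIDE, TagSchema, decode_tags

TagSeqs = Sequence[Sequence[str]]


def round1(x: float) -> float:
    """Round half away from zero to 1 decimal (as percentages print)."""
    q = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
    )
    return float(q)


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall on the percent scale,
    rounded to 1 decimal; 0.0 when both are 0 (convention)."""
    if not (0 <= precision <= 100 and 0 <= recall <= 100):
        raise ValueError("precision and recall must be percentages in [0, 100]")
    if precision + recall == 0:
        return 0.0
    return round1(2 * precision * recall / (precision + recall))


def _f1_frac(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


@dataclass
class ClassScores:
    true_positive: int = 0
    predicted: int = 0
    gold: int = 0

    @property
    def precision(self) -> float:
        return self.true_positive / self.predicted if self.predicted else 0.0

    @property
    def recall(self) -> float:
        return self.true_positive / self.gold if self.gold else 0.0

    @property
    def f1(self) -> float:
        return _f1_frac(self.precision, self.recall)


@dataclass
class EvalReport:
    """Micro P/R/F1 plus a per-label breakdown and raw counts."""

    mode: str
    micro: ClassScores
    per_class: dict[str, ClassScores] = field(default_factory=dict)

    @property
    def precision(self) -> float:
        return self.micro.precision

    @property
    def recall(self) -> float:
        return self.micro.recall

    @property
    def f1(self) -> float:
        return self.micro.f1

    def as_percent(self) -> dict[str, float]:
        return {
            "precision": round1(100 * self.precision),
            "recall": round1(100 * self.recall),
            "f1": round1(100 * self.f1),
        }

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            **self.as_percent(),
            "counts": {
                "true_positive": self.micro.true_positive,
                "predicted": self.micro.predicted,
                "gold": self.micro.gold,
            },
            "per_class": {
                label: {
                    "precision": round1(100 * s.precision),
                    "recall": round1(100 * s.recall),
                    "f1": round1(100 * s.f1),
                    "true_positive": s.true_positive,
                    "predicted": s.predicted,
                    "gold": s.gold,
                }
                for label, s in sorted(self.per_class.items())
            },
        }


def _check_aligned(gold: TagSeqs, pred: TagSeqs) -> None:
    if len(gold) != len(pred):
        raise ValueError(
            f"gold has {len(gold)} sentences, predictions have {len(pred)}"
        )
    for i, (g, p) in enumerate(zip(gold, pred)):
        if len(g) != len(p):
            raise ValueError(
                f"length mismatch at sentence {i}: gold {len(g)}, pred {len(p)}"
            )


def classification_metrics(
    gold: TagSeqs, pred: TagSeqs, schema: TagSchema = DEFAULT_SCHEMA
) -> EvalReport:
    """Token-level micro scores over all positions and all 11 tags."""
    _check_aligned(gold, pred)
    micro = ClassScores()
    per: dict[str, ClassScores] = {t: ClassScores() for t in schema.tags}
    for g_seq, p_seq in zip(gold, pred):
        for g, p in zip(g_seq, p_seq):
            schema.validate_tag(g)
            schema.validate_tag(p)
            micro.gold += 1
            micro.predicted += 1
            per[g].gold += 1
            per[p].predicted += 1
            if g == p:
                micro.true_positive += 1
                per[g].true_positive += 1
    return EvalReport("classification", micro, per)


def identification_metrics(
    gold: TagSeqs, pred: TagSeqs, schema: TagSchema = DEFAULT_SCHEMA
) -> EvalReport:
    """Micro scores over the 10 entity tags at gold non-O positions.

    Both sequences are filtered to the positions whose gold tag is not
    O; a predicted O at such a position counts as a miss (recall loss)
    but not as a prediction, and anything the model does at gold-O
    positions cannot change the result.
    """
    _check_aligned(gold, pred)
    micro = ClassScores()
    per: dict[str, ClassScores] = {
        t: ClassScores() for t in schema.tags if t != OUTSIDE
    }
    for g_seq, p_seq in zip(gold, pred):
        for g, p in zip(g_seq, p_seq):
            schema.validate_tag(g)
            schema.validate_tag(p)
            if g == OUTSIDE:
                continue
            micro.gold += 1
            per[g].gold += 1
            if p != OUTSIDE:
                micro.predicted += 1
                per[p].predicted += 1
            if g == p:
                micro.true_positive += 1
                per[g].true_positive += 1
    return EvalReport("identification", micro, per)


def entity_strict_metrics(
    gold: TagSeqs, pred: TagSeqs, schema: TagSchema = DEFAULT_SCHEMA
) -> EvalReport:
    """Entity-level strict matching on decoded (class, start, end) spans."""
    _check_aligned(gold, pred)
    micro = ClassScores()
    per: dict[str, ClassScores] = {}
    for g_seq, p_seq in zip(gold, pred):
        g_ents = {
            (e.cls, e.start, e.end) for e in decode_tags(g_seq, schema=schema)
        }
        p_ents = {
            (e.cls, e.start, e.end) for e in decode_tags(p_seq, schema=schema)
        }
        micro.gold += len(g_ents)
        micro.predicted += len(p_ents)
        micro.true_positive += len(g_ents & p_ents)
        for cls, _, _ in g_ents:
            per.setdefault(cls.value, ClassScores()).gold += 1
        for key in p_ents:
            per.setdefault(key[0].value, ClassScores()).predicted += 1
            if key in g_ents:
                per[key[0].value].true_positive += 1
    return EvalReport("entity_strict", micro, per)


def single_class_subsets(
    samples: Sequence, schema: TagSchema = DEFAULT_SCHEMA
) -> dict[str, list]:
    """Per-class evaluation subsets: samples whose entities all belong to
    exactly one class (samples mixing classes, or without entities, are
    dropped)."""
    out: dict[str, list] = {}
    for sample in samples:
        classes = {
            schema.class_of[t] for t in sample.tags if schema.class_of[t] is not None
        }
        if len(classes) == 1:
            (only,) = classes
            out.setdefault(only.value, []).append(sample)
    return out
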