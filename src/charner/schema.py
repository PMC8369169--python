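"""Entity classes and the BIO tag vocabulary for TCM clinical text.

The schema covers the five entity classes a traditional-Chinese-medicine
record mentions — clinical manifestation (symptoms, incl. tongue and pulse
findings), syndrome (the TCM diagnostic pattern), disease, treatment law
(the therapeutic principle) and herb — tagged per character with a BIO
scheme: ``B-<class>`` on the first character of a mention, ``I-<class>``
on the rest, ``O`` elsewhere.  Tagging is strictly character-level: word
segmentation never touches the label side.

Conversion between the two views of a labeled sentence — a list of
``Entity`` spans and a per-character tag sequence — is lossless for
well-formed input; decoding of arbitrary (model-produced) tag sequences is
total, repairing a dangling ``I-`` as a ``B-``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence


class SchemaError(ValueError):
    """Raised for tags or spans that violate the tagging schema."""


class EntityClass(str, enum.Enum):
    """The five TCM entity classes (CSDTH)."""

    CLINICAL_MANIFESTATION = "clinical_manifestation"
    SYNDROME = "syndrome"
    DISEASE = "disease"
    TREATMENT_LAW = "treatment_law"
    HERB = "herb"

    @property
    def tag_stem(self) -> str:
        """Stem used in B-/I- tag labels.

        Clinical manifestations are tagged with the stem ``symptom``;
        ``treatment law`` keeps its internal space in tag labels (file
        format compatibility), while the Python identifier uses an
        underscore.
        """
        return _TAG_STEMS[self]


_TAG_STEMS = {
    EntityClass.CLINICAL_MANIFESTATION: "symptom",
    EntityClass.SYNDROME: "syndrome",
    EntityClass.DISEASE: "disease",
    EntityClass.TREATMENT_LAW: "treatment law",
    EntityClass.HERB: "herb",
}

OUTSIDE = "O"


@dataclass(frozen=True)
class TagSchema:
    """The 11-tag vocabulary: B-/I- pairs for 5 classes plus O."""

    tags: tuple[str, ...]
    index_of: dict[str, int]
    class_of: dict[str, Optional[EntityClass]]

    @classmethod
    def default(cls) -> "TagSchema":
        tags: list[str] = []
        class_of: dict[str, Optional[EntityClass]] = {}
        for ec in EntityClass:
            for prefix in ("B", "I"):
                tag = f"{prefix}-{ec.tag_stem}"
                tags.append(tag)
                class_of[tag] = ec
        tags.append(OUTSIDE)
        class_of[OUTSIDE] = None
        return cls(
            tags=tuple(tags),
            index_of={t: i for i, t in enumerate(tags)},
            class_of=class_of,
        )

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def outside_index(self) -> int:
        return self.index_of[OUTSIDE]

    def begin_tag(self, ec: EntityClass) -> str:
        return f"B-{ec.tag_stem}"

    def inside_tag(self, ec: EntityClass) -> str:
        return f"I-{ec.tag_stem}"

    def validate_tag(self, tag: str) -> None:
        if tag not in self.index_of:
            raise SchemaError(f"unknown tag label: {tag!r}")

    def to_indices(self, tags: Sequence[str]) -> list[int]:
        for t in tags:
            self.validate_tag(t)
        return [self.index_of[t] for t in tags]


#: Module-level default schema; immutable, safe to share.
DEFAULT_SCHEMA = TagSchema.default()


@dataclass(frozen=True)
class Entity:
    """A flat entity mention as a half-open character span [start, end)."""

    cls: EntityClass
    start: int
    end: int
    text: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SchemaError(
                f"invalid span [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.text and len(self.text) != self.end - self.start:
            raise SchemaError(
                f"text {self.text!r} has length {len(self.text)}, "
                f"span [{self.start}, {self.end}) has length {self.end - self.start}"
            )


@dataclass
class LabeledSample:
    """A character sequence with one BIO tag per character.

    ``words``, when present, is a sorted, gap-free partition of
    ``[0, len(chars))`` into word spans; it serves the representation
    side only and never constrains the tags.
    """

    chars: str
    tags: list[str]
    words: Optional[list[tuple[int, int]]] = None
    schema: TagSchema = field(default=DEFAULT_SCHEMA, repr=False)

    def __post_init__(self) -> None:
        if len(self.tags) != len(self.chars):
            raise SchemaError(
                f"{len(self.chars)} characters but {len(self.tags)} tags"
            )
        for t in self.tags:
            self.schema.validate_tag(t)
        if self.words is not None:
            _check_partition(self.words, len(self.chars))

    def entities(self) -> list[Entity]:
        return decode_tags(self.tags, chars=self.chars, schema=self.schema)

    def __len__(self) -> int:
        return len(self.chars)


def _check_partition(spans: Sequence[tuple[int, int]], length: int) -> None:
    pos = 0
    for s, e in spans:
        if s != pos or e <= s:
            raise SchemaError(
                f"word spans must partition [0, {length}) without gaps or "
                f"overlaps; offending span ({s}, {e}) at position {pos}"
            )
        pos = e
    if pos != length:
        raise SchemaError(
            f"word spans cover [0, {pos}) but the sample has {length} characters"
        )


def encode_entities(
    chars: str,
    entities: Sequence[Entity],
    schema: TagSchema = DEFAULT_SCHEMA,
) -> list[str]:
    """BIO-encode non-overlapping entity spans over ``chars``.

    The first character of each entity gets ``B-<class>``, the remaining
    characters ``I-<class>``; every other position gets ``O``.

    Raises
    ------
    SchemaError
        If a span is out of bounds or two spans overlap (both offenders
        are reported).
    """
    n = len(chars)
    for ent in entities:
        if ent.end > n:
            raise SchemaError(
                f"span [{ent.start}, {ent.end}) out of bounds for length {n}"
            )
    ordered = sorted(entities, key=lambda e: (e.start, e.end))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise SchemaError(
                "overlapping entity spans: "
                f"[{prev.start}, {prev.end}) ({prev.cls.value}) and "
                f"[{cur.start}, {cur.end}) ({cur.cls.value})"
            )
    tags = [OUTSIDE] * n
    for ent in ordered:
        tags[ent.start] = schema.begin_tag(ent.cls)
        for i in range(ent.start + 1, ent.end):
            tags[i] = schema.inside_tag(ent.cls)
    return tags


def decode_tags(
    tags: Sequence[str],
    chars: Optional[str] = None,
    schema: TagSchema = DEFAULT_SCHEMA,
) -> list[Entity]:
    """Decode a BIO tag sequence into sorted, non-overlapping entities.

    Total over arbitrary tag sequences from the schema: an ``I-<c>`` that
    does not continue a ``B-<c>``/``I-<c>`` run of the same class opens a
    new entity (conll-style begin repair), so raw model output never
    errors mid-evaluation.

    Raises
    ------
    SchemaError
        If a tag label is not in the schema (the label is named).
    """
    for t in tags:
        schema.validate_tag(t)
    entities: list[Entity] = []
    start: Optional[int] = None
    cur_cls: Optional[EntityClass] = None

    def flush(end: int) -> None:
        nonlocal start, cur_cls
        if start is not None:
            assert cur_cls is not None
            text = chars[start:end] if chars is not None else ""
            entities.append(Entity(cur_cls, start, end, text))
        start, cur_cls = None, None

    for i, tag in enumerate(tags):
        cls = schema.class_of[tag]
        if cls is None:  # O
            flush(i)
        elif tag.startswith("B-"):
            flush(i)
            start, cur_cls = i, cls
        else:  # I-
            if cls is not cur_cls:  # dangling I- : begin repair
                flush(i)
                start, cur_cls = i, cls
    flush(len(tags))
    return entities
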