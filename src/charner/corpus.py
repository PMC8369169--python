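"""Seeded generator of TCM-like labeled corpora.

No public TCM NER corpus with this schema exists, so every other module
is exercised against synthetic text that reproduces the *structure* of
such data: five entity classes with very different frequencies
(clinical manifestations dominate, diseases are rare); variable-length
entities, with clinical-manifestation phrases frequently longer than six
characters; and two sample styles — entity-sparse "publication"
sentences (expository prose around occasional terms) and entity-dense
"record" sentences (clinical records list many entities with little
filler).  Characters are real CJK ideographs so multi-byte handling is
exercised end to end.

Each corpus draws per-class entity vocabularies once, then assembles
sentences as filler/entity alternations.  Entity surfaces mix
class-specific "marker" characters with characters from a shared
ambiguous pool; the ``marker_noise`` knob sets the fraction of shared
characters and thereby how much a character-only model can infer without
word-level information, since the emitted lexicon always contains every
entity surface (plus distractor words), letting maximum-matching
segmentation recover gold word boundaries.  Generation is byte-for-byte
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .schema import (
    DEFAULT_SCHEMA,
    Entity,
    EntityClass,
    LabeledSample,
    TagSchema,
    encode_entities,
)
from .segmentation import Lexicon

STYLES = ("publication", "record")

#: First code point of the CJK unified ideograph block.
CJK_BASE = 0x4E00


def _default_length_dists() -> dict[EntityClass, dict[int, float]]:
    """Entity length (characters) distributions per class.

    Clinical manifestations are phrases of 2-12 characters with most
    mass above 6; herbs and diseases are short names; syndromes and
    treatment laws sit in between.
    """
    cm = {2: 0.04, 3: 0.06, 4: 0.08, 5: 0.10, 6: 0.12, 7: 0.10,
          8: 0.14, 9: 0.12, 10: 0.11, 11: 0.07, 12: 0.06}
    short = {2: 0.45, 3: 0.35, 4: 0.20}
    mid = {3: 0.30, 4: 0.30, 5: 0.25, 6: 0.15}
    return {
        EntityClass.CLINICAL_MANIFESTATION: cm,
        EntityClass.SYNDROME: mid,
        EntityClass.DISEASE: short,
        EntityClass.TREATMENT_LAW: mid,
        EntityClass.HERB: short,
    }


def _default_class_weights() -> dict[EntityClass, float]:
    """Relative class frequencies (clinical manifestations dominate,
    diseases are rare — mirroring real publication statistics)."""
    return {
        EntityClass.CLINICAL_MANIFESTATION: 0.37,
        EntityClass.SYNDROME: 0.18,
        EntityClass.DISEASE: 0.03,
        EntityClass.TREATMENT_LAW: 0.22,
        EntityClass.HERB: 0.20,
    }


@dataclass
class CorpusSpec:
    """Conditions under which a corpus is generated.

    ``entities_per_sample`` is the Poisson mean of entity mentions per
    sentence for each style; records are far denser than publications.
    ``filler_mean`` is the geometric-mean length of the non-entity runs
    between mentions (long prose in publications, terse separators in
    records).  ``marker_noise`` is the probability that an entity-surface
    character is drawn from the shared (class-ambiguous) pool instead of
    the class's marker pool.
    """

    n_samples: dict[str, int] = field(
        default_factory=lambda: {"publication": 1650, "record": 1650}
    )
    entities_per_sample: dict[str, float] = field(
        default_factory=lambda: {"publication": 0.8, "record": 6.0}
    )
    filler_mean: dict[str, float] = field(
        default_factory=lambda: {"publication": 9.0, "record": 1.5}
    )
    class_weights: dict[EntityClass, float] = field(default_factory=_default_class_weights)
    length_dists: dict[EntityClass, dict[int, float]] = field(
        default_factory=_default_length_dists
    )
    vocab_per_class: int = 60
    alphabet_size: int = 300
    n_marker_chars: int = 12
    n_distractors: int = 150
    marker_noise: float = 0.3
    max_len: int = 120
    seed: int = 0

    def validate(self) -> None:
        for style in self.n_samples:
            if style not in STYLES:
                raise ValueError(f"unknown style {style!r}")
        if any(r < 0 for r in self.entities_per_sample.values()):
            raise ValueError("entity rates must be >= 0")
        if not (0.0 <= self.marker_noise <= 1.0):
            raise ValueError("marker_noise must be in [0, 1]")
        mean_len = {
            ec: sum(l * w for l, w in dist.items()) / sum(dist.values())
            for ec, dist in self.length_dists.items()
        }
        wsum = sum(self.class_weights.values())
        for style, rate in self.entities_per_sample.items():
            expected = sum(
                rate * (w / wsum) * mean_len[ec] + rate * (w / wsum) * self.filler_mean[style]
                for ec, w in self.class_weights.items()
            ) + self.filler_mean[style]
            if expected > self.max_len:
                worst = max(
                    self.class_weights,
                    key=lambda ec: self.class_weights[ec] * mean_len[ec],
                )
                raise ValueError(
                    f"entity rate {rate} for style {style!r} implies an expected "
                    f"sentence length of {expected:.0f} > max_len {self.max_len}; "
                    f"largest contribution from class {worst.value}"
                )

    @property
    def expected_record_density_exceeds_publication(self) -> bool:
        return (
            self.entities_per_sample["record"] > self.entities_per_sample["publication"]
        )


@dataclass
class GeneratedCorpus:
    samples: list[LabeledSample]
    styles: list[str]
    entities: list[list[Entity]]
    lexicon: Lexicon
    manifest: dict
    #: Per-class entity surface vocabulary the mentions were drawn from.
    entity_vocabulary: dict[str, list[str]] = field(default_factory=dict)

    def by_style(self, style: str) -> list[LabeledSample]:
        return [s for s, st in zip(self.samples, self.styles) if st == style]


class _Alphabet:
    def __init__(self, spec: CorpusSpec, rng: np.random.Generator) -> None:
        chars = [chr(CJK_BASE + i) for i in range(spec.alphabet_size)]
        order = rng.permutation(len(chars))
        chars = [chars[i] for i in order]
        self.markers: dict[EntityClass, list[str]] = {}
        k = spec.n_marker_chars
        for j, ec in enumerate(EntityClass):
            self.markers[ec] = chars[j * k : (j + 1) * k]
        self.shared = chars[len(EntityClass) * k :]
        if not self.shared:
            raise ValueError("alphabet too small for the marker pools")


def _draw_from(dist: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    w = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=w / w.sum()))


def _entity_surface(
    ec: EntityClass, length: int, alpha: _Alphabet, noise: float, rng: np.random.Generator
) -> str:
    out = []
    for _ in range(length):
        if rng.random() < noise:
            out.append(alpha.shared[rng.integers(len(alpha.shared))])
        else:
            out.append(alpha.markers[ec][rng.integers(len(alpha.markers[ec]))])
    return "".join(out)


def _filler(length: int, alpha: _Alphabet, rng: np.random.Generator) -> str:
    return "".join(
        alpha.shared[rng.integers(len(alpha.shared))] for _ in range(length)
    )


def generate(spec: CorpusSpec, schema: TagSchema = DEFAULT_SCHEMA) -> GeneratedCorpus:
    """Generate a corpus under ``spec``; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alpha = _Alphabet(spec, rng)

    # Fixed per-class entity vocabularies: surfaces are sampled once and
    # reused, like real herb names or stock clinical phrases.
    vocab: dict[EntityClass, list[str]] = {}
    seen: set[str] = set()
    for ec in EntityClass:
        surfaces = []
        while len(surfaces) < spec.vocab_per_class:
            # collisions redraw the characters at the same length, so the
            # surface lengths stay an exact iid sample of the length law
            length = _draw_from(spec.length_dists[ec], rng)
            while True:
                s = _entity_surface(ec, length, alpha, spec.marker_noise, rng)
                if s not in seen:
                    break
            seen.add(s)
            surfaces.append(s)
        vocab[ec] = surfaces

    classes = list(EntityClass)
    weights = np.array([spec.class_weights[ec] for ec in classes], dtype=float)
    weights /= weights.sum()

    samples: list[LabeledSample] = []
    styles: list[str] = []
    all_entities: list[list[Entity]] = []
    counts = {style: {ec.value: 0 for ec in EntityClass} for style in spec.n_samples}

    for style, n in spec.n_samples.items():
        rate = spec.entities_per_sample[style]
        fmean = spec.filler_mean[style]
        for _ in range(n):
            k = int(rng.poisson(rate)) if rate > 0 else 0
            parts: list[str] = []
            entities: list[Entity] = []
            pos = 0

            def add_filler() -> None:
                nonlocal pos
                length = int(rng.geometric(1.0 / (1.0 + fmean))) - 1
                length = min(length, spec.max_len - pos)
                if length > 0:
                    parts.append(_filler(length, alpha, rng))
                    pos += length

            add_filler()
            for _ in range(k):
                ec = classes[int(rng.choice(len(classes), p=weights))]
                surface = vocab[ec][int(rng.integers(len(vocab[ec])))]
                if pos + len(surface) > spec.max_len:
                    break
                entities.append(Entity(ec, pos, pos + len(surface), surface))
                parts.append(surface)
                pos += len(surface)
                counts[style][ec.value] += 1
                add_filler()
            if pos == 0:  # never emit an empty sentence
                parts.append(_filler(1, alpha, rng) or alpha.shared[0])
                pos = len(parts[-1])
            chars = "".join(parts)
            tags = encode_entities(chars, entities, schema)
            samples.append(LabeledSample(chars, tags, schema=schema))
            styles.append(style)
            all_entities.append(entities)

    distractors = set()
    while len(distractors) < spec.n_distractors:
        w = _filler(int(rng.integers(2, 5)), alpha, rng)
        if w not in seen:
            distractors.add(w)
    lexicon = Lexicon.from_words(
        [s for surfaces in vocab.values() for s in surfaces] + sorted(distractors)
    )

    manifest = {
        "seed": spec.seed,
        "n_samples": dict(spec.n_samples),
        "entity_counts": counts,
        "total_entities": int(sum(sum(c.values()) for c in counts.values())),
        "lexicon_size": len(lexicon),
    }
    return GeneratedCorpus(
        samples,
        styles,
        all_entities,
        lexicon,
        manifest,
        entity_vocabulary={ec.value: list(vocab[ec]) for ec in EntityClass},
    )


def split(
    samples: Sequence,
    proportions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Disjoint train/valid/test split with ``floor(p_i * N)`` sizes and
    the remainder assigned to train; shuffling is seeded.

    94,380 samples at 6:2:2 yield (56,628, 18,876, 18,876).
    """
    if len(samples) == 0:
        raise ValueError("cannot split an empty corpus")
    props = np.array(proportions, dtype=float)
    if len(props) != 3 or np.any(props <= 0):
        raise ValueError("need three positive proportions")
    props = props / props.sum()
    n = len(samples)
    sizes = [int(np.floor(p * n)) for p in props]
    sizes[0] += n - sum(sizes)
    order = np.random.default_rng(seed).permutation(n)
    idx = np.split(order, [sizes[0], sizes[0] + sizes[1]])
    return tuple([samples[i] for i in part] for part in idx)  # type: ignore[return-value]
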