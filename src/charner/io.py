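"""Readers and writers for the on-disk formats.

* CoNLL-style character files: one ``<char>\\t<tag>`` line per character,
  a blank line between sentences, UTF-8.  Tag labels are the printed
  forms (``B-treatment law`` keeps its internal space).
* JSONL samples: one object per line with ``text`` and ``entities``
  (list of ``{"cls", "start", "end"}`` with half-open spans).
* YAML/JSON run configuration.

Reading validates against the tag schema and reports ``file:line`` for
malformed input; ``write_conll(read_conll(f)) == f`` for canonical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .schema import (
    DEFAULT_SCHEMA,
    Entity,
    EntityClass,
    LabeledSample,
    SchemaError,
    TagSchema,
    encode_entities,
)


class FormatError(ValueError):
    """Malformed input file; message carries ``path:line``."""


def read_conll(path: str | Path, schema: TagSchema = DEFAULT_SCHEMA) -> list[LabeledSample]:
    samples: list[LabeledSample] = []
    chars: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        nonlocal chars, tags
        if chars:
            samples.append(LabeledSample("".join(chars), tags, schema=schema))
            chars, tags = [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                flush()
                continue
            parts = line.split("\t")
            if len(parts) != 2 or len(parts[0]) != 1:
                raise FormatError(
                    f"{path}:{lineno}: expected '<char>\\t<tag>', got {line!r}"
                )
            ch, tag = parts
            if tag not in schema.index_of:
                raise FormatError(f"{path}:{lineno}: unknown tag label {tag!r}")
            chars.append(ch)
            tags.append(tag)
    flush()
    return samples


def write_conll(
    path: str | Path, samples: Sequence[LabeledSample]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, sample in enumerate(samples):
            for ch, tag in zip(sample.chars, sample.tags):
                fh.write(f"{ch}\t{tag}\n")
            if k != len(samples) - 1:
                fh.write("\n")


def read_jsonl(path: str | Path, schema: TagSchema = DEFAULT_SCHEMA) -> list[LabeledSample]:
    samples = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            try:
                obj = json.loads(raw)
                text = obj["text"]
                ents = [
                    Entity(EntityClass(e["cls"]), e["start"], e["end"],
                           text[e["start"]:e["end"]])
                    for e in obj.get("entities", [])
                ]
            except (KeyError, ValueError, SchemaError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            tags = encode_entities(text, ents, schema)
            samples.append(LabeledSample(text, tags, schema=schema))
    return samples


def write_jsonl(path: str | Path, samples: Sequence[LabeledSample]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample in samples:
            obj = {
                "text": sample.chars,
                "entities": [
                    {"cls": e.cls.value, "start": e.start, "end": e.end}
                    for e in sample.entities()
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def load_config(path: str | Path) -> dict:
    """YAML (or JSON, a YAML subset) run configuration; the seed is
    mandatory."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    if "seed" not in cfg.get("training", cfg):
        raise FormatError(f"{path}: a seed is mandatory in the configuration")
    return cfg
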