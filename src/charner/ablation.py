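"""Paired ablation of the word-character fusion module.

Trains the tagger twice per seed — once with the fusion module, once on
raw character embeddings — with everything else (corpus, split,
architecture, initialization stream, shuffling) shared, and reports the
per-seed and mean deltas in identification F1 (plus the other two
protocols).  This is the desk-scale analogue of switching a "-c" module
on and off across otherwise identical models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .corpus import CorpusSpec, GeneratedCorpus, generate, split
from .evaluation import (
    classification_metrics,
    entity_strict_metrics,
    identification_metrics,
)
from .schema import LabeledSample
from .tagger import EncoderConfig, ModelConfig, TrainConfig, train


def high_signal_spec(seed: int = 0, n_total: int = 3300) -> CorpusSpec:
    """Corpus conditions under which word-level semantics carry real
    information beyond single characters: half of the entity-surface
    characters come from the shared pool, so word identity (always
    recoverable from the emitted lexicon) disambiguates what characters
    alone often cannot."""
    n_pub = n_total // 2
    return CorpusSpec(
        n_samples={"publication": n_pub, "record": n_total - n_pub},
        marker_noise=0.5,
        seed=seed,
    )


def small_model(fusion: str, hidden_dim: int = 24) -> ModelConfig:
    return ModelConfig(
        fusion=fusion,
        head="crf",
        d_char=12,
        d_word=12,
        encoder=EncoderConfig(kind="bilstm", hidden_dim=hidden_dim),
    )


@dataclass
class AblationReport:
    seeds: list[int]
    fused: list[dict]
    baseline: list[dict]
    deltas: list[dict]
    mean_delta: dict[str, float]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _scores(tagger, test: Sequence[LabeledSample]) -> dict[str, float]:
    gold = [s.tags for s in test]
    pred = tagger.predict_tags(test)
    return {
        "identification_f1": 100 * identification_metrics(gold, pred).f1,
        "classification_f1": 100 * classification_metrics(gold, pred).f1,
        "entity_f1": 100 * entity_strict_metrics(gold, pred).f1,
    }


def run_ablation(
    seeds: Sequence[int] = (0, 1, 2),
    corpus_spec: Optional[CorpusSpec] = None,
    fused_variant: str = "bilinear",
    epochs: int = 5,
    batch_size: int = 32,
    lr: float = 1e-2,
    hidden_dim: int = 24,
    n_total: int = 3300,
) -> AblationReport:
    """Run the paired fusion-on/fusion-off comparison across seeds."""
    fused_scores: list[dict] = []
    base_scores: list[dict] = []
    deltas: list[dict] = []
    for seed in seeds:
        spec = corpus_spec if corpus_spec is not None else high_signal_spec(seed, n_total)
        spec = dataclasses.replace(spec, seed=seed)
        corpus: GeneratedCorpus = generate(spec)
        train_set, _, test_set = split(corpus.samples, (0.6, 0.2, 0.2), seed=seed)
        tcfg = TrainConfig(epochs=epochs, batch_size=batch_size, lr=lr, seed=seed)
        pair = {}
        for variant in (fused_variant, "none"):
            model = train(
                train_set, corpus.lexicon, small_model(variant, hidden_dim), tcfg
            )
            pair[variant] = _scores(model, test_set)
        fused_scores.append(pair[fused_variant])
        base_scores.append(pair["none"])
        deltas.append(
            {k: pair[fused_variant][k] - pair["none"][k] for k in pair["none"]}
        )
    mean_delta = {
        k: sum(d[k] for d in deltas) / len(deltas) for k in deltas[0]
    }
    return AblationReport(
        seeds=list(seeds),
        fused=fused_scores,
        baseline=base_scores,
        deltas=deltas,
        mean_delta=mean_delta,
        config={
            "fused_variant": fused_variant,
            "epochs": epochs,
            "batch_size": batch_size,
            "lr": lr,
            "hidden_dim": hidden_dim,
            "n_total": n_total,
        },
    )
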