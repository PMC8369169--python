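import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from charner import EntityClass, Entity, LabeledSample, Lexicon
from charner.tagger import EncoderConfig, ModelConfig, Tagger

CLASSES = list(EntityClass)


def random_entities(rng: np.random.Generator, length: int, max_entities: int = 3):
    """Random non-overlapping entity spans over a sequence of ``length``."""
    entities = []
    pos = 0
    for _ in range(rng.integers(0, max_entities + 1)):
        if pos >= length:
            break
        start = int(rng.integers(pos, length))
        end = int(rng.integers(start + 1, length + 1))
        cls = CLASSES[int(rng.integers(len(CLASSES)))]
        entities.append(Entity(cls, start, end))
        pos = end
    return entities


@pytest.fixture
def tiny_corpus():
    return [
        LabeledSample("甲乙丙丁戊", ["B-herb", "I-herb", "O", "B-disease", "O"]),
        LabeledSample("丙甲乙", ["O", "B-symptom", "I-symptom"]),
        LabeledSample("丁丁", ["O", "O"]),
    ]


@pytest.fixture
def tiny_lexicon():
    return Lexicon.from_words({"甲乙", "丙丁戊", "丙甲乙"})


def tiny_tagger(tiny_corpus, tiny_lexicon, fusion="bilinear", encoder="bilstm",
                head="crf", seed=0):
    cfg = ModelConfig(
        fusion=fusion, head=head, d_char=4, d_word=4, d_model=4, n_heads=2,
        encoder=EncoderConfig(kind=encoder, hidden_dim=3),
    )
    return Tagger.build(tiny_corpus, tiny_lexicon, cfg, seed=seed)
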