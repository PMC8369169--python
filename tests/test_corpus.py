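"""Synthetic corpus generator: determinism, statistics, splitting."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from charner import EntityClass, LabeledSample, split
from charner.corpus import CorpusSpec, generate
from charner.schema import OUTSIDE


def small_spec(**kw):
    defaults = dict(
        n_samples={"publication": 40, "record": 40},
        seed=0,
    )
    defaults.update(kw)
    return CorpusSpec(**defaults)


def test_zero_rates_all_outside():
    spec = small_spec(entities_per_sample={"publication": 0.0, "record": 0.0})
    corpus = generate(spec)
    assert all(t == OUTSIDE for s in corpus.samples for t in s.tags)
    assert corpus.manifest["total_entities"] == 0


def test_same_seed_byte_identical():
    a = generate(small_spec(seed=11))
    b = generate(small_spec(seed=11))
    assert [s.chars for s in a.samples] == [s.chars for s in b.samples]
    assert [s.tags for s in a.samples] == [s.tags for s in b.samples]
    assert a.lexicon.words == b.lexicon.words
    assert a.manifest == b.manifest


def test_different_seed_differs():
    a = generate(small_spec(seed=1))
    b = generate(small_spec(seed=2))
    assert [s.chars for s in a.samples] != [s.chars for s in b.samples]


def test_every_entity_surface_in_lexicon():
    corpus = generate(small_spec(seed=3))
    for ents in corpus.entities:
        for e in ents:
            assert e.text in corpus.lexicon


def test_manifest_counts_match_recount():
    corpus = generate(small_spec(seed=4))
    recount = {
        style: {ec.value: 0 for ec in EntityClass} for style in ("publication", "record")
    }
    for ents, style in zip(corpus.entities, corpus.styles):
        for e in ents:
            recount[style][e.cls.value] += 1
    assert corpus.manifest["entity_counts"] == recount


def test_record_style_denser_than_publication():
    corpus = generate(small_spec(seed=5))
    def density(style):
        pairs = [
            (len(ents), 1)
            for ents, st in zip(corpus.entities, corpus.styles)
            if st == style
        ]
        return sum(k for k, _ in pairs) / len(pairs)
    assert density("record") > density("publication")


def test_max_length_respected_and_no_empty_samples():
    spec = small_spec(seed=6, max_len=60)
    corpus = generate(spec)
    assert all(0 < len(s) <= 60 for s in corpus.samples)


def test_samples_validate_against_schema():
    corpus = generate(small_spec(seed=7))
    for s in corpus.samples:
        LabeledSample(s.chars, s.tags)  # re-validates


def test_excessive_rate_rejected_naming_class():
    spec = small_spec(
        entities_per_sample={"publication": 0.5, "record": 50.0}, max_len=60
    )
    with pytest.raises(ValueError, match="clinical_manifestation"):
        generate(spec)


@pytest.fixture(scope="module")
def big():
    return generate(
        CorpusSpec(
            n_samples={"publication": 5000, "record": 5000},
            seed=123,
        )
    )


class TestStatistics:
    """Distributional checks on a 10,000-sample corpus."""

    def test_per_class_counts_within_3_sigma(self, big):
        spec = CorpusSpec()
        wsum = sum(spec.class_weights.values())
        for style, n in (("publication", 5000), ("record", 5000)):
            rate = spec.entities_per_sample[style]
            for ec in EntityClass:
                expected = n * rate * spec.class_weights[ec] / wsum
                sigma = np.sqrt(expected)
                got = big.manifest["entity_counts"][style][ec.value]
                assert abs(got - expected) < 3 * sigma, (style, ec, got, expected)

    def test_manifestation_length_distribution_chi2(self):
        """Vocabulary surface lengths are iid draws from the configured
        clinical-manifestation length distribution: chi-square GOF,
        Fisher-combined over four independent corpora, at alpha = 0.01."""
        spec = CorpusSpec()
        dist = spec.length_dists[EntityClass.CLINICAL_MANIFESTATION]
        keys = sorted(dist)
        total = sum(dist.values())
        pvals = []
        for seed in range(4):
            corpus = generate(
                CorpusSpec(
                    n_samples={"publication": 1, "record": 1},
                    vocab_per_class=600,
                    seed=seed,
                )
            )
            lengths = [len(s) for s in corpus.entity_vocabulary["clinical_manifestation"]]
            observed = np.array([lengths.count(k) for k in keys])
            expected = np.array([dist[k] / total * len(lengths) for k in keys])
            pvals.append(stats.chisquare(observed, expected).pvalue)
        stat = -2 * np.log(pvals).sum()
        combined_p = stats.chi2.sf(stat, df=2 * len(pvals))
        assert combined_p > 0.01, pvals

    def test_manifestations_often_longer_than_six(self, big):
        lengths = [
            e.end - e.start
            for ents in big.entities
            for e in ents
            if e.cls is EntityClass.CLINICAL_MANIFESTATION
        ]
        assert np.mean(np.array(lengths) > 6) > 0.4


class TestSplit:
    def test_headline_arithmetic(self):
        """94,380 samples at 6:2:2 -> (56,628, 18,876, 18,876)."""
        parts = split(list(range(94380)), (0.6, 0.2, 0.2), seed=0)
        assert tuple(len(p) for p in parts) == (56628, 18876, 18876)

    def test_ten_samples(self):
        parts = split(list(range(10)), (0.6, 0.2, 0.2), seed=0)
        assert tuple(len(p) for p in parts) == (6, 2, 2)

    def test_disjoint_cover_exhaustive_small_n(self):
        rng = np.random.default_rng(0)
        for n in range(1, 101):
            props = rng.dirichlet([2.0, 2.0, 2.0]) + 0.01
            parts = split(list(range(n)), props, seed=int(rng.integers(1000)))
            flat = [x for p in parts for x in p]
            assert len(flat) == n
            assert sorted(flat) == list(range(n))
            # remainder goes to train
            assert len(parts[0]) >= int(np.floor(props[0] / props.sum() * n))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split([], (0.6, 0.2, 0.2))

    def test_seeded_shuffle_reproducible(self):
        a = split(list(range(50)), seed=9)
        b = split(list(range(50)), seed=9)
        assert [list(x) for x in a] == [list(x) for x in b]
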