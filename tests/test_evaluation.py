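"""Evaluation protocols: classification, identification, entity-strict."""

import numpy as np
import pytest

from charner import (
    DEFAULT_SCHEMA,
    classification_metrics,
    entity_strict_metrics,
    f1_from_pr,
    identification_metrics,
)
from charner.evaluation import round1
from charner.schema import OUTSIDE

TAGS = DEFAULT_SCHEMA.tags
ENTITY_TAGS = [t for t in TAGS if t != OUTSIDE]


def random_tagseqs(rng, n_sentences, max_len=12):
    gold, pred = [], []
    for _ in range(n_sentences):
        L = int(rng.integers(1, max_len + 1))
        gold.append([TAGS[i] for i in rng.integers(0, len(TAGS), L)])
        pred.append([TAGS[i] for i in rng.integers(0, len(TAGS), L)])
    return gold, pred


class TestF1FromPr:
    @pytest.mark.parametrize(
        "p,r,f1",
        [
            (92.6, 96.7, 94.6),
            (60.8, 30.6, 40.7),
            (85.5, 88.1, 86.8),
        ],
    )
    def test_printed_pairs(self, p, r, f1):
        assert f1_from_pr(p, r) == f1

    @pytest.mark.parametrize("x", [0.1, 33.3, 50.0, 87.5, 100.0])
    def test_symmetry(self, x):
        assert f1_from_pr(x, x) == x

    def test_both_zero_convention(self):
        assert f1_from_pr(0.0, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            f1_from_pr(120.0, 10.0)

    def test_rounding_half_away_from_zero(self):
        assert round1(57.45) == 57.5
        assert round1(-57.45) == -57.5
        assert round1(71.94) == 71.9


class TestClassification:
    def test_perfect(self):
        gold = [["B-herb", "I-herb", "O"]]
        rep = classification_metrics(gold, gold)
        assert rep.as_percent() == {"precision": 100.0, "recall": 100.0, "f1": 100.0}

    def test_all_outside_predictions(self):
        gold = [["B-herb", "I-herb", "O", "O", "O"]]
        pred = [["O"] * 5]
        rep = classification_metrics(gold, pred)
        # micro over all positions = token accuracy (n-k)/n
        assert rep.micro.true_positive == 3
        assert rep.per_class["O"].recall == 1.0
        assert rep.per_class["B-herb"].recall == 0.0

    def test_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(0)
        gold, pred = random_tagseqs(rng, 20)
        rep = classification_metrics(gold, pred)
        # independent per-position tally
        n = sum(len(g) for g in gold)
        hits = sum(g == p for gs, ps in zip(gold, pred) for g, p in zip(gs, ps))
        assert rep.micro.true_positive == hits
        assert rep.micro.gold == rep.micro.predicted == n
        assert rep.precision == rep.recall == pytest.approx(hits / n)
        for tag in TAGS:
            tp = sum(
                g == p == tag for gs, ps in zip(gold, pred) for g, p in zip(gs, ps)
            )
            assert rep.per_class[tag].true_positive == tp

    def test_length_mismatch_names_sentence(self):
        with pytest.raises(ValueError, match="sentence 1"):
            classification_metrics([["O"], ["O", "O"]], [["O"], ["O"]])


class TestIdentification:
    def test_perfect(self):
        gold = [["B-herb", "I-herb", "O"]]
        assert identification_metrics(gold, gold).as_percent()["f1"] == 100.0

    def test_o_position_error_filtered(self):
        gold = [["B-herb", "I-herb", "O"]]
        pred = [["B-herb", "I-herb", "B-disease"]]
        ident = identification_metrics(gold, pred)
        clas = classification_metrics(gold, pred)
        assert ident.as_percent()["f1"] == 100.0
        assert clas.as_percent()["f1"] < 100.0

    def test_predicted_o_is_a_miss_not_a_prediction(self):
        gold = [["B-herb", "I-herb"]]
        pred = [["B-herb", "O"]]
        rep = identification_metrics(gold, pred)
        assert rep.micro.gold == 2
        assert rep.micro.predicted == 1
        assert rep.micro.true_positive == 1
        assert rep.precision == pytest.approx(1.0)
        assert rep.recall == pytest.approx(0.5)

    def test_invariant_to_changes_at_gold_o_positions(self):
        rng = np.random.default_rng(1)
        gold, pred = random_tagseqs(rng, 50)
        base = identification_metrics(gold, pred).to_dict()
        scrambled = [
            [
                TAGS[int(rng.integers(len(TAGS)))] if g == OUTSIDE else p
                for g, p in zip(gs, ps)
            ]
            for gs, ps in zip(gold, pred)
        ]
        assert identification_metrics(gold, scrambled).to_dict() == base

    def test_matches_position_filtering_oracle(self):
        rng = np.random.default_rng(2)
        gold, pred = random_tagseqs(rng, 50)
        rep = identification_metrics(gold, pred)
        g_flat = [g for gs in gold for g in gs]
        p_flat = [p for ps in pred for p in ps]
        keep = [i for i, g in enumerate(g_flat) if g != OUTSIDE]
        tp = sum(g_flat[i] == p_flat[i] for i in keep)
        n_pred = sum(p_flat[i] != OUTSIDE for i in keep)
        assert rep.micro.true_positive == tp
        assert rep.micro.predicted == n_pred
        assert rep.micro.gold == len(keep)


class TestEntityStrict:
    def test_perfect(self):
        gold = [["B-herb", "I-herb", "O", "B-disease"]]
        assert entity_strict_metrics(gold, gold).as_percent()["f1"] == 100.0

    def test_wrong_class_right_span_incorrect(self):
        gold = [["B-herb", "I-herb", "O"]]
        pred = [["B-disease", "I-disease", "O"]]
        rep = entity_strict_metrics(gold, pred)
        assert rep.micro.true_positive == 0
        assert rep.micro.predicted == 1
        assert rep.micro.gold == 1

    def test_matches_set_intersection_oracle(self):
        from charner import decode_tags

        rng = np.random.default_rng(3)
        gold, pred = random_tagseqs(rng, 40)
        rep = entity_strict_metrics(gold, pred)
        tp = npred = ngold = 0
        for gs, ps in zip(gold, pred):
            ge = {(e.cls, e.start, e.end) for e in decode_tags(gs)}
            pe = {(e.cls, e.start, e.end) for e in decode_tags(ps)}
            tp += len(ge & pe)
            npred += len(pe)
            ngold += len(ge)
        assert (rep.micro.true_positive, rep.micro.predicted, rep.micro.gold) == (
            tp, npred, ngold,
        )


def test_single_class_subsets():
    from charner import LabeledSample
    from charner.evaluation import single_class_subsets

    samples = [
        LabeledSample("ab", ["B-herb", "I-herb"]),
        LabeledSample("ab", ["B-herb", "B-disease"]),
        LabeledSample("ab", ["O", "O"]),
        LabeledSample("ab", ["B-disease", "O"]),
    ]
    subsets = single_class_subsets(samples)
    assert sorted(subsets) == ["disease", "herb"]
    assert len(subsets["herb"]) == 1 and len(subsets["disease"]) == 1
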