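"""Word-character attention fusion: weights, bilinear and multihead."""

import numpy as np
import pytest

from charner import (
    FusionParameters,
    LabeledSample,
    Lexicon,
    Vocabulary,
    attention_weights,
    fuse_bilinear,
    fuse_multihead,
    segment,
)


def make_params(d_char=4, d_word=4, n_heads=2, d_model=4, seed=0, chars="甲乙丙丁戊", words=("甲乙", "丙丁戊")):
    cv = Vocabulary(chars)
    wv = Vocabulary(words)
    return FusionParameters.init(cv, wv, d_char, d_word, n_heads, d_model, seed)


class TestAttentionWeights:
    def test_single_character_word(self):
        p = make_params()
        w = attention_weights(np.ones(4), np.ones((1, 4)), p.W_attn, p.b_attn)
        assert w.shape == (1,)
        assert w[0] == pytest.approx(1.0)

    def test_zero_matrix_uniform(self):
        w = attention_weights(np.ones(4), np.random.default_rng(0).normal(size=(3, 4)),
                              np.zeros((4, 4)), 7.5)
        np.testing.assert_allclose(w, np.full(3, 1 / 3), atol=1e-12)

    def test_matches_scalar_oracle(self):
        """Hand-computed softmax of the three bilinear scores, 1e-9."""
        rng = np.random.default_rng(42)
        wv = rng.normal(size=4)
        cvs = rng.normal(size=(3, 4))
        W = rng.normal(size=(4, 4))
        b = 0.3
        # independent scalar arithmetic
        scores = []
        for i in range(3):
            s = b
            for a in range(4):
                for c in range(4):
                    s += wv[a] * W[a, c] * cvs[i, c]
            scores.append(s)
        exps = [np.exp(s - max(scores)) for s in scores]
        expected = np.array(exps) / sum(exps)
        got = attention_weights(wv, cvs, W, b)
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_dimension_mismatch_names_shapes(self):
        p = make_params()
        with pytest.raises(ValueError, match="mismatch"):
            attention_weights(np.ones(3), np.ones((2, 4)), p.W_attn, 0.0)


def _sample_and_seg(chars="甲乙丙丁戊", words=("甲乙", "丙丁戊")):
    sample = LabeledSample(chars, ["O"] * len(chars))
    seg = segment(chars, Lexicon.from_words(words))
    return sample, seg


class TestBilinearFusion:
    def test_single_char_word_weight_one(self):
        p = make_params(words=())
        sample, seg = _sample_and_seg(words=())
        fused = fuse_bilinear(sample, seg, p)
        assert fused.attention == pytest.approx([1.0] * 5)
        # vector = 1.0 * concat(R_char, R_word)
        r_char = p.char_embedding[p.char_vocab.id("甲")] @ p.W_character
        r_word = p.word_embedding[p.word_vocab.id("甲")] @ p.W_word
        np.testing.assert_allclose(fused.vectors[0], np.concatenate([r_char, r_word]))

    def test_zero_embeddings_zero_output(self):
        p = make_params()
        p.char_embedding[:] = 0.0
        p.word_embedding[:] = 0.0
        sample, seg = _sample_and_seg()
        fused = fuse_bilinear(sample, seg, p)
        assert fused.vectors.shape == (5, 8)
        np.testing.assert_array_equal(fused.vectors, 0.0)

    def test_matches_independent_scalar_recomputation(self):
        """Step-by-step re-derivation of the fused vectors without any
        shared code paths (pure Python loops)."""
        p = make_params(seed=7)
        sample, seg = _sample_and_seg()
        fused = fuse_bilinear(sample, seg, p)
        for (s, e) in seg.spans:
            word = sample.chars[s:e]
            rw = p.word_embedding[p.word_vocab.id(word)] @ p.W_word
            rcs = [p.char_embedding[p.char_vocab.id(c)] @ p.W_character
                   for c in word]
            scores = [float(rw @ p.W_attn @ rc) + p.b_attn for rc in rcs]
            m = max(scores)
            exps = [np.exp(x - m) for x in scores]
            ws = [x / sum(exps) for x in exps]
            for i, rc in enumerate(rcs):
                expected = ws[i] * np.concatenate([rc, rw])
                np.testing.assert_allclose(fused.vectors[s + i], expected, atol=1e-12)
                assert fused.attention[s + i] == pytest.approx(ws[i])

    def test_weights_sum_to_one_per_span(self):
        p = make_params()
        sample, seg = _sample_and_seg()
        fused = fuse_bilinear(sample, seg, p)
        for (s, e) in seg.spans:
            assert fused.attention[s:e].sum() == pytest.approx(1.0)
            assert (fused.attention[s:e] > 0).all()

    def test_collapse_variant_sums_over_word(self):
        p = make_params()
        sample, seg = _sample_and_seg()
        per_char = fuse_bilinear(sample, seg, p)
        collapsed = fuse_bilinear(sample, seg, p, collapse=True)
        for (s, e) in seg.spans:
            total = per_char.vectors[s:e].sum(axis=0)
            for i in range(s, e):
                np.testing.assert_allclose(collapsed.vectors[i], total)

    def test_locality_outside_word(self):
        """Changing a character outside word w leaves w's vectors alone."""
        p = make_params()
        a, seg_a = _sample_and_seg("甲乙丙丁戊")
        b, seg_b = _sample_and_seg("甲乙戊丁戊")  # changed char at pos 2
        assert seg_a.spans[0] == seg_b.spans[0] == (0, 2)
        fa = fuse_bilinear(a, seg_a, p)
        fb = fuse_bilinear(b, seg_b, p)
        np.testing.assert_array_equal(fa.vectors[0:2], fb.vectors[0:2])

    def test_unknown_tokens_map_to_unk(self):
        p = make_params(chars="甲")
        sample, seg = _sample_and_seg("??", words=())
        fused = fuse_bilinear(sample, seg, p)  # no error
        assert fused.vectors.shape == (2, 8)

    def test_determinism(self):
        sample, seg = _sample_and_seg()
        a = fuse_bilinear(sample, seg, make_params(seed=5))
        b = fuse_bilinear(sample, seg, make_params(seed=5))
        np.testing.assert_array_equal(a.vectors, b.vectors)


class TestMultiheadFusion:
    def test_single_head_single_char_equals_value(self):
        p = make_params(n_heads=1, words=())
        sample, seg = _sample_and_seg("甲", words=())
        fused = fuse_multihead(sample, seg, p)
        rc = p.char_embedding[p.char_vocab.id("甲")] @ p.W_character
        v = rc @ p.W_v
        np.testing.assert_allclose(fused.vectors[0, 4:], v)
        np.testing.assert_allclose(fused.vectors[0, :4], rc)

    def test_equal_keys_uniform_attention_mean_value(self):
        p = make_params()
        p.char_embedding[:] = 0.3  # all characters identical -> equal keys
        sample, seg = _sample_and_seg()
        fused = fuse_multihead(sample, seg, p)
        for (s, e) in seg.spans:
            np.testing.assert_allclose(
                fused.attention[s:e], np.full(e - s, 1 / (e - s)), atol=1e-12
            )

    def test_matches_dense_head_by_head_oracle(self):
        """Brute-force per-head attention with explicit loops, 1e-6."""
        p = make_params(n_heads=2, d_model=4, seed=11)
        sample, seg = _sample_and_seg()
        fused = fuse_multihead(sample, seg, p)
        d_k = 2
        for (s, e) in seg.spans:
            word = sample.chars[s:e]
            rw = p.word_embedding[p.word_vocab.id(word)] @ p.W_word
            rcs = np.array([p.char_embedding[p.char_vocab.id(c)] @ p.W_character for c in word])
            q = rw @ p.W_q
            K = rcs @ p.W_k
            V = rcs @ p.W_v
            out = []
            for h in range(2):
                qh = q[h * d_k:(h + 1) * d_k]
                Kh = K[:, h * d_k:(h + 1) * d_k]
                Vh = V[:, h * d_k:(h + 1) * d_k]
                scores = np.array([float(qh @ k) for k in Kh]) / np.sqrt(d_k)
                w = np.exp(scores - scores.max())
                w = w / w.sum()
                out.append(sum(wi * vi for wi, vi in zip(w, Vh)))
            o = np.concatenate(out)
            for i in range(s, e):
                np.testing.assert_allclose(fused.vectors[i, 4:], o, atol=1e-6)

    def test_attention_sums_to_one_per_span(self):
        p = make_params()
        sample, seg = _sample_and_seg()
        fused = fuse_multihead(sample, seg, p)
        for (s, e) in seg.spans:
            assert fused.attention[s:e].sum() == pytest.approx(1.0)

    def test_bad_head_count_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            make_params(n_heads=3, d_model=4)


def test_plug_and_play_signature():
    """Both fusion variants consume (sample, seg, params) and emit one
    vector and one attention weight per character."""
    p = make_params()
    sample, seg = _sample_and_seg()
    for fn in (fuse_bilinear, fuse_multihead):
        fused = fn(sample, seg, p)
        assert fused.vectors.shape[0] == len(sample.chars)
        assert fused.attention.shape == (len(sample.chars),)
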