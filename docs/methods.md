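# Methods

## Problem setting

Traditional-Chinese-medicine (TCM) clinical text mentions five kinds of
entities — clinical manifestations (symptoms, including tongue and pulse
findings), syndromes, diseases, treatment laws (therapeutic principles)
and herbs.  Clinical-manifestation mentions are frequently long phrases
(often more than six characters), and Chinese has no word separators, so
a pipeline that segments first and tags segmented words inherits every
segmentation error and can split an entity mid-phrase.  `charner`
therefore tags at the character level — one BIO label per character over
an 11-tag vocabulary (B-/I- pairs for the five classes plus O) — and
re-introduces word and phrase semantics only on the representation side,
where errors cannot corrupt span boundaries.

## Word-character attention fusion

Characters and words are embedded separately and projected:

    R_word   = E_word[x_word]   · W_word
    R_char_i = E_char[x_char_i] · W_character

For every word span produced by the segmenter, a bilinear attention
score is computed for each of its `l` characters,

    s_i = R_word · W_attn · R_char_i + b_attn,    e = softmax(s),

so `e_i` measures how important character `i` is inside its word.  The
fused representation of character `i` is the gated concatenation
`e_i · [R_char_i, R_word]`.  Two readings of the combination step are
possible: a per-character gating (one fused vector per character) and a
literal weighted sum over the word (one vector per word).  The package
uses per-character gating as its default because the downstream tagger
needs one vector per character and the two coincide for single-character
words; the summed variant is available behind a `collapse` flag for
comparison.  Two further choices that the formulation leaves open were
fixed as: `b_attn` is a scalar, and the softmax normalizes within each
word span (consistent with reading the weights as within-word character
importance), never across the sentence.

The multihead variant replaces the bilinear score with standard
scaled-dot-product multihead attention masked to the word span: the word
representation is the query, the word's character representations are
keys and values, scores are scaled by 1/sqrt(d_k), and the attended
output is concatenated after the character's own representation.  Both
variants expose the same `(sample, segmentation, parameters) ->
FusedSequence` signature, so the tagger can consume either, or plain
character embeddings (the ablation baseline).

Word spans come from greedy forward maximum matching against a lexicon
(longest lexicon word at each position, else a singleton character).
This is deliberate: it is deterministic, dependency-free, and the
synthetic corpus emits a lexicon containing every gold entity surface,
so fusion can be studied under exact segmentation.  Segmentation informs
representations only; the label side never sees word boundaries.  Any
external segmenter can be substituted by supplying precomputed word
spans on the samples.

## Sequence labeler

Fused (or raw) character vectors feed an encoder (identity, LSTM, or
BiLSTM; default one BiLSTM layer), a linear emission projection, and
either a linear-chain CRF or a per-position softmax head.  The CRF uses
virtual START/STOP states; its likelihood is exact (forward recursion in
log space), gradients come from forward-backward marginals, and decoding
is Viterbi with ties broken toward the lower tag index.  Masked
transitions (into START, out of STOP) use a large finite negative
constant (−10⁴) rather than −∞ so forward-backward stays NaN-free.  BIO
transition legality is *not* hard-masked in the CRF: the model may emit
an I- without a B-, and the decoder's begin-repair (I-x after anything
other than B-x/I-x opens a new x entity) keeps evaluation total over raw
model output.  A config flag is the natural place to add hard
constraints; it is intentionally off so that evaluation sees what the
model actually learned.

All neural components — embeddings, fusion, LSTM, CRF — are implemented
directly in numpy (float64) with hand-derived backpropagation, verified
against central finite differences at 1e-4 in the test suite.  Batches
pad with a reserved PAD id; the LSTM carries state through padded steps,
so batched and one-by-one prediction are identical.  Training uses Adam
(default lr 1e-3; the desk-scale experiments use 1e-2, which converges
in a handful of epochs at these model sizes), batch size 32, and a
single master seed that fans out via numpy `SeedSequence` to parameter
initialization, shuffling and dropout.  Embeddings initialize uniform
(−0.1, 0.1); UNK and PAD ids are reserved at 0 and 1.  No encoder sizes
or optimizer settings are claims about any external experiment; they are
package defaults chosen for small-corpus CPU training.  Pretrained
contextual encoders are out of scope, but the encoder interface accepts
externally computed per-character vectors.

## Evaluation protocols

Three protocols are computed and always labeled explicitly:

* **classification** — micro P/R/F1 over all positions and all 11 tags
  (equal to token accuracy for single-label tagging); rewards calling
  non-entities O.
* **identification** — restrict both sequences to positions whose gold
  tag is an entity tag, then micro P/R/F1 over the 10 entity tags at
  those positions.  Predictions at gold-O positions are invisible by
  construction (property-tested).  A predicted O at a kept position
  counts against recall but is not a prediction.
* **entity_strict** — decode both sequences and require class, start and
  end to match exactly.

F1 is `2PR/(P+R)` with the convention F1 = 0 when P + R = 0.  Reported
percentages round half away from zero to one decimal (implemented in
decimal arithmetic so boundary cases round as printed numbers do).
A helper builds per-class evaluation subsets by keeping only samples
whose entities all belong to one class.

## Synthetic corpus

Real TCM NER corpora of this shape are not publicly deposited, so the
generator emulates their structure: two styles — entity-sparse
"publication" sentences (mean 0.8 mentions, long filler runs) and
entity-dense "record" sentences (mean 6 mentions, terse filler) — with
class frequencies dominated by clinical manifestations and with disease
rarest; clinical-manifestation lengths span 2–12 characters with most
mass above 6, herbs/diseases 2–4, syndromes/treatment laws 3–6.
Characters are CJK ideographs.  Each corpus first draws fixed per-class
vocabularies of entity surfaces (like recurring herb names and stock
phrases), then assembles sentences as filler/entity alternations;
mention counts are Poisson per style, fillers geometric, and sentences
cap at 120 characters.  Surface characters come from a class-specific
marker pool with probability 1 − `marker_noise` and from a shared
ambiguous pool otherwise; the emitted lexicon contains every entity
surface plus distractor words.  `marker_noise` is the learnability knob:
at 0.5 (the "high-signal" ablation setting) characters alone are
substantially ambiguous about the class while word identity — always
recoverable via the lexicon — is not, which is exactly the regime where
word-character fusion should help.  Generation is byte-identical under a
fixed seed; a spec whose rates imply sentences longer than the cap is
rejected up front, naming the worst-contributing class.

What the generator does **not** model: true TCM vocabulary and
morphology, segmentation ambiguity against an imperfect lexicon,
annotation noise, nested or discontinuous mentions, and document-level
context.  Passing tests therefore demonstrate correctness of the
machinery and the *direction* of the fusion effect under favorable,
controlled segmentation — not expected scores on real clinical records.

## Desk-scale experiment sizes

The paired ablation trains the bilinear-fusion BiLSTM-CRF and the
character-only BiLSTM-CRF on a 3,300-sentence high-signal corpus
(6:2:2 split → 1,980 train / 660 test), d_char = d_word = 12, hidden 24,
5 epochs, batch 32, lr 1e-2, three paired seeds; the reported quantity
is the mean fused-minus-baseline difference in identification F1.  The
overfit check memorizes 50 sentences to ≥ 99% token accuracy within 30
epochs.  These sizes were chosen so the full study runs in minutes on a
single CPU core while leaving the fusion effect clearly resolvable.

## Known limitations

* The greedy segmenter has no notion of ambiguity; on real text with an
  incomplete lexicon its errors propagate into the fusion module (never
  into the labels).
* The numpy implementation is single-threaded per batch and not meant
  for GPU-scale corpora.
* Flat, non-overlapping gold spans are assumed; BIOES and nested
  schemes are out of scope.
* Single-layer defaults; deeper stacks are supported but untuned.
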