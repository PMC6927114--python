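# Methods

## Problem and approach

Clinical named entity recognition (NER) in Chinese lacks the surface cues
available in Latin-script languages (capitalisation, whitespace), but Chinese
characters carry two internal feature channels that correlate with biomedical
vocabulary: the **primary radical**, which usually signals a character's
semantic field (the sickness radical 疒 dominates disease and symptom names,
the meat radical 月/⺼ dominates body-part names), and the **pinyin** of the
character, whose final is often inherited from a **phonetic radical** embedded
in the character. Characters built as semantic-radical + phonetic-radical are
*phono-semantic*; the package detects them, measures their prevalence in a
corpus, and exploits radical/pinyin features in a character-level neural
tagger.

## Phono-semantic detection

A character's composition is read from its Ideographic Description Sequence
(IDS): prefix notation over the IDC operators U+2FF0–U+2FFB (binary except the
two ternary operators U+2FF2–U+2FF3). Expanding every component's own IDS
recursively yields the nested component set; the checker walks it breadth
first and declares a character phono-semantic as soon as some component has a
reading whose final equals a final of the character (toneless comparison, over
the full cross product of readings on both sides, so polyphones match on any
syllable). The reported phonetic radical is the matching component at minimal
depth, ties broken by IDS order.

Numerical/structural choices:

- **max_depth defaults to 3** with a visited-set cycle guard. Unbounded
  recursion is unsafe on real IDS data (variant-form references can form
  cycles); every worked example in the shipped fixture needs depth ≤ 2.
- **All nested components are candidates**, including the primary radical
  itself. Excluding it would require knowing which component is semantic, which
  is exactly what the method does not assume.
- **Known limitation (by design):** phonetic radicals whose pronunciation has
  drifted entirely are missed — 脑 (nǎo) is not flagged because its phonetic
  component 凶 reads xiōng. This keeps measured phono-semantic percentages well
  below the ~90% rate etymologists report for the full character inventory.
- Percentage computations consider only symbols that are present in the
  character table and ideographic (CJK ranges or the private-use area used by
  the synthetic script); punctuation, Latin letters and digits are excluded
  from numerator and denominator. Token-level and unique (deduplicated)
  variants are provided.

## Pinyin segmentation

A syllable is split by longest-prefix match against the initial inventory
{b p m f d t n l g k h j q x zh ch sh r z c s y w}; the residue must belong to
a closed final inventory (the standard Mandarin finals plus the i-/u-/ü-medial
series), otherwise parsing fails loudly. `y`/`w` are treated as initials
rather than re-spelled medials — the convention under which tòng and yǒng
share the final "ong", which is the comparison the detection algorithm relies
on. Both diacritic and trailing-digit tone notations are accepted (`v` = ü,
digit 5 = neutral); tone is parsed into {0..4} but deliberately unused by all
feature models, since phonetic radicals rarely predict tone.

## Feature models and composition layer

Three feature models build the per-character embedding fed to the tagger, all
composing a left feature (always the primary-radical embedding) with a right
feature:

| model | right feature key |
|-------|-------------------|
| R+C   | the character itself |
| R+P   | toneless pinyin of the canonical (first) reading |
| R+F   | final of the canonical reading |

Composition is the affine map `E = LW·left + RW·right + b` with parameters
shared across positions (per-position weights could not generalise across
sentences) and trained jointly with the tagger. The **Sum variant** freezes
`LW = RW = I, b = 0`, i.e. plain vector addition; it exists to isolate the
contribution of learning the composition.

Feature tables are pretrained with skip-gram/negative sampling (implemented in
numpy) over *view streams*: the character stream mapped position-wise to
radicals, toneless pinyins or finals, so each feature vocabulary is trained on
contexts aligned with the character stream. Unknown positions become an UNK
token kept in the stream; a table's UNK vector is the mean of its trained
vectors. Tables are fine-tuned during tagger training by default (a flag turns
this off); the pretraining hyperparameters default to dimension 40, window 2,
one epoch, five negatives — small because the feature vocabularies (radicals,
pinyins, finals) are tiny compared to word vocabularies.

## Tagger

A single-layer bidirectional LSTM (100 hidden units per direction, Glorot
initialisation, forget-gate bias 1) produces contextual states; a linear layer
maps them to emission scores over the 11-tag BIO tagset (O plus B-/I- for BOD,
SYM, DIS, EXP, TRE); a linear-chain CRF with virtual START/STOP states scores
tag sequences. Training minimises mean negative log-likelihood with Adam
(lr 2e-3, batch 32, gradient-norm clip 5, 20 epochs); gradients are derived
manually (CRF forward–backward marginals, standard LSTM backprop), and padded
batch positions are masked out of every score and gradient.

- **Transition constraints.** During training, disallowed BIO transitions are
  pinned at −10⁴ — the normaliser is effectively restricted to valid paths but
  stays finite. Decoding applies hard −∞ constraints, so output is always
  BIO-valid; Viterbi ties break toward the lowest tag index for determinism.
- All randomness (init, batch order, negative sampling) flows from explicit
  seeds; training is bit-reproducible, and a saved checkpoint reloads to
  bit-identical decoding.

## Evaluation

Entity scoring is exact-match (type + span) with micro-averaged overall
P/R/F — chosen over macro because published "ALL" rows of this kind are not
the mean of the per-type rows. Strict BIO reading drops dangling I-X; a
lenient flag promotes them to B-X instead. Cross-validation shuffles with a
seed, splits into k near-equal folds (sizes differ by ≤1) and reports per-fold
metrics plus their arithmetic mean. The sectioning procedure computes the
token-level phono-semantic percentage per document and splits at the median:
strictly greater → section A, ties and below → section B (so a collection of
identical percentages puts everything in B). Radical-occurrence tables rank
primary radicals by their share of characters, either inside entity mentions
of each type or over the whole corpus.

## Synthetic data: what it emulates and what it does not

The generator builds a pseudo-script of private-use Unicode symbols so that no
real-script knowledge can leak into tests, while the pinyin machinery runs
unchanged on real syllables. It reproduces the two statistical structures the
method exploits:

1. **Phono-semantic structure.** Every character is `⿰ radical component`;
   exactly `round(p·n_chars)` characters copy their final from their phonetic
   component (the planted flag set is the ground truth returned alongside the
   table). Radical readings draw from a reserved final set disjoint from the
   character/component finals, so the checker's verdict provably equals the
   planted flag.
2. **Radical–entity-type affinity.** Each entity type is assigned an affine
   radical; an entity character of type t comes from the affine pool with
   probability α/(1+α) (α = 49 by default, i.e. 98% pool purity — strong
   affinity), background characters from the non-affine pool with the same
   mixture. Consecutive mentions are separated by at least one background
   character, as mentions in running text are separated by context
   characters. With weaker affinity the per-token contamination noise caps
   even an oracle tagger's achievable F well below what a sequence model
   should demonstrate, which would make learnability comparisons meaningless.

Default corpus conditions: 300-character inventory, 10 radicals, 60 phonetic
components, phono fraction 0.6, 2000 sentences of mean length 12 (Poisson),
one entity mention per sentence in expectation with lengths uniform on 1–3.

What the synthetic corpus does **not** emulate: real lexical statistics,
sentence semantics, segmentation ambiguity, annotation noise, or the long
tail of rare clinical symbols. Passing the learnability check shows the
pipeline can exploit radical/pinyin structure when it is present; it does not
predict absolute F-measures on clinical text.

The shuffled-feature control permutes radical and reading assignments across
the synthetic characters (independent permutations), preserving marginal
feature frequencies while destroying the feature–entity correlation; the gap
between the R+P tagger and this control is the desk-scale analogue of the
published model-comparison experiments.

## Degenerate inputs and edge policies

- Unknown characters resolve to a sentinel record (NONE radical, no readings,
  atomic IDS); feature extraction degrades to UNK embeddings and never raises
  mid-tagging.
- A character with no parsable reading is never phono-semantic (verdict
  carries a "no reading" note); components without readings are skipped for
  comparison but still expanded.
- Duplicate rows in a character TSV: last one wins with a warning; lenient
  loading skips malformed lines and counts them, strict loading raises.
- Empty sentences are rejected by the embedder and decoder; empty considered
  text is an error for percentage computations.

## Known limitations

- The Bi-LSTM-CRF is desk-scale CPU numpy: appropriate for the synthetic
  benchmark and small corpora, not for training on millions of sentences.
- Only character-based tagging is implemented; word-based NER is out of scope.
- No traditional/simplified normalisation and no etymological dictionary
  lookup; detection is purely the finals-matching rule over IDS components.
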