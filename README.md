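# phonosem

Graphical and phonetic character features for Chinese clinical named entity
recognition: phono-semantic character detection over nested Ideographic
Description Sequences, radical/pinyin feature embeddings with a learned
composition layer, and a character-based Bi-LSTM-CRF tagger.

## Who this is for

Researchers in Chinese biomedical text mining who want to (a) measure how
phono-semantic a corpus is, (b) build character embeddings from subcharacter
features — the primary (semantic) radical and the pinyin — instead of treating
characters as opaque code points, and (c) train and evaluate a character-level
clinical NER tagger over those features. Real clinical corpora are typically
licence-restricted, so the package also ships a synthetic pseudo-script
generator that reproduces the statistical structure the method exploits, with
known ground truth.

## The core ideas

**Phono-semantic detection.** Most Chinese characters combine a semantic
radical with a phonetic radical whose reading predicts the character's
pronunciation. Writing `Final(·)` for the final of a pinyin syllable and
`IDS(·)` for a character's Ideographic Description Sequence, character *c* is
flagged phono-semantic iff some nested component *r* of `IDS(c)` (expanded
recursively, depth ≤ 3 by default) satisfies

```
Final(pinyin(r)) = Final(pinyin(c))        (toneless, any reading pair)
```

So 病 (bìng) is detected via its component 丙 (bǐng, shared final *ing*), and
徒 (tú) only via the depth-2 component 土 (tǔ) inside 走 — while 脑 (nǎo) is
*not* detected because its phonetic component 凶 reads xiōng: pronunciation
drift is a documented blind spot of the rule.

**Composed feature embeddings.** The embedding of character *i* is

```
E_i = LW·LE_i + RW·RE_i + b
```

where `LE_i` is the pretrained primary-radical embedding and `RE_i` is, per
model, the character (R+C), toneless-pinyin (R+P) or final (R+F) embedding.
`LW`, `RW`, `b` are trained jointly with the tagger; freezing `LW = RW = I`,
`b = 0` gives the Sum variant (plain addition). Tables are pretrained with
skip-gram/negative sampling over view-mapped token streams.

**Tagger.** A Bi-LSTM produces emission scores over the 11-tag BIO tagset
(five clinical entity types: BOD, SYM, DIS, EXP, TRE); a linear-chain CRF with
START/STOP states and hard BIO constraints scores tag sequences; training
minimises the CRF negative log-likelihood, decoding is Viterbi. Evaluation is
exact-match entity-level micro P/R/F, plus k-fold cross-validation, median
sectioning by phono-semantic percentage, and ranked radical-occurrence tables.

## Worked example

```
$ python examples/check_characters.py
char  verdict  phonetic radical  final  depth
病    True     丙                ing    1
痨    True     劳                ao     1
痛    True     甬                ong    1
肝    True     干                an     1
胸    True     匈                iong   1
胃    False    -                -      -
心    False    -                -      -
害    False    -                -      -
脑    False    -                -      -
徒    True     土                u      2
```

Each row is the checker's verdict on a biomedical character from the shipped
demonstration table: the five phono-semantic characters are detected with
their phonetic radical and the shared final; the stomach/heart/harm/brain
characters are correctly rejected; 徒 is found only through a depth-2 nested
component.

```
$ python examples/train_synthetic_ner.py
inventory: 300 characters, 180 phono-semantic; corpus: 500 train / 150 test sentences
R+P model              P=0.813  R=0.894  F=0.851
shuffled control       P=0.214  R=0.085  F=0.122

gap attributable to radical/pinyin structure: +0.730 F
```

The R+P tagger reaches held-out entity F = 0.851 on a small synthetic corpus
whose entity types correlate with primary radicals; shuffling the
radical/pinyin assignments across characters (same marginal frequencies, no
correlation) collapses performance, showing the score comes from the feature
structure, not memorisation.

Other examples: `examples/segment_pinyin.py` (initial/final/tone
segmentation) and `examples/section_documents.py` (median sectioning and
radical-occurrence tables).

## Command line

A thin CLI wraps the library:

```
phonosem check --char 病 --explain          # phono-semantic verdict
phonosem synth --config synth.yaml --seed 7 --out data/
phonosem pretrain --corpus data/train.bio --db data/chars.tsv --view radical --out rad.vec
phonosem train --corpus data/train.bio --db data/chars.tsv --mode R+P --out model.npz
phonosem tag --model model.npz --db data/chars.tsv --in notes.txt
phonosem eval --gold gold.bio --pred pred.bio
phonosem section --db data/chars.tsv --docs records/
phonosem radstats --corpus data/train.bio --db data/chars.tsv --top 5
```

File formats are all plain text: 4-column character TSV
(`char  radical  readings  ids`), CoNLL-style BIO corpora (`char<TAB>tag`),
and word2vec text embeddings.

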