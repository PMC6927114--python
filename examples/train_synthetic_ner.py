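"""Train a Radical+Pinyin tagger on a small synthetic clinical corpus.

Generates a pseudo-script whose entity types correlate with primary
radicals, pretrains radical and pinyin embedding tables, trains the
Bi-LSTM-CRF and reports held-out entity-level F. A shuffled-feature
control shows how much of the score comes from the radical/pinyin
structure rather than memorisation. (Desk-scale sizes so the script
finishes in about a minute; see docs/methods.md for the full-scale
benchmark conditions.)
"""

from phonosem.nertagger import TrainConfig
from phonosem.pipeline import PretrainConfig, evaluate_tagger, train_tagger
from phonosem.synthetic import (SyntheticConfig, generate_chardb,
                                generate_corpus, shuffle_features)

cfg = SyntheticConfig(seed=1)
db, truth = generate_chardb(cfg)
train = generate_corpus(cfg, db, n_sentences=500, seed=11)
test = generate_corpus(cfg, db, n_sentences=150, seed=12)
print(f"inventory: {cfg.n_chars} characters, {sum(truth.values())} "
      f"phono-semantic; corpus: {len(train)} train / {len(test)} test sentences")


def fit(dbx, label):
    tagger = train_tagger(dbx, train, "R+P",
                          config=TrainConfig(epochs=12, seed=2),
                          pretrain=PretrainConfig(seed=2))
    rep = evaluate_tagger(tagger, test)
    p, r, f = rep.overall
    print(f"{label:<22} P={p:.3f}  R={r:.3f}  F={f:.3f}")
    return f


f_rp = fit(db, "R+P model")
f_ctrl = fit(shuffle_features(db, seed=5), "shuffled control")
print(f"\ngap attributable to radical/pinyin structure: {f_rp - f_ctrl:+.3f} F")
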