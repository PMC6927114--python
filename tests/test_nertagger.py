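"""CRF scoring, partition and decoding against brute-force enumeration,
plus training behaviour."""

import itertools

import numpy as np
import pytest

from phonosem.chardb import CharacterDB, CharacterRecord
from phonosem.corpus import TagSet, TaggedSentence, is_valid_bio
from phonosem.embeddings import (CompositionParams, EmbeddingTable,
                                 FeatureModel)
from phonosem.nertagger import CRFTagger, TrainConfig
from phonosem.pinyin import parse_pinyin


def _tiny_tagger(types=("DIS", "SYM"), hidden=5, seed=0, n_chars=6):
    db = CharacterDB()
    syllables = ["ba1", "bo2", "de1", "di4", "lu3", "ma1", "mi2", "su4"]
    for i in range(n_chars):
        ch = chr(ord("a") + i)
        db.add(CharacterRecord(ch, chr(0xE900 + i % 3),
                               (parse_pinyin(syllables[i % len(syllables)]),), ch))
    rads = [chr(0xE900 + i) for i in range(3)]
    pinyins = sorted({s[:-1] for s in syllables})
    left = EmbeddingTable.random(rads, 6, seed=seed + 1)
    right = EmbeddingTable.random(pinyins, 6, seed=seed + 2)
    fm = FeatureModel("R+P", left, right,
                      CompositionParams.random_init(6, 6, 6, seed=seed + 3), db)
    return CRFTagger(fm, TagSet(types=types), hidden=hidden, seed=seed)


def _brute_force(tagger, chars):
    """Exhaustive path enumeration over the raw transition scores."""
    ts = tagger.tagset
    K = ts.n_tags
    emis, _, _ = tagger._emissions_batch([list(chars)])
    emis = emis[0]
    trans = tagger.params["trans"]
    best_path, best_score, scores = None, -np.inf, []
    for path in itertools.product(range(K), repeat=len(chars)):
        s = trans[ts.start, path[0]] + emis[0, path[0]]
        for t in range(1, len(chars)):
            s += trans[path[t - 1], path[t]] + emis[t, path[t]]
        s += trans[path[-1], ts.stop]
        scores.append(s)
        if s > best_score:
            best_score, best_path = s, path
    m = max(scores)
    logZ = m + np.log(sum(np.exp(s - m) for s in scores))
    return best_path, best_score, logZ


def test_sequence_score_is_termwise_sum():
    tagger = _tiny_tagger()
    ts = tagger.tagset
    chars = list("abc")
    tags = ("B-DIS", "I-DIS", "O")
    emis, _, _ = tagger._emissions_batch([chars])
    emis = emis[0]
    trans = tagger.params["trans"]
    ids = [ts.index(t) for t in tags]
    expected = (trans[ts.start, ids[0]] + emis[0, ids[0]]
                + trans[ids[0], ids[1]] + emis[1, ids[1]]
                + trans[ids[1], ids[2]] + emis[2, ids[2]]
                + trans[ids[2], ts.stop])
    assert tagger.sequence_score(chars, tags) == pytest.approx(expected)


def test_length_one_sentence_score():
    tagger = _tiny_tagger()
    ts = tagger.tagset
    emis, _, _ = tagger._emissions_batch([["a"]])
    got = tagger.sequence_score(["a"], ("O",))
    expected = (tagger.params["trans"][ts.start, ts.index("O")]
                + emis[0, 0, ts.index("O")]
                + tagger.params["trans"][ts.index("O"), ts.stop])
    assert got == pytest.approx(expected)


def test_length_mismatch_raises():
    tagger = _tiny_tagger()
    with pytest.raises(ValueError):
        tagger.sequence_score(list("ab"), ("O",))


def test_partition_decode_match_brute_force_100_instances():
    """log_partition equals exhaustive logsumexp and viterbi equals the
    exhaustive argmax on 100 random small instances (n<=6, 7 tags)."""
    rng = np.random.default_rng(12)
    tagger = _tiny_tagger(types=("DIS", "SYM", "TRE"))  # 7 tags
    for trial in range(100):
        if trial % 10 == 0:  # fresh scorer every so often
            tagger = _tiny_tagger(types=("DIS", "SYM", "TRE"), seed=trial)
        n = int(rng.integers(1, 7))
        chars = [chr(ord("a") + int(rng.integers(6))) for _ in range(n)]
        bp, bs, blogZ = _brute_force(tagger, chars)
        assert tagger.log_partition(chars) == pytest.approx(blogZ, abs=1e-6)
        decoded = tagger.viterbi_decode(chars)
        score = tagger.sequence_score(decoded.chars, decoded.tags)
        assert score == pytest.approx(bs, abs=1e-6)
        assert is_valid_bio(decoded.tags, tagger.tagset)
        assert len(decoded) == n


def test_partition_upper_bounds_any_path_score():
    rng = np.random.default_rng(5)
    tagger = _tiny_tagger()
    ts = tagger.tagset
    for _ in range(20):
        n = int(rng.integers(1, 6))
        chars = [chr(ord("a") + int(rng.integers(6))) for _ in range(n)]
        tags = ["O"]
        for _ in range(n - 1):
            allowed = [t for t in ts.tags if ts.allowed[ts.index(tags[-1]), ts.index(t)]]
            tags.append(allowed[int(rng.integers(len(allowed)))])
        nll = tagger.log_partition(chars) - tagger.sequence_score(chars, tuple(tags))
        assert nll >= 0


def test_uniform_zero_scores_count_paths():
    tagger = _tiny_tagger()
    ts = tagger.tagset
    K = ts.n_tags
    tagger.params["W_out"][:] = 0
    tagger.params["b_out"][:] = 0
    tagger.params["trans"][:] = 0.0  # all transitions allowed, score 0
    n = 3
    assert tagger.log_partition(list("abc")) == pytest.approx(n * np.log(K))


def test_decode_respects_bio_constraints_even_when_emissions_favor_I():
    tagger = _tiny_tagger()
    ts = tagger.tagset
    tagger.params["W_out"][:] = 0
    # bias emissions heavily toward I-DIS everywhere
    tagger.params["b_out"][:] = 0
    tagger.params["b_out"][ts.index("I-DIS")] = 50.0
    decoded = tagger.viterbi_decode(list("abcd"))
    assert is_valid_bio(decoded.tags, tagger.tagset)
    assert decoded.tags[0] != "I-DIS"  # START cannot precede I-X


def test_training_descends_and_memorizes():
    """On a tiny separable corpus the loss decreases and, with enough
    epochs, the tagger reproduces the training annotation exactly."""
    tagger = _tiny_tagger(hidden=12, seed=3)
    corpus = [
        TaggedSentence(tuple("abc"), ("B-DIS", "I-DIS", "O")),
        TaggedSentence(tuple("cde"), ("O", "B-SYM", "O")),
        TaggedSentence(tuple("fa"), ("O", "B-DIS")),
        TaggedSentence(tuple("eb"), ("B-SYM", "O")),
    ] * 2
    trace = tagger.train(corpus, TrainConfig(hidden=12, epochs=60, lr=1e-2,
                                             batch_size=4, seed=1))
    assert trace[1] < trace[0]
    assert trace[-1] < trace[0]
    for sent in corpus:
        assert tagger.viterbi_decode(sent.chars).tags == sent.tags


def test_invalid_bio_corpus_rejected_before_training():
    tagger = _tiny_tagger()
    bad = [TaggedSentence(tuple("ab"), ("O", "I-DIS"))]
    with pytest.raises(ValueError):
        tagger.train(bad, TrainConfig(epochs=1))


def test_sum_variant_params_stay_frozen():
    db = CharacterDB()
    for i, ch in enumerate("abcd"):
        db.add(CharacterRecord(ch, chr(0xE900 + i % 2),
                               (parse_pinyin(["ba1", "lu3", "mi2", "de1"][i]),), ch))
    left = EmbeddingTable.random([chr(0xE900), chr(0xE901)], 6, seed=1)
    right = EmbeddingTable.random(["ba", "lu", "mi", "de"], 6, seed=2)
    fm = FeatureModel("R+P", left, right, CompositionParams.identity_sum(6), db)
    tagger = CRFTagger(fm, TagSet(types=("DIS",)), hidden=8, seed=0)
    corpus = [TaggedSentence(tuple("ab"), ("B-DIS", "O"))] * 4
    tagger.train(corpus, TrainConfig(hidden=8, epochs=5, seed=2))
    assert np.array_equal(fm.params.LW, np.eye(6))
    assert np.array_equal(fm.params.RW, np.eye(6))
    assert np.all(fm.params.b == 0)


def test_fixed_seed_reproducible_training():
    def run():
        tagger = _tiny_tagger(hidden=6, seed=2)
        corpus = [TaggedSentence(tuple("abc"), ("B-DIS", "I-DIS", "O"))] * 3
        return tagger.train(corpus, TrainConfig(hidden=6, epochs=3, seed=5))
    assert run() == run()


def test_checkpoint_roundtrip_decode_identical(tmp_path):
    tagger = _tiny_tagger(hidden=7, seed=4)
    corpus = [TaggedSentence(tuple("abc"), ("B-DIS", "I-DIS", "O"))] * 3
    tagger.train(corpus, TrainConfig(hidden=7, epochs=2, seed=6))
    path = tmp_path / "model.npz"
    tagger.save(path)
    # rebuild the db identically to the fixture used by _tiny_tagger
    db = tagger.feature_model.db
    again = CRFTagger.load(path, db)
    for chars in (list("abc"), list("fedcba")):
        assert again.viterbi_decode(chars).tags == tagger.viterbi_decode(chars).tags
        assert again.log_partition(chars) == pytest.approx(
            tagger.log_partition(chars), abs=1e-9)
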