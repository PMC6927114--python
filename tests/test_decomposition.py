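"""IDS parsing and phono-semantic detection, checked against brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phonosem.chardb import CharacterDB, CharacterRecord
from phonosem.decomposition import (IDSError, parse_ids, nested_components,
                                    phono_semantic_check,
                                    phono_semantic_percentage)
from phonosem.pinyin import parse_pinyin

# ---------- IDS parsing ----------


def test_single_symbol_is_leaf():
    t = parse_ids("水")
    assert t.op is None and t.leaf == "水" and t.serialize() == "水"


def test_binary_operator_two_leaves():
    t = parse_ids("⿰月干")
    assert t.op == "⿰" and len(t.children) == 2
    assert t.leaves() == ["月", "干"]


def test_ternary_operator_three_children():
    t = parse_ids("⿲月干水")
    assert len(t.children) == 3


def test_nested_roundtrip():
    s = "⿰彳⿱土龰"
    t = parse_ids(s)
    assert t.serialize() == s
    assert t.leaves() == ["彳", "土", "龰"]


@pytest.mark.parametrize("bad", ["", "⿰月", "⿰", "⿲月干", "⿰月干水"])
def test_malformed_ids_rejected(bad):
    with pytest.raises(IDSError):
        parse_ids(bad)


_COMPONENTS = st.sampled_from(list("月干水木彳土"))


@st.composite
def ids_trees(draw, depth=0):
    if depth >= 3 or draw(st.booleans()):
        return draw(_COMPONENTS)
    op = draw(st.sampled_from(["⿰", "⿱", "⿲", "⿳", "⿸"]))
    arity = 3 if op in ("⿲", "⿳") else 2
    return op + "".join(draw(ids_trees(depth=depth + 1)) for _ in range(arity))


@settings(max_examples=150, deadline=None)
@given(ids_trees())
def test_parse_serialize_roundtrip_random(s):
    assert parse_ids(s).serialize() == s


# ---------- nested components ----------


def _mini_db(rows):
    db = CharacterDB()
    for char, radical, readings, ids in rows:
        db.add(CharacterRecord(char, radical,
                               tuple(parse_pinyin(r) for r in readings.split(";")),
                               ids))
    return db


def test_atomic_char_has_no_components(demo_db):
    assert nested_components(demo_db, "心") == []


def test_tu_character_depth_two_components(demo_db):
    comps = nested_components(demo_db, "徒", max_depth=2)
    assert ("彳", 1) in comps and ("走", 1) in comps
    assert ("土", 2) in comps


def test_cycle_guard_terminates():
    db = _mini_db([("A", "A", "ma1", "⿰BC"), ("B", "B", "mo1", "⿰AC"),
                   ("C", "C", "me1", "C")])
    comps = nested_components(db, "A", max_depth=10)
    assert sorted(c for c, _ in comps) == ["B", "C"]


# ---------- phono-semantic check: worked examples ----------

BIOMEDICAL_VERDICTS = [
    ("病", True, "丙", "ing"),   # illness: bìng ~ bǐng
    ("痨", True, "劳", "ao"),    # tuberculosis: láo ~ láo
    ("痛", True, "甬", "ong"),   # pain: tòng ~ yǒng
    ("肝", True, "干", "an"),    # liver: gān ~ gàn (second reading)
    ("胸", True, "匈", "iong"),  # chest: xiōng ~ xiōng
    ("胃", False, None, None),   # stomach: wèi vs tián
    ("心", False, None, None),   # heart: atomic
    ("害", False, None, None),   # harm: hài vs fēng/kǒu
    ("脑", False, None, None),   # brain: nǎo vs xiōng — final mismatch
]


@pytest.mark.parametrize("char,expected,radical,final", BIOMEDICAL_VERDICTS)
def test_biomedical_character_verdicts(demo_db, char, expected, radical, final):
    v = phono_semantic_check(demo_db, char)
    assert v.is_phono_semantic is expected
    assert v.phonetic_radical == radical
    assert v.matched_final == final


def test_tu_needs_nested_expansion(demo_db):
    """The phonetic radical of 徒 (tú) is the depth-2 component 土 (tǔ)."""
    assert not phono_semantic_check(demo_db, "徒", max_depth=1).is_phono_semantic
    v = phono_semantic_check(demo_db, "徒", max_depth=2)
    assert v.is_phono_semantic and v.phonetic_radical == "土"
    assert v.matched_final == "u" and v.depth == 2


def test_no_reading_gives_false_with_note(demo_db):
    v = phono_semantic_check(demo_db, "Q")
    assert not v.is_phono_semantic and v.note == "no reading"


# ---------- brute-force oracle ----------


def _random_db(rng, n_chars=30, max_depth_gen=4):
    finals = ["a", "an", "ang", "ou", "i", "ing", "u", "e"]
    initials = ["b", "d", "l", "m", "s", ""]
    syms = [chr(0xF100 + i) for i in range(n_chars)]
    db = CharacterDB()
    for i, s in enumerate(syms):
        reading = (initials[rng.integers(len(initials))]
                   + finals[rng.integers(len(finals))]
                   + str(rng.integers(1, 5)))
        if rng.random() < 0.45 or i < 2:
            ids = s
        else:
            op = ["⿰", "⿱", "⿲"][rng.integers(3)]
            arity = 3 if op == "⿲" else 2
            comps = [syms[rng.integers(n_chars)] for _ in range(arity)]
            ids = op + "".join(comps)
        db.add(CharacterRecord(s, s, (parse_pinyin(reading),), ids))
    return db, syms


def _oracle_components(db, char, max_depth):
    """Exhaustive nested expansion, independent of the BFS implementation."""
    out = {}

    def expand(sym, depth):
        if depth > max_depth:
            return
        rec = db.lookup(sym)
        if rec.is_atomic:
            return
        for comp in parse_ids(rec.ids).leaves():
            if comp == char or comp in out and out[comp] <= depth:
                continue
            if comp not in out or depth < out[comp]:
                out[comp] = depth
                expand(comp, depth + 1)

    expand(char, 1)
    return out


def _oracle_verdict(db, char, max_depth):
    rec = db.lookup(char)
    if not rec.readings:
        return False
    finals = {p.final for p in rec.readings}
    for comp in _oracle_components(db, char, max_depth):
        for r in db.lookup(comp).readings:
            if r.final in finals:
                return True
    return False


def test_agrees_with_exhaustive_oracle_on_random_dbs():
    """Checker vs exhaustive expansion + all-reading-pairs comparison on
    200 random fixture databases."""
    rng = np.random.default_rng(42)
    agree = total = 0
    for _ in range(200):
        db, syms = _random_db(rng)
        depth = int(rng.integers(1, 5))
        for s in syms:
            total += 1
            agree += (phono_semantic_check(db, s, max_depth=depth).is_phono_semantic
                      == _oracle_verdict(db, s, depth))
    assert agree == total


def test_depth_monotonicity_and_atomic_never_phono():
    rng = np.random.default_rng(7)
    for _ in range(30):
        db, syms = _random_db(rng)
        for s in syms:
            verdicts = [phono_semantic_check(db, s, max_depth=d).is_phono_semantic
                        for d in (1, 2, 3, 4)]
            # once True, stays True at greater depth
            assert all(b or not a for a, b in zip(verdicts, verdicts[1:]))
            if db.lookup(s).is_atomic:
                assert not any(verdicts)


# ---------- percentages ----------


def test_percentage_token_vs_unique(demo_db):
    # 病 is phono-semantic, 胃 is not
    assert phono_semantic_percentage(demo_db, "病病胃胃") == 50.0
    assert phono_semantic_percentage(demo_db, "病病病胃", unique=False) == 75.0
    assert phono_semantic_percentage(demo_db, "病病病胃", unique=True) == 50.0


def test_percentage_skips_non_db_symbols(demo_db):
    assert phono_semantic_percentage(demo_db, "病, x3 胃!") == 50.0
    with pytest.raises(ValueError):
        phono_semantic_percentage(demo_db, ", x3 !")


def test_percentage_matches_planted_fraction():
    from phonosem.synthetic import SyntheticConfig, generate_chardb
    cfg = SyntheticConfig(n_chars=500, phono_fraction=0.4, seed=5)
    db, truth = generate_chardb(cfg)
    rng = np.random.default_rng(1)
    chars = sorted(truth)
    text = "".join(chars[i] for i in rng.integers(0, len(chars), size=10_000))
    pct = phono_semantic_percentage(db, text)
    assert abs(pct - 40.0) < 3.0
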