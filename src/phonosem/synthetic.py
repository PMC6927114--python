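"""Synthetic pseudo-script generator for end-to-end testing.

Real clinical NER corpora for Chinese are licence-restricted, so the
package ships a generator that reproduces the two statistical structures
the method exploits, with known ground truth:

* a character inventory in which a controllable fraction ``p`` of
  characters share a pinyin final with their embedded phonetic
  component (phono-semantic by construction), and
* annotated sentences in which each entity type draws its characters
  from a pool sharing that type's affine primary radical, at a
  controllable affinity strength ``alpha``.

Synthetic characters are distinct Unicode private-use symbols, so no
real-script knowledge leaks into tests; their pinyin readings are drawn
from the real initial/final inventories so the pinyin machinery is
exercised unchanged.  Radical readings use a reserved final set disjoint
from the character/component final pool, so a character is
phono-semantic exactly when the generator made it so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chardb import CharacterDB, CharacterRecord
from .corpus import ENTITY_TYPES, TaggedSentence
from .pinyin import parse_pinyin

__all__ = ["SyntheticConfig", "generate_chardb", "generate_corpus",
           "generate_documents", "shuffle_features"]

# private-use code points: characters, radicals, phonetic components
_CHAR_BASE = 0xE000
_RADICAL_BASE = 0xE900
_PHONETIC_BASE = 0xEA00

#: finals available to characters and phonetic components
_CHAR_FINALS = ("a", "ai", "an", "ang", "ao", "ou", "e", "ei", "en",
                "eng", "i", "ing", "u", "ong")
#: reserved finals for radicals — disjoint from _CHAR_FINALS
_RADICAL_FINALS = ("ia", "iao", "uo", "uan", "un", "ue")
_INITIALS = ("b", "d", "g", "l", "m", "s")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic pseudo-script.

    ``phono_fraction`` is the probability that a generated character
    copies its final from its phonetic component.  ``alpha`` is the
    radical–entity-type affinity strength: an entity character of type t
    comes from the pool sharing t's affine radical with probability
    alpha/(1+alpha) (alpha=0 → uniform over the whole inventory).
    ``entity_density`` is the expected number of entity mentions per
    sentence; mention lengths are uniform on 1..3 characters.
    """

    n_chars: int = 300
    n_radicals: int = 10
    n_phonetic_pool: int = 60
    phono_fraction: float = 0.6
    finals_pool: tuple[str, ...] = _CHAR_FINALS
    entity_types: tuple[str, ...] = ENTITY_TYPES
    alpha: float = 49.0
    n_sentences: int = 2000
    mean_sentence_length: float = 12.0
    entity_density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phono_fraction <= 1.0:
            raise ValueError("phono_fraction must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not self.finals_pool:
            raise ValueError("finals pool must be non-empty")
        if self.n_radicals < len(self.entity_types) + 1:
            raise ValueError("need more radicals than entity types "
                             "(one affine radical per type plus background)")


def _syllable(rng, finals, taken: set | None = None) -> str:
    """Random numbered-pinyin syllable, optionally avoiding finals in *taken*."""
    pool = [f for f in finals if taken is None or f not in taken]
    final = pool[rng.integers(len(pool))]
    initial = _INITIALS[rng.integers(len(_INITIALS))]
    tone = int(rng.integers(1, 5))
    return f"{initial}{final}{tone}"


def generate_chardb(cfg: SyntheticConfig) -> tuple[CharacterDB, dict[str, bool]]:
    """Build the pseudo-script inventory; returns (db, truth flags).

    Every character is ``⿰ radical phonetic-component``; with
    probability ``phono_fraction`` its reading's final is copied from
    the component (phono-semantic by construction), otherwise drawn to
    differ from it.
    """
    rng = np.random.default_rng(cfg.seed)
    db = CharacterDB()

    radicals = [chr(_RADICAL_BASE + i) for i in range(cfg.n_radicals)]
    for r in radicals:
        db.add(CharacterRecord(r, r, (parse_pinyin(_syllable(rng, _RADICAL_FINALS)),), r))

    phonetics = [chr(_PHONETIC_BASE + i) for i in range(cfg.n_phonetic_pool)]
    for q in phonetics:
        db.add(CharacterRecord(q, q, (parse_pinyin(_syllable(rng, cfg.finals_pool)),), q))

    # plant exactly round(p * n) phono-semantic characters
    n_phono = int(round(cfg.phono_fraction * cfg.n_chars))
    phono_slots = set(rng.permutation(cfg.n_chars)[:n_phono].tolist())
    truth: dict[str, bool] = {}
    for i in range(cfg.n_chars):
        ch = chr(_CHAR_BASE + i)
        radical = radicals[rng.integers(len(radicals))]
        phonetic = phonetics[rng.integers(len(phonetics))]
        comp_final = db.lookup(phonetic).canonical_reading.final
        is_phono = i in phono_slots
        if is_phono:
            initial = _INITIALS[rng.integers(len(_INITIALS))]
            tone = int(rng.integers(1, 5))
            reading = f"{initial}{comp_final}{tone}"
        else:
            reading = _syllable(rng, cfg.finals_pool, taken={comp_final})
        ids = "⿰" + radical + phonetic
        db.add(CharacterRecord(ch, radical, (parse_pinyin(reading),), ids))
        truth[ch] = is_phono
    return db, truth


def _char_pools(cfg: SyntheticConfig, db: CharacterDB):
    """Partition characters by radical into per-type affine pools and a
    background pool (characters whose radical is affine to no type)."""
    radicals = [chr(_RADICAL_BASE + i) for i in range(cfg.n_radicals)]
    affine = {t: radicals[i] for i, t in enumerate(cfg.entity_types)}
    chars = [chr(_CHAR_BASE + i) for i in range(cfg.n_chars)]
    pools = {t: [c for c in chars if db.lookup(c).primary_radical == affine[t]]
             for t in cfg.entity_types}
    affine_set = set(affine.values())
    background = [c for c in chars
                  if db.lookup(c).primary_radical not in affine_set]
    return chars, pools, background


def generate_corpus(cfg: SyntheticConfig, db: CharacterDB,
                    n_sentences: int | None = None,
                    seed: int | None = None) -> list[TaggedSentence]:
    """Annotated BIO sentences with radical–type correlated entities.

    Entity characters of type t come from t's affine-radical pool with
    probability alpha/(1+alpha), else uniformly from the inventory;
    background positions draw from the non-affine pool with the same
    mixture.  Seeded and reproducible.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n = cfg.n_sentences if n_sentences is None else n_sentences
    chars, pools, background = _char_pools(cfg, db)
    p_pool = cfg.alpha / (1.0 + cfg.alpha)

    def draw(pool) -> str:
        if pool and rng.random() < p_pool:
            return pool[rng.integers(len(pool))]
        return chars[rng.integers(len(chars))]

    sentences = []
    for _ in range(n):
        length = max(3, int(rng.poisson(cfg.mean_sentence_length)))
        n_ent = int(rng.poisson(cfg.entity_density))
        spans = []  # (type, length)
        used = 0
        for _ in range(n_ent):
            elen = int(rng.integers(1, 4))
            if used + elen + len(spans) + 1 > length:
                break
            etype = cfg.entity_types[rng.integers(len(cfg.entity_types))]
            spans.append((etype, elen))
            used += elen
        n_background = length - used
        # >=1 background character between consecutive entities, as in
        # running text where mentions are separated by context characters
        gaps = np.zeros(len(spans) + 1, dtype=int)
        if len(spans) > 1:
            gaps[1:-1] = 1
        for _ in range(n_background - int(gaps.sum())):
            gaps[rng.integers(len(gaps))] += 1
        out_chars: list[str] = []
        out_tags: list[str] = []
        for g, span in zip(gaps, list(spans) + [None]):
            for _ in range(g):
                out_chars.append(draw(background))
                out_tags.append("O")
            if span is not None:
                etype, elen = span
                for j in range(elen):
                    out_chars.append(draw(pools[etype]))
                    out_tags.append(("B-" if j == 0 else "I-") + etype)
        sentences.append(TaggedSentence(tuple(out_chars), tuple(out_tags)))
    return sentences


def generate_documents(db: CharacterDB, truth: dict[str, bool],
                       rates: list[float], docs_per_rate: int = 10,
                       doc_length: int = 400, seed: int = 0
                       ) -> tuple[list[str], list[int]]:
    """Documents with planted phono-semantic token rates.

    For each rate r, each token is phono-semantic with probability r.
    Returns (documents, rate index per document) in shuffled order.
    """
    rng = np.random.default_rng(seed)
    phono = sorted(c for c, flag in truth.items() if flag)
    plain = sorted(c for c, flag in truth.items() if not flag)
    if not phono or not plain:
        raise ValueError("need both phono-semantic and plain characters")
    docs, labels = [], []
    for ri, rate in enumerate(rates):
        for _ in range(docs_per_rate):
            toks = [phono[rng.integers(len(phono))] if rng.random() < rate
                    else plain[rng.integers(len(plain))]
                    for _ in range(doc_length)]
            docs.append("".join(toks))
            labels.append(ri)
    order = rng.permutation(len(docs))
    return [docs[i] for i in order], [labels[i] for i in order]


def shuffle_features(db: CharacterDB, seed: int = 0) -> CharacterDB:
    """Control inventory: permute radical and reading assignments across
    the synthetic characters, breaking every feature–entity correlation
    while keeping marginal feature frequencies."""
    rng = np.random.default_rng(seed)
    out = CharacterDB()
    char_recs = []
    for ch, rec in db.records.items():
        if _CHAR_BASE <= ord(ch) < _CHAR_BASE + 0x900:
            char_recs.append(rec)
        else:
            out.add(rec)
    rad_perm = rng.permutation(len(char_recs))
    read_perm = rng.permutation(len(char_recs))
    for i, rec in enumerate(char_recs):
        out.add(CharacterRecord(
            rec.char,
            char_recs[rad_perm[i]].primary_radical,
            char_recs[read_perm[i]].readings,
            rec.ids))
    return out
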