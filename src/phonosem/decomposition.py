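"""IDS parsing, nested component enumeration, phono-semantic detection.

An Ideographic Description Sequence (IDS) writes a CJK character's
composition in prefix notation: an Ideographic Description Character
(IDC, U+2FF0–U+2FFB) followed by two or three components, each of which
may itself be an IDS.  Expanding every component's own IDS recursively
yields the character's *nested* components.

A character is taken to be phono-semantic when one of its nested
components — a candidate phonetic radical — has a pinyin reading whose
final equals a final of the character itself.  The comparison is
toneless and runs over the cross-product of readings on both sides, so
polyphones match on any of their syllables.  This deliberately misses
phonetic radicals whose pronunciation drifted entirely (e.g. a character
read nǎo whose phonetic component is read xiōng), and it accepts a match
at any nesting depth: a character read tú whose depth-1 components read
chì and zǒu only reveals its phonetic radical tǔ one level further down.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .chardb import CharacterDB, is_idc, is_ideograph

__all__ = ["IDSTree", "IDSError", "PhonoSemanticVerdict", "parse_ids",
           "nested_components", "phono_semantic_check",
           "phono_semantic_percentage", "DEFAULT_MAX_DEPTH"]

DEFAULT_MAX_DEPTH = 3

_TERNARY = {chr(0x2FF2), chr(0x2FF3)}


class IDSError(ValueError):
    """Malformed Ideographic Description Sequence."""


@dataclass(frozen=True)
class IDSTree:
    """Prefix-notation parse of an IDS; a leaf holds one component symbol."""

    op: str | None  # IDC operator, or None for a leaf
    children: tuple["IDSTree", ...] = ()
    leaf: str | None = None

    def serialize(self) -> str:
        if self.op is None:
            return self.leaf
        return self.op + "".join(c.serialize() for c in self.children)

    def leaves(self) -> list[str]:
        """Component symbols in left-to-right (IDS) order."""
        if self.op is None:
            return [self.leaf]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def parse_ids(ids: str) -> IDSTree:
    """Parse an IDS string; a bare symbol parses to a leaf.

    Raises :class:`IDSError` with the offending position for a truncated
    sequence or trailing garbage.
    """
    if not ids:
        raise IDSError("empty IDS string")

    def parse_at(i: int) -> tuple[IDSTree, int]:
        if i >= len(ids):
            raise IDSError(f"truncated IDS {ids!r}: operand missing at position {i}")
        ch = ids[i]
        if is_idc(ch):
            arity = 3 if ch in _TERNARY else 2
            children = []
            j = i + 1
            for _ in range(arity):
                child, j = parse_at(j)
                children.append(child)
            return IDSTree(op=ch, children=tuple(children)), j
        return IDSTree(op=None, leaf=ch), i + 1

    tree, end = parse_at(0)
    if end != len(ids):
        raise IDSError(f"trailing garbage in IDS {ids!r} at position {end}")
    return tree


@dataclass(frozen=True)
class PhonoSemanticVerdict:
    """Outcome of the phono-semantic check for one character."""

    char: str
    is_phono_semantic: bool
    phonetic_radical: str | None = None
    matched_final: str | None = None
    depth: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        consistent = (self.is_phono_semantic
                      == (self.phonetic_radical is not None)
                      == (self.matched_final is not None))
        if not consistent:
            raise ValueError("inconsistent verdict fields")


def nested_components(db: CharacterDB, char: str,
                      max_depth: int = DEFAULT_MAX_DEPTH) -> list[tuple[str, int]]:
    """Breadth-first list of (component, depth) for every nested component.

    A component at depth d is expanded to depth d+1 through its own IDS in
    the database; components absent from the database, or whose IDS equals
    themselves, terminate recursion.  The character itself is excluded;
    duplicates are kept once at their minimal depth; cycles are broken by
    a visited set.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    rec = db.lookup(char)
    out: list[tuple[str, int]] = []
    visited = {char}
    queue: deque[tuple[str, int]] = deque()
    if not rec.is_atomic:
        for comp in parse_ids(rec.ids).leaves():
            queue.append((comp, 1))
    while queue:
        comp, depth = queue.popleft()
        if comp in visited:
            continue
        visited.add(comp)
        out.append((comp, depth))
        if depth >= max_depth:
            continue
        comp_rec = db.lookup(comp)
        if not comp_rec.is_atomic:
            for sub in parse_ids(comp_rec.ids).leaves():
                queue.append((sub, depth + 1))
    return out


def phono_semantic_check(db: CharacterDB, char: str,
                         max_depth: int = DEFAULT_MAX_DEPTH) -> PhonoSemanticVerdict:
    """Decide whether *char* is phono-semantic.

    True iff some nested component (depth <= max_depth) has a reading
    whose final equals a final of some reading of *char*.  The phonetic
    radical reported is the matching component at minimal depth, ties
    broken by component order within the IDS (breadth-first order).
    Components with no known reading are skipped for comparison but
    still expanded.
    """
    rec = db.lookup(char)
    if not rec.readings:
        return PhonoSemanticVerdict(char=char, is_phono_semantic=False,
                                    note="no reading")
    char_finals = {p.final for p in rec.readings}
    for comp, depth in nested_components(db, char, max_depth=max_depth):
        comp_rec = db.lookup(comp)
        for reading in comp_rec.readings:
            if reading.final in char_finals:
                return PhonoSemanticVerdict(
                    char=char, is_phono_semantic=True,
                    phonetic_radical=comp, matched_final=reading.final,
                    depth=depth)
    return PhonoSemanticVerdict(char=char, is_phono_semantic=False)


def phono_semantic_percentage(db: CharacterDB, text, unique: bool = False,
                              max_depth: int = DEFAULT_MAX_DEPTH) -> float:
    """Percentage of phono-semantic characters in *text*.

    Only symbols present in the database and ideographic (per
    :func:`~phonosem.chardb.is_ideograph`) enter numerator and
    denominator; punctuation, Latin letters, digits and unknown symbols
    are skipped.  ``unique=True`` computes the percentage over the
    deduplicated character set instead of token positions.
    """
    considered = [ch for ch in text if ch in db and is_ideograph(ch)]
    if not considered:
        raise ValueError("no considered characters in text")
    if unique:
        considered = sorted(set(considered))
    cache: dict[str, bool] = {}
    hits = 0
    for ch in considered:
        if ch not in cache:
            cache[ch] = phono_semantic_check(db, ch, max_depth=max_depth).is_phono_semantic
        hits += cache[ch]
    return 100.0 * hits / len(considered)
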