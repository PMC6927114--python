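"""Character knowledge base: primary radical, pinyin readings, IDS.

Every analysis in this package consults one flattened table that maps a
character to (a) its primary — usually semantic — radical, (b) its
pinyin reading(s), and (c) its Ideographic Description Sequence.  The
canonical on-disk form is a 4-column UTF-8 TSV::

    # char  primary_radical  readings  ids
    病      疒               bìng       ⿸疒丙

Readings are ``;``-separated; the first is the canonical reading used
wherever a single reading is needed.  An IDS equal to the character
itself marks an atomic (indivisible) character.  Real Unihan / CHISE
dumps are expected to be flattened to this dialect by an external import
step; the core library never parses those raw formats.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field

from .pinyin import Pinyin, PinyinError, parse_pinyin

__all__ = ["CharacterRecord", "CharacterDB", "ChardbError",
           "load_chardb", "save_chardb", "is_idc", "NONE_RADICAL"]

logger = logging.getLogger(__name__)

#: Reserved sentinel radical for characters absent from the table.
NONE_RADICAL = "␀"  # ␀ SYMBOL FOR NULL

_IDC_RANGE = range(0x2FF0, 0x2FFC)


def is_idc(ch: str) -> bool:
    """True if *ch* is an Ideographic Description Character (operator)."""
    return len(ch) == 1 and ord(ch) in _IDC_RANGE


class ChardbError(ValueError):
    """Malformed character-table input."""


@dataclass(frozen=True)
class CharacterRecord:
    """One script symbol with its primary radical, readings and IDS.

    ``readings`` may be empty only for the unknown-character sentinel;
    table rows always carry at least one reading.  ``ids == char`` marks
    an atomic character.
    """

    char: str
    primary_radical: str
    readings: tuple[Pinyin, ...]
    ids: str

    def __post_init__(self) -> None:
        if len(self.char) != 1:
            raise ChardbError(f"char field must be a single symbol, got {self.char!r}")
        if is_idc(self.char):
            raise ChardbError(f"IDC operator {self.char!r} cannot be a character record")

    @property
    def canonical_reading(self) -> Pinyin | None:
        return self.readings[0] if self.readings else None

    @property
    def is_atomic(self) -> bool:
        return self.ids == self.char


def _sentinel(char: str) -> CharacterRecord:
    return CharacterRecord(char=char, primary_radical=NONE_RADICAL,
                           readings=(), ids=char)


@dataclass
class CharacterDB:
    """Map from character to :class:`CharacterRecord` with a total lookup.

    Unknown characters resolve to a sentinel record (radical =
    ``NONE_RADICAL``, no readings, atomic IDS) so that feature
    extraction over raw clinical text degrades to UNK features instead
    of failing.
    """

    records: dict[str, CharacterRecord] = field(default_factory=dict)
    skipped_lines: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, char: str) -> bool:
        return char in self.records

    def lookup(self, char: str) -> CharacterRecord:
        if len(char) != 1:
            raise ChardbError(f"lookup wants a single symbol, got {char!r}")
        if is_idc(char):
            raise ChardbError(f"IDC operator {char!r} is structural, not a character")
        rec = self.records.get(char)
        return rec if rec is not None else _sentinel(char)

    def add(self, rec: CharacterRecord) -> None:
        if rec.char in self.records:
            logger.warning("duplicate character %r: last definition wins", rec.char)
        self.records[rec.char] = rec


def _parse_line(line: str, lineno: int) -> CharacterRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 4:
        raise ChardbError(f"line {lineno}: expected 4 tab-separated columns, got {len(cols)}")
    char, radical, readings_field, ids = (c.strip() for c in cols)
    if len(char) != 1:
        raise ChardbError(f"line {lineno}: char field {char!r} is not a single symbol")
    if len(radical) != 1:
        raise ChardbError(f"line {lineno}: radical field {radical!r} is not a single symbol")
    try:
        readings = tuple(parse_pinyin(r) for r in readings_field.split(";") if r.strip())
    except PinyinError as exc:
        raise ChardbError(f"line {lineno}: {exc}") from exc
    if not readings:
        raise ChardbError(f"line {lineno}: no readings for {char!r}")
    if not ids:
        ids = char
    return CharacterRecord(char=char, primary_radical=radical,
                           readings=readings, ids=ids)


def load_chardb(path, strict: bool = False) -> CharacterDB:
    """Load a 4-column character TSV.

    ``strict=True`` raises :class:`ChardbError` on the first malformed
    line; otherwise malformed lines are skipped with a warning and
    counted in ``db.skipped_lines``.
    """
    db = CharacterDB()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                rec = _parse_line(line, lineno)
            except ChardbError as exc:
                if strict:
                    raise
                logger.warning("skipping malformed line: %s", exc)
                db.skipped_lines += 1
                continue
            db.add(rec)
    return db


def save_chardb(db: CharacterDB, path) -> None:
    """Write the table back to the canonical TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# char\tprimary_radical\treadings\tids\n")
        for rec in db.records.values():
            readings = ";".join(p.raw for p in rec.readings)
            fh.write(f"{rec.char}\t{rec.primary_radical}\t{readings}\t{rec.ids}\n")


def is_ideograph(ch: str) -> bool:
    """Heuristic: symbols that participate in phono-semantic statistics.

    CJK unified ideographs, their extensions, and private-use symbols
    (used by the synthetic generator) count; punctuation, Latin, digits
    and whitespace do not.
    """
    if len(ch) != 1:
        return False
    cp = ord(ch)
    if 0xE000 <= cp <= 0xF8FF or 0xF0000 <= cp <= 0x10FFFD:
        return True
    try:
        return unicodedata.name(ch).startswith("CJK")
    except ValueError:
        return False
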