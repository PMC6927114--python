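"""Pinyin syllable segmentation into initial, final and tone.

A Mandarin syllable romanized in pinyin carries at most one consonantal
onset (the *initial*), an obligatory vowel-bearing remainder (the
*final*) and one of five tones (neutral plus four contour tones, marked
either by a diacritic on a vowel or by a trailing digit).  Downstream
feature models use only the toneless form: the Radical+Pinyin model keys
on ``initial + final`` and the Radical+Final model on the final alone,
because a phonetic radical usually predicts the final (and sometimes the
initial) of a character but almost never its tone.

``y`` and ``w`` are treated as initials rather than re-spelled medials,
so ``yǒng`` segments as ``y + ong`` — the convention under which the
finals of ``tòng`` and ``yǒng`` coincide (both ``ong``).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Pinyin", "PinyinError", "parse_pinyin", "toneless", "final_of",
           "INITIALS", "FINALS"]


class PinyinError(ValueError):
    """Raised when a string is not a segmentable pinyin syllable."""


#: Onset inventory, longest-match from the left.  y/w count as initials.
INITIALS = (
    "zh", "ch", "sh",
    "b", "p", "m", "f", "d", "t", "n", "l",
    "g", "k", "h", "j", "q", "x", "r", "z", "c", "s", "y", "w",
)

#: Closed final inventory (standard Mandarin finals plus the i-/u-/ü-
#: medial series).  The residue left after stripping the initial must be
#: a member, otherwise the syllable is rejected.
FINALS = frozenset({
    "a", "o", "e", "i", "u", "ü", "er",
    "ai", "ei", "ao", "ou", "an", "en", "ang", "eng", "ong",
    "ia", "ie", "iao", "iou", "iu", "ian", "in", "iang", "ing", "iong",
    "ua", "uo", "uai", "uei", "ui", "uan", "uen", "un", "uang", "ueng",
    "üe", "ue", "üan", "ün",
})

# accented vowel -> (bare vowel, tone number)
_TONED = {}
for _bare, _marks in {
    "a": "āáǎà", "o": "ōóǒò", "e": "ēéěè", "i": "īíǐì",
    "u": "ūúǔù", "ü": "ǖǘǚǜ",
}.items():
    for _tone, _ch in enumerate(_marks, start=1):
        _TONED[_ch] = (_bare, _tone)


@dataclass(frozen=True)
class Pinyin:
    """An (initial, final, tone) decomposition of one romanized reading.

    ``tone`` is 0 for the neutral tone, 1–4 for flat, rising,
    falling-rising and falling.  ``initial + final`` reconstructs the
    toneless syllable exactly.
    """

    raw: str
    initial: str
    final: str
    tone: int

    def __post_init__(self) -> None:
        if not self.final:
            raise PinyinError(f"syllable {self.raw!r} has an empty final")
        if self.tone not in (0, 1, 2, 3, 4):
            raise PinyinError(f"tone {self.tone} out of range for {self.raw!r}")


def _strip_tone(raw: str) -> tuple[str, int]:
    """Remove the tone mark (diacritic or trailing digit) from *raw*."""
    tone = 0
    if raw and raw[-1].isdigit():
        d = int(raw[-1])
        if d > 5:
            raise PinyinError(f"tone digit {d} out of range in {raw!r}")
        tone = 0 if d in (0, 5) else d
        raw = raw[:-1]
    bare_chars = []
    seen_diacritic = False
    for ch in raw:
        if ch in _TONED:
            if seen_diacritic or tone:
                raise PinyinError(f"multiple tone marks in {raw!r}")
            bare, tone = _TONED[ch]
            seen_diacritic = True
            bare_chars.append(bare)
        else:
            bare_chars.append(ch)
    return "".join(bare_chars), tone


def parse_pinyin(raw: str) -> Pinyin:
    """Split a romanized syllable into its initial, final and tone.

    Accepts both diacritic form (``bìng``) and numbered form (``bing4``);
    ``v`` is read as ``ü``; a trailing ``5`` or ``0`` marks the neutral
    tone.  Raises :class:`PinyinError` for empty input, multiple tone
    marks, or a residue that is not in the final inventory.
    """
    if not raw or not raw.strip():
        raise PinyinError("empty pinyin syllable")
    s, tone = _strip_tone(raw.strip().lower())
    s = s.replace("v", "ü")
    initial = ""
    for cand in INITIALS:
        if s.startswith(cand):
            initial = cand
            break
    final = s[len(initial):]
    if final not in FINALS:
        raise PinyinError(
            f"cannot segment {raw!r}: residue {final!r} after initial "
            f"{initial!r} is not a known final"
        )
    return Pinyin(raw=raw, initial=initial, final=final, tone=tone)


def toneless(p: Pinyin) -> str:
    """The tone-free syllable ``initial + final`` — the Radical+Pinyin key."""
    return p.initial + p.final


def final_of(raw: str) -> str:
    """Final of a romanized syllable (parse shortcut used by the
    phono-semantic check)."""
    return parse_pinyin(raw).final
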