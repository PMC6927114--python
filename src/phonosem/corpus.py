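"""Tagged sentences, the BIO tagset, and CoNLL-style corpus IO.

The annotation scheme is character-level BIO over five clinical entity
types: body part (BOD), symptom (SYM), disease (DIS), experiment (EXP)
and treatment (TRE) — eleven surface tags in total.  The on-disk corpus
format is CoNLL-style UTF-8: one ``char<TAB>tag`` pair per line, blank
line between sentences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ENTITY_TYPES", "TagSet", "TaggedSentence", "read_conll",
           "write_conll", "is_valid_bio"]

ENTITY_TYPES = ("BOD", "SYM", "DIS", "EXP", "TRE")


@dataclass(frozen=True)
class TagSet:
    """BIO tagset with virtual START/STOP states and transition constraints.

    ``allowed`` is a boolean matrix over tag indices 0..K+1 where
    K = len(tags), index K is START and K+1 is STOP.  ``I-X`` is
    reachable only from ``B-X`` or ``I-X``; START cannot precede any
    ``I-X``.
    """

    types: tuple[str, ...] = ENTITY_TYPES
    tags: tuple[str, ...] = field(init=False)
    allowed: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        tags = ["O"]
        for t in self.types:
            tags += [f"B-{t}", f"I-{t}"]
        object.__setattr__(self, "tags", tuple(tags))
        K = len(tags)
        allowed = np.zeros((K + 2, K + 2), dtype=bool)
        start, stop = K, K + 1
        for i, src in enumerate(tags):
            for j, dst in enumerate(tags):
                if dst.startswith("I-"):
                    allowed[i, j] = src == f"B-{dst[2:]}" or src == dst
                else:
                    allowed[i, j] = True
            allowed[i, stop] = True
            allowed[start, i] = not tags[i].startswith("I-")
        object.__setattr__(self, "allowed", allowed)

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    @property
    def start(self) -> int:
        return self.n_tags

    @property
    def stop(self) -> int:
        return self.n_tags + 1

    def index(self, tag: str) -> int:
        try:
            return self.tags.index(tag)
        except ValueError:
            raise KeyError(f"unknown tag {tag!r}") from None


def is_valid_bio(tags, tagset: TagSet | None = None) -> bool:
    """True when a tag sequence respects the BIO transition constraints."""
    ts = tagset or TagSet()
    prev = ts.start
    for tag in tags:
        i = ts.index(tag)
        if not ts.allowed[prev, i]:
            return False
        prev = i
    return True


@dataclass(frozen=True)
class TaggedSentence:
    """A character sequence with aligned BIO tags."""

    chars: tuple[str, ...]
    tags: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.chars) != len(self.tags):
            raise ValueError(
                f"{len(self.chars)} characters vs {len(self.tags)} tags")

    def __len__(self) -> int:
        return len(self.chars)

    @property
    def text(self) -> str:
        return "".join(self.chars)


def read_conll(path) -> list[TaggedSentence]:
    """Read a CoNLL-style corpus (char<TAB>tag, blank-line separated)."""
    sentences: list[TaggedSentence] = []
    chars: list[str] = []
    tags: list[str] = []

    def flush():
        if chars:
            sentences.append(TaggedSentence(tuple(chars), tuple(tags)))
            chars.clear()
            tags.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected char<TAB>tag")
            chars.append(cols[0])
            tags.append(cols[1])
    flush()
    return sentences


def write_conll(sentences, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            for ch, tag in zip(sent.chars, sent.tags):
                fh.write(f"{ch}\t{tag}\n")
            fh.write("\n")
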