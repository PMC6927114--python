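"""Entity-level scoring, cross-validation, sectioning and radical stats.

Scoring is exact-match at the entity level: a predicted mention counts
as a true positive only when its type, start and end all agree with a
gold mention.  Overall precision/recall/F are micro-averaged over all
mentions (not a mean of the per-type rows).  The sectioning procedure
splits a document collection at the median per-document phono-semantic
percentage: documents strictly above the median go to section A, the
rest (including ties) to section B.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from .chardb import CharacterDB
from .corpus import TaggedSentence
from .decomposition import phono_semantic_percentage

__all__ = ["EntityMention", "PRFReport", "SectionSplit", "extract_entities",
           "score", "cross_validate", "section_by_phonosemantic",
           "radical_occurrence"]


@dataclass(frozen=True)
class EntityMention:
    """One entity span: type plus [start, end) character offsets."""

    type: str
    start: int
    end: int
    sentence_id: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty entity span")


def extract_entities(sentence: TaggedSentence, sentence_id: int = 0,
                     lenient: bool = False) -> list[EntityMention]:
    """Maximal B-X (I-X)* runs as entity mentions.

    Strict mode (default) drops a dangling ``I-X`` that does not
    continue a ``B-X``/``I-X`` run of the same type; ``lenient=True``
    promotes it to a new mention start.
    """
    mentions: list[EntityMention] = []
    cur_type: str | None = None
    cur_start = 0
    for i, tag in enumerate(sentence.tags):
        if tag == "O":
            prefix, etype = "O", None
        elif len(tag) > 2 and tag[1] == "-" and tag[0] in "BI":
            prefix, etype = tag[0], tag[2:]
        else:
            raise ValueError(f"unknown tag {tag!r}")
        if prefix == "I" and etype == cur_type and cur_type is not None:
            continue  # run continues
        if cur_type is not None:
            mentions.append(EntityMention(cur_type, cur_start, i, sentence_id))
            cur_type = None
        if prefix == "B" or (prefix == "I" and lenient):
            cur_type, cur_start = etype, i
    if cur_type is not None:
        mentions.append(EntityMention(cur_type, cur_start, len(sentence),
                                      sentence_id))
    return mentions


@dataclass
class PRFReport:
    """Micro-averaged precision/recall/F with per-type breakdown."""

    tp: dict = field(default_factory=dict)
    fp: dict = field(default_factory=dict)
    fn: dict = field(default_factory=dict)

    def _prf(self, tp: int, fp: int, fn: int) -> tuple[float, float, float]:
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    def per_type(self, etype: str) -> tuple[float, float, float]:
        return self._prf(self.tp.get(etype, 0), self.fp.get(etype, 0),
                         self.fn.get(etype, 0))

    @property
    def overall(self) -> tuple[float, float, float]:
        return self._prf(sum(self.tp.values()), sum(self.fp.values()),
                         sum(self.fn.values()))

    @property
    def f_measure(self) -> float:
        return self.overall[2]

    def as_dict(self) -> dict:
        types = sorted(set(self.tp) | set(self.fp) | set(self.fn))
        out = {}
        for t in types:
            p, r, f = self.per_type(t)
            out[t] = dict(precision=p, recall=r, f=f, tp=self.tp.get(t, 0),
                          fp=self.fp.get(t, 0), fn=self.fn.get(t, 0))
        p, r, f = self.overall
        out["ALL"] = dict(precision=p, recall=r, f=f,
                          tp=sum(self.tp.values()), fp=sum(self.fp.values()),
                          fn=sum(self.fn.values()))
        return out


def score(gold: list[TaggedSentence], pred: list[TaggedSentence],
          lenient: bool = False) -> PRFReport:
    """Exact-match entity P/R/F of *pred* against *gold*."""
    if len(gold) != len(pred):
        raise ValueError("gold and predicted corpora differ in size")
    report = PRFReport()
    for sid, (g, p) in enumerate(zip(gold, pred)):
        if len(g) != len(p):
            raise ValueError(f"sentence {sid}: gold/pred length mismatch")
        gset = set(extract_entities(g, sid, lenient))
        pset = set(extract_entities(p, sid, lenient))
        for m in pset:
            key = m.type
            if m in gset:
                report.tp[key] = report.tp.get(key, 0) + 1
            else:
                report.fp[key] = report.fp.get(key, 0) + 1
        for m in gset - pset:
            report.fn[m.type] = report.fn.get(m.type, 0) + 1
    return report


def cross_validate(corpus: list[TaggedSentence], train_fn, k: int = 5,
                   seed: int = 0) -> tuple[list[PRFReport], dict]:
    """k-fold cross-validation with a seeded shuffle.

    ``train_fn(train_sents, test_sents) -> list[TaggedSentence]`` fits a
    model and returns predictions for the test fold.  Fold sizes differ
    by at most one; every sentence appears in exactly one test fold.
    Returns per-fold reports and a summary with the arithmetic mean of
    fold P/R/F.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(corpus) < k:
        raise ValueError("corpus smaller than number of folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    folds = [order[i::k] for i in range(k)]
    reports = []
    for i in range(k):
        test_idx = set(folds[i].tolist())
        train = [corpus[j] for j in range(len(corpus)) if j not in test_idx]
        test = [corpus[j] for j in sorted(test_idx)]
        preds = train_fn(train, test)
        reports.append(score(test, preds))
    mean = {m: float(np.mean([getattr(r, "overall")[i] for r in reports]))
            for i, m in enumerate(("precision", "recall", "f"))}
    return reports, mean


def fold_sizes(n: int, k: int) -> list[int]:
    """Sizes of k near-equal folds of n items (max difference 1)."""
    return [len(range(i, n, k)) for i in range(k)]


@dataclass
class SectionSplit:
    """Median split of documents by phono-semantic percentage."""

    section_a: list[int]
    section_b: list[int]
    median: float
    per_doc_percentages: list[float]


def section_by_phonosemantic(db: CharacterDB, documents,
                             max_depth: int = 3) -> SectionSplit:
    """Split documents at the median per-document phono-semantic
    percentage (token-level): strictly above the median → section A,
    the rest including ties → section B."""
    if len(documents) < 2:
        raise ValueError("need at least two documents to section")
    percentages = [phono_semantic_percentage(db, doc, unique=False,
                                             max_depth=max_depth)
                   for doc in documents]
    med = statistics.median(percentages)
    a = [i for i, p in enumerate(percentages) if p > med]
    b = [i for i, p in enumerate(percentages) if p <= med]
    return SectionSplit(section_a=a, section_b=b, median=med,
                        per_doc_percentages=percentages)


def radical_occurrence(db: CharacterDB, corpus: list[TaggedSentence],
                       scope: str = "entities-by-type",
                       top: int | None = None) -> dict[str, list[tuple[str, float]]]:
    """Primary-radical frequency tables, ranked descending.

    ``scope="entities-by-type"`` counts characters inside entity
    mentions per entity type; ``scope="overall"`` counts every character
    of the corpus.  Values are percentages of the column's character
    count.  Ties rank alphabetically for determinism.
    """
    if scope not in ("entities-by-type", "overall"):
        raise ValueError(f"unknown scope {scope!r}")
    columns: dict[str, dict[str, int]] = {}

    def bump(col: str, radical: str) -> None:
        columns.setdefault(col, {})
        columns[col][radical] = columns[col].get(radical, 0) + 1

    for sid, sent in enumerate(corpus):
        if scope == "overall":
            for ch in sent.chars:
                bump("ALL", db.lookup(ch).primary_radical)
        else:
            for m in extract_entities(sent, sid):
                for ch in sent.chars[m.start:m.end]:
                    bump(m.type, db.lookup(ch).primary_radical)

    out: dict[str, list[tuple[str, float]]] = {}
    for col, counts in columns.items():
        total = sum(counts.values())
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        rows = [(rad, 100.0 * n / total) for rad, n in ranked]
        out[col] = rows[:top] if top else rows
    return out
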