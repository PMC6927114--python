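"""Feature embedding tables and the linear composition layer.

Character embeddings are composed from two pretrained feature tables.
The left feature is always the primary-radical embedding; the right
feature depends on the model:

* ``R+C`` — the character itself (graphical control),
* ``R+P`` — the toneless pinyin of the canonical reading,
* ``R+F`` — the final of the canonical reading.

Composition is a learned affine map ``E = LW @ left + RW @ right + b``
whose parameters are trained jointly with the tagger.  Fixing
``LW = RW = I`` and ``b = 0`` gives the Sum variant, a plain vector
addition.

Tables are pretrained with skip-gram / negative sampling over *view
streams*: the raw character stream is mapped position-wise to radicals,
pinyins or finals, so every feature vocabulary is trained on contexts
aligned with the character stream.  Tables are read and written in the
word2vec text format (header ``<vocab> <dim>``, then one token and its
coefficients per line).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .chardb import CharacterDB
from .pinyin import toneless

__all__ = ["EmbeddingTable", "CompositionParams", "FeatureModel",
           "pretrain_embeddings", "compose", "load_word2vec_text",
           "save_word2vec_text", "view_token", "Mode", "View"]

Mode = Literal["R+C", "R+P", "R+F"]
View = Literal["char", "radical", "pinyin", "final"]

UNK = "<UNK>"


@dataclass
class EmbeddingTable:
    """token -> vector map of fixed dimension with an UNK fallback."""

    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    unk_vector: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.unk_vector is None:
            self.unk_vector = np.zeros(self.dim, dtype=np.float32)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def get(self, token: str) -> np.ndarray:
        v = self.vectors.get(token)
        return v if v is not None else self.unk_vector

    @classmethod
    def random(cls, tokens: Iterable[str], dim: int, seed: int = 0,
               scale: float = 0.1) -> "EmbeddingTable":
        """Small random table, for training from scratch."""
        rng = np.random.default_rng(seed)
        vecs = {t: (rng.standard_normal(dim) * scale).astype(np.float32)
                for t in tokens}
        unk = (np.mean(list(vecs.values()), axis=0).astype(np.float32)
               if vecs else np.zeros(dim, dtype=np.float32))
        return cls(dim=dim, vectors=vecs, unk_vector=unk)


def view_token(db: CharacterDB, char: str, view: View) -> str | None:
    """Map one character to its feature token, or None when unavailable."""
    if view == "char":
        return char
    rec = db.lookup(char)
    if view == "radical":
        return rec.primary_radical
    reading = rec.canonical_reading
    if reading is None:
        return None
    return toneless(reading) if view == "pinyin" else reading.final


def pretrain_embeddings(corpus: Iterable[Iterable[str]], view: View,
                        db: CharacterDB, dim: int = 50, window: int = 2,
                        epochs: int = 3, negatives: int = 5,
                        lr: float = 0.025, seed: int = 0) -> EmbeddingTable:
    """Skip-gram with negative sampling over the view-mapped token stream.

    Each sentence of characters is mapped position-wise to view tokens
    (characters, primary radicals, toneless pinyins, or finals); unknown
    positions become UNK and are kept in the stream so contexts stay
    aligned with the character stream.  Returns a table whose UNK vector
    is the mean of all trained vectors.
    """
    sentences = [[view_token(db, ch, view) or UNK for ch in sent]
                 for sent in corpus]
    sentences = [s for s in sentences if s]
    if not sentences:
        raise ValueError("empty corpus")
    vocab = sorted({t for s in sentences for t in s})
    if vocab == [UNK]:
        raise ValueError(f"view {view!r} maps the whole corpus to UNK")
    index = {t: i for i, t in enumerate(vocab)}
    counts = np.zeros(len(vocab))
    for s in sentences:
        for t in s:
            counts[index[t]] += 1
    # unigram^0.75 negative-sampling distribution
    neg_probs = counts ** 0.75
    neg_probs /= neg_probs.sum()

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W_in = (rng.random((V, dim)) - 0.5).astype(np.float64) / dim
    W_out = np.zeros((V, dim), dtype=np.float64)

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))

    for _epoch in range(epochs):
        for sent in sentences:
            ids = [index[t] for t in sent]
            for pos, center in enumerate(ids):
                lo = max(0, pos - window)
                hi = min(len(ids), pos + window + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    ctx = ids[cpos]
                    negs = rng.choice(V, size=negatives, p=neg_probs)
                    targets = np.concatenate(([ctx], negs))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    vin = W_in[center]
                    vout = W_out[targets]
                    scores = sigmoid(vout @ vin)
                    grad = (scores - labels) * lr
                    W_in[center] -= grad @ vout
                    W_out[targets] -= np.outer(grad, vin)

    vecs = {t: W_in[index[t]].astype(np.float32) for t in vocab if t != UNK}
    if not vecs:  # degenerate all-UNK-but-survived case
        vecs = {UNK: W_in[index[UNK]].astype(np.float32)}
    unk = np.mean(list(vecs.values()), axis=0).astype(np.float32)
    return EmbeddingTable(dim=dim, vectors=vecs, unk_vector=unk)


def save_word2vec_text(table: EmbeddingTable, path) -> None:
    """Write a table in word2vec text format (UNK stored as <UNK>)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors) + 1} {table.dim}\n")
        def fmt(v):
            return " ".join(np.format_float_positional(x, unique=True, trim="0")
                            for x in np.asarray(v, dtype=np.float32))
        fh.write(f"{UNK} {fmt(table.unk_vector)}\n")
        for tok, vec in table.vectors.items():
            fh.write(f"{tok} {fmt(vec)}\n")


def load_word2vec_text(path) -> EmbeddingTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"bad word2vec header in {path}")
        _, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        unk = None
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            tok, coeffs = parts[0], parts[1:]
            if len(coeffs) != dim:
                raise ValueError(f"token {tok!r}: expected {dim} coefficients")
            vec = np.array(coeffs, dtype=np.float32)
            if tok == UNK:
                unk = vec
            else:
                vectors[tok] = vec
    return EmbeddingTable(dim=dim, vectors=vectors, unk_vector=unk)


@dataclass
class CompositionParams:
    """Affine composition ``E = LW @ left + RW @ right + b``.

    ``trainable=False`` is the Sum variant: LW and RW are the identity
    (requiring equal left/right/output dims) and b is zero, and the
    parameters are frozen during training.
    """

    LW: np.ndarray
    RW: np.ndarray
    b: np.ndarray
    trainable: bool = True

    def __post_init__(self) -> None:
        self.LW = np.asarray(self.LW, dtype=np.float64)
        self.RW = np.asarray(self.RW, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        out = self.b.shape[0]
        if self.LW.shape[0] != out or self.RW.shape[0] != out:
            raise ValueError("LW/RW/b output dimensions disagree")
        if not self.trainable:
            if (self.LW.shape[0] != self.LW.shape[1]
                    or self.RW.shape[0] != self.RW.shape[1]):
                raise ValueError("Sum variant requires square identity weights")
            if (not np.array_equal(self.LW, np.eye(out))
                    or not np.array_equal(self.RW, np.eye(out))
                    or np.any(self.b != 0)):
                raise ValueError("Sum variant requires LW=RW=I and b=0")

    @property
    def out_dim(self) -> int:
        return self.b.shape[0]

    @classmethod
    def identity_sum(cls, dim: int) -> "CompositionParams":
        """The frozen Sum variant (plain vector addition)."""
        return cls(LW=np.eye(dim), RW=np.eye(dim), b=np.zeros(dim),
                   trainable=False)

    @classmethod
    def random_init(cls, out_dim: int, left_dim: int, right_dim: int,
                    seed: int = 0) -> "CompositionParams":
        rng = np.random.default_rng(seed)
        scale_l = 1.0 / np.sqrt(left_dim)
        scale_r = 1.0 / np.sqrt(right_dim)
        return cls(LW=rng.standard_normal((out_dim, left_dim)) * scale_l,
                   RW=rng.standard_normal((out_dim, right_dim)) * scale_r,
                   b=np.zeros(out_dim), trainable=True)


def compose(params: CompositionParams, left: np.ndarray,
            right: np.ndarray) -> np.ndarray:
    """Apply the composition layer to one (left, right) feature pair."""
    left = np.asarray(left, dtype=np.float64)
    right = np.asarray(right, dtype=np.float64)
    if left.shape[-1] != params.LW.shape[1] or right.shape[-1] != params.RW.shape[1]:
        raise ValueError(
            f"shape mismatch: left {left.shape} vs LW {params.LW.shape}, "
            f"right {right.shape} vs RW {params.RW.shape}")
    return left @ params.LW.T + right @ params.RW.T + params.b


@dataclass
class FeatureModel:
    """One of the three feature models, ready to embed sentences.

    The left table always holds primary-radical embeddings; the right
    table holds character, toneless-pinyin, or final embeddings
    according to ``mode``.
    """

    mode: Mode
    left_table: EmbeddingTable
    right_table: EmbeddingTable
    params: CompositionParams
    db: CharacterDB

    def __post_init__(self) -> None:
        if self.mode not in ("R+C", "R+P", "R+F"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def right_key(self, char: str) -> str | None:
        view = {"R+C": "char", "R+P": "pinyin", "R+F": "final"}[self.mode]
        return view_token(self.db, char, view)

    def feature_tokens(self, char: str) -> tuple[str | None, str | None]:
        """(left token, right token); None falls back to UNK vectors."""
        rec = self.db.lookup(char)
        left = rec.primary_radical if rec.primary_radical in self.left_table else None
        right = self.right_key(char)
        if right is not None and right not in self.right_table:
            right = None
        return left, right

    def embed_sentence(self, chars) -> np.ndarray:
        """Composed embedding per character; shape (len(chars), out_dim)."""
        if len(chars) == 0:
            raise ValueError("empty sentence")
        lefts = np.stack([
            self.left_table.get(tok) if tok is not None else self.left_table.unk_vector
            for tok, _ in (self.feature_tokens(c) for c in chars)])
        rights = np.stack([
            self.right_table.get(tok) if tok is not None else self.right_table.unk_vector
            for _, tok in (self.feature_tokens(c) for c in chars)])
        return compose(self.params, lefts, rights)


def embed_sentence(model: FeatureModel, chars) -> np.ndarray:
    """Functional alias for :meth:`FeatureModel.embed_sentence`."""
    return model.embed_sentence(chars)
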