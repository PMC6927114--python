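"""High-level pipeline: pretrain feature tables, build a model, train, score.

This is the programmatic equivalent of the CLI's ``pretrain``/``train``
subcommands: map the training text to feature-view token streams,
pretrain embedding tables with skip-gram, assemble the chosen feature
model (learned composition or frozen Sum variant), and fit the
Bi-LSTM-CRF.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chardb import CharacterDB
from .corpus import TaggedSentence, TagSet
from .embeddings import (CompositionParams, EmbeddingTable, FeatureModel,
                         Mode, pretrain_embeddings)
from .evaluation import PRFReport, score
from .nertagger import CRFTagger, TrainConfig

__all__ = ["build_feature_model", "train_tagger", "evaluate_tagger",
           "PretrainConfig"]

_RIGHT_VIEW = {"R+C": "char", "R+P": "pinyin", "R+F": "final"}


@dataclass
class PretrainConfig:
    dim: int = 40
    window: int = 2
    epochs: int = 1
    seed: int = 0


def build_feature_model(db: CharacterDB, mode: Mode,
                        corpus: list[TaggedSentence],
                        pretrain: PretrainConfig | None = None,
                        sum_variant: bool = False,
                        left_table: EmbeddingTable | None = None,
                        right_table: EmbeddingTable | None = None,
                        seed: int = 0) -> FeatureModel:
    """Assemble a feature model, pretraining any table not supplied."""
    pc = pretrain or PretrainConfig(seed=seed)
    sents = [list(s.chars) for s in corpus]
    if left_table is None:
        left_table = pretrain_embeddings(sents, "radical", db, dim=pc.dim,
                                         window=pc.window, epochs=pc.epochs,
                                         seed=pc.seed)
    if right_table is None:
        right_table = pretrain_embeddings(sents, _RIGHT_VIEW[mode], db,
                                          dim=pc.dim, window=pc.window,
                                          epochs=pc.epochs, seed=pc.seed + 1)
    if sum_variant:
        if left_table.dim != right_table.dim:
            raise ValueError("Sum variant needs equal table dimensions")
        params = CompositionParams.identity_sum(left_table.dim)
    else:
        params = CompositionParams.random_init(
            out_dim=left_table.dim, left_dim=left_table.dim,
            right_dim=right_table.dim, seed=seed)
    return FeatureModel(mode=mode, left_table=left_table,
                        right_table=right_table, params=params, db=db)


def train_tagger(db: CharacterDB, corpus: list[TaggedSentence], mode: Mode = "R+P",
                 sum_variant: bool = False, config: TrainConfig | None = None,
                 pretrain: PretrainConfig | None = None,
                 tagset: TagSet | None = None) -> CRFTagger:
    """End-to-end fit: pretrain tables, build the model, train the tagger."""
    config = config or TrainConfig()
    fm = build_feature_model(db, mode, corpus, pretrain=pretrain,
                             sum_variant=sum_variant, seed=config.seed)
    tagger = CRFTagger(fm, tagset=tagset, hidden=config.hidden,
                       seed=config.seed)
    tagger.train(corpus, config)
    return tagger


def evaluate_tagger(tagger: CRFTagger, corpus: list[TaggedSentence]) -> PRFReport:
    """Decode every sentence and score against the gold annotation."""
    preds = [tagger.viterbi_decode(s.chars) for s in corpus]
    return score(corpus, preds)
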