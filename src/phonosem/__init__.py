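"""Graphical and phonetic character features for Chinese clinical NER.

The package detects phono-semantic characters by matching pinyin finals
across a character's nested IDS components, composes character
embeddings from primary-radical and pinyin features through a learned
linear composition layer, and tags clinical text with a character-based
Bi-LSTM-CRF.
"""

from importlib import resources

from .chardb import CharacterDB, CharacterRecord, load_chardb, save_chardb
from .decomposition import (IDSTree, PhonoSemanticVerdict, nested_components,
                            parse_ids, phono_semantic_check,
                            phono_semantic_percentage)
from .pinyin import Pinyin, final_of, parse_pinyin, toneless

__version__ = "0.1.0"


def demo_chars_path():
    """Path to the shipped demonstration character table."""
    return resources.files("phonosem") / "fixtures" / "biomedical_chars.tsv"
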