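"""Loaders for the small inventories bundled with the package.

These ship as plain-text package data so that transcript annotation and
feature extraction are fully deterministic and work offline:

* ``picture_aois.json`` — the 13 area-of-interest polygons on the picture
  stimulus (screen pixels, origin top-left).
* ``information_units.json`` — the 13 picture information units and their
  synonym sets used for mention scoring.
* ``cfg_rules.json`` — the fixed inventory of 44 context-free-grammar rules
  over which rule-frequency features are computed.
* ``vocabulary.tsv`` — generator vocabulary with coarse part-of-speech tags
  and syllable counts.
* ``toy_psycholinguistic_norms.tsv`` — a small synthetic stand-in for
  MRC-style psycholinguistic word norms (concreteness, familiarity,
  imageability, age of acquisition, frequency).  A user-supplied norms table
  in the same format can be passed to the feature extractor instead.
* ``reading_paragraph.txt`` — the fixed paragraph shown in the reading task,
  one sentence per line.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources as _ir

import pandas as pd

_PKG = "gazespeech.data"


def _path(name: str):
    return _ir.files(_PKG).joinpath(name)


@lru_cache(maxsize=None)
def picture_aoi_definitions() -> tuple:
    """The 13 picture AoIs as ``{"name": ..., "polygon": [[x, y], ...]}``."""
    with _path("picture_aois.json").open() as fh:
        return tuple(json.load(fh))


@lru_cache(maxsize=None)
def information_unit_lexicon() -> dict:
    """Mapping information-unit name -> tuple of lower-case synonym words."""
    with _path("information_units.json").open() as fh:
        raw = json.load(fh)
    return {k: tuple(w.lower() for w in v) for k, v in raw.items()}


@lru_cache(maxsize=None)
def cfg_rule_inventory() -> tuple:
    """The fixed, ordered inventory of 44 CFG rule names."""
    with _path("cfg_rules.json").open() as fh:
        return tuple(json.load(fh))


@lru_cache(maxsize=None)
def vocabulary() -> pd.DataFrame:
    """Generator vocabulary indexed by word, with ``pos`` and ``syllables``."""
    with _path("vocabulary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="word")


@lru_cache(maxsize=None)
def psycholinguistic_norms() -> pd.DataFrame:
    """Bundled toy word norms indexed by word (synthetic MRC-style table)."""
    with _path("toy_psycholinguistic_norms.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="word")


@lru_cache(maxsize=None)
def reading_paragraph() -> tuple:
    """Sentences of the reading paragraph as tuples of lower-case words."""
    text = _path("reading_paragraph.txt").read_text()
    sentences = []
    for line in text.strip().splitlines():
        words = [w.strip(".,").lower() for w in line.split()]
        sentences.append(tuple(w for w in words if w))
    return tuple(sentences)
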