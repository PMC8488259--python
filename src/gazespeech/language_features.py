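"""Language feature vectors from transcripts and acoustic frame matrices.

Per speaking task the schema is:

* picture description: 13 information-unit + 97 text + 172 acoustic = 282
* memory description: 97 text + 172 acoustic = 269 (no information units —
  they are specific to the picture stimulus)
* paragraph reading: 12 fluency + 172 acoustic = 184

Text features (97) decompose into part-of-speech (15), context-free-grammar
rule frequencies over a fixed 44-rule inventory, syntactic complexity (24),
vocabulary richness (4), psycholinguistic norms means (5) and
repetitiveness (5).  Acoustic features are four moments {mean, variance,
skewness, kurtosis} of each of 43 coefficient streams (43 x 4 = 172); the
two shape moments form the "distribution of" feature family.  All are pure
functions of their inputs.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import resources
from .cohort import ACOUSTIC_STREAMS
from .errors import ConfigurationError
from .feature_vector import FeatureVector

_NAN = float("nan")

_TAG_CATEGORY = {
    "NN": "noun", "NNS": "noun", "NNP": "noun",
    "VB": "verb", "VBZ": "verb", "VBD": "verb", "VBG": "verb", "VBN": "verb",
    "JJ": "adj", "RB": "adv", "PRP": "pron", "DT": "det",
    "IN": "prep", "TO": "prep", "CC": "conj", "CD": "num", "UH": "filler",
}

_CONTENT = {"noun", "verb", "adj", "adv"}


def _words(tokens: Sequence[dict]) -> list:
    return [t for t in tokens if t.get("type") == "word"]


def _sentences(tokens: Sequence[dict]) -> dict:
    by_id: dict = {}
    for t in tokens:
        if t.get("type") == "word":
            by_id.setdefault(t.get("sentence_id", 0), []).append(t)
    return by_id


def _safe_stats(vec, prefix, unit_group, fv, stats=("Mean", "SD", "Max")):
    arr = np.asarray(vec, dtype=float)
    fns = {"Mean": np.mean, "SD": np.std, "Max": np.max, "Min": np.min}
    for s in stats:
        name = f"{s} {prefix}" if s != "SD" else f"SD of {prefix}"
        fv.add(unit_group, name, float(fns[s](arr)) if arr.size else _NAN)


# ---------------------------------------------------------------------------
# text features (97)
# ---------------------------------------------------------------------------


def text_features(tokens: Sequence[dict], norms: pd.DataFrame | None = None,
                  task: str = "") -> FeatureVector:
    """The 97 transcript text features (POS, CFG, syntax, richness,
    psycholinguistic, repetitiveness)."""
    fv = FeatureVector(task=task, modality="language")
    words = _words(tokens)
    fillers = [t for t in tokens if t.get("type") == "filler"]
    n_words = len(words)

    # --- part-of-speech (15) ---------------------------------------------
    cats = Counter(_TAG_CATEGORY.get(t.get("pos", ""), "other") for t in words)
    order = ("noun", "verb", "adj", "adv", "pron", "det", "prep", "conj", "num", "other")
    labels = {
        "noun": "nouns", "verb": "verbs", "adj": "adjectives", "adv": "adverbs",
        "pron": "pronouns", "det": "determiners", "prep": "prepositions",
        "conj": "conjunctions", "num": "numerals", "other": "other POS tags",
    }
    for c in order:
        fv.add("pos", f"Proportion of {labels[c]}",
               cats.get(c, 0) / n_words if n_words else _NAN)
    fv.add("pos", "Noun to verb ratio",
           cats.get("noun", 0) / cats["verb"] if cats.get("verb") else _NAN)
    fv.add("pos", "Pronoun to noun ratio",
           cats.get("pron", 0) / cats["noun"] if cats.get("noun") else _NAN)
    content = sum(cats.get(c, 0) for c in _CONTENT)
    fv.add("pos", "Proportion of content words", content / n_words if n_words else _NAN)
    fv.add("pos", "Proportion of function words",
           (n_words - content) / n_words if n_words else _NAN)
    fv.add("pos", "Fillers per word", len(fillers) / n_words if n_words else _NAN)

    # --- context-free-grammar rule frequencies (44) ------------------------
    sentences = _sentences(tokens)
    n_sent = len(sentences)
    rule_counts: Counter = Counter()
    for t in tokens:
        for rule, c in (t.get("rules") or {}).items():
            rule_counts[rule] += c
    for rule in resources.cfg_rule_inventory():
        fv.add("cfg", f"CFG rule frequency: {rule}",
               rule_counts.get(rule, 0) / n_sent if n_sent else _NAN)

    # --- syntactic complexity (24) -----------------------------------------
    sent_lens = [len(s) for s in sentences.values()]
    syls = [t.get("syllables", 0) for t in words]
    sent_durs = [s[-1]["end_ms"] - s[0]["start_ms"] for s in sentences.values()]
    depths = [
        t["depth"] for t in tokens if t.get("depth") is not None
    ]
    _safe_stats(sent_lens, "words per sentence", "syntax", fv,
                ("Mean", "SD", "Max", "Min"))
    _safe_stats(syls, "syllables per word", "syntax", fv)
    fv.add("syntax", "Proportion of polysyllabic words",
           sum(1 for s in syls if s >= 3) / n_words if n_words else _NAN)
    _safe_stats(sent_durs, "sentence duration", "syntax", fv)
    _safe_stats(depths, "parse tree depth", "syntax", fv)

    def _lhs_count(lhs):
        return sum(c for r, c in rule_counts.items() if r.startswith(lhs + " ->"))

    np_c, vp_c, pp_c, sbar_c = (_lhs_count(x) for x in ("NP", "VP", "PP", "SBAR"))
    clause_c = _lhs_count("S") + sbar_c
    fv.add("syntax", "Mean NP constituents per sentence", np_c / n_sent if n_sent else _NAN)
    fv.add("syntax", "Mean VP constituents per sentence", vp_c / n_sent if n_sent else _NAN)
    fv.add("syntax", "Mean PP constituents per sentence", pp_c / n_sent if n_sent else _NAN)
    fv.add("syntax", "Mean subordinate clauses per sentence",
           sbar_c / n_sent if n_sent else _NAN)
    fv.add("syntax", "Subordinate clause proportion",
           sbar_c / clause_c if clause_c else _NAN)
    fv.add("syntax", "Mean clauses per sentence", clause_c / n_sent if n_sent else _NAN)
    fv.add("syntax", "Mean words per clause", n_words / clause_c if clause_c else _NAN)
    fv.add("syntax", "Coordination rate",
           cats.get("conj", 0) / n_words if n_words else _NAN)
    total_rules = sum(rule_counts.values())
    fv.add("syntax", "Mean constituents per sentence",
           total_rules / n_sent if n_sent else _NAN)
    fv.add("syntax", "Parse rule diversity",
           len(rule_counts) / total_rules if total_rules else _NAN)

    # --- vocabulary richness (4) -------------------------------------------
    texts = [t["text"].lower() for t in words]
    types = Counter(texts)
    N, V = len(texts), len(types)
    v1 = sum(1 for c in types.values() if c == 1)
    fv.add("richness", "Type-token ratio", V / N if N else _NAN)
    fv.add("richness", "Brunet's index", N ** (V ** -0.165) if N and V else _NAN)
    # Honore's statistic, natural-log convention; undefined when every type
    # is a hapax (V1 == V)
    honore = 100.0 * math.log(N) / (1.0 - v1 / V) if N > 1 and V and v1 < V else _NAN
    fv.add("richness", "Honore's statistic", honore)
    fv.add("richness", "Mean word length",
           float(np.mean([len(w) for w in texts])) if texts else _NAN)

    # --- psycholinguistic means (5) ----------------------------------------
    norms = resources.psycholinguistic_norms() if norms is None else norms
    labels5 = {
        "concreteness": "Mean concreteness", "familiarity": "Mean familiarity",
        "imageability": "Mean imageability",
        "age_of_acquisition": "Mean age of acquisition",
        "frequency": "Mean word frequency",
    }
    known = [w for w in texts if w in norms.index]
    for col, label in labels5.items():
        vals = norms.loc[known, col] if known else []
        fv.add("psycholinguistic", label, float(np.mean(vals)) if len(vals) else _NAN)

    # --- repetitiveness (5) -------------------------------------------------
    fv.add("repetitiveness", "Proportion of repeated words",
           (N - V) / N if N else _NAN)
    bigrams = list(zip(texts[:-1], texts[1:]))
    bt = Counter(bigrams)
    fv.add("repetitiveness", "Proportion of repeated bigrams",
           (len(bigrams) - len(bt)) / len(bigrams) if bigrams else _NAN)
    sims = _utterance_similarities(sentences)
    fv.add("repetitiveness", "Mean inter-utterance similarity",
           float(np.mean(sims)) if len(sims) else _NAN)
    fv.add("repetitiveness", "Max inter-utterance similarity",
           float(np.max(sims)) if len(sims) else _NAN)
    fv.add("repetitiveness", "Proportion of near-duplicate utterance pairs",
           float(np.mean(sims >= 0.9)) if len(sims) else _NAN)
    return fv


def _utterance_similarities(sentences: dict) -> np.ndarray:
    """Cosine similarity over word-count vectors for every utterance pair."""
    bags = [Counter(t["text"].lower() for t in s) for s in sentences.values()]
    bags = [b for b in bags if b]
    sims = []
    for i in range(len(bags)):
        for j in range(i + 1, len(bags)):
            a, b = bags[i], bags[j]
            dot = sum(a[w] * b[w] for w in a if w in b)
            na = math.sqrt(sum(c * c for c in a.values()))
            nb = math.sqrt(sum(c * c for c in b.values()))
            sims.append(dot / (na * nb) if na and nb else 0.0)
    return np.array(sims)


# ---------------------------------------------------------------------------
# information units (13)
# ---------------------------------------------------------------------------


def information_unit_features(
    tokens: Sequence[dict], lexicon: dict | None = None, task: str = "picture"
) -> FeatureVector:
    """Mention counts of the 13 picture information units.

    Matching is case-insensitive over word tokens against each unit's
    synonym set ("exterior" counts toward the window unit by default).
    """
    lexicon = lexicon or resources.information_unit_lexicon()
    if len(lexicon) != 13:
        raise ConfigurationError(
            f"information-unit lexicon must define exactly 13 units, got {len(lexicon)}"
        )
    fv = FeatureVector(task=task, modality="language")
    texts = Counter(t["text"].lower() for t in _words(tokens))
    for unit, synonyms in lexicon.items():
        fv.add("information_units", f"Mentions of {unit} information unit",
               sum(texts.get(s, 0) for s in synonyms))
    return fv


# ---------------------------------------------------------------------------
# reading fluency (12)
# ---------------------------------------------------------------------------


def reading_fluency_features(tokens: Sequence[dict], task: str = "reading") -> FeatureVector:
    """The 12 reading-fluency features.

    Durations are in ms except the pause-duration statistics, reported in
    seconds; speech rate is syllables per second of total task duration.
    """
    fv = FeatureVector(task=task, modality="language")
    g = "reading_fluency"
    words = _words(tokens)
    pauses = [t for t in tokens if t.get("type") == "pause"]
    syll = sum(t.get("syllables", 0) for t in words)
    total_ms = tokens[-1]["end_ms"] - tokens[0]["start_ms"] if tokens else 0.0
    pause_ms = sum(t["end_ms"] - t["start_ms"] for t in pauses)
    speaking_ms = total_ms - pause_ms
    total_s = total_ms / 1000.0

    fv.add(g, "Syllable count", syll)
    fv.add(g, "Pause count", len(pauses))
    fv.add(g, "Overall task duration", total_ms if tokens else _NAN)
    fv.add(g, "Total time spent speaking", speaking_ms if tokens else _NAN)
    fv.add(g, "Proportion of time spent speaking",
           speaking_ms / total_ms if total_ms > 0 else _NAN)
    fv.add(g, "Speech rate", syll / total_s if total_s > 0 else _NAN)
    fv.add(g, "Average syllable duration",
           speaking_ms / syll if syll else _NAN)
    fv.add(g, "Pauses per syllable", len(pauses) / syll if syll else _NAN)
    fv.add(g, "Pause rate", len(pauses) / total_s if total_s > 0 else _NAN)
    pdur_s = np.array([(t["end_ms"] - t["start_ms"]) / 1000.0 for t in pauses])
    fv.add(g, "Max pause duration", float(np.max(pdur_s)) if len(pdur_s) else _NAN)
    fv.add(g, "Mean pause duration", float(np.mean(pdur_s)) if len(pdur_s) else _NAN)
    fv.add(g, "SD of pause duration", float(np.std(pdur_s)) if len(pdur_s) else _NAN)
    return fv


# ---------------------------------------------------------------------------
# acoustic summary features (172)
# ---------------------------------------------------------------------------


def acoustic_summary_features(frames: pd.DataFrame, task: str = "") -> FeatureVector:
    """Four moments per acoustic stream: 43 x {mean, variance, skewness,
    kurtosis} = 172 features.

    Variance is the population variance; kurtosis is Fisher (excess).
    Zero-variance streams have skewness and kurtosis 0 by convention; with
    fewer than two frames the variance-family statistics are missing.
    """
    if list(frames.columns) != list(ACOUSTIC_STREAMS):
        missing = set(ACOUSTIC_STREAMS) - set(frames.columns)
        if missing:
            raise ConfigurationError(f"acoustic matrix lacks streams: {sorted(missing)}")
        frames = frames[list(ACOUSTIC_STREAMS)]
    fv = FeatureVector(task=task, modality="language")
    n = len(frames)
    for stream in ACOUSTIC_STREAMS:
        v = frames[stream].to_numpy(dtype=float)
        fv.add("acoustic", f"Mean of acoustic feature ({stream})",
               float(np.mean(v)) if n else _NAN)
        if n < 2:
            var = skw = kur = _NAN
        else:
            var = float(np.var(v))
            if var == 0.0:
                skw = kur = 0.0
            else:
                skw = float(sps.skew(v))
                kur = float(sps.kurtosis(v))  # Fisher
        fv.add("acoustic", f"Variance of acoustic feature ({stream})", var)
        fv.add("acoustic", f"Skewness of acoustic feature ({stream})", skw)
        fv.add("acoustic", f"Kurtosis of acoustic feature ({stream})", kur)
    return fv


# ---------------------------------------------------------------------------
# per-task composition
# ---------------------------------------------------------------------------


def language_vector(
    task: str,
    tokens: Sequence[dict],
    frames: pd.DataFrame,
    norms: pd.DataFrame | None = None,
    iu_lexicon: dict | None = None,
) -> FeatureVector:
    """Assemble the full language feature vector for one speaking task."""
    fv = FeatureVector(task=task, modality="language")
    if task == "picture":
        fv.update(information_unit_features(tokens, iu_lexicon, task=task))
        fv.update(text_features(tokens, norms, task=task))
    elif task == "memory":
        fv.update(text_features(tokens, norms, task=task))
    elif task == "reading":
        fv.update(reading_fluency_features(tokens, task=task))
    else:
        raise ConfigurationError(f"no language features for task {task!r}")
    fv.update(acoustic_summary_features(frames, task=task))
    return fv
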