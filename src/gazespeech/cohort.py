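"""Synthetic cohort generator for the multi-task speech + gaze pipeline.

Emulates the data layout of a memory-clinic study in which every participant
completes four tasks — pupil calibration (gaze only), picture description
(gaze + speech), paragraph reading (gaze + speech) and memory description
(speech only) — and is labelled patient or control.  Three on-disk forms are
produced per participant:

* gaze sample streams (tab-separated; timestamp, x/y in screen pixels,
  per-eye validity flags, per-eye pupil diameter in mm),
* timestamped transcripts (JSON lines; word / filler / ``[pause]`` tokens
  with POS, syllable and parse-rule annotations from fixed inventories),
* acoustic frame matrices (headered CSV, one row per 10-ms frame, 43 named
  coefficient streams standing in for MFCC-style extraction).

Patient/control differences are injected only through an
:class:`EffectProfile`; at ``effect_scale=0`` the two groups are generated
from identical parameters.  Effect *directions* follow the clinical
literature on dementia (more fixation-interrupting square-wave jerks,
shorter fixations, more reading regressions and re-fixations, longer
reading times, fewer picture information-unit mentions, more and longer
pauses, altered acoustic stream variance); magnitudes are free parameters
of the generator, documented in the methods note.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import resources
from .errors import ConfigurationError, UnsupportedTaskError

SCREEN_W, SCREEN_H = 1920, 1080

TASKS = ("pupil_calibration", "picture", "reading", "memory")
GAZE_TASKS = ("pupil_calibration", "picture", "reading")
SPEAKING_TASKS = ("picture", "reading", "memory")

GAZE_COLUMNS = (
    "timestamp_ms",
    "gaze_x_px",
    "gaze_y_px",
    "validity_left",
    "validity_right",
    "pupil_left_mm",
    "pupil_right_mm",
)

#: The 43 acoustic coefficient streams summarised into 172 features
#: (12 MFCCs + energy + MFCC 13, each with velocity and acceleration,
#: plus a zero-crossing-rate stream).
ACOUSTIC_STREAMS: tuple = tuple(
    f"MFCC {i}{suffix}" for i in range(1, 13) for suffix in ("", " velocity", " acceleration")
) + (
    "energy",
    "energy velocity",
    "energy acceleration",
    "MFCC 13",
    "MFCC 13 velocity",
    "MFCC 13 acceleration",
    "zero-crossing rate",
)

# rng stream codes: one independent child stream per (participant, purpose)
_RNG_LATENTS = 0
_RNG_GAZE = {"pupil_calibration": 1, "picture": 2, "reading": 3}
_RNG_TRANSCRIPT = {"picture": 4, "reading": 5, "memory": 6}
_RNG_ACOUSTIC = {"picture": 7, "reading": 8, "memory": 9}
_RNG_MISSING = 999_983  # cohort-level stream for missing-gaze assignment


@dataclass(frozen=True)
class CohortSpec:
    """Composition and recording parameters of a synthetic cohort."""

    n_patients: int
    n_controls: int
    effect_scale: float = 1.0
    missing_gaze_fraction: float = 36 / 162
    seed: int = 0
    sampling_rate_hz: float = 120.0
    pupil_duration_ms: float = 10_000.0
    picture_duration_ms: float = 40_000.0
    memory_duration_ms: float = 45_000.0

    def __post_init__(self):
        if self.n_patients < 0 or self.n_controls < 0:
            raise ConfigurationError("group sizes must be nonnegative")
        if not 0.0 <= self.missing_gaze_fraction <= 1.0:
            raise ConfigurationError("missing_gaze_fraction must lie in [0, 1]")
        if self.effect_scale < 0:
            raise ConfigurationError("effect_scale must be nonnegative")
        if self.sampling_rate_hz <= 0:
            raise ConfigurationError("sampling_rate_hz must be positive")


@dataclass(frozen=True)
class EffectProfile:
    """Control-group baselines and signed patient deltas per feature family.

    Every generative parameter is realised as ``control + delta * effect_scale``
    for patients and ``control`` for controls, so a zero effect scale makes
    the groups statistically identical.
    """

    # -- pupil-calibration gaze: square-wave-jerk-like excursions -----------
    jerk_rate_hz: float = 0.55          #: control rate of paired excursions
    jerk_rate_delta: float = 0.40       #: patients jerk more often (+)
    jerk_amplitude_px: float = 55.0
    jerk_amplitude_sd_px: float = 12.0
    jerk_amplitude_sd_delta: float = 10.0  #: more variable saccades (+)

    # -- picture-description gaze ------------------------------------------
    dwell_mean_ms: float = 380.0
    dwell_mean_delta: float = -55.0     #: shorter dwells (-)
    window_weight: float = 1.3          #: attention to window/curtain AoIs
    window_weight_delta: float = -0.60  #: patients attend less to exterior (-)

    # -- reading gaze --------------------------------------------------------
    refixation_prob: float = 0.12
    refixation_delta: float = 0.08      #: more re-fixations (+)
    regression_prob: float = 0.06
    regression_delta: float = 0.06      #: more regressive saccades (+)
    word_fixation_ms: float = 215.0
    word_fixation_delta: float = 20.0   #: longer per-word fixations (+)
    skip_prob: float = 0.18
    skip_delta: float = -0.05           #: fewer word skips (-)

    # -- speech/language -----------------------------------------------------
    iu_mention_prob: float = 0.72
    iu_mention_delta: float = -0.10     #: fewer information units mentioned (-)
    pause_rate_per_word: float = 0.055
    pause_rate_delta: float = 0.014     #: more unfilled pauses (+)
    pause_extra_ms: float = 320.0
    pause_extra_delta: float = 70.0    #: longer pauses (+)
    filler_rate_per_word: float = 0.03
    filler_rate_delta: float = 0.010     #: more fillers (+)
    sentence_length_mean: float = 11.0
    sentence_length_delta: float = -0.8  #: shorter sentences (-)
    subordination_prob: float = 0.45
    subordination_delta: float = -0.06  #: less subordination (-)
    reading_pace: float = 1.0
    reading_pace_delta: float = 0.05    #: longer overall reading time (+)

    # -- acoustic frame streams ---------------------------------------------
    #: multiplicative patient delta on the per-participant stream sd
    acoustic_var_delta: dict = field(
        default_factory=lambda: {
            "MFCC 8": -0.09,
            "MFCC 12": -0.09,
            "MFCC 2": -0.07,
            "MFCC 3": 0.07,
        }
    )
    #: additive patient delta on the stream mean, in units of the
    #: between-participant sd of that mean
    acoustic_mean_delta: dict = field(
        default_factory=lambda: {
            "MFCC 5": 0.28,
            "MFCC 4": 0.28,
            "MFCC 3": 0.22,
            "energy": 0.28,
        }
    )
    #: additive patient delta on the skew-normal shape parameter
    acoustic_skew_delta: dict = field(
        default_factory=lambda: {
            "MFCC 6": -0.7,
            "energy acceleration": 0.7,
        }
    )

    @classmethod
    def default(cls) -> "EffectProfile":
        return cls()

    @classmethod
    def null(cls) -> "EffectProfile":
        """A profile whose patient deltas are all zero (for explicit nulls)."""
        prof = cls()
        zeros = {
            f: 0.0
            for f in (
                "jerk_rate_delta", "jerk_amplitude_sd_delta", "dwell_mean_delta",
                "window_weight_delta", "refixation_delta", "regression_delta",
                "word_fixation_delta", "skip_delta", "iu_mention_delta",
                "pause_rate_delta", "pause_extra_delta", "filler_rate_delta",
                "sentence_length_delta", "subordination_delta", "reading_pace_delta",
            )
        }
        return replace(
            prof,
            acoustic_var_delta={},
            acoustic_mean_delta={},
            acoustic_skew_delta={},
            **zeros,
        )


@dataclass
class ParticipantRecord:
    """One synthetic participant: identity, label and on-disk file handles."""

    participant_id: str
    group: str  # "patient" | "control"
    gaze_valid: bool
    index: int  # participant index inside the cohort (seeds the rng streams)
    cohort_seed: int
    files: dict = field(default_factory=dict)

    @property
    def is_patient(self) -> bool:
        return self.group == "patient"


# ---------------------------------------------------------------------------
# group-level and participant-level generative parameters
# ---------------------------------------------------------------------------

_SCALARS = (
    ("jerk_rate_hz", "jerk_rate_delta"),
    ("jerk_amplitude_sd_px", "jerk_amplitude_sd_delta"),
    ("dwell_mean_ms", "dwell_mean_delta"),
    ("window_weight", "window_weight_delta"),
    ("refixation_prob", "refixation_delta"),
    ("regression_prob", "regression_delta"),
    ("word_fixation_ms", "word_fixation_delta"),
    ("skip_prob", "skip_delta"),
    ("iu_mention_prob", "iu_mention_delta"),
    ("pause_rate_per_word", "pause_rate_delta"),
    ("pause_extra_ms", "pause_extra_delta"),
    ("filler_rate_per_word", "filler_rate_delta"),
    ("sentence_length_mean", "sentence_length_delta"),
    ("subordination_prob", "subordination_delta"),
    ("reading_pace", "reading_pace_delta"),
)

# acoustic stream baselines: (mean, within-participant sd)
_ACOUSTIC_BASE = {}
for _s in ACOUSTIC_STREAMS:
    if _s.startswith("energy"):
        _base = (5.0, 1.2) if _s == "energy" else (0.0, 0.5 if "velocity" in _s else 0.22)
    elif _s == "zero-crossing rate":
        _base = (0.10, 0.03)
    elif "velocity" in _s:
        _base = (0.0, 0.45)
    elif "acceleration" in _s:
        _base = (0.0, 0.20)
    else:
        _base = (0.0, 1.0)
    _ACOUSTIC_BASE[_s] = _base

#: between-participant sd of a stream mean, as a fraction of the within sd
_ACOUSTIC_BETWEEN_FRAC = 0.30
#: lognormal sd of the per-participant within-stream sd
_ACOUSTIC_SIGMA_SD = 0.22


def group_params(group: str, profile: EffectProfile, effect_scale: float) -> dict:
    """Generative parameters for one group at a given effect scale."""
    scale = effect_scale if group == "patient" else 0.0
    params = {
        base: getattr(profile, base) + scale * getattr(profile, delta)
        for base, delta in _SCALARS
    }
    params["acoustic"] = {}
    for stream, (mean, sd) in _ACOUSTIC_BASE.items():
        params["acoustic"][stream] = {
            "mean": mean
            + scale
            * profile.acoustic_mean_delta.get(stream, 0.0)
            * _ACOUSTIC_BETWEEN_FRAC
            * sd,
            "sd": sd * (1.0 + scale * profile.acoustic_var_delta.get(stream, 0.0)),
            "skew": scale * profile.acoustic_skew_delta.get(stream, 0.0),
        }
    return params


def _rng(record: ParticipantRecord, purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((record.cohort_seed, record.index, purpose))
    )


def participant_latents(
    record: ParticipantRecord, spec: CohortSpec, profile: EffectProfile
) -> dict:
    """Draw the participant's latent generative parameters.

    Between-participant variability is drawn identically for both groups
    around the group-level parameters, so classes overlap and downstream
    classification is a statistical rather than a deterministic problem.
    """
    g = group_params(record.group, profile, spec.effect_scale)
    rng = _rng(record, _RNG_LATENTS)
    lat = {
        "jerk_rate_hz": max(0.05, rng.normal(g["jerk_rate_hz"], 0.28)),
        "jerk_amplitude_sd_px": max(2.0, rng.normal(g["jerk_amplitude_sd_px"], 6.0)),
        "dwell_mean_ms": max(120.0, rng.normal(g["dwell_mean_ms"], 55.0)),
        "window_weight": max(0.05, rng.normal(g["window_weight"], 0.35)),
        "refixation_prob": float(np.clip(rng.normal(g["refixation_prob"], 0.06), 0.0, 0.9)),
        "regression_prob": float(np.clip(rng.normal(g["regression_prob"], 0.04), 0.0, 0.6)),
        "word_fixation_ms": max(100.0, rng.normal(g["word_fixation_ms"], 22.0)),
        "skip_prob": float(np.clip(rng.normal(g["skip_prob"], 0.05), 0.0, 0.6)),
        "iu_mention_prob": float(np.clip(rng.normal(g["iu_mention_prob"], 0.11), 0.02, 0.99)),
        "pause_rate_per_word": max(0.0, rng.normal(g["pause_rate_per_word"], 0.022)),
        "pause_extra_ms": max(20.0, rng.normal(g["pause_extra_ms"], 110.0)),
        "filler_rate_per_word": max(0.0, rng.normal(g["filler_rate_per_word"], 0.016)),
        "sentence_length_mean": max(4.0, rng.normal(g["sentence_length_mean"], 1.4)),
        "subordination_prob": float(np.clip(rng.normal(g["subordination_prob"], 0.1), 0.0, 1.0)),
        "reading_pace": max(0.5, rng.normal(g["reading_pace"], 0.07)),
        "pupil_base_mm": rng.normal(3.5, 0.3),
        "acoustic": {},
    }
    for stream, p in g["acoustic"].items():
        base_sd = _ACOUSTIC_BASE[stream][1]
        lat["acoustic"][stream] = {
            "mean": rng.normal(p["mean"], _ACOUSTIC_BETWEEN_FRAC * base_sd),
            "sd": p["sd"] * math.exp(rng.normal(0.0, _ACOUSTIC_SIGMA_SD)),
            "skew": rng.normal(p["skew"], 0.4),
        }
    return lat


# ---------------------------------------------------------------------------
# reading-task word layout
# ---------------------------------------------------------------------------


def reading_word_aois() -> list:
    """Word-box AoIs for the fixed reading paragraph.

    Words are laid out left-to-right, wrapping into lines; each AoI carries
    a global reading-order index, its sentence id, a sentence-final marker
    and its line number, plus line start/end markers.
    """
    sentences = resources.reading_paragraph()
    aois = []
    x, line = 160.0, 0
    y0, line_h, box_h, gap = 260.0, 100.0, 56.0, 18.0
    order = 0
    for s_id, words in enumerate(sentences):
        for w_id, word in enumerate(words):
            width = 26.0 + 24.0 * len(word)
            if x + width > 1760.0:
                x, line = 160.0, line + 1
            y = y0 + line * line_h
            aois.append(
                {
                    "name": f"w{order:02d}_{word}",
                    "word": word,
                    "polygon": [
                        [x, y],
                        [x + width, y],
                        [x + width, y + box_h],
                        [x, y + box_h],
                    ],
                    "order": order,
                    "sentence_id": s_id,
                    "sentence_final": w_id == len(words) - 1,
                    "line": line,
                }
            )
            x += width + gap
            order += 1
    # line start/end markers
    for ln in {a["line"] for a in aois}:
        members = [a for a in aois if a["line"] == ln]
        members[0]["line_start"] = True
        members[-1]["line_end"] = True
    return aois


# ---------------------------------------------------------------------------
# gaze simulation
# ---------------------------------------------------------------------------


def _rasterize(
    plan: Sequence[tuple],
    spec: CohortSpec,
    rng: np.random.Generator,
    pupil_base: float,
    degraded: bool,
    jitter_px: float = 2.0,
) -> pd.DataFrame:
    """Turn a segment plan into a sampled gaze stream.

    ``plan`` is a sequence of ``(kind, x0, y0, x1, y1, duration_ms)`` with
    kind ``"fix"`` (hold position with jitter) or ``"move"`` (linear sweep).
    """
    durs = np.array([seg[5] for seg in plan], dtype=float)
    starts = np.concatenate([[0.0], np.cumsum(durs)])
    total = starts[-1]
    step = 1000.0 / spec.sampling_rate_hz
    ts = np.arange(0.0, total, step)
    seg_idx = np.minimum(np.searchsorted(starts, ts, side="right") - 1, len(plan) - 1)
    x = np.empty_like(ts)
    y = np.empty_like(ts)
    for i, seg in enumerate(plan):
        mask = seg_idx == i
        if not mask.any():
            continue
        kind, x0, y0, x1, y1, dur = seg
        if kind == "fix" or dur <= 0:
            x[mask], y[mask] = x0, y0
        else:
            frac = (ts[mask] - starts[i]) / dur
            x[mask] = x0 + frac * (x1 - x0)
            y[mask] = y0 + frac * (y1 - y0)
    x = x + rng.normal(0.0, jitter_px, ts.size)
    y = y + rng.normal(0.0, jitter_px, ts.size)

    drift = 0.05 * np.sin(2 * np.pi * ts / 7000.0 + rng.uniform(0, 2 * np.pi))
    pupil = pupil_base + drift + rng.normal(0.0, 0.02, ts.size)
    asym = rng.normal(0.0, 0.01, ts.size)

    p_valid = 0.30 if degraded else 0.985
    valid_l = rng.random(ts.size) < p_valid
    valid_r = rng.random(ts.size) < p_valid
    return pd.DataFrame(
        {
            "timestamp_ms": ts,
            "gaze_x_px": np.clip(x, 0, SCREEN_W),
            "gaze_y_px": np.clip(y, 0, SCREEN_H),
            "validity_left": valid_l.astype(int),
            "validity_right": valid_r.astype(int),
            "pupil_left_mm": pupil + asym,
            "pupil_right_mm": pupil - asym,
        }
    )


def _pupil_calibration_plan(lat: dict, spec: CohortSpec, rng) -> list:
    cx, cy = SCREEN_W / 2.0, SCREEN_H / 2.0
    plan, t = [], 0.0
    total = spec.pupil_duration_ms
    mean_gap = 1000.0 / lat["jerk_rate_hz"]
    while t < total:
        gap = min(max(250.0, rng.exponential(mean_gap)), total - t)
        plan.append(("fix", cx, cy, cx, cy, gap))
        t += gap
        if t >= total:
            break
        amp = rng.normal(55.0, lat["jerk_amplitude_sd_px"]) * rng.choice([-1.0, 1.0])
        hold = max(80.0, rng.normal(150.0, 25.0))
        plan.append(("move", cx, cy, cx + amp, cy, 25.0))
        plan.append(("fix", cx + amp, cy, cx + amp, cy, hold))
        plan.append(("move", cx + amp, cy, cx, cy, 25.0))
        t += 50.0 + hold
    return plan


def _polygon_point(polygon: Sequence, rng) -> tuple:
    xs = [p[0] for p in polygon]
    ys = [p[1] for p in polygon]
    inset_x = 0.12 * (max(xs) - min(xs))
    inset_y = 0.12 * (max(ys) - min(ys))
    return (
        rng.uniform(min(xs) + inset_x, max(xs) - inset_x),
        rng.uniform(min(ys) + inset_y, max(ys) - inset_y),
    )


def _picture_plan(lat: dict, spec: CohortSpec, rng) -> list:
    aois = resources.picture_aoi_definitions()
    weights = np.array(
        [lat["window_weight"] if a["name"] in ("window", "curtain") else 1.0 for a in aois]
    )
    plan, t = [], 0.0
    x, y = SCREEN_W / 2.0, SCREEN_H / 2.0
    prev = -1
    total = spec.picture_duration_ms
    while t < total:
        w = weights.copy()
        if prev >= 0:
            w[prev] = 0.0
        idx = rng.choice(len(aois), p=w / w.sum())
        prev = idx
        poly = aois[idx]["polygon"]
        n_sub = int(rng.integers(1, 4))
        for k in range(n_sub):
            nx, ny = _polygon_point(poly, rng)
            plan.append(("move", x, y, nx, ny, 35.0 if k == 0 else 22.0))
            dur = max(90.0, rng.normal(lat["dwell_mean_ms"], 70.0))
            plan.append(("fix", nx, ny, nx, ny, dur))
            x, y = nx, ny
            t += dur + (35.0 if k == 0 else 22.0)
            if t >= total:
                break
    return plan


def _reading_plan(lat: dict, spec: CohortSpec, rng) -> list:
    words = reading_word_aois()
    centers = [
        (
            sum(p[0] for p in a["polygon"]) / 4.0,
            sum(p[1] for p in a["polygon"]) / 4.0,
        )
        for a in words
    ]
    plan = []
    x, y = centers[0]
    plan.append(("fix", x, y, x, y, max(100.0, rng.normal(lat["word_fixation_ms"], 40.0))))

    def _fix_at(i, scale=1.0):
        nonlocal x, y
        nx = centers[i][0] + rng.normal(0, 6.0)
        ny = centers[i][1] + rng.normal(0, 4.0)
        plan.append(("move", x, y, nx, ny, 28.0))
        dur = max(80.0, rng.normal(lat["word_fixation_ms"] * scale, 38.0))
        plan.append(("fix", nx, ny, nx, ny, dur))
        x, y = nx, ny

    i = 1
    n = len(words)
    while i < n:
        if i < n - 1 and rng.random() < lat["skip_prob"]:
            i += 1
            continue
        _fix_at(i)
        while rng.random() < lat["refixation_prob"]:
            _fix_at(i, scale=0.65)
        if i > 1 and rng.random() < lat["regression_prob"]:
            back = int(rng.integers(1, min(5, i) + 1))
            _fix_at(i - back, scale=0.8)
            if rng.random() < 0.5 and back > 1:
                _fix_at(i - back + 1, scale=0.6)
            _fix_at(i, scale=0.5)
        i += 1
    # wrap-up gaze on the final word
    _fix_at(n - 1, scale=1.6)
    return plan


def simulate_gaze_stream(
    record: ParticipantRecord,
    task: str,
    spec: CohortSpec,
    profile: EffectProfile | None = None,
) -> pd.DataFrame:
    """Simulate one task's raw gaze sample stream for one participant.

    The memory-description task has no visual stimulus and therefore no
    gaze stream; requesting it raises :class:`UnsupportedTaskError`.
    """
    profile = profile or EffectProfile.default()
    if task == "memory":
        raise UnsupportedTaskError("the memory-description task produces no gaze stream")
    if task not in GAZE_TASKS:
        raise UnsupportedTaskError(f"unknown gaze task: {task!r}")
    lat = participant_latents(record, spec, profile)
    rng = _rng(record, _RNG_GAZE[task])
    if task == "pupil_calibration":
        plan = _pupil_calibration_plan(lat, spec, rng)
    elif task == "picture":
        plan = _picture_plan(lat, spec, rng)
    else:
        plan = _reading_plan(lat, spec, rng)
    return _rasterize(plan, spec, rng, lat["pupil_base_mm"], degraded=not record.gaze_valid)


# ---------------------------------------------------------------------------
# transcript simulation
# ---------------------------------------------------------------------------

_MIN_PAUSE_MS = 250.0


def _vocab_pools():
    vocab = resources.vocabulary()
    pools = {}
    for pos in ("noun", "verb", "adj", "adv", "det", "prep", "pron", "conj", "filler"):
        pools[pos] = list(vocab.index[vocab["pos"] == pos])
    return vocab, pools


_POS_TAG = {
    "noun": "NN", "verb": "VB", "adj": "JJ", "adv": "RB", "pron": "PRP",
    "det": "DT", "prep": "IN", "conj": "CC", "num": "CD", "filler": "UH",
}

_MEMORY_NOUNS = (
    "friend", "trip", "job", "school", "teacher", "summer", "family", "child",
    "children", "beach", "mountain", "dog", "pet", "day", "year", "time",
    "home", "town", "place", "event", "birthday", "wedding", "vacation", "memory",
)
_MEMORY_VERBS = (
    "remember", "met", "went", "visited", "played", "worked", "traveled",
    "moved", "loved", "enjoyed", "lived", "walked",
)
_PICTURE_NOUNS = (
    "kitchen", "counter", "floor", "cupboard", "shelf", "lid", "hand",
    "apron", "chair", "faucet",
)
_PICTURE_VERBS = (
    "is", "are", "standing", "falling", "reaching", "taking", "stealing",
    "washing", "drying", "wiping", "overflowing", "running", "spilling",
    "looking", "laughing", "tipping", "wobbling",
)


def _sentence_words(noun_pool, verb_pool, pools, lat, rng, iu_queue) -> tuple:
    """One sentence as (words, rules, depth) from a small template grammar."""
    target = max(3, int(rng.normal(lat["sentence_length_mean"], 2.2)))
    rules = {"ROOT -> S": 1, "S -> NP VP": 1}
    depth = 3
    words = []

    def _np():
        noun = iu_queue.pop(0) if iu_queue and rng.random() < 0.8 else rng.choice(noun_pool)
        if rng.random() < 0.35:
            adj = rng.choice(pools["adj"])
            words.extend([rng.choice(("the", "a")), adj, noun])
            rules["NP -> DT JJ NN"] = rules.get("NP -> DT JJ NN", 0) + 1
        else:
            words.extend([rng.choice(("the", "a")), noun])
            rules["NP -> DT NN"] = rules.get("NP -> DT NN", 0) + 1

    _np()
    verb = rng.choice(verb_pool)
    words.append(verb)
    if rng.random() < 0.5:
        rules["VP -> VB NP"] = rules.get("VP -> VB NP", 0) + 1
        _np()
    else:
        rules["VP -> VB PP"] = rules.get("VP -> VB PP", 0) + 1
        words.append(rng.choice(pools["prep"]))
        rules["PP -> IN NP"] = rules.get("PP -> IN NP", 0) + 1
        depth += 1
        _np()
    while len(words) < target:
        words.append(rng.choice(pools["prep"]))
        rules["PP -> IN NP"] = rules.get("PP -> IN NP", 0) + 1
        rules["NP -> NP PP"] = rules.get("NP -> NP PP", 0) + 1
        depth += 1
        _np()
    if rng.random() < lat["subordination_prob"]:
        words.append(rng.choice(("because", "while", "when")))
        rules["SBAR -> IN S"] = rules.get("SBAR -> IN S", 0) + 1
        rules["S -> NP VP"] += 1
        depth += 2
        _np()
        words.append(rng.choice(verb_pool))
        rules["VP -> VB"] = rules.get("VP -> VB", 0) + 1
    return words, rules, depth


def simulate_transcript(
    record: ParticipantRecord,
    task: str,
    spec: CohortSpec,
    profile: EffectProfile | None = None,
) -> list:
    """Simulate a timestamped token stream for one speaking task.

    Tokens are dicts ``{type, text, start_ms, end_ms, sentence_id, ...}``
    with POS tags and syllable counts from the bundled vocabulary; the first
    word of each sentence additionally carries a parse-rule count map and a
    tree-depth annotation.  Unfilled-pause tokens always last >= 250 ms.
    """
    profile = profile or EffectProfile.default()
    if task not in SPEAKING_TASKS:
        raise UnsupportedTaskError(f"task {task!r} involves no speech")
    lat = participant_latents(record, spec, profile)
    rng = _rng(record, _RNG_TRANSCRIPT[task])
    vocab, pools = _vocab_pools()
    tokens: list = []
    t = 0.0

    def _emit(tok_type, text, dur, sentence_id, **extra):
        nonlocal t
        text = str(text)
        tok = {
            "type": tok_type,
            "text": text,
            "start_ms": round(t, 1),
            "end_ms": round(t + dur, 1),
            "sentence_id": sentence_id,
        }
        if tok_type == "word":
            row = vocab.loc[text] if text in vocab.index else None
            tok["pos"] = _POS_TAG.get(row["pos"], "NN") if row is not None else "NN"
            tok["syllables"] = int(row["syllables"]) if row is not None else 2
        tok.update(extra)
        tokens.append(tok)
        t += dur + 30.0

    if task == "reading":
        sentences = resources.reading_paragraph()
        pace = lat["reading_pace"]
        for s_id, sent in enumerate(sentences):
            first = True
            for word in sent:
                syl = int(vocab.loc[word, "syllables"]) if word in vocab.index else 2
                dur = max(90.0, rng.normal(175.0 * syl * pace, 28.0))
                extra = {}
                if first:
                    extra = {"rules": {"ROOT -> S": 1, "S -> NP VP": 1}, "depth": 3}
                    first = False
                _emit("word", word, dur, s_id, **extra)
                if rng.random() < lat["pause_rate_per_word"]:
                    pdur = _MIN_PAUSE_MS + rng.exponential(lat["pause_extra_ms"])
                    _emit("pause", "[pause]", pdur, s_id)
            if rng.random() < 0.6:
                pdur = _MIN_PAUSE_MS + rng.exponential(lat["pause_extra_ms"])
                _emit("pause", "[pause]", pdur, s_id)
        return tokens

    # spontaneous tasks: picture description / memory description
    if task == "picture":
        iu_lex = resources.information_unit_lexicon()
        iu_queue = []
        for unit, synonyms in iu_lex.items():
            if rng.random() < lat["iu_mention_prob"]:
                mentions = 1 + rng.geometric(0.7) - 1
                for _ in range(int(mentions)):
                    iu_queue.append(str(rng.choice(synonyms)))
        rng.shuffle(iu_queue)
        noun_pool = list(_PICTURE_NOUNS)
        verb_pool = list(_PICTURE_VERBS)
        total = spec.picture_duration_ms
    else:
        iu_queue = []
        noun_pool = list(_MEMORY_NOUNS)
        verb_pool = list(_MEMORY_VERBS)
        total = spec.memory_duration_ms

    s_id = 0
    while t < total:
        words, rules, depth = _sentence_words(noun_pool, verb_pool, pools, lat, rng, iu_queue)
        first = True
        for word in words:
            if rng.random() < lat["filler_rate_per_word"]:
                _emit("filler", str(rng.choice(pools["filler"])), 270.0, s_id)
            syl = int(vocab.loc[word, "syllables"]) if word in vocab.index else 2
            dur = max(90.0, rng.normal(165.0 * syl, 30.0))
            extra = {"rules": rules, "depth": depth} if first else {}
            first = False
            _emit("word", word, dur, s_id, **extra)
            if rng.random() < lat["pause_rate_per_word"]:
                pdur = _MIN_PAUSE_MS + rng.exponential(lat["pause_extra_ms"])
                _emit("pause", "[pause]", pdur, s_id)
            if t >= total:
                break
        if rng.random() < 0.5:
            pdur = _MIN_PAUSE_MS + rng.exponential(lat["pause_extra_ms"])
            _emit("pause", "[pause]", pdur, s_id)
        s_id += 1
    return tokens


# ---------------------------------------------------------------------------
# acoustic frame simulation
# ---------------------------------------------------------------------------


def simulate_acoustic_frames(
    record: ParticipantRecord,
    task: str,
    spec: CohortSpec,
    profile: EffectProfile | None = None,
) -> pd.DataFrame:
    """Simulate a frames x 43 acoustic coefficient matrix (10-ms frames).

    Streams are Gaussian (skew-normal where a distribution-shape effect is
    configured) with participant-level means and variances drawn around the
    group parameters of the :class:`EffectProfile`.
    """
    profile = profile or EffectProfile.default()
    if task not in SPEAKING_TASKS:
        raise UnsupportedTaskError(f"task {task!r} involves no speech")
    lat = participant_latents(record, spec, profile)
    rng = _rng(record, _RNG_ACOUSTIC[task])
    if task == "picture":
        total = spec.picture_duration_ms
    elif task == "memory":
        total = spec.memory_duration_ms
    else:
        total = 18_000.0 * lat["reading_pace"]
    n = max(2, int(total / 10.0))
    data = {}
    for stream in ACOUSTIC_STREAMS:
        p = lat["acoustic"][stream]
        a = p["skew"]
        if abs(a) > 1e-9:
            # skew-normal via the additive representation, centred so that
            # the configured mean/sd still hold
            delta = a / math.sqrt(1 + a * a)
            u0 = np.abs(rng.standard_normal(n))
            u1 = rng.standard_normal(n)
            z = delta * u0 + math.sqrt(1 - delta * delta) * u1
            z = (z - delta * math.sqrt(2 / math.pi)) / math.sqrt(1 - 2 * delta * delta / math.pi)
            data[stream] = p["mean"] + p["sd"] * z
        else:
            data[stream] = rng.normal(p["mean"], p["sd"], n)
    return pd.DataFrame(data, columns=list(ACOUSTIC_STREAMS))


# ---------------------------------------------------------------------------
# cohort assembly and serialization
# ---------------------------------------------------------------------------


def participant_table(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic participant roster: id, group, gaze validity.

    The number of gaze-missing participants is ``round(fraction * n)``,
    split between groups proportionally (largest-remainder per group) and
    assigned to individuals by a seeded draw stratified by group.
    """
    n_total = spec.n_patients + spec.n_controls
    ids = [f"p{i + 1:03d}" for i in range(spec.n_patients)] + [
        f"c{i + 1:03d}" for i in range(spec.n_controls)
    ]
    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    n_missing = int(round(spec.missing_gaze_fraction * n_total))
    n_missing = min(n_missing, n_total)
    n_miss_p = int(round(n_missing * spec.n_patients / n_total)) if n_total else 0
    n_miss_p = min(n_miss_p, spec.n_patients)
    n_miss_c = min(n_missing - n_miss_p, spec.n_controls)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, _RNG_MISSING)))
    miss_p = rng.choice(spec.n_patients, size=n_miss_p, replace=False) if n_miss_p else []
    miss_c = rng.choice(spec.n_controls, size=n_miss_c, replace=False) if n_miss_c else []
    gaze_valid = np.ones(n_total, dtype=bool)
    for i in miss_p:
        gaze_valid[int(i)] = False
    for i in miss_c:
        gaze_valid[spec.n_patients + int(i)] = False
    return pd.DataFrame(
        {"participant_id": ids, "group": groups, "gaze_valid": gaze_valid}
    )


def cohort_records(spec: CohortSpec) -> list:
    table = participant_table(spec)
    return [
        ParticipantRecord(
            participant_id=row.participant_id,
            group=row.group,
            gaze_valid=bool(row.gaze_valid),
            index=i,
            cohort_seed=spec.seed,
        )
        for i, row in enumerate(table.itertuples(index=False))
    ]


def _write_gaze_tsv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    out["timestamp_ms"] = out["timestamp_ms"].map(lambda v: f"{v:.1f}")
    for col in ("gaze_x_px", "gaze_y_px"):
        out[col] = out[col].map(lambda v: f"{v:.2f}")
    for col in ("pupil_left_mm", "pupil_right_mm"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _write_transcript_jsonl(tokens: Iterable[dict], path: Path) -> None:
    with open(path, "w") as fh:
        for tok in tokens:
            fh.write(json.dumps(tok) + "\n")


def read_transcript_jsonl(path) -> list:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def generate_cohort(
    spec: CohortSpec,
    profile: EffectProfile | None = None,
    out_dir: str | Path | None = None,
) -> list:
    """Generate the full cohort; write all per-participant files if ``out_dir``.

    Returns the list of :class:`ParticipantRecord`.  With an output
    directory the layout is::

        out_dir/
          labels.csv                      # participant_id,group
          aois/picture_aois.json
          aois/reading_aois.json
          participants/<pid>/<task>_{gaze.tsv,transcript.jsonl,acoustic.csv}

    Identical ``(spec, profile)`` produce byte-identical trees.
    """
    profile = profile or EffectProfile.default()
    records = cohort_records(spec)
    if out_dir is None:
        return records
    out = Path(out_dir)
    (out / "participants").mkdir(parents=True, exist_ok=True)
    (out / "aois").mkdir(exist_ok=True)
    participant_table(spec)[["participant_id", "group"]].to_csv(
        out / "labels.csv", index=False, lineterminator="\n"
    )
    with open(out / "aois" / "picture_aois.json", "w") as fh:
        json.dump(list(resources.picture_aoi_definitions()), fh, indent=1)
    with open(out / "aois" / "reading_aois.json", "w") as fh:
        json.dump(reading_word_aois(), fh, indent=1)
    for rec in records:
        pdir = out / "participants" / rec.participant_id
        pdir.mkdir(exist_ok=True)
        for task in GAZE_TASKS:
            path = pdir / f"{task}_gaze.tsv"
            _write_gaze_tsv(simulate_gaze_stream(rec, task, spec, profile), path)
            rec.files[f"{task}_gaze"] = path
        for task in SPEAKING_TASKS:
            tpath = pdir / f"{task}_transcript.jsonl"
            _write_transcript_jsonl(simulate_transcript(rec, task, spec, profile), tpath)
            rec.files[f"{task}_transcript"] = tpath
            apath = pdir / f"{task}_acoustic.csv"
            simulate_acoustic_frames(rec, task, spec, profile).to_csv(
                apath, index=False, float_format="%.5f", lineterminator="\n"
            )
            rec.files[f"{task}_acoustic"] = apath
    return records
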