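"""Eye-movement feature vectors.

Three extractors build the eye modality of the feature schema:

* :func:`summary_features` — 34 task-agnostic statistics (6 fixation,
  22 saccade, 6 pupil) computed over the whole display;
* :func:`aoi_features` — per-AoI templates (9 fixation + 6 pupil per AoI,
  2 transition features per ordered AoI pair) binding gaze to semantic
  regions of the picture or to word boxes of the reading paragraph;
* :func:`reading_gaze_features` — 17 reading-specific features describing
  regressive saccades, pass structure, re-fixations and wrap-up gaze.

Durations are in ms, rates per second of recording, proportions in [0, 1].
Statistics of empty event sets are NaN (missing), except counts and rates,
which are genuinely zero, and regression statistics, which are zero when
no regressive saccade occurred.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .feature_vector import FeatureVector
from .gaze_events import AoI, Fixation, Saccade, assign_fixation_aois

_NAN = float("nan")


def _mean(v):
    return float(np.mean(v)) if len(v) else _NAN


def _sd(v):
    # population convention: a single event has zero spread
    return float(np.std(v)) if len(v) else _NAN


def _max(v):
    return float(np.max(v)) if len(v) else _NAN


def _min(v):
    return float(np.min(v)) if len(v) else _NAN


def _sum0(v):
    return float(np.sum(v)) if len(v) else 0.0


# ---------------------------------------------------------------------------
# task-agnostic summary statistics (6 + 22 + 6 = 34)
# ---------------------------------------------------------------------------


def summary_features(
    fixations: Sequence[Fixation],
    saccades: Sequence[Saccade],
    pupil: tuple | None,
    task_duration_ms: float,
    task: str = "",
) -> FeatureVector:
    """The 34 display-wide fixation/saccade/pupil features.

    ``pupil`` is ``(timestamps_ms, standardized_values)`` or ``None`` when
    the participant has no usable calibration baseline, in which case all
    six pupil features are missing.
    """
    fv = FeatureVector(task=task, modality="eye")
    dur_s = task_duration_ms / 1000.0 if task_duration_ms > 0 else _NAN

    fdur = np.array([f.duration for f in fixations])
    fv.add("fixation", "Fixation count", len(fixations))
    fv.add("fixation", "Fixation rate", len(fixations) / dur_s if dur_s == dur_s else _NAN)
    fv.add("fixation", "Mean fixation duration", _mean(fdur))
    fv.add("fixation", "SD of fixation duration", _sd(fdur))
    fv.add("fixation", "Max fixation duration", _max(fdur))
    sdur = np.array([s.duration for s in saccades])
    total_sacc = float(np.sum(sdur)) if len(sdur) else 0.0
    ratio = float(np.sum(fdur)) / total_sacc if total_sacc > 0 else _NAN
    fv.add("fixation", "Ratio of time spent fixating to saccading", ratio)

    sdist = np.array([s.distance for s in saccades])
    speeds = np.array([s.speed for s in saccades])
    speeds = speeds[~np.isnan(speeds)]
    aang = np.array([s.absolute_angle for s in saccades])
    rang = np.array([s.relative_angle for s in saccades])
    fv.add("saccade", "Saccade count", len(saccades))
    fv.add("saccade", "Saccade rate", len(saccades) / dur_s if dur_s == dur_s else _NAN)
    for stat, fn in (("Sum of", _sum0), ("Mean", _mean), ("SD of", _sd), ("Max", _max)):
        fv.add("saccade", f"{stat} saccade distance", fn(sdist))
    for stat, fn in (("Sum of", _sum0), ("Mean", _mean), ("SD of", _sd), ("Max", _max)):
        fv.add("saccade", f"{stat} saccade duration", fn(sdur))
    fv.add("saccade", "Mean saccade speed", _mean(speeds))
    fv.add("saccade", "SD of saccade speed", _sd(speeds))
    fv.add("saccade", "Max saccade speed", _max(speeds))
    fv.add("saccade", "Min saccade speed", _min(speeds))
    for label, vec in (("absolute", aang), ("relative", rang)):
        fv.add("saccade", f"Sum of {label} saccade angle", _sum0(vec))
        fv.add("saccade", f"Mean {label} saccade angle", _mean(vec))
        fv.add("saccade", f"SD of {label} saccade angle", _sd(vec))
        fv.add("saccade", f"Max {label} saccade angle", _max(vec))

    if pupil is None:
        vals = rates = np.array([])
    else:
        ts, pv = pupil
        keep = ~np.isnan(pv)
        ts, vals = np.asarray(ts, dtype=float)[keep], np.asarray(pv, dtype=float)[keep]
        if vals.size >= 2:
            rates = np.abs(np.diff(vals) / np.diff(ts)) * 1000.0  # mm/s
        else:
            rates = np.array([])
    fv.add("pupil", "Mean pupil size", _mean(vals))
    fv.add("pupil", "SD of pupil size", _sd(vals))
    fv.add("pupil", "Range of pupil size", _max(vals) - _min(vals) if len(vals) else _NAN)
    fv.add("pupil", "Mean pupil change rate", _mean(rates))
    fv.add("pupil", "SD of pupil change rate", _sd(rates))
    fv.add("pupil", "Max pupil change rate", _max(rates))
    return fv


# ---------------------------------------------------------------------------
# AoI-bound features (9 + 6 per AoI, 2 per ordered AoI pair)
# ---------------------------------------------------------------------------


def aoi_features(
    fixations: Sequence[Fixation],
    aois: Sequence[AoI],
    task_duration_ms: float,
    task: str = "",
) -> FeatureVector:
    """Per-AoI fixation/pupil templates and per-AoI-pair transition features."""
    if not aois:
        raise ConfigurationError("aoi_features requires a non-empty AoI set")
    fv = FeatureVector(task=task, modality="eye")
    dur_s = task_duration_ms / 1000.0 if task_duration_ms > 0 else _NAN
    assigned = assign_fixation_aois(fixations, aois)
    total_fix_time = float(np.sum([f.duration for f in fixations])) if fixations else 0.0

    names = [a.name for a in aois]
    by_aoi = {n: [f for f, a in zip(fixations, assigned) if a == n] for n in names}

    for n in names:
        fs = by_aoi[n]
        d = np.array([f.duration for f in fs])
        fv.add("aoi_fixation", f"Fixation count on {n} AoI", len(fs))
        fv.add("aoi_fixation", f"Fixation rate on {n} AoI",
               len(fs) / dur_s if dur_s == dur_s else _NAN)
        fv.add("aoi_fixation", f"Total fixation duration on {n} AoI", _sum0(d))
        fv.add("aoi_fixation", f"Mean fixation duration on {n} AoI", _mean(d))
        fv.add("aoi_fixation", f"SD of fixation duration on {n} AoI", _sd(d))
        fv.add("aoi_fixation", f"Longest fixation on {n} AoI", _max(d))
        fv.add("aoi_fixation", f"Time before first fixation on {n} AoI",
               fs[0].start if fs else _NAN)
        fv.add("aoi_fixation", f"Time of last fixation on {n} AoI",
               fs[-1].start if fs else _NAN)
        fv.add("aoi_fixation", f"Proportion of fixation time on {n} AoI",
               _sum0(d) / total_fix_time if total_fix_time > 0 else 0.0)

        pup = np.array([f.mean_pupil for f in fs])
        pup = pup[~np.isnan(pup)]
        fv.add("aoi_pupil", f"Mean pupil size on {n} AoI", _mean(pup))
        fv.add("aoi_pupil", f"SD of pupil size on {n} AoI", _sd(pup))
        fv.add("aoi_pupil", f"Max pupil size on {n} AoI", _max(pup))
        fv.add("aoi_pupil", f"Min pupil size on {n} AoI", _min(pup))
        # pupil change between consecutive fixations inside the AoI
        mids = np.array([(f.start + f.end) / 2.0 for f, a, m in
                         zip(fixations, assigned, [f.mean_pupil for f in fixations])
                         if a == n and not np.isnan(m)])
        vals = np.array([f.mean_pupil for f, a in zip(fixations, assigned)
                         if a == n and not np.isnan(f.mean_pupil)])
        if vals.size >= 2:
            rates = np.abs(np.diff(vals) / np.diff(mids)) * 1000.0
        else:
            rates = np.array([])
        fv.add("aoi_pupil", f"Mean pupil change rate on {n} AoI", _mean(rates))
        fv.add("aoi_pupil", f"SD of pupil change rate on {n} AoI", _sd(rates))

    counts, out_totals = transition_counts(assigned, names)
    for a in names:
        for b in names:
            if a == b:
                continue
            c = counts.get((a, b), 0)
            fv.add("aoi_transition", f"Number of transitions from {a} AoI to {b} AoI", c)
            prop = c / out_totals[a] if out_totals.get(a, 0) > 0 else 0.0
            fv.add("aoi_transition", f"Proportion of transitions from {a} AoI to {b} AoI", prop)
    return fv


def transition_counts(assigned: Sequence, names: Sequence[str]):
    """Counts of consecutive-fixation transitions between distinct AoIs."""
    counts: dict = {}
    out_totals: dict = {n: 0 for n in names}
    for a, b in zip(assigned[:-1], assigned[1:]):
        if a is None or b is None or a == b:
            continue
        counts[(a, b)] = counts.get((a, b), 0) + 1
        out_totals[a] = out_totals.get(a, 0) + 1
    return counts, out_totals


# ---------------------------------------------------------------------------
# reading-specific features (17)
# ---------------------------------------------------------------------------


def reading_pass_structure(word_path: Sequence[int]) -> dict:
    """Pass bookkeeping over the sequence of fixated word indices.

    A fixation is *first-pass* when no earlier fixation landed on a word
    with a higher reading-order index; otherwise it is a *re-reading*
    (later-pass) fixation.  A later-pass *visit* starts whenever a
    later-pass fixation lands on a different word than the previous
    fixation.  Regressions are consecutive word-fixation pairs moving
    backwards in reading order.
    """
    first_pass = []
    rereading = []
    later_pass_entries = 0
    regressions = []  # (amplitude_words, from_position, to_position)
    max_seen = -1
    for pos, w in enumerate(word_path):
        fp = w >= max_seen
        first_pass.append(fp)
        rereading.append(not fp)
        if not fp and (pos == 0 or word_path[pos - 1] != w):
            later_pass_entries += 1
        if pos > 0 and w < word_path[pos - 1]:
            regressions.append((word_path[pos - 1] - w, pos - 1, pos))
        max_seen = max(max_seen, w)

    # visits: maximal runs on a single word; multi-fixation words have a run >= 2
    multi_words = set()
    refixations = 0
    run_word, run_len = None, 0
    for w in word_path:
        if w == run_word:
            run_len += 1
            refixations += 1
        else:
            if run_len >= 2:
                multi_words.add(run_word)
            run_word, run_len = w, 1
    if run_len >= 2:
        multi_words.add(run_word)
    return {
        "first_pass": first_pass,
        "rereading": rereading,
        "later_pass_entries": later_pass_entries,
        "regressions": regressions,
        "multi_fixation_words": multi_words,
        "refixation_count": refixations,
    }


def reading_gaze_features(
    fixations: Sequence[Fixation],
    word_aois: Sequence[AoI],
    task_duration_ms: float,
    task: str = "reading",
) -> FeatureVector:
    """The 17 regression / pass-structure / wrap-up reading features."""
    if not word_aois:
        raise ConfigurationError("reading features require word AoIs with order indices")
    order = {a.name: a.order for a in word_aois}
    if any(v is None for v in order.values()):
        raise ConfigurationError("word AoIs must carry reading-order indices")
    final_words = {a.name for a in word_aois if a.sentence_final}

    assigned = assign_fixation_aois(fixations, word_aois)
    on_words = [(f, a) for f, a in zip(fixations, assigned) if a is not None]
    word_path = [order[a] for _, a in on_words]
    info = reading_pass_structure(word_path)

    amp = np.array([r[0] for r in info["regressions"]], dtype=float)
    dist = np.array(
        [
            np.hypot(
                on_words[r[1]][0].centroid_x - on_words[r[2]][0].centroid_x,
                on_words[r[1]][0].centroid_y - on_words[r[2]][0].centroid_y,
            )
            for r in info["regressions"]
        ]
    )
    fv = FeatureVector(task=task, modality="eye")
    g = "reading_gaze"
    # no regression at all is a true zero, not a missing measurement
    for label, vec in (("amplitude", amp), ("distance", dist)):
        fv.add(g, f"Max regression {label}", _max(vec) if len(vec) else 0.0)
        fv.add(g, f"Mean regression {label}", _mean(vec) if len(vec) else 0.0)
        fv.add(g, f"SD of regression {label}", _sd(vec) if len(vec) else 0.0)

    dur_s = task_duration_ms / 1000.0 if task_duration_ms > 0 else _NAN
    fp_durs = np.array(
        [f.duration for (f, _), fp in zip(on_words, info["first_pass"]) if fp]
    )
    fv.add(g, "First-pass fixation count", int(sum(info["first_pass"])))
    fv.add(g, "First-pass fixation duration", _sum0(fp_durs))
    fv.add(g, "First-pass fixation rate",
           sum(info["first_pass"]) / dur_s if dur_s == dur_s else _NAN)
    fv.add(g, "Later pass first fixation count", info["later_pass_entries"])
    fv.add(g, "Multi-fixation count", len(info["multi_fixation_words"]))
    fv.add(g, "Refixation count", info["refixation_count"])
    fv.add(g, "Reading fixation count", len(on_words))
    fv.add(g, "Re-reading fixation count", int(sum(info["rereading"])))

    wrap = np.array([f.duration for f, a in on_words if a in final_words])
    fv.add(g, "Max wrap-up gaze duration", _max(wrap))
    fv.add(g, "Mean wrap-up gaze duration", _mean(wrap))
    fv.add(g, "Sum of wrap-up gaze duration", _sum0(wrap))
    return fv
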