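"""Cohort-level feature extraction: raw files -> feature tables.

Reads a cohort directory written by :mod:`gazespeech.cohort` (or any data
in the same on-disk formats), runs gaze event processing and the eye and
language feature extractors, and assembles one participant-indexed
DataFrame per (task, modality).  Participants whose gaze streams fail
validity screening contribute no eye features anywhere; every participant
contributes language features for the three speaking tasks.  Gaze features
are never computed for the memory-description task.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import gaze_events as ge
from .errors import ConfigurationError
from .feature_vector import FeatureVector
from .gaze_features import aoi_features, reading_gaze_features, summary_features
from .language_features import language_vector
from .cohort import read_transcript_jsonl

GAZE_TASKS = ("pupil_calibration", "picture", "reading")
SPEAKING_TASKS = ("picture", "reading", "memory")


def eye_vector_for_task(
    task: str,
    stream: pd.DataFrame,
    pupil_std: np.ndarray | None,
    aois,
    dispersion_px: float = ge.DEFAULT_DISPERSION_PX,
    min_fixation_ms: float = ge.DEFAULT_MIN_FIXATION_MS,
) -> FeatureVector:
    """Full eye feature vector for one task from a raw stream."""
    fixations = ge.detect_fixations(
        stream, dispersion_px=dispersion_px, min_duration_ms=min_fixation_ms,
        pupil=pupil_std,
    )
    saccades = ge.derive_saccades(fixations)
    duration = float(stream["timestamp_ms"].iloc[-1]) if len(stream) else 0.0
    pupil = None
    if pupil_std is not None:
        pupil = (stream["timestamp_ms"].to_numpy(dtype=float), pupil_std)
    fv = summary_features(fixations, saccades, pupil, duration, task=task)
    if task == "picture":
        fv.update(aoi_features(fixations, aois["picture"], duration, task=task))
    elif task == "reading":
        fv.update(aoi_features(fixations, aois["reading"], duration, task=task))
        fv.update(reading_gaze_features(fixations, aois["reading"], duration, task=task))
    return fv


def extract_participant(
    pdir: Path,
    aois: dict,
    gaze_valid_hint: bool | None = None,
    validity_threshold: float = ge.DEFAULT_VALIDITY_THRESHOLD,
    dispersion_px: float = ge.DEFAULT_DISPERSION_PX,
    min_fixation_ms: float = ge.DEFAULT_MIN_FIXATION_MS,
) -> tuple:
    """Extract all feature vectors for one participant directory.

    Returns ``(vectors, validity_report)``; ``vectors`` is a dict
    ``(task, modality) -> FeatureVector``.  Eye vectors are omitted
    entirely when the participant's gaze fails the validity screen.
    """
    pdir = Path(pdir)
    vectors: dict = {}

    streams = {}
    for task in GAZE_TASKS:
        path = pdir / f"{task}_gaze.tsv"
        if path.exists():
            streams[task] = ge.read_gaze_tsv(path)
    report = ge.assess_validity(list(streams.values()), threshold=validity_threshold)

    if report.accepted and len(streams) == len(GAZE_TASKS):
        calib = streams["pupil_calibration"]
        for task in GAZE_TASKS:
            pupil_std = ge.standardize_pupil(streams[task], calib)
            vectors[(task, "eye")] = eye_vector_for_task(
                task, streams[task], pupil_std, aois,
                dispersion_px=dispersion_px, min_fixation_ms=min_fixation_ms,
            )

    for task in SPEAKING_TASKS:
        tokens = read_transcript_jsonl(pdir / f"{task}_transcript.jsonl")
        frames = pd.read_csv(pdir / f"{task}_acoustic.csv")
        vectors[(task, "language")] = language_vector(task, tokens, frames)
    return vectors, report


def load_cohort_aois(cohort_dir: Path) -> dict:
    cohort_dir = Path(cohort_dir)
    picture = cohort_dir / "aois" / "picture_aois.json"
    reading = cohort_dir / "aois" / "reading_aois.json"
    return {"picture": ge.load_aois(picture), "reading": ge.load_aois(reading)}


def extract_cohort(cohort_dir, validity_threshold: float = ge.DEFAULT_VALIDITY_THRESHOLD,
                   dispersion_px: float = ge.DEFAULT_DISPERSION_PX,
                   min_fixation_ms: float = ge.DEFAULT_MIN_FIXATION_MS) -> dict:
    """Extract the whole cohort.

    Returns ``{"features": {(task, modality): DataFrame}, "labels": Series,
    "gaze_valid": Series, "validity": DataFrame}``.
    """
    cohort_dir = Path(cohort_dir)
    labels_path = cohort_dir / "labels.csv"
    if not labels_path.exists():
        raise ConfigurationError(f"cohort label file not found: {labels_path}")
    labels = pd.read_csv(labels_path, index_col="participant_id")["group"]
    aois = load_cohort_aois(cohort_dir)

    rows: dict = {}
    validity_rows = []
    gaze_valid = {}
    for pid in labels.index:
        pdir = cohort_dir / "participants" / pid
        if not pdir.exists():
            raise ConfigurationError(f"participant directory missing: {pdir}")
        vectors, report = extract_participant(
            pdir, aois, validity_threshold=validity_threshold,
            dispersion_px=dispersion_px, min_fixation_ms=min_fixation_ms,
        )
        gaze_valid[pid] = report.accepted
        validity_rows.append(
            {"participant_id": pid, "valid_sample_ratio": report.valid_sample_ratio,
             "accepted": report.accepted, "reason": report.reason}
        )
        for key, fv in vectors.items():
            rows.setdefault(key, {})[pid] = fv.series()

    features = {
        key: pd.DataFrame.from_dict(d, orient="index") for key, d in rows.items()
    }
    return {
        "features": features,
        "labels": labels,
        "gaze_valid": pd.Series(gaze_valid),
        "validity": pd.DataFrame(validity_rows).set_index("participant_id"),
    }


# ---------------------------------------------------------------------------
# on-disk feature table round trip
# ---------------------------------------------------------------------------


def write_feature_tables(extracted: dict, out_dir) -> None:
    """Write features.csv (long layout) + schema.json + validity.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parts = []
    schema = {}
    for (task, modality), df in extracted["features"].items():
        block = df.copy()
        block.insert(0, "task", task)
        block.insert(1, "modality", modality)
        block.index.name = "participant_id"
        parts.append(block.reset_index())
        schema[f"{task}:{modality}"] = list(df.columns)
    pd.concat(parts, ignore_index=True).to_csv(out / "features.csv", index=False)
    with open(out / "feature_schema.json", "w") as fh:
        json.dump(schema, fh, indent=1)
    extracted["validity"].to_csv(out / "validity.csv")
    pd.DataFrame(
        {"group": extracted["labels"], "gaze_valid": extracted["gaze_valid"]}
    ).rename_axis("participant_id").to_csv(out / "cohort_index.csv")


def read_feature_tables(out_dir) -> dict:
    out = Path(out_dir)
    with open(out / "feature_schema.json") as fh:
        schema = json.load(fh)
    long_df = pd.read_csv(out / "features.csv")
    features = {}
    for key, cols in schema.items():
        task, modality = key.split(":")
        block = long_df[(long_df["task"] == task) & (long_df["modality"] == modality)]
        features[(task, modality)] = block.set_index("participant_id")[cols]
    idx = pd.read_csv(out / "cohort_index.csv", index_col="participant_id")
    return {
        "features": features,
        "labels": idx["group"],
        "gaze_valid": idx["gaze_valid"].astype(bool),
        "validity": pd.read_csv(out / "validity.csv", index_col="participant_id"),
    }
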