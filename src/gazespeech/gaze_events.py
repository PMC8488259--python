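"""Gaze event processing: fixations, saccades, pupil series, AoIs.

Raw gaze sample streams are reduced to validated event sequences with a
dispersion-threshold (I-DT) fixation detector.  A fixation is a maximal
window of valid samples whose summed x+y dispersion stays below a pixel
threshold and which spans at least 60 ms; saccades are the movements
between consecutive fixations.  Pupil diameter is combined across eyes and
standardized by subtracting the participant's mean pupil size during the
pupil-calibration task.  Gaps longer than 200 ms between valid samples
(blinks, tracking loss) break fixation windows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from .errors import ConfigurationError

DEFAULT_DISPERSION_PX = 40.0
DEFAULT_MIN_FIXATION_MS = 60.0
DEFAULT_GAP_BREAK_MS = 200.0
DEFAULT_VALIDITY_THRESHOLD = 0.75


@dataclass(frozen=True)
class Fixation:
    start: float
    end: float
    centroid_x: float
    centroid_y: float
    mean_pupil: float  # standardized; NaN when unavailable

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Saccade:
    start: float
    end: float
    from_fixation: int
    to_fixation: int
    distance: float
    duration: float
    speed: float  # px/ms; NaN when duration == 0
    absolute_angle: float  # |angle to horizontal|, [0, pi]
    relative_angle: float  # turn vs previous saccade, [0, pi]; first = 0


@dataclass(frozen=True)
class ValidityReport:
    valid_sample_ratio: float
    accepted: bool
    reason: str


@dataclass(frozen=True)
class AoI:
    """A named polygonal area of interest on the stimulus."""

    name: str
    polygon: "shapely.Polygon"
    order: int | None = None
    sentence_id: int | None = None
    sentence_final: bool = False
    line: int | None = None


# ---------------------------------------------------------------------------
# stream I/O and pupil handling
# ---------------------------------------------------------------------------


def read_gaze_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    ts = df["timestamp_ms"].to_numpy()
    if np.any(np.diff(ts) <= 0):
        raise ConfigurationError(f"timestamps not strictly increasing in {path}")
    return df


def combine_pupil(df: pd.DataFrame) -> np.ndarray:
    """Per-sample pupil diameter: mean of the valid eyes, NaN if neither.

    The tracker reports each eye's physical diameter separately; with no
    stated combination rule we average the two when both are valid and fall
    back to the single valid eye otherwise.
    """
    left = df["pupil_left_mm"].to_numpy(dtype=float)
    right = df["pupil_right_mm"].to_numpy(dtype=float)
    vl = df["validity_left"].to_numpy(dtype=bool)
    vr = df["validity_right"].to_numpy(dtype=bool)
    out = np.full(len(df), np.nan)
    both = vl & vr
    out[both] = 0.5 * (left[both] + right[both])
    only_l = vl & ~vr
    out[only_l] = left[only_l]
    only_r = vr & ~vl
    out[only_r] = right[only_r]
    return out


def calibration_pupil_mean(calibration_df: pd.DataFrame) -> float:
    """Mean combined pupil diameter over the calibration stream (NaN if none)."""
    p = combine_pupil(calibration_df)
    if np.all(np.isnan(p)):
        return float("nan")
    return float(np.nanmean(p))


def standardize_pupil(task_df: pd.DataFrame, calibration_df: pd.DataFrame) -> np.ndarray | None:
    """Subtract the calibration-task mean pupil size from a task's series.

    Returns ``None`` when the calibration stream has no valid pupil sample,
    in which case the participant's pupil features are treated as missing.
    """
    base = calibration_pupil_mean(calibration_df)
    if np.isnan(base):
        return None
    return combine_pupil(task_df) - base


def valid_mask(df: pd.DataFrame) -> np.ndarray:
    """A sample is usable for gaze when at least one eye tracked it."""
    return (df["validity_left"].to_numpy(dtype=bool)) | (
        df["validity_right"].to_numpy(dtype=bool)
    )


def assess_validity(
    streams: Sequence[pd.DataFrame], threshold: float = DEFAULT_VALIDITY_THRESHOLD
) -> ValidityReport:
    """Accept or reject a participant's gaze data by valid-sample ratio."""
    total = sum(len(df) for df in streams)
    if total == 0:
        return ValidityReport(0.0, False, "no gaze samples")
    valid = sum(int(valid_mask(df).sum()) for df in streams)
    ratio = valid / total
    accepted = ratio >= threshold
    reason = "ok" if accepted else f"valid-sample ratio {ratio:.2f} < {threshold:.2f}"
    return ValidityReport(ratio, accepted, reason)


# ---------------------------------------------------------------------------
# fixation detection (I-DT) and saccade derivation
# ---------------------------------------------------------------------------


def _dispersion(x: np.ndarray, y: np.ndarray) -> float:
    return (x.max() - x.min()) + (y.max() - y.min())


def detect_fixations(
    df: pd.DataFrame,
    dispersion_px: float = DEFAULT_DISPERSION_PX,
    min_duration_ms: float = DEFAULT_MIN_FIXATION_MS,
    gap_break_ms: float = DEFAULT_GAP_BREAK_MS,
    pupil: np.ndarray | None = None,
) -> list:
    """Dispersion-threshold fixation identification on one gaze stream.

    Invalid samples are ignored; runs of valid samples separated by more
    than ``gap_break_ms`` are processed independently so blinks and tracking
    losses terminate fixation windows.  ``pupil`` is an optional per-sample
    (standardized) pupil series aligned with ``df``; the fixation's mean
    pupil is averaged over its member samples.
    """
    mask = valid_mask(df)
    if mask.sum() < 2:
        if len(df):
            warnings.warn("gaze stream has < 2 valid samples; no fixations")
        return []
    ts = df["timestamp_ms"].to_numpy(dtype=float)[mask]
    xs = df["gaze_x_px"].to_numpy(dtype=float)[mask]
    ys = df["gaze_y_px"].to_numpy(dtype=float)[mask]
    pup = pupil[mask] if pupil is not None else np.full(ts.size, np.nan)

    # segment at long gaps
    breaks = np.flatnonzero(np.diff(ts) > gap_break_ms)
    seg_bounds = np.concatenate([[0], breaks + 1, [ts.size]])
    fixations: list = []
    for s, e in zip(seg_bounds[:-1], seg_bounds[1:]):
        fixations.extend(
            _idt_segment(ts[s:e], xs[s:e], ys[s:e], pup[s:e], dispersion_px, min_duration_ms)
        )
    return fixations


def _idt_segment(ts, xs, ys, pup, dispersion_px, min_duration_ms) -> list:
    out = []
    n = ts.size
    i = 0
    while i < n:
        # smallest j such that the window spans the minimum duration
        j = int(np.searchsorted(ts, ts[i] + min_duration_ms, side="left"))
        if j >= n:
            break
        if _dispersion(xs[i : j + 1], ys[i : j + 1]) <= dispersion_px:
            while j + 1 < n and _dispersion(xs[i : j + 2], ys[i : j + 2]) <= dispersion_px:
                j += 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                mp = float(np.nanmean(pup[i : j + 1]))
            out.append(
                Fixation(
                    start=float(ts[i]),
                    end=float(ts[j]),
                    centroid_x=float(xs[i : j + 1].mean()),
                    centroid_y=float(ys[i : j + 1].mean()),
                    mean_pupil=mp,
                )
            )
            i = j + 1
        else:
            i += 1
    return out


def derive_saccades(fixations: Sequence[Fixation]) -> list:
    """One saccade per consecutive fixation pair."""
    if len(fixations) < 2:
        return []
    out = []
    prev_vec = None
    for k in range(len(fixations) - 1):
        a, b = fixations[k], fixations[k + 1]
        dx = b.centroid_x - a.centroid_x
        dy = b.centroid_y - a.centroid_y
        dist = float(np.hypot(dx, dy))
        dur = b.start - a.end
        speed = dist / dur if dur > 0 else float("nan")
        abs_angle = abs(float(np.arctan2(dy, dx)))
        if prev_vec is None or dist == 0 or prev_vec[2] == 0:
            rel = 0.0
        else:
            cosang = (prev_vec[0] * dx + prev_vec[1] * dy) / (prev_vec[2] * dist)
            rel = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
        out.append(
            Saccade(
                start=a.end,
                end=b.start,
                from_fixation=k,
                to_fixation=k + 1,
                distance=dist,
                duration=float(dur),
                speed=float(speed),
                absolute_angle=abs_angle,
                relative_angle=rel,
            )
        )
        prev_vec = (dx, dy, dist)
    return out


# ---------------------------------------------------------------------------
# areas of interest
# ---------------------------------------------------------------------------


def build_aois(definitions: Sequence[dict]) -> list:
    """Build AoI objects from ``{"name", "polygon", ...}`` definitions."""
    aois = []
    for d in definitions:
        poly = d["polygon"]
        if len(poly) < 3:
            raise ConfigurationError(f"AoI {d.get('name')!r} has < 3 vertices")
        shp = shapely.Polygon(poly)
        if not shp.is_valid:
            raise ConfigurationError(f"AoI {d.get('name')!r} polygon is not simple")
        aois.append(
            AoI(
                name=d["name"],
                polygon=shp,
                order=d.get("order"),
                sentence_id=d.get("sentence_id"),
                sentence_final=bool(d.get("sentence_final", False)),
                line=d.get("line"),
            )
        )
    return aois


def load_aois(path) -> list:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"AoI definition file not found: {path}")
    with open(path) as fh:
        return build_aois(json.load(fh))


def assign_aoi(x: float, y: float, aois: Sequence[AoI]) -> str | None:
    """Name of the first listed AoI containing the point (boundary counts
    as inside); ``None`` when the point is outside all AoIs."""
    pt = shapely.Point(x, y)
    for aoi in aois:
        if aoi.polygon.covers(pt):
            return aoi.name
    return None


def assign_fixation_aois(fixations: Sequence[Fixation], aois: Sequence[AoI]) -> list:
    """Vectorised AoI assignment of fixation centroids (first listed wins)."""
    if not fixations:
        return []
    pts = shapely.points(
        np.array([[f.centroid_x, f.centroid_y] for f in fixations])
    )
    assigned: list = [None] * len(fixations)
    for aoi in aois:
        inside = shapely.covers(aoi.polygon, pts)
        for i in np.flatnonzero(inside):
            if assigned[i] is None:
                assigned[i] = aoi.name
    return assigned
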