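import numpy as np
import pandas as pd
import pytest

from gazespeech.cohort import CohortSpec, EffectProfile, cohort_records, generate_cohort
from gazespeech.gaze_events import Fixation


def make_stream(points, step_ms=10.0, pupil=3.0, valid=True):
    """Gaze DataFrame from a list of (x, y) sampled every ``step_ms``."""
    n = len(points)
    pts = np.asarray(points, dtype=float)
    v = np.full(n, 1 if valid else 0, dtype=int)
    return pd.DataFrame(
        {
            "timestamp_ms": np.arange(n) * step_ms,
            "gaze_x_px": pts[:, 0],
            "gaze_y_px": pts[:, 1],
            "validity_left": v,
            "validity_right": v,
            "pupil_left_mm": np.full(n, pupil, dtype=float),
            "pupil_right_mm": np.full(n, pupil, dtype=float),
        }
    )


def make_fixation(start, end, x, y, pupil=float("nan")):
    return Fixation(start=float(start), end=float(end), centroid_x=float(x),
                    centroid_y=float(y), mean_pupil=float(pupil))


def word_token(text, start, dur, sentence_id=0, pos="NN", syllables=1, **extra):
    tok = {"type": "word", "text": text, "start_ms": float(start),
           "end_ms": float(start + dur), "sentence_id": sentence_id,
           "pos": pos, "syllables": syllables}
    tok.update(extra)
    return tok


def pause_token(start, dur, sentence_id=0):
    return {"type": "pause", "text": "[pause]", "start_ms": float(start),
            "end_ms": float(start + dur), "sentence_id": sentence_id}


@pytest.fixture(scope="session")
def tiny_spec():
    # short recordings keep the synthetic data cheap without changing the
    # statistical structure under test
    return CohortSpec(
        n_patients=4, n_controls=4, seed=7, missing_gaze_fraction=0.25,
        picture_duration_ms=8_000.0, memory_duration_ms=8_000.0,
    )


@pytest.fixture(scope="session")
def default_profile():
    return EffectProfile.default()


@pytest.fixture(scope="session")
def tiny_records(tiny_spec):
    return cohort_records(tiny_spec)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory, tiny_spec, default_profile):
    out = tmp_path_factory.mktemp("cohort") / "tiny"
    generate_cohort(tiny_spec, default_profile, out_dir=out)
    return out
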