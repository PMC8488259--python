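"""Synthetic cohort generator: composition, determinism, null effect,
effect directions and file formats."""

import filecmp
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from gazespeech.cohort import (
    ACOUSTIC_STREAMS,
    CohortSpec,
    EffectProfile,
    cohort_records,
    generate_cohort,
    group_params,
    participant_table,
    reading_word_aois,
    simulate_acoustic_frames,
    simulate_gaze_stream,
    simulate_transcript,
)
from gazespeech.errors import ConfigurationError, UnsupportedTaskError
from gazespeech.gaze_events import detect_fixations
from gazespeech.gaze_features import reading_gaze_features
from gazespeech import gaze_events as ge


def _tree_bytes(root: Path) -> dict:
    return {p.relative_to(root): p.read_bytes() for p in sorted(root.rglob("*")) if p.is_file()}


class TestComposition:
    def test_group_counts_and_missing_split(self):
        table = participant_table(CohortSpec(79, 83, missing_gaze_fraction=36 / 162, seed=1))
        assert len(table) == 162
        assert (table["group"] == "patient").sum() == 79
        assert (table["group"] == "control").sum() == 83
        # 36 missing overall, split near-evenly between groups
        assert (~table["gaze_valid"]).sum() == 36
        by_group = table.groupby("group")["gaze_valid"].apply(lambda s: (~s).sum())
        assert abs(by_group["patient"] - by_group["control"]) <= 2
        assert table["gaze_valid"].sum() == 126

    def test_missing_assignment_deterministic(self):
        spec = CohortSpec(10, 10, missing_gaze_fraction=0.3, seed=5)
        t1, t2 = participant_table(spec), participant_table(spec)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(-1, 5)
        with pytest.raises(ConfigurationError):
            CohortSpec(5, 5, missing_gaze_fraction=1.5)


class TestDeterminism:
    def test_same_spec_same_seed_bit_identical_trees(self, tmp_path):
        spec = CohortSpec(2, 2, seed=3, picture_duration_ms=5000, memory_duration_ms=5000)
        prof = EffectProfile.default()
        generate_cohort(spec, prof, out_dir=tmp_path / "a")
        generate_cohort(spec, prof, out_dir=tmp_path / "b")
        a, b = _tree_bytes(tmp_path / "a"), _tree_bytes(tmp_path / "b")
        assert list(a) == list(b)
        assert all(a[k] == b[k] for k in a)


class TestNullEffect:
    def test_zero_scale_equalises_group_parameters(self):
        prof = EffectProfile.default()
        p = group_params("patient", prof, effect_scale=0.0)
        c = group_params("control", prof, effect_scale=0.0)
        assert p == c

    def test_group_parameter_gap_monotone_in_effect_scale(self):
        prof = EffectProfile.default()
        gaps = []
        for scale in (0.0, 0.5, 1.0):
            p = group_params("patient", prof, scale)
            c = group_params("control", prof, scale)
            gaps.append(abs(p["refixation_prob"] - c["refixation_prob"]))
        assert gaps[0] == 0.0 and gaps[0] <= gaps[1] <= gaps[2]


class TestGazeStreams:
    def test_pupil_task_sampling_and_center_fixation(self, tiny_records, tiny_spec,
                                                     default_profile):
        rec = tiny_records[0]
        df = simulate_gaze_stream(rec, "pupil_calibration", tiny_spec, default_profile)
        assert len(df) == pytest.approx(1200, abs=2)  # 10 s at 120 Hz
        # the bulk of samples cluster at screen centre
        cx = df["gaze_x_px"].median()
        cy = df["gaze_y_px"].median()
        assert abs(cx - 960) < 15 and abs(cy - 540) < 15
        near = (df["gaze_x_px"] - cx).abs() < 30
        assert near.mean() > 0.5
        assert near.mean() < 1.0  # excursions exist

    def test_memory_task_has_no_gaze(self, tiny_records, tiny_spec, default_profile):
        with pytest.raises(UnsupportedTaskError):
            simulate_gaze_stream(tiny_records[0], "memory", tiny_spec, default_profile)

    def test_patients_refixate_more_when_effect_on(self):
        """Group mean of the downstream refixation count follows the
        generator's configured patient-elevated refixation rate."""
        spec = CohortSpec(16, 16, seed=13, missing_gaze_fraction=0.0)
        prof = EffectProfile.default()
        aois = ge.build_aois(reading_word_aois())
        means = {}
        for grp in ("patient", "control"):
            counts = []
            for rec in cohort_records(spec):
                if rec.group != grp:
                    continue
                stream = simulate_gaze_stream(rec, "reading", spec, prof)
                fx = detect_fixations(stream)
                fv = reading_gaze_features(fx, aois, stream["timestamp_ms"].iloc[-1])
                counts.append(fv.values["Refixation count"])
            means[grp] = np.mean(counts)
        assert means["patient"] > means["control"]


class TestTranscripts:
    @pytest.mark.parametrize("task", ["picture", "reading", "memory"])
    def test_tokens_time_ordered_and_pauses_long_enough(self, task, tiny_records,
                                                        tiny_spec, default_profile):
        toks = simulate_transcript(tiny_records[1], task, tiny_spec, default_profile)
        starts = [t["start_ms"] for t in toks]
        ends = [t["end_ms"] for t in toks]
        assert all(e > s for s, e in zip(starts, ends))
        assert all(s2 >= e1 for e1, s2 in zip(ends[:-1], starts[1:]))
        for t in toks:
            if t["type"] == "pause":
                assert t["end_ms"] - t["start_ms"] >= 250.0

    def test_reading_words_come_from_paragraph(self, tiny_records, tiny_spec,
                                               default_profile):
        from gazespeech.resources import reading_paragraph

        vocab = {w for sent in reading_paragraph() for w in sent}
        toks = simulate_transcript(tiny_records[0], "reading", tiny_spec, default_profile)
        words = [t["text"] for t in toks if t["type"] == "word"]
        assert words and set(words) <= vocab

    def test_patients_mention_fewer_information_units(self):
        from gazespeech.language_features import information_unit_features

        spec = CohortSpec(20, 20, seed=29, picture_duration_ms=30_000)
        prof = EffectProfile.default()
        means = {}
        for grp in ("patient", "control"):
            distinct = []
            for rec in cohort_records(spec):
                if rec.group != grp:
                    continue
                toks = simulate_transcript(rec, "picture", spec, prof)
                fv = information_unit_features(toks)
                distinct.append(sum(1 for v in fv.values.values() if v > 0))
            means[grp] = np.mean(distinct)
        assert means["patient"] < means["control"]


class TestAcousticFrames:
    def test_always_43_streams(self, tiny_records, tiny_spec, default_profile):
        frames = simulate_acoustic_frames(tiny_records[0], "picture", tiny_spec,
                                          default_profile)
        assert frames.shape[1] == 43
        assert list(frames.columns) == list(ACOUSTIC_STREAMS)
        assert np.isfinite(frames.to_numpy()).all()

    def test_mfcc8_variance_lower_in_patients_on_average(self):
        spec = CohortSpec(25, 25, seed=17, picture_duration_ms=20_000)
        prof = EffectProfile.default()
        var = {"patient": [], "control": []}
        for rec in cohort_records(spec):
            frames = simulate_acoustic_frames(rec, "picture", spec, prof)
            var[rec.group].append(frames["MFCC 8"].var())
        assert np.mean(var["patient"]) < np.mean(var["control"])

    def test_zero_scale_variances_match(self):
        spec = CohortSpec(25, 25, seed=17, effect_scale=0.0, picture_duration_ms=10_000)
        prof = EffectProfile.default()
        var = {"patient": [], "control": []}
        for rec in cohort_records(spec):
            frames = simulate_acoustic_frames(rec, "memory", spec, prof)
            var[rec.group].append(frames["MFCC 8"].var())
        # identical generative parameters: group means differ only by noise
        p, c = np.mean(var["patient"]), np.mean(var["control"])
        assert abs(p - c) / c < 0.25


class TestCohortFiles:
    def test_layout_and_formats(self, tiny_cohort_dir, tiny_spec):
        labels = pd.read_csv(tiny_cohort_dir / "labels.csv")
        assert list(labels.columns) == ["participant_id", "group"]
        assert len(labels) == 8
        aois = json.loads((tiny_cohort_dir / "aois" / "picture_aois.json").read_text())
        assert [a["name"] for a in aois] == [
            "cookie", "cookie jar", "boy", "girl", "woman", "stool", "plate",
            "dishcloth", "water", "window", "curtain", "dishes", "sink",
        ]
        pdir = tiny_cohort_dir / "participants" / labels["participant_id"].iloc[0]
        gaze = pd.read_csv(pdir / "picture_gaze.tsv", sep="\t")
        assert list(gaze.columns) == [
            "timestamp_ms", "gaze_x_px", "gaze_y_px", "validity_left",
            "validity_right", "pupil_left_mm", "pupil_right_mm",
        ]

    def test_reading_word_aois_ordered_with_sentence_markers(self):
        aois = reading_word_aois()
        orders = [a["order"] for a in aois]
        assert orders == list(range(len(aois)))
        assert sum(a["sentence_final"] for a in aois) == 4  # one per sentence
        assert any(a.get("line_start") for a in aois)
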