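"""Eye-movement feature schema and values: summary statistics, AoI
templates, transitions and reading-specific features."""

import numpy as np
import pytest

import _oracles
from conftest import make_fixation
from gazespeech.cohort import reading_word_aois
from gazespeech.errors import ConfigurationError
from gazespeech.gaze_events import build_aois, derive_saccades
from gazespeech.gaze_features import (
    aoi_features,
    reading_gaze_features,
    summary_features,
    transition_counts,
)
from gazespeech.resources import picture_aoi_definitions

PICTURE_AOIS = build_aois(picture_aoi_definitions())


def _centroid(aoi):
    return aoi.polygon.centroid.x, aoi.polygon.centroid.y


def _fix_in(aoi_name, start, end, aois=PICTURE_AOIS, pupil=float("nan")):
    aoi = next(a for a in aois if a.name == aoi_name)
    x, y = _centroid(aoi)
    return make_fixation(start, end, x, y, pupil)


class TestSummaryFeatures:
    def test_schema_is_6_22_6(self):
        fv = summary_features([], [], None, 10_000.0)
        sizes = fv.group_sizes()
        assert sizes == {"fixation": 6, "saccade": 22, "pupil": 6}
        assert len(fv) == 34

    def test_hand_arithmetic_on_two_fixations(self):
        fx = [make_fixation(0, 500, 0, 0), make_fixation(600, 1100, 200, 0)]
        sac = derive_saccades(fx)
        fv = summary_features(fx, sac, None, 1100.0).values
        assert fv["Mean saccade distance"] == pytest.approx(200.0)
        assert fv["Mean saccade speed"] == pytest.approx(2.0)
        assert fv["Ratio of time spent fixating to saccading"] == pytest.approx(10.0)
        assert fv["Fixation count"] == 2
        assert fv["Sum of saccade distance"] == pytest.approx(200.0)

    def test_single_fixation_zero_saccades(self):
        fx = [make_fixation(0, 500, 10, 10)]
        fv = summary_features(fx, [], None, 1000.0).values
        assert fv["Saccade count"] == 0
        assert fv["Saccade rate"] == 0
        assert np.isnan(fv["Mean saccade distance"])

    def test_empty_events_counts_zero_statistics_missing(self):
        fv = summary_features([], [], None, 1000.0).values
        assert fv["Fixation count"] == 0 and fv["Fixation rate"] == 0
        assert np.isnan(fv["Mean fixation duration"])
        assert np.isnan(fv["Mean pupil size"])  # no pupil baseline

    def test_pupil_statistics(self):
        ts = np.array([0.0, 100.0, 200.0])
        vals = np.array([0.1, 0.3, 0.2])
        fv = summary_features([], [], (ts, vals), 1000.0).values
        assert fv["Mean pupil size"] == pytest.approx(0.2)
        assert fv["Range of pupil size"] == pytest.approx(0.2)
        # |0.2|/100ms and |-0.1|/100ms in mm/s
        assert fv["Mean pupil change rate"] == pytest.approx((2.0 + 1.0) / 2)


class TestAoIFeatures:
    def test_template_count_for_13_aois(self):
        fv = aoi_features([], PICTURE_AOIS, 1000.0)
        sizes = fv.group_sizes()
        assert sizes["aoi_fixation"] == 13 * 9
        assert sizes["aoi_pupil"] == 13 * 6
        assert sizes["aoi_transition"] == 13 * 12 * 2
        assert len(fv) == 507

    def test_toy_transition_path(self):
        fx = [
            _fix_in("window", 0, 200),
            _fix_in("curtain", 300, 500),
            _fix_in("window", 600, 800),
        ]
        fv = aoi_features(fx, PICTURE_AOIS, 1000.0).values
        assert fv["Number of transitions from curtain AoI to window AoI"] == 1
        assert fv["Number of transitions from window AoI to curtain AoI"] == 1
        assert fv["Number of transitions from boy AoI to cookie AoI"] == 0
        assert fv["Proportion of transitions from curtain AoI to window AoI"] == 1.0

    def test_unfixated_aoi_counts_zero_times_missing(self):
        fx = [_fix_in("boy", 0, 300)]
        fv = aoi_features(fx, PICTURE_AOIS, 1000.0).values
        assert fv["Fixation count on water AoI"] == 0
        assert fv["Proportion of fixation time on water AoI"] == 0.0
        assert np.isnan(fv["Time before first fixation on water AoI"])
        assert fv["Fixation count on boy AoI"] == 1
        assert fv["Proportion of fixation time on boy AoI"] == 1.0

    def test_empty_aoi_set_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            aoi_features([], [], 1000.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_transition_counts_match_path_oracle(self, seed):
        rng = np.random.default_rng(seed)
        names = [a.name for a in PICTURE_AOIS]
        path = [rng.choice(names + [None]) for _ in range(40)]
        counts, out_totals = transition_counts(path, names)
        assert counts == _oracles.transition_counts_path(path)
        # proportions per source sum to one whenever a transition exists
        for a in names:
            total = sum(c for (s, _), c in counts.items() if s == a)
            assert total == out_totals[a]


class TestReadingFeatures:
    WORDS = build_aois(reading_word_aois())

    def _path_to_fixations(self, word_indices, dur=200.0):
        out, t = [], 0.0
        for w in word_indices:
            aoi = self.WORDS[w]
            x, y = _centroid(aoi)
            out.append(make_fixation(t, t + dur, x, y))
            t += dur + 50.0
        return out

    def test_feature_count_is_17_with_3_wrap_up(self):
        fx = self._path_to_fixations([0, 1, 2])
        fv = reading_gaze_features(fx, self.WORDS, 2000.0)
        assert len(fv) == 17
        assert sum(1 for n in fv.values if "wrap-up" in n) == 3

    def test_monotone_path_has_zero_regressions(self):
        fx = self._path_to_fixations(list(range(8)))
        fv = reading_gaze_features(fx, self.WORDS, 3000.0).values
        assert fv["Max regression amplitude"] == 0.0
        assert fv["Mean regression distance"] == 0.0
        assert fv["Re-reading fixation count"] == 0

    def test_regression_and_rereading_on_toy_path(self):
        fx = self._path_to_fixations([1, 2, 3, 1, 4])
        fv = reading_gaze_features(fx, self.WORDS, 3000.0).values
        assert fv["Max regression amplitude"] == 2.0
        assert fv["Re-reading fixation count"] == 1
        assert fv["Later pass first fixation count"] == 1
        assert fv["Reading fixation count"] == 5
        assert fv["First-pass fixation count"] == 4

    def test_refixation_and_multi_fixation_counting(self):
        fx = self._path_to_fixations([0, 0, 1, 2, 2, 2, 3])
        fv = reading_gaze_features(fx, self.WORDS, 3000.0).values
        assert fv["Refixation count"] == 3  # 0->0, 2->2, 2->2
        assert fv["Multi-fixation count"] == 2  # words 0 and 2

    def test_wrap_up_gaze_on_sentence_final_words(self):
        finals = [a for a in self.WORDS if a.sentence_final]
        idx = self.WORDS.index(finals[0])
        fx = self._path_to_fixations([0, 1, idx], dur=400.0)
        fv = reading_gaze_features(fx, self.WORDS, 3000.0).values
        assert fv["Sum of wrap-up gaze duration"] == pytest.approx(400.0)
        assert fv["Max wrap-up gaze duration"] == pytest.approx(400.0)

    def test_no_word_aois_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            reading_gaze_features([], [], 1000.0)

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_pass_structure_matches_oracle_on_random_paths(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        path = []
        w = 0
        for _ in range(n):
            w = max(0, min(len(self.WORDS) - 1,
                           w + int(rng.choice([-3, -2, -1, 0, 1, 1, 1, 2]))))
            path.append(w)
        fx = self._path_to_fixations(path)
        fv = reading_gaze_features(fx, self.WORDS, 5000.0).values
        expect = _oracles.reading_pass_oracle(path)
        assert fv["First-pass fixation count"] == expect["first_pass_count"]
        assert fv["Re-reading fixation count"] == expect["rereading_count"]
        assert fv["Later pass first fixation count"] == expect["later_pass_entries"]
        assert fv["Refixation count"] == expect["refixation_count"]
        assert fv["Multi-fixation count"] == len(expect["multi_fixation_words"])
        amps = expect["regression_amplitudes"]
        assert fv["Max regression amplitude"] == (max(amps) if amps else 0.0)
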