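"""Intensity extraction, calibration, OWA aggregation and the seven indexes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from auscult import indexing as idx
from auscult.types import (
    OrdinalLabel,
    ParameterError,
    PredictionRaster,
    RecordingIntensity,
)

C = {name: i for i, name in enumerate(
    ("wheeze", "rhonchi", "fine_crackle", "coarse_crackle", "inspiration", "expiration", "noise")
)}


def make_raster(n_frames: int, **columns) -> PredictionRaster:
    values = np.zeros((n_frames, 7))
    for name, mask in columns.items():
        values[np.asarray(mask), C[name]] = 1.0
    return PredictionRaster(values, 0.1)


class TestRawIntensity:
    def test_all_zero_raster_signals_bad_quality(self):
        raw = idx.raster_to_raw_intensity(make_raster(50))
        assert not raw.breath_detected
        assert all(v == 0.0 for v in raw.scores.values())

    def test_full_coverage_scores_one(self):
        raster = make_raster(40, inspiration=range(40), wheeze=range(40))
        raw = idx.raster_to_raw_intensity(raster)
        assert raw.breath_detected
        assert raw.scores["wheezes"] == 1.0

    def test_noise_frames_excluded_from_both_counts(self):
        # 100 breathing frames; wheeze on 30 of them; 20 frames marked noise,
        # 5 of which carry wheeze -> (30-5) / (100-20) = 0.3125
        raster = make_raster(
            100, inspiration=range(100), wheeze=range(30), noise=list(range(25, 45))
        )
        raw = idx.raster_to_raw_intensity(raster)
        assert raw.scores["wheezes"] == pytest.approx(25 / 80)

    def test_zero_frames_rejected(self):
        with pytest.raises(Exception):
            idx.raster_to_raw_intensity(PredictionRaster(np.zeros((0, 7)), 0.1))


class TestCalibration:
    def test_preserves_ordering(self):
        labels = [OrdinalLabel(l) for l in (0, 0, 1, 1, 2, 2)]
        cal = idx.calibrate_intensity([0.0, 0.1, 0.4, 0.5, 0.8, 0.9], labels)
        out = cal(np.array([0.0, 0.1, 0.4, 0.5, 0.8, 0.9]))
        assert np.all(np.diff(out) >= 0)

    def test_single_level_degenerates_to_identity_with_warning(self):
        labels = [OrdinalLabel(0)] * 4
        with pytest.warns(UserWarning):
            cal = idx.calibrate_intensity([0.1, 0.2, 0.3, 0.4], labels)
        assert cal(0.37) == pytest.approx(0.37)

    def test_matches_pool_adjacent_violators_on_ordered_anchors(self):
        # anchors (0,0,.5,.5,1,1) are already isotonic in the scores, so the
        # PAV solution is the anchors themselves
        scores = [0.0, 0.1, 0.4, 0.5, 0.8, 0.9]
        labels = [OrdinalLabel(l) for l in (0, 0, 1, 1, 2, 2)]
        cal = idx.calibrate_intensity(scores, labels)
        assert np.allclose(cal(np.array(scores)), [0.0, 0.0, 0.5, 0.5, 1.0, 1.0])

    def test_matches_pool_adjacent_violators_with_violation(self):
        # sorted by score the anchors are (0.5, 1.0, 0.0); PAV pools all three
        # blocks to their mean 0.5
        scores = [0.1, 0.9, 0.5]
        labels = [OrdinalLabel(1), OrdinalLabel(0), OrdinalLabel(2)]
        cal = idx.calibrate_intensity(scores, labels)
        assert np.allclose(cal(np.array([0.1, 0.5, 0.9])), 0.5)


class TestOWA:
    def test_constant_values(self):
        w = idx.derive_owa_weights(3, decay=0.7)
        assert idx.owa_aggregate([0.5, 0.5, 0.5], w) == pytest.approx(0.5)

    def test_max_selecting_weights(self):
        w = idx.OWAWeights((1.0, 0.0, 0.0))
        assert idx.owa_aggregate([0.2, 0.9, 0.4], w) == pytest.approx(0.9)

    def test_hand_computed_sorted_weighted_sum(self):
        w = idx.OWAWeights((0.5, 0.3, 0.2))
        assert idx.owa_aggregate([0.8, 0.2, 0.6], w) == pytest.approx(0.62)

    def test_errors(self):
        with pytest.raises(ParameterError):
            idx.owa_aggregate([0.1, 0.2], idx.OWAWeights((1.0,)))
        with pytest.raises(ParameterError):
            idx.OWAWeights((0.5, 0.4))  # does not sum to 1
        with pytest.raises(ParameterError):
            idx.derive_owa_weights(0)

    def test_weight_family(self):
        assert np.allclose(idx.derive_owa_weights(4, 1.0).weights, 0.25)
        assert idx.derive_owa_weights(1, 0.3).weights == (1.0,)
        assert np.allclose(idx.derive_owa_weights(3, 0.5).weights, [4 / 7, 2 / 7, 1 / 7])

    @settings(max_examples=100, deadline=None)
    @given(
        values=st.lists(st.floats(0, 1), min_size=1, max_size=8),
        decay=st.floats(0.05, 1.0),
    )
    def test_bounded_by_min_and_max(self, values, decay):
        w = idx.derive_owa_weights(len(values), decay)
        out = idx.owa_aggregate(values, w)
        assert min(values) - 1e-12 <= out <= max(values) + 1e-12
        if decay == 1.0:
            assert out == pytest.approx(np.mean(values))


def intensity(rid="r", wh=0.0, rh=0.0, fc=0.0, cc=0.0, quality="good"):
    return RecordingIntensity(rid, wh, rh, fc, cc, quality)


class TestExaminationIndexes:
    def test_zero_intensities_propagate(self):
        out = idx.compute_examination_indexes([intensity(), intensity()])
        assert all(v == 0.0 for v in out.as_dict().values())

    def test_single_wheeze_saturation(self):
        out = idx.compute_examination_indexes([intensity(wh=1.0)])
        d = out.as_dict()
        assert d["wheezes_index"] == d["continuous_phenomena_index"] == d["overall_index"] == 1.0
        assert d["rhonchi_index"] == d["fine_crackles_index"] == d["transient_phenomena_index"] == 0.0

    def test_composition_of_owa_oracles(self):
        its = [intensity("a", wh=0.8), intensity("b", wh=0.2), intensity("c", wh=0.6)]
        out = idx.compute_examination_indexes(its, decay=0.5)
        assert out.wheezes_index == pytest.approx(0.8 * 4 / 7 + 0.6 * 2 / 7 + 0.2 * 1 / 7)

    def test_bad_quality_excluded_and_all_bad_uncomputable(self):
        its = [intensity("a", wh=1.0, quality="bad"), intensity("b", wh=0.4)]
        out = idx.compute_examination_indexes(its)
        assert out.wheezes_index == pytest.approx(0.4)
        with pytest.raises(idx.UncomputableExaminationError):
            idx.compute_examination_indexes([intensity(quality="bad")])

    def test_permutation_invariance(self):
        its = [intensity("a", wh=0.8, fc=0.1), intensity("b", rh=0.5), intensity("c", cc=0.9)]
        a = idx.compute_examination_indexes(its).as_dict()
        b = idx.compute_examination_indexes(its[::-1]).as_dict()
        assert a == b

    @settings(max_examples=60, deadline=None)
    @given(data=st.data())
    def test_range_and_monotonicity(self, data):
        n = data.draw(st.integers(1, 5))
        vals = data.draw(
            st.lists(
                st.tuples(*[st.floats(0, 1) for _ in range(4)]), min_size=n, max_size=n
            )
        )
        its = [intensity(f"r{i}", *v) for i, v in enumerate(vals)]
        base = idx.compute_examination_indexes(its).as_dict()
        assert all(0.0 <= v <= 1.0 for v in base.values())
        # bump one recording's wheeze intensity: no index may decrease
        k = data.draw(st.integers(0, n - 1))
        bumped = list(its)
        bumped[k] = intensity(
            f"r{k}", min(1.0, vals[k][0] + 0.3), vals[k][1], vals[k][2], vals[k][3]
        )
        after = idx.compute_examination_indexes(bumped).as_dict()
        for name in base:
            assert after[name] >= base[name] - 1e-12
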