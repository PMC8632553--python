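"""Detector contracts: targets, shapes, ranges, training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from auscult import detection as det
from auscult import synthesis as syn
from auscult.types import CLASS_NAMES, AudioRecording, DataError, FrameAnnotation, ParameterError


class TestAnnotationsToTarget:
    def test_empty_annotations_all_zero(self):
        target = det.annotations_to_target([], 1.0, 0.1)
        assert target.shape == (10, 7)
        assert not target.any()

    def test_full_overlap_sets_whole_column(self):
        target = det.annotations_to_target([FrameAnnotation(0.0, 1.0, "wheeze")], 1.0, 0.1)
        assert np.array_equal(target[:, CLASS_NAMES.index("wheeze")], np.ones(10))

    def test_partial_overlap_marks_touched_frames(self):
        target = det.annotations_to_target([FrameAnnotation(0.05, 0.15, "wheeze")], 1.0, 0.1)
        col = target[:, CLASS_NAMES.index("wheeze")]
        assert np.array_equal(np.flatnonzero(col), [0, 1])

    def test_annotation_beyond_duration_rejected(self):
        with pytest.raises(DataError):
            det.annotations_to_target([FrameAnnotation(0.5, 2.0, "noise")], 1.0, 0.1)

    @settings(max_examples=50, deadline=None)
    @given(
        onset=st.floats(0.0, 4.9),
        length=st.floats(0.01, 2.0),
        hop=st.sampled_from([0.05, 0.1, 0.25]),
        label=st.sampled_from(CLASS_NAMES),
    )
    def test_matches_bruteforce_interval_overlap(self, onset, length, hop, label):
        duration = 7.0
        offset = min(onset + length, duration)
        ann = FrameAnnotation(onset, offset, label)
        target = det.annotations_to_target([ann], duration, hop)
        n = target.shape[0]
        for f in range(n):  # oracle: per-frame open-interval overlap test
            lo, hi = f * hop, (f + 1) * hop
            expect = (onset < hi - 1e-12) and (offset > lo + 1e-12)
            assert target[f, CLASS_NAMES.index(label)] == pytest.approx(float(expect))


class TestArchitecture:
    def test_full_preset_parameter_count_near_target(self):
        model = det.build_detector("full")
        assert 6_660_000 <= model.n_trainable_parameters() <= 8_140_000

    def test_small_preset_is_compact(self):
        model = det.build_detector("small")
        assert model.n_trainable_parameters() < 100_000

    def test_unknown_preset_rejected(self):
        with pytest.raises(ParameterError):
            det.build_detector("huge")

    def test_raster_shape_and_range(self, mini_model):
        rec, _ = syn.simulate_recording(
            syn.SimulationConfig(duration_s=10.0, sample_rate_hz=4000, n_wheeze=1, seed=4)
        )
        raster = det.predict_raster(mini_model, rec)
        assert raster.n_frames == 100  # ceil(10 s / 0.1 s)
        assert raster.values.min() >= 0.0 and raster.values.max() <= 1.0

    def test_mean_length_recording_frame_count(self, mini_model):
        # 14.6 s at a 0.1 s hop -> 146 output frames
        rec, _ = syn.simulate_recording(
            syn.SimulationConfig(duration_s=14.6, sample_rate_hz=4000, seed=0)
        )
        assert det.predict_raster(mini_model, rec).n_frames == 146

    def test_target_and_raster_frame_counts_agree(self, mini_model):
        for dur in (3.0, 9.95, 14.6):
            rec, anns = syn.simulate_recording(
                syn.SimulationConfig(duration_s=dur, sample_rate_hz=4000, seed=1)
            )
            raster = det.predict_raster(mini_model, rec)
            target = det.annotations_to_target(anns, dur, raster.frame_hop_s)
            assert raster.n_frames == target.shape[0]


class TestTraining:
    def test_zero_learning_rate_is_identity(self):
        data = syn.make_detector_dataset(2, seed=0, duration_s=2.0)
        model = det.build_detector("small", seed=0)
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        det.train_detector(model, data, epochs=1, learning_rate=0.0)
        after = model.state_arrays()
        for k in before:
            if "running" in k:  # batch-norm statistics update regardless
                continue
            assert np.array_equal(before[k], after[k]), k

    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            det.train_detector(det.build_detector("small"), [])

    def test_loss_decreases(self, trained_small):
        _, history = trained_small
        assert history[-1] < history[0]

    def test_inference_is_deterministic(self, mini_model):
        rec, _ = syn.simulate_recording(
            syn.SimulationConfig(duration_s=4.0, sample_rate_hz=4000, n_wheeze=2, seed=5)
        )
        r1 = det.predict_raster(mini_model, rec)
        r2 = det.predict_raster(mini_model, rec)
        assert np.array_equal(r1.values, r2.values)

    def test_silence_scores_below_wheeze_rich_input(self, trained_small):
        model, _ = trained_small
        silence = AudioRecording(np.zeros(4 * 4000), 4000)
        rich, _ = syn.simulate_recording(
            syn.SimulationConfig(duration_s=4.0, sample_rate_hz=4000, n_wheeze=3, seed=6)
        )
        quiet = det.predict_raster(model, silence).column("wheeze").mean()
        loud = det.predict_raster(model, rich).column("wheeze").mean()
        assert quiet < loud

    def test_empty_waveform_rejected(self, mini_model):
        with pytest.raises(DataError):
            det.predict_internal(mini_model, AudioRecording(np.zeros(0), 4000))

    def test_class_threshold_selection(self, mini_model):
        data = syn.make_detector_dataset(10, seed=42)
        thr = det.select_class_thresholds(mini_model, data)
        assert set(thr) == set(CLASS_NAMES)
        assert all(0.0 < v <= 1.0 for v in thr.values())
        assert thr["noise"] == 0.5  # single-outcome class keeps the default
        assert mini_model.class_thresholds == thr

    def test_checkpoint_roundtrip(self, mini_model, tmp_path):
        path = tmp_path / "model.npz"
        mini_model.save(path)
        clone = det.RasterDetector.load(path)
        assert clone.class_thresholds == mini_model.class_thresholds
        rec, _ = syn.simulate_recording(
            syn.SimulationConfig(duration_s=3.0, sample_rate_hz=4000, n_rhonchi=1, seed=8)
        )
        assert np.array_equal(
            det.predict_raster(mini_model, rec).values, det.predict_raster(clone, rec).values
        )

    def test_resampling_policy(self, mini_model):
        # an 8 kHz recording is resampled to the model's 4 kHz before inference
        rec, _ = syn.simulate_recording(
            syn.SimulationConfig(duration_s=3.0, sample_rate_hz=8000, n_wheeze=1, seed=2)
        )
        raster = det.predict_raster(mini_model, rec)
        assert raster.n_frames == 30
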