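"""On-disk formats: WAV audio, CSV tables, raster archives, YAML configs.

All tabular artifacts are plain CSV with documented headers; rasters are
compressed numpy archives carrying their frame hop.  WAV files are PCM 16-bit
mono.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .types import (
    AudioRecording,
    DataError,
    FrameAnnotation,
    PredictionRaster,
    QualityVerdict,
    RecordingIntensity,
)


class FormatError(DataError):
    """A file exists but is not in the expected format."""


def read_wav(path) -> AudioRecording:
    """Read a PCM mono WAV file into a [-1, 1]-normalized recording."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise FormatError(f"{path.name}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise FormatError(f"{path.name}: unsupported sample format {data.dtype}")
    return AudioRecording(samples, int(rate), recording_id=path.stem)


def write_wav(path, recording: AudioRecording) -> None:
    """Write a recording as PCM 16-bit mono WAV."""
    clipped = np.clip(recording.samples, -1.0, 1.0)
    codes = np.clip(np.round(clipped * 32768.0), -32768, 32767)
    wavfile.write(path, recording.sample_rate_hz, codes.astype(np.int16))


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_annotations(path, annotations_by_recording: dict[str, list[FrameAnnotation]]) -> None:
    rows = [
        {"recording_id": rid, "onset_s": a.onset_s, "offset_s": a.offset_s, "label": a.label}
        for rid, anns in annotations_by_recording.items()
        for a in anns
    ]
    pd.DataFrame(rows, columns=["recording_id", "onset_s", "offset_s", "label"]).to_csv(
        path, index=False
    )


def read_annotations(path) -> dict[str, list[FrameAnnotation]]:
    df = pd.read_csv(path)
    out: dict[str, list[FrameAnnotation]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.recording_id), []).append(
            FrameAnnotation(float(row.onset_s), float(row.offset_s), str(row.label))
        )
    return out


def write_manifest(path, rows: list[dict]) -> None:
    """Examination manifest: exam_id, recording_id, asthma_flag, abnormal_flag."""
    pd.DataFrame(rows, columns=["exam_id", "recording_id", "asthma_flag", "abnormal_flag"]).to_csv(
        path, index=False
    )


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_verdicts(path, verdicts: list[QualityVerdict]) -> None:
    pd.DataFrame(
        [{"recording_id": v.recording_id, "verdict": v.verdict, "reason": v.reason} for v in verdicts]
    ).to_csv(path, index=False)


def write_intensities(path, intensities: list[RecordingIntensity]) -> None:
    pd.DataFrame(
        [
            {
                "recording_id": it.recording_id,
                "wheezes": it.wheezes,
                "rhonchi": it.rhonchi,
                "fine_crackles": it.fine_crackles,
                "coarse_crackles": it.coarse_crackles,
                "quality": it.quality,
            }
            for it in intensities
        ]
    ).to_csv(path, index=False)


def read_index_table(path) -> pd.DataFrame:
    """Per-examination index table (the supplementary-data schema)."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_raster(path, raster: PredictionRaster) -> None:
    np.savez_compressed(path, values=raster.values, frame_hop_s=raster.frame_hop_s)


def read_raster(path) -> PredictionRaster:
    with np.load(path) as data:
        return PredictionRaster(data["values"], float(data["frame_hop_s"]))


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end demo-pipeline parameters; round-trips losslessly via YAML."""

    n_exams_per_group: int = 10
    n_recordings_per_exam: int = 4
    duration_s: float = 4.0
    sample_rate_hz: int = 4000
    snr_db: float = 10.0
    n_train_recordings: int = 200
    detector_preset: str = "small"
    epochs: int = 25
    decay: float = 0.5
    min_breath_fraction: float = 0.1
    max_noise_fraction: float = 0.5
    min_good_recordings: int = 4
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig(**data)
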