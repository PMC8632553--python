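"""Core domain types shared across the auscultation-analysis pipeline.

The unit of analysis is an *examination*: a set of up to 12 chest-location
recordings taken during one auscultation session.  A frame-level detector maps
each recording to a *prediction raster* (time x class probability matrix over
the seven annotation classes), which is reduced to four per-recording phenomenon
intensities and finally aggregated into seven examination-level indexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Fixed class order used everywhere a 7-class axis appears.
CLASS_NAMES: tuple[str, ...] = (
    "wheeze",
    "rhonchi",
    "fine_crackle",
    "coarse_crackle",
    "inspiration",
    "expiration",
    "noise",
)

#: The four adventitious (abnormal) phenomena, in raster column order.
PHENOMENA: tuple[str, ...] = CLASS_NAMES[:4]

#: The seven examination-level indexes, in canonical report order.
INDEX_NAMES: tuple[str, ...] = (
    "wheezes_index",
    "rhonchi_index",
    "fine_crackles_index",
    "coarse_crackles_index",
    "continuous_phenomena_index",
    "transient_phenomena_index",
    "overall_index",
)

CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


class ParameterError(ValueError):
    """A caller-supplied parameter is outside its documented domain."""


class DataError(ValueError):
    """Input data violate a structural precondition (empty, malformed...)."""


@dataclass
class AudioRecording:
    """A mono auscultation recording with its examination metadata.

    ``samples`` is a float waveform normalized to [-1, 1]; ``chest_location``
    indexes the thorax position (1-12).
    """

    samples: np.ndarray
    sample_rate_hz: int
    recording_id: str = "rec"
    exam_id: str = "exam"
    chest_location: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise DataError(f"expected mono waveform, got shape {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("waveform contains non-finite samples")
        if not 1 <= int(self.chest_location) <= 12:
            raise ParameterError(f"chest_location must be in 1..12, got {self.chest_location}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass(frozen=True)
class FrameAnnotation:
    """A timestamped sound event; annotations of different classes may overlap."""

    onset_s: float
    offset_s: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_NAMES:
            raise ParameterError(f"unknown label {self.label!r}; expected one of {CLASS_NAMES}")
        if not self.onset_s < self.offset_s:
            raise ParameterError(f"onset {self.onset_s} must precede offset {self.offset_s}")


def n_frames_for(duration_s: float, frame_hop_s: float) -> int:
    """Frame-count contract shared by targets and predictions."""
    return int(math.ceil(duration_s / frame_hop_s - 1e-9))


@dataclass
class PredictionRaster:
    """Time x class probability matrix produced by the frame-level detector."""

    values: np.ndarray  # (n_frames, 7), entries in [0, 1]
    frame_hop_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(CLASS_NAMES):
            raise DataError(f"raster must be (n_frames, {len(CLASS_NAMES)}), got {self.values.shape}")
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise DataError("raster entries must lie in [0, 1]")
        if self.frame_hop_s <= 0:
            raise ParameterError("frame_hop_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, CLASS_INDEX[label]]


@dataclass
class RecordingIntensity:
    """Per-recording intensity of the four abnormal phenomena, each in [0, 1]."""

    recording_id: str
    wheezes: float
    rhonchi: float
    fine_crackles: float
    coarse_crackles: float
    quality: str = "good"  # good | bad

    def __post_init__(self) -> None:
        if self.quality not in ("good", "bad"):
            raise ParameterError(f"quality must be good|bad, got {self.quality!r}")
        for name in ("wheezes", "rhonchi", "fine_crackles", "coarse_crackles"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.wheezes, self.rhonchi, self.fine_crackles, self.coarse_crackles])


@dataclass
class ExaminationIndexes:
    """The seven examination-level intensity indexes, each in [0, 1]."""

    exam_id: str
    wheezes_index: float
    rhonchi_index: float
    fine_crackles_index: float
    coarse_crackles_index: float
    continuous_phenomena_index: float
    transient_phenomena_index: float
    overall_index: float

    def __post_init__(self) -> None:
        for name in INDEX_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


@dataclass(frozen=True)
class OrdinalLabel:
    """3-point severity label: 0 none/negligible, 1 moderate, 2 high intensity."""

    level: int
    scope: str = "recording"  # recording | examination

    def __post_init__(self) -> None:
        if self.level not in (0, 1, 2):
            raise ParameterError(f"ordinal level must be 0, 1 or 2, got {self.level}")
        if self.scope not in ("recording", "examination"):
            raise ParameterError(f"scope must be recording|examination, got {self.scope!r}")


@dataclass(frozen=True)
class QualityVerdict:
    """Good/bad verdict for one recording with the rejection reason."""

    recording_id: str
    verdict: str  # good | bad
    reason: str = "none"  # none | no_breath | too_noisy

    def __post_init__(self) -> None:
        if self.verdict not in ("good", "bad"):
            raise ParameterError(f"verdict must be good|bad, got {self.verdict!r}")
        if self.reason not in ("none", "no_breath", "too_noisy"):
            raise ParameterError(f"unknown reason {self.reason!r}")
        if self.verdict == "bad" and self.reason == "none":
            raise ParameterError("a bad verdict must carry a reason")
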