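"""From prediction rasters to the seven examination-level intensity indexes.

The chain is: raster -> per-recording raw phenomenon scores (noise-excluded
breath-phase coverage) -> monotone calibration against 3-point ordinal labels
-> ordered weighted averaging (OWA) across a examination's recordings ->
optional examination-level calibration.  All scores and indexes live in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .types import (
    CLASS_INDEX,
    DataError,
    ExaminationIndexes,
    OrdinalLabel,
    ParameterError,
    PredictionRaster,
    RecordingIntensity,
)

#: RecordingIntensity field per raster phenomenon column.
_PHENOMENON_FIELDS = {
    "wheeze": "wheezes",
    "rhonchi": "rhonchi",
    "fine_crackle": "fine_crackles",
    "coarse_crackle": "coarse_crackles",
}

#: Ordinal level -> calibration anchor on the [0, 1] intensity scale.
ORDINAL_ANCHORS = {0: 0.0, 1: 0.5, 2: 1.0}

DEFAULT_THRESHOLDS = {name: 0.5 for name in CLASS_INDEX}


class UncomputableExaminationError(DataError):
    """No good-quality recording is available to aggregate."""


@dataclass
class RawIntensity:
    """Noise-excluded breath-phase coverage per phenomenon, plus validity."""

    scores: dict[str, float]
    breath_detected: bool  # False => no usable breathing frames; quality bad


def raster_to_raw_intensity(
    raster: PredictionRaster,
    thresholds: dict[str, float] | None = None,
) -> RawIntensity:
    """Raw phenomenon scores from one prediction raster.

    A frame is *active* for a class when its probability reaches that class's
    threshold.  Noise-active frames are discarded; within the remaining frames
    each phenomenon's score is the fraction of breathing-cycle-active frames
    (inspiration or expiration) that the phenomenon covers.  With no usable
    breathing frames the scores are defined as 0 and ``breath_detected`` is
    False, signalling undefined quality.
    """
    if raster.n_frames == 0:
        raise DataError("raster has zero frames")
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    active = {name: raster.column(name) >= thr[name] for name in CLASS_INDEX}
    usable = ~active["noise"]
    breathing = (active["inspiration"] | active["expiration"]) & usable
    n_breath = int(breathing.sum())
    if n_breath == 0:
        return RawIntensity({f: 0.0 for f in _PHENOMENON_FIELDS.values()}, False)
    scores = {
        field: float((active[cls] & breathing).sum() / n_breath)
        for cls, field in _PHENOMENON_FIELDS.items()
    }
    return RawIntensity(scores, True)


def calibrate_intensity(
    raw_scores,
    labels: list[OrdinalLabel],
):
    """Monotone map [0,1] -> [0,1] fitted to ordinal ground-truth labels.

    Isotonic regression of the anchor values (0 -> 0.0, 1 -> 0.5, 2 -> 1.0)
    on the raw scores; applying the map preserves score ordering.  With fewer
    than two distinct label levels calibration degenerates to the identity
    (with a warning).
    """
    raw = np.asarray(raw_scores, dtype=float)
    levels = np.array([lab.level for lab in labels])
    if raw.shape != levels.shape:
        raise ParameterError("raw_scores and labels must align")
    if np.unique(levels).size < 2:
        warnings.warn("single ordinal level present; calibration is the identity", stacklevel=2)
        return lambda x: np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    anchors = np.vectorize(ORDINAL_ANCHORS.get)(levels).astype(float)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(raw, anchors)

    def apply(x):
        x = np.asarray(x, dtype=float)
        return iso.predict(np.atleast_1d(x)).reshape(x.shape) if x.ndim else float(iso.predict([x])[0])

    return apply


@dataclass(frozen=True)
class OWAWeights:
    """Rank-indexed aggregation weights (descending order), summing to 1."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size == 0 or np.any(w < 0):
            raise ParameterError("weights must be a non-empty non-negative vector")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError(f"weights must sum to 1, got {w.sum()!r}")

    def __len__(self) -> int:
        return len(self.weights)


def derive_owa_weights(n_recordings: int, decay: float = 0.5) -> OWAWeights:
    """Geometric rank weights: w_i proportional to decay**i over descending rank.

    ``decay=1`` recovers the arithmetic mean; small decay approaches the
    maximum operator (the loudest recording dominates the examination).
    """
    if n_recordings < 1:
        raise ParameterError("n_recordings must be >= 1")
    if not 0.0 < decay <= 1.0:
        raise ParameterError("decay must lie in (0, 1]")
    w = decay ** np.arange(n_recordings, dtype=float)
    w /= w.sum()
    return OWAWeights(tuple(w))


def owa_aggregate(values, weights: OWAWeights) -> float:
    """Ordered weighted average: weights applied to values sorted descending."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) != len(weights):
        raise ParameterError(f"got {len(v)} values for {len(weights)} weights")
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ParameterError("values must lie in [0, 1]")
    return float(np.sort(v)[::-1] @ np.asarray(weights.weights))


#: index name -> the RecordingIntensity fields combined (via max) per recording.
INDEX_CONSTITUENTS = {
    "wheezes_index": ("wheezes",),
    "rhonchi_index": ("rhonchi",),
    "fine_crackles_index": ("fine_crackles",),
    "coarse_crackles_index": ("coarse_crackles",),
    "continuous_phenomena_index": ("wheezes", "rhonchi"),
    "transient_phenomena_index": ("fine_crackles", "coarse_crackles"),
    "overall_index": ("wheezes", "rhonchi", "fine_crackles", "coarse_crackles"),
}


def compute_examination_indexes(
    intensities: list[RecordingIntensity],
    decay: float = 0.5,
    exam_calibration: dict[str, object] | None = None,
    exam_id: str = "exam",
) -> ExaminationIndexes:
    """Aggregate per-recording intensities into the seven examination indexes.

    Bad-quality recordings are excluded first.  Each index is the OWA (with
    geometric weights) of the per-recording constituent value — the phenomenon
    intensity for base indexes, the max over constituents for joint indexes —
    optionally passed through a per-index examination-level calibration map.
    """
    good = [it for it in intensities if it.quality == "good"]
    if not good:
        raise UncomputableExaminationError(
            f"examination {exam_id!r} has no good-quality recording"
        )
    weights = derive_owa_weights(len(good), decay)
    out: dict[str, float] = {}
    for name, fields in INDEX_CONSTITUENTS.items():
        per_rec = [max(getattr(it, f) for f in fields) for it in good]
        value = owa_aggregate(per_rec, weights)
        if exam_calibration and name in exam_calibration:
            value = float(np.clip(exam_calibration[name](value), 0.0, 1.0))
        out[name] = value
    return ExaminationIndexes(exam_id=exam_id, **out)
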