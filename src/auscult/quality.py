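"""Recording-quality assessment and examination validity filtering.

In the clinical workflow a trained acoustician rejects recordings in which no
breathing cycle is audible or background noise dominates, and an examination
is valid only with at least four good-quality recordings.  Here the human
judgment is proxied by the detector's own inspiration/expiration and noise
channels.
"""

from __future__ import annotations

from .types import DataError, PredictionRaster, QualityVerdict

DEFAULT_MIN_BREATH_FRACTION = 0.1
DEFAULT_MAX_NOISE_FRACTION = 0.5
DEFAULT_MIN_GOOD_RECORDINGS = 4


def assess_recording_quality(
    raster: PredictionRaster,
    recording_id: str = "rec",
    min_breath_fraction: float = DEFAULT_MIN_BREATH_FRACTION,
    max_noise_fraction: float = DEFAULT_MAX_NOISE_FRACTION,
    threshold: float = 0.5,
    thresholds: dict[str, float] | None = None,
) -> QualityVerdict:
    """Good/bad verdict from the breath- and noise-channel activity fractions.

    ``thresholds`` optionally overrides the scalar activity ``threshold`` per
    class (keys among inspiration/expiration/noise), e.g. with the detector's
    calibrated operating points.
    """
    if raster.n_frames == 0:
        raise DataError("raster has zero frames")
    thr = {name: threshold for name in ("inspiration", "expiration", "noise")}
    if thresholds:
        thr.update({k: v for k, v in thresholds.items() if k in thr})
    breath = (
        (raster.column("inspiration") >= thr["inspiration"])
        | (raster.column("expiration") >= thr["expiration"])
    ).mean()
    noise = (raster.column("noise") >= thr["noise"]).mean()
    if breath < min_breath_fraction:
        return QualityVerdict(recording_id, "bad", "no_breath")
    if noise > max_noise_fraction:
        return QualityVerdict(recording_id, "bad", "too_noisy")
    return QualityVerdict(recording_id, "good")


def filter_examinations(
    verdicts_by_exam: dict[str, list[QualityVerdict]],
    min_good_recordings: int = DEFAULT_MIN_GOOD_RECORDINGS,
) -> tuple[list[str], list[str]]:
    """Partition examinations into (kept, rejected) by good-recording count."""
    kept, rejected = [], []
    for exam_id, verdicts in verdicts_by_exam.items():
        n_good = sum(v.verdict == "good" for v in verdicts)
        (kept if n_good >= min_good_recordings else rejected).append(exam_id)
    return kept, rejected
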