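"""Synthetic auscultation data.

Two layers of simulation back the test surface of the whole pipeline:

* **Audio level** — annotated mono recordings containing a breath-cycle noise
  envelope plus inserted adventitious events.  Acoustic conventions follow the
  standard respiratory-acoustics nomenclature: a wheeze is a tonal, slowly
  frequency-modulated event >= 100 ms between 100 and 1000 Hz; rhonchi are
  low-pitched (<= 200 Hz) tonal events with a snoring-like harmonic stack; fine
  crackles are ~5 ms exponentially damped oscillations near 650 Hz and coarse
  crackles ~15 ms near 350 Hz.

* **Index level** — per-examination tables of the seven intensity indexes drawn
  per group (AA/AN/NA/NN: asthma crossed with physician-verified abnormal
  sounds) from [0, 1]-truncated normal distributions whose *truncated* mean and
  SD match the archetype targets.  The underlying (mu, sigma) are solved
  numerically: plugging the targets in directly would shift the realised mean
  upward once the distribution is clipped to the unit interval.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .types import (
    INDEX_NAMES,
    AudioRecording,
    DataError,
    FrameAnnotation,
    OrdinalLabel,
    ParameterError,
)


class PlacementError(DataError):
    """Requested events cannot be placed inside the recording."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.

    Defaults emulate a typical auscultation: 14.6 s (the mean clinical
    recording length), 8 kHz sampling, a 4 s resting breath cycle and events
    10 dB above the breath-noise floor.
    """

    duration_s: float = 14.6
    sample_rate_hz: int = 8000
    n_wheeze: int = 0
    n_rhonchi: int = 0
    n_fine: int = 0
    n_coarse: int = 0
    snr_db: float = 10.0
    breath_period_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.sample_rate_hz < 4000:
            raise ParameterError("sample_rate_hz must be >= 4000")
        if self.breath_period_s <= 0:
            raise ParameterError("breath_period_s must be positive")
        for name in ("n_wheeze", "n_rhonchi", "n_fine", "n_coarse"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# event synthesis
# ---------------------------------------------------------------------------

def _smooth_noise(n: int, sample_rate_hz: int, cutoff_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass-filtered unit-variance noise; the FM/AM wander source."""
    raw = rng.standard_normal(n)
    b, a = signal.butter(2, cutoff_hz / (sample_rate_hz / 2), btype="low")
    out = signal.filtfilt(b, a, raw)
    sd = out.std()
    return out / sd if sd > 0 else out


def _fade_envelope(n: int, fade_frac: float = 0.2) -> np.ndarray:
    """Raised-cosine attack/release envelope, flat in the middle."""
    env = np.ones(n)
    n_fade = max(1, int(n * fade_frac))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
    env[:n_fade] = ramp
    env[-n_fade:] = ramp[::-1]
    return env


def simulate_wheeze(
    duration_s: float,
    center_freq_hz: float,
    sample_rate_hz: int = 8000,
    seed: int = 0,
) -> np.ndarray:
    """A tonal, slowly frequency-modulated segment (continuous phenomenon).

    The instantaneous frequency wanders within ~4% of ``center_freq_hz`` so the
    dominant spectral peak stays within +-10% of the requested centre.
    """
    if duration_s < 0.1:
        raise ParameterError("continuous phenomena are >= 100 ms; duration_s too short")
    if not 100.0 <= center_freq_hz <= 1000.0:
        raise ParameterError("center_freq_hz must lie in [100, 1000] Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    wander = _smooth_noise(n, sample_rate_hz, cutoff_hz=3.0, rng=rng)
    inst_freq = center_freq_hz * (1.0 + 0.04 * wander)
    phase = 2 * np.pi * np.cumsum(inst_freq) / sample_rate_hz + rng.uniform(0, 2 * np.pi)
    seg = np.sin(phase) * _fade_envelope(n)
    return 0.9 * seg / np.max(np.abs(seg))


def simulate_rhonchi(
    duration_s: float,
    fundamental_hz: float = 120.0,
    sample_rate_hz: int = 8000,
    seed: int = 0,
) -> np.ndarray:
    """A low-pitched snoring-like tonal segment (fundamental <= 200 Hz)."""
    if duration_s < 0.1:
        raise ParameterError("continuous phenomena are >= 100 ms; duration_s too short")
    if not 60.0 <= fundamental_hz <= 200.0:
        raise ParameterError("rhonchi fundamental must lie in [60, 200] Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    wander = _smooth_noise(n, sample_rate_hz, cutoff_hz=3.0, rng=rng)
    inst_freq = fundamental_hz * (1.0 + 0.05 * wander)
    phase = 2 * np.pi * np.cumsum(inst_freq) / sample_rate_hz + rng.uniform(0, 2 * np.pi)
    # harmonic stack gives the buzzing quality; fundamental stays dominant
    seg = np.sin(phase) + 0.5 * np.sin(2 * phase) + 0.25 * np.sin(3 * phase)
    seg *= _fade_envelope(n)
    return 0.9 * seg / np.max(np.abs(seg))


#: (total duration s, oscillation frequency Hz) per crackle kind.
CRACKLE_PARAMS = {"fine": (0.005, 650.0), "coarse": (0.015, 350.0)}


def simulate_crackle(kind: str, sample_rate_hz: int = 8000, seed: int = 0) -> np.ndarray:
    """An exponentially damped oscillation (transient phenomenon)."""
    if kind not in CRACKLE_PARAMS:
        raise ParameterError(f"unknown crackle kind {kind!r}; expected fine|coarse")
    duration_s, freq_hz = CRACKLE_PARAMS[kind]
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    tau = duration_s / 4.0
    f = freq_hz * (1.0 + 0.05 * rng.uniform(-1, 1))
    seg = np.sin(2 * np.pi * f * t) * np.exp(-t / tau)
    return seg / np.max(np.abs(seg))


# ---------------------------------------------------------------------------
# whole-recording synthesis
# ---------------------------------------------------------------------------

def _breath_phases(duration_s: float, period_s: float) -> list[tuple[float, float, str]]:
    """Inspiration/expiration intervals tiling the breathing cycles."""
    phases = []
    t0 = 0.0
    while t0 < duration_s - 1e-9:
        insp = (t0, min(t0 + 0.40 * period_s, duration_s), "inspiration")
        exp_on = t0 + 0.45 * period_s
        exp_ = (exp_on, min(exp_on + 0.40 * period_s, duration_s), "expiration")
        for on, off, label in (insp, exp_):
            if off - on > 0.05:
                phases.append((on, off, label))
        t0 += period_s
    return phases


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if len(x) else 0.0


def _place_event(
    rng: np.random.Generator,
    ev_dur: float,
    duration_s: float,
    preferred: list[tuple[float, float]],
) -> float:
    """Onset for an event: inside a preferred phase if it fits, else uniform."""
    fitting = [(on, off) for on, off in preferred if off - on >= ev_dur]
    if fitting:
        on, off = fitting[rng.integers(len(fitting))]
        return float(rng.uniform(on, off - ev_dur))
    if duration_s < ev_dur:
        raise PlacementError(
            f"event of {ev_dur:.3f}s cannot fit in a {duration_s:.3f}s recording"
        )
    return float(rng.uniform(0, duration_s - ev_dur))


def simulate_recording(
    config: SimulationConfig,
    recording_id: str = "rec",
    exam_id: str = "exam",
    chest_location: int = 1,
) -> tuple[AudioRecording, list[FrameAnnotation]]:
    """Breath-cycle noise plus inserted events, with exact annotations.

    Continuous phenomena are placed preferentially in expiration (where
    obstructive sounds dominate), crackles in inspiration; every inserted event
    yields exactly one annotation, and inspiration/expiration annotations tile
    the breathing cycles.
    """
    rng = np.random.default_rng(config.seed)
    sr = config.sample_rate_hz
    n = int(round(config.duration_s * sr))
    t = np.arange(n) / sr

    phases = _breath_phases(config.duration_s, config.breath_period_s)
    envelope = np.zeros(n)
    for on, off, label in phases:
        i0, i1 = int(on * sr), int(off * sr)
        seg = np.hanning(max(i1 - i0, 2))
        envelope[i0:i1] += (1.0 if label == "inspiration" else 0.7) * seg[: i1 - i0]

    # breath sound: band-passed noise shaped by the phase envelope
    lo, hi = 80.0, min(900.0, 0.45 * sr)
    b, a = signal.butter(4, [lo / (sr / 2), hi / (sr / 2)], btype="band")
    breath = signal.lfilter(b, a, rng.standard_normal(n)) * envelope
    breath *= 0.1 / max(_rms(breath), 1e-12)
    waveform = breath + 0.01 * rng.standard_normal(n)

    annotations = [FrameAnnotation(on, off, label) for on, off, label in phases]
    insp = [(on, off) for on, off, lab in phases if lab == "inspiration"]
    exp_ = [(on, off) for on, off, lab in phases if lab == "expiration"]

    def insert(seg: np.ndarray, label: str, preferred: list[tuple[float, float]]) -> None:
        ev_dur = len(seg) / sr
        onset = _place_event(rng, ev_dur, config.duration_s, preferred)
        i0 = int(round(onset * sr))
        i1 = min(i0 + len(seg), n)
        span = breath[i0:i1]
        target_rms = max(_rms(span), 0.02) * 10 ** (config.snr_db / 20)
        seg_scaled = seg[: i1 - i0] * target_rms / max(_rms(seg), 1e-12)
        waveform[i0:i1] += seg_scaled
        annotations.append(FrameAnnotation(onset, onset + ev_dur, label))

    for _ in range(config.n_wheeze):
        dur = float(rng.uniform(0.4, 1.2))
        fc = float(rng.uniform(250, 800))
        insert(simulate_wheeze(dur, fc, sr, seed=int(rng.integers(2**31))), "wheeze", exp_)
    for _ in range(config.n_rhonchi):
        dur = float(rng.uniform(0.4, 1.2))
        f0 = float(rng.uniform(80, 180))
        insert(simulate_rhonchi(dur, f0, sr, seed=int(rng.integers(2**31))), "rhonchi", exp_)
    for _ in range(config.n_fine):
        insert(simulate_crackle("fine", sr, seed=int(rng.integers(2**31))), "fine_crackle", insp)
    for _ in range(config.n_coarse):
        insert(simulate_crackle("coarse", sr, seed=int(rng.integers(2**31))), "coarse_crackle", insp)

    peak = np.max(np.abs(waveform))
    if peak > 0.98:
        waveform *= 0.98 / peak
    rec = AudioRecording(waveform, sr, recording_id, exam_id, chest_location)
    annotations.sort(key=lambda ann: (ann.onset_s, ann.label))
    return rec, annotations


# ---------------------------------------------------------------------------
# examination-level datasets (audio)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticExamination:
    """One simulated examination: recordings, annotations and ground truth."""

    exam_id: str
    asthma: bool
    abnormal: bool
    recordings: list[AudioRecording]
    annotations: dict[str, list[FrameAnnotation]]
    recording_labels: dict[str, dict[str, OrdinalLabel]]  # rec_id -> phenomenon -> label
    exam_label: OrdinalLabel


def _ordinal_from_count(count: int) -> OrdinalLabel:
    return OrdinalLabel(0 if count == 0 else (1 if count <= 2 else 2))


def simulate_examination(
    exam_id: str,
    asthma: bool,
    abnormal: bool,
    n_recordings: int = 4,
    duration_s: float = 4.0,
    sample_rate_hz: int = 4000,
    snr_db: float = 10.0,
    seed: int = 0,
) -> SyntheticExamination:
    """Simulate the recordings of one examination in a given study group.

    Abnormal examinations carry wheeze/rhonchi-rich recordings (asthmatic) or a
    mix of continuous and transient phenomena (non-asthmatic); normal
    examinations contain breath sounds only.
    """
    rng = np.random.default_rng(seed)
    recordings, annotations, rec_labels = [], {}, {}
    max_count = 0
    for k in range(n_recordings):
        if not abnormal:
            counts = dict(n_wheeze=0, n_rhonchi=0, n_fine=0, n_coarse=0)
        elif asthma:
            counts = dict(
                n_wheeze=int(rng.integers(1, 4)),
                n_rhonchi=int(rng.integers(0, 3)),
                n_fine=int(rng.integers(0, 2)),
                n_coarse=0,
            )
        else:
            counts = dict(
                n_wheeze=int(rng.integers(0, 3)),
                n_rhonchi=int(rng.integers(0, 3)),
                n_fine=int(rng.integers(0, 3)),
                n_coarse=int(rng.integers(0, 2)),
            )
        cfg = SimulationConfig(
            duration_s=duration_s,
            sample_rate_hz=sample_rate_hz,
            snr_db=snr_db,
            seed=int(rng.integers(2**31)),
            **counts,
        )
        rec_id = f"{exam_id}_r{k}"
        rec, anns = simulate_recording(cfg, rec_id, exam_id, chest_location=k % 12 + 1)
        recordings.append(rec)
        annotations[rec_id] = anns
        rec_labels[rec_id] = {
            "wheezes": _ordinal_from_count(counts["n_wheeze"]),
            "rhonchi": _ordinal_from_count(counts["n_rhonchi"]),
            "fine_crackles": _ordinal_from_count(counts["n_fine"]),
            "coarse_crackles": _ordinal_from_count(counts["n_coarse"]),
        }
        max_count = max(max_count, sum(counts.values()))
    exam_label = OrdinalLabel(0 if max_count == 0 else (1 if max_count <= 3 else 2), "examination")
    return SyntheticExamination(
        exam_id, asthma, abnormal, recordings, annotations, rec_labels, exam_label
    )


def simulate_study(
    n_exams_per_group: int,
    n_recordings: int = 4,
    duration_s: float = 4.0,
    sample_rate_hz: int = 4000,
    snr_db: float = 10.0,
    seed: int = 0,
) -> list[SyntheticExamination]:
    """Simulate a four-group study (AA, AN, NA, NN) of examinations."""
    rng = np.random.default_rng(seed)
    exams = []
    for asthma, abnormal, tag in (
        (True, True, "AA"),
        (True, False, "AN"),
        (False, True, "NA"),
        (False, False, "NN"),
    ):
        for i in range(n_exams_per_group):
            exams.append(
                simulate_examination(
                    f"{tag}{i:03d}",
                    asthma,
                    abnormal,
                    n_recordings,
                    duration_s,
                    sample_rate_hz,
                    snr_db,
                    seed=int(rng.integers(2**31)),
                )
            )
    return exams


def make_detector_dataset(
    n_recordings: int,
    seed: int = 0,
    snr_db: float = 10.0,
    duration_s: float = 4.0,
    sample_rate_hz: int = 4000,
) -> list[tuple[AudioRecording, list[FrameAnnotation]]]:
    """Mixed-content recordings for detector training/evaluation.

    Roughly half the recordings contain wheezes; rhonchi and crackles appear
    independently so the detector must discriminate, not merely detect energy.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_recordings):
        cfg = SimulationConfig(
            duration_s=duration_s,
            sample_rate_hz=sample_rate_hz,
            n_wheeze=int(rng.integers(1, 4)) if rng.random() < 0.5 else 0,
            n_rhonchi=int(rng.integers(1, 3)) if rng.random() < 0.4 else 0,
            n_fine=int(rng.integers(1, 4)) if rng.random() < 0.4 else 0,
            n_coarse=int(rng.integers(1, 3)) if rng.random() < 0.3 else 0,
            snr_db=snr_db,
            seed=int(rng.integers(2**31)),
        )
        out.append(simulate_recording(cfg, recording_id=f"train{i:04d}"))
    return out


# ---------------------------------------------------------------------------
# index-level datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupArchetype:
    """Target moments of the seven indexes within one study group."""

    group: str  # AA | AN | NA | NN
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("AA", "AN", "NA", "NN"):
            raise ParameterError(f"group must be AA|AN|NA|NN, got {self.group!r}")
        for name in INDEX_NAMES:
            m = self.means.get(name)
            s = self.sds.get(name)
            if m is None or s is None:
                raise ParameterError(f"archetype {self.group} missing moments for {name}")
            if not 0.0 <= m <= 1.0:
                raise ParameterError(f"{self.group}.{name} mean {m} outside [0, 1]")
            if s < 0:
                raise ParameterError(f"{self.group}.{name} SD {s} must be >= 0")


def _arch(group: str, overall, cont, wh, rh, trans, fine, coarse) -> GroupArchetype:
    names = (
        "overall_index",
        "continuous_phenomena_index",
        "wheezes_index",
        "rhonchi_index",
        "transient_phenomena_index",
        "fine_crackles_index",
        "coarse_crackles_index",
    )
    vals = (overall, cont, wh, rh, trans, fine, coarse)
    return GroupArchetype(
        group,
        means={n: v[0] for n, v in zip(names, vals)},
        sds={n: v[1] for n, v in zip(names, vals)},
    )


#: Per-group index moments observed in a large asthma-monitoring validation
#: cohort (asthmatic/non-asthmatic x with/without physician-verified abnormal
#: sounds); the defaults the index-level simulator reproduces.
DEFAULT_ARCHETYPES: tuple[GroupArchetype, ...] = (
    _arch("AA", (0.37, 0.33), (0.30, 0.29), (0.14, 0.16), (0.17, 0.23), (0.08, 0.12), (0.06, 0.12), (0.02, 0.06)),
    _arch("AN", (0.02, 0.04), (0.01, 0.02), (0.01, 0.01), (0.01, 0.02), (0.01, 0.03), (0.01, 0.03), (0.00, 0.00)),
    _arch("NA", (0.39, 0.35), (0.26, 0.32), (0.11, 0.18), (0.17, 0.24), (0.16, 0.23), (0.13, 0.19), (0.03, 0.12)),
    _arch("NN", (0.02, 0.03), (0.01, 0.02), (0.00, 0.01), (0.01, 0.02), (0.01, 0.02), (0.01, 0.02), (0.00, 0.00)),
)


def _trunc_exp_moments(lam: float) -> tuple[float, float]:
    """Moments of an exponential(rate lam) truncated to [0, 1]; lam >> 0."""
    if lam > 50.0:
        return 1.0 / lam, 1.0 / lam
    em1 = np.expm1(lam)
    mean = 1.0 / lam - 1.0 / em1
    var = 1.0 / lam**2 - np.exp(lam) / em1**2
    return float(mean), float(np.sqrt(max(var, 0.0)))


def _trunc_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and SD of N(mu, sigma^2) truncated to [0, 1], tail-stable.

    The normalizing mass uses survival-function forms chosen by tail side, and
    deep one-sided truncation falls back to the exponential limit of the
    conditional law, so the result stays finite for any bracket the moment
    solver explores.
    """
    from scipy.special import ndtr

    alpha, beta = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    if alpha > 30.0:  # mass far below 0: conditional law ~ Exp(alpha/sigma)
        m, s = _trunc_exp_moments(alpha / sigma)
        return m, s
    if beta < -30.0:  # mass far above 1: mirrored exponential
        m, s = _trunc_exp_moments(-beta / sigma)
        return 1.0 - m, s
    if alpha > 0:
        z = ndtr(-alpha) - ndtr(-beta)
    else:
        z = ndtr(beta) - ndtr(alpha)
    phi_a = np.exp(-0.5 * alpha**2) / np.sqrt(2 * np.pi)
    phi_b = np.exp(-0.5 * beta**2) / np.sqrt(2 * np.pi)
    r1 = (phi_a - phi_b) / z
    r2 = (alpha * phi_a - beta * phi_b) / z
    mean = mu + sigma * r1
    var = sigma**2 * max(1.0 + r2 - r1**2, 0.0)
    return float(mean), float(np.sqrt(var))


@functools.lru_cache(maxsize=256)
def _solve_truncnorm(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) whose [0,1]-truncated moments best match targets.

    For a fixed sigma the truncated mean is strictly increasing in mu, so mu is
    root-solved to match the mean exactly; sigma is then chosen to bring the
    truncated SD as close as possible to the target.  Some target pairs are not
    exactly attainable inside the truncated-normal family (the SD is then
    matched in the least-squares sense while the mean stays exact; a zero
    printed mean with a positive SD is clamped just inside the unit interval).
    """
    mean = float(np.clip(mean, 1e-3, 1.0 - 1e-3))

    def mu_for_mean(sigma: float) -> float:
        # lower bracket reaches the exponential-limit regime where the
        # truncated mean ~ sigma^2/|mu| falls below any target in (0, 1)
        lo = min(mean - 9.0 * sigma, -2.0 * sigma**2 / mean)
        hi = mean + 9.0 * sigma
        return float(
            optimize.brentq(lambda mu: _trunc_moments(mu, sigma)[0] - mean, lo, hi, xtol=1e-13)
        )

    def sd_error(log_sigma: float) -> float:
        sigma = float(np.exp(log_sigma))
        return (_trunc_moments(mu_for_mean(sigma), sigma)[1] - sd) ** 2

    res = optimize.minimize_scalar(
        sd_error,
        bounds=(np.log(max(sd / 3, 1e-4)), np.log(3.0)),
        method="bounded",
        options={"xatol": 1e-7},
    )
    sigma = float(np.exp(res.x))
    return mu_for_mean(sigma), sigma


def effective_index_targets(
    archetypes: tuple[GroupArchetype, ...] = DEFAULT_ARCHETYPES,
    print_resolution: float = 0.01,
) -> dict[tuple[str, str], tuple[float, float]]:
    """(group, index) -> the moment targets actually fitted, after pooling.

    Reported group moments are rounded to ``print_resolution``, so two groups
    whose printed mean AND SD agree within one printing unit are statistically
    indistinguishable at the table's precision; their cells are pooled
    (single linkage) and share one fitted distribution.  Without pooling, a
    one-unit rounding difference between two near-zero cells would fabricate
    strong group separation that the underlying data do not support.
    """
    out: dict[tuple[str, str], tuple[float, float]] = {}
    groups = [a.group for a in archetypes]
    for name in INDEX_NAMES:
        moments = [(a.means[name], a.sds[name]) for a in archetypes]
        parent = list(range(len(archetypes)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        if print_resolution > 0:
            tol = print_resolution + 1e-12
            for i in range(len(moments)):
                for j in range(i + 1, len(moments)):
                    if (
                        abs(moments[i][0] - moments[j][0]) <= tol
                        and abs(moments[i][1] - moments[j][1]) <= tol
                    ):
                        parent[find(i)] = find(j)
        for i in range(len(moments)):
            members = [k for k in range(len(moments)) if find(k) == find(i)]
            mean = float(np.mean([moments[k][0] for k in members]))
            sd = float(np.mean([moments[k][1] for k in members]))
            out[(groups[i], name)] = (mean, sd)
    return out


def simulate_index_dataset(
    archetypes: tuple[GroupArchetype, ...] = DEFAULT_ARCHETYPES,
    n_per_group: int = 250,
    seed: int = 0,
    print_resolution: float = 0.01,
) -> pd.DataFrame:
    """Per-examination index table with group labels.

    Each index column is drawn independently from a [0,1]-truncated normal
    whose truncated moments match the archetype targets (SD in the
    least-squares sense where exact matching is infeasible).  Targets are
    first pooled across groups that agree to the reporting precision (see
    :func:`effective_index_targets`); pass ``print_resolution=0`` to disable.
    """
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    targets = effective_index_targets(archetypes, print_resolution)
    rng = np.random.default_rng(seed)
    frames = []
    for arch in archetypes:
        data: dict[str, object] = {
            "exam_id": [f"{arch.group}{i:05d}" for i in range(n_per_group)],
            "group": arch.group,
            "asthma": arch.group[0] == "A",
            "abnormal": arch.group[1] == "A",
        }
        for name in INDEX_NAMES:
            mean, sd = targets[(arch.group, name)]
            if sd == 0.0:
                data[name] = np.full(n_per_group, mean)
                continue
            mu, sigma = _solve_truncnorm(round(mean, 6), round(sd, 6))
            a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
            data[name] = stats.truncnorm.rvs(
                a, b, loc=mu, scale=sigma, size=n_per_group, random_state=rng
            )
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
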