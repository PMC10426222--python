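"""Synthetic multi-day, multi-subject PPG cohort generator.

Produces wrist-style photoplethysmography recordings with known ground-truth
emotion structure so that every downstream stage (denoising, windowing,
feature screening, classification) can be exercised and validated without any
real recordings.  Each participant contributes two day sessions; sessions walk
through a scripted elicitation protocol (resting baselines, picture blocks
seated and walking, self-statements, a video block, personal recall), and
anger-targeted sections perturb the cardiovascular ground truth in the
directions the psychophysiology literature reports for anger: heart rate up,
heart-rate variability down, pulse amplitude down.

The generator is a pure function of ``(GeneratorConfig, seed)``: identical
inputs reproduce identical cohorts bit for bit.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ScheduleConfig",
    "SectionSpec",
    "Section",
    "GeneratorConfig",
    "SessionRecording",
    "generate_beat_train",
    "inject_motion",
    "generate_labels",
    "generate_cohort",
    "QUADRANT_WORDS",
    "ANGER_WORDS",
]

# Circumplex quadrants: HV/LV = high/low valence, HA/LA = high/low arousal.
QUADRANTS = ("HVHA", "HVLA", "LVHA", "LVLA", "neutral")

# Retrospective vocabulary per quadrant (LVHA holds the anger set).
QUADRANT_WORDS = {
    "HVHA": ("happy", "excited"),
    "HVLA": ("calm", "content"),
    "LVHA": ("anger", "frustrated"),
    "LVLA": ("sad", "bored"),
    "neutral": ("neutral",),
}
ANGER_WORDS = frozenset(QUADRANT_WORDS["LVHA"])

#: signed valence attributed to each quadrant target
QUADRANT_VALENCE = {"HVHA": 0.6, "HVLA": 0.5, "LVHA": -0.6, "LVLA": -0.5, "neutral": 0.0}

_EMOTION_METHODS = frozenset(
    {"pictures", "pictures_walking", "self_statements", "video", "recall"}
)


@dataclass(frozen=True)
class SectionSpec:
    """One scheduled protocol section (before per-session realization)."""

    method: str  # baseline / neutral_pre / neutral_post / pictures / ...
    duration: float  # seconds
    quadrant: str = "neutral"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {self.quadrant!r}")

    @property
    def walking(self) -> bool:
        return self.method == "pictures_walking"

    @property
    def is_emotion(self) -> bool:
        return self.method in _EMOTION_METHODS


@dataclass(frozen=True)
class Section:
    """A realized section within a session timeline."""

    start: float
    end: float
    method: str
    quadrant: str
    word: str
    true_state: str  # "anger" | "non-anger" | "neutral"
    walking: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("time error: section end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def _wrap(spec: SectionSpec) -> list[SectionSpec]:
    """Surround an emotion section with the 30-s lead-in / 90-s tail neutrals."""
    return [
        SectionSpec("neutral_pre", 30.0),
        spec,
        SectionSpec("neutral_post", 90.0),
    ]


@dataclass(frozen=True)
class ScheduleConfig:
    """Ordered protocol for one day session.

    ``sections`` lists the protocol in order.  Emotion sections outside the
    video block must already include their neutral lead-in/tail clips; the
    factory constructors enforce that.  ``randomize_blocks`` shuffles the
    quadrant order within the picture blocks per session (the protocol
    randomizes the presentation order within each block).
    """

    sections: tuple[SectionSpec, ...]
    randomize_blocks: bool = True

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.sections))

    @staticmethod
    def default(video_block_s: float = 900.0) -> "ScheduleConfig":
        """Full-length protocol: ~2 h per session.

        Picture sections last 120 s (20 pictures x 6 s), recall sections
        120 s, resting baselines 300 s, self-statement sections run at ~7 s
        per phrase (50 anger statements, 53 elation statements).  The video
        block plays nine clips back to back inside one 30-s/90-s neutral
        envelope.
        """
        secs: list[SectionSpec] = [SectionSpec("baseline", 300.0)]
        for q in ("HVHA", "HVLA", "LVHA", "LVLA"):
            secs += _wrap(SectionSpec("pictures", 120.0, q))
        for q in ("HVHA", "HVLA", "LVHA", "LVLA"):
            secs += _wrap(SectionSpec("pictures_walking", 120.0, q))
        secs += _wrap(SectionSpec("self_statements", 350.0, "LVHA"))
        secs += _wrap(SectionSpec("self_statements", 371.0, "HVHA"))
        secs.append(SectionSpec("baseline", 300.0))
        # video block: 9 clips, back to back, block-level neutral envelope
        secs.append(SectionSpec("neutral_pre", 30.0))
        clip = video_block_s / 9.0
        for q in ("HVHA", "LVHA", "HVLA", "LVLA", "LVHA", "HVHA", "LVLA", "LVHA", "HVLA"):
            secs.append(SectionSpec("video", clip, q))
        secs.append(SectionSpec("neutral_post", 90.0))
        secs += _wrap(SectionSpec("recall", 120.0, "LVHA"))
        secs += _wrap(SectionSpec("recall", 120.0, "HVHA"))
        return ScheduleConfig(tuple(secs))

    @staticmethod
    def compact() -> "ScheduleConfig":
        """Shortened protocol (~40 min) with the same section grammar.

        Used for fast end-to-end runs; keeps every elicitation method, the
        neutral envelopes, and an anger minority class, at roughly half the
        windows per session of the full protocol.
        """
        secs: list[SectionSpec] = [SectionSpec("baseline", 120.0)]
        for q in ("LVHA", "HVLA"):
            secs += _wrap(SectionSpec("pictures", 120.0, q))
        for q in ("LVHA", "HVLA"):
            secs += _wrap(SectionSpec("pictures_walking", 120.0, q))
        secs += _wrap(SectionSpec("self_statements", 180.0, "LVHA"))
        secs += _wrap(SectionSpec("self_statements", 180.0, "HVHA"))
        secs.append(SectionSpec("neutral_pre", 30.0))
        for q in ("HVHA", "LVHA", "LVLA"):
            secs.append(SectionSpec("video", 100.0, q))
        secs.append(SectionSpec("neutral_post", 90.0))
        secs += _wrap(SectionSpec("recall", 120.0, "LVHA"))
        secs += _wrap(SectionSpec("recall", 120.0, "HVHA"))
        return ScheduleConfig(tuple(secs))


def _check_range(name: str, rng: tuple[float, float], positive: bool = True) -> None:
    lo, hi = rng
    if not (lo < hi):
        raise ValueError(f"{name} must be a non-degenerate (lo, hi) interval")
    if positive and lo <= 0:
        raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for cohort generation.

    Defaults emulate the study conditions: 32 participants of whom 10 carry a
    TBI flag, PPG at 64 Hz, tri-axis accelerometer at 32 Hz, two sessions per
    participant on different days, and ~8 % of emotion sections whose
    retrospective word fails to corroborate the real-time valence trace.
    Anger sections raise heart rate by ``anger_hr_delta`` bpm, scale the IBI
    variability by ``anger_hrv_scale`` and the pulse amplitude by
    ``anger_amp_scale``.
    """

    n_participants: int = 32
    tbi_fraction: float = 10 / 32
    fs_ppg: float = 64.0
    fs_acc: float = 32.0
    fs_valence: float = 4.0
    base_hr_range: tuple[float, float] = (62.0, 86.0)
    hrv_sd_range: tuple[float, float] = (0.03, 0.08)  # s, IBI standard deviation
    resp_rate_range: tuple[float, float] = (0.20, 0.33)  # Hz
    amp_range: tuple[float, float] = (0.8, 1.2)
    anger_hr_delta: float = 8.0  # bpm, > 0
    anger_hrv_scale: float = 0.6  # in (0, 1]
    anger_amp_scale: float = 0.75  # in (0, 1]
    day_drift_sd: float = 0.05  # log-normal sigma on HR / amplitude / noise
    noise_floor: float = 0.02  # sensor noise SD relative to unit pulse
    motion_gain: float = 1.0
    miscorroboration_rate: float = 0.08
    tbi_effect_scale: float = 1.0  # optional blunting multiplier on anger deltas
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig.default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for nm in ("tbi_fraction", "miscorroboration_rate"):
            v = getattr(self, nm)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{nm} must lie in [0, 1]")
        for nm in ("fs_ppg", "fs_acc", "fs_valence", "anger_hr_delta"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        for nm in ("anger_hrv_scale", "anger_amp_scale"):
            v = getattr(self, nm)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{nm} must lie in (0, 1]")
        if self.day_drift_sd < 0 or self.motion_gain < 0 or self.noise_floor < 0:
            raise ValueError("day_drift_sd, motion_gain, noise_floor must be >= 0")
        _check_range("base_hr_range", self.base_hr_range)
        _check_range("hrv_sd_range", self.hrv_sd_range)
        _check_range("resp_rate_range", self.resp_rate_range)
        _check_range("amp_range", self.amp_range)

    def config_hash(self) -> str:
        payload = repr(self).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class SessionRecording:
    """One participant-day of raw signals plus section annotations."""

    participant_id: str
    group: str  # "TBI" | "nonTBI"
    age: float
    gender: str
    day: str  # "A" | "B"
    fs_ppg: float
    fs_acc: float
    fs_valence: float
    ppg_raw: np.ndarray
    ppg_clean_truth: np.ndarray  # generator-only ground truth
    acc: np.ndarray  # (3, n_acc)
    valence: np.ndarray
    sections: list[Section]
    truth: dict = field(default_factory=dict)  # generator-only parameters

    @property
    def session_id(self) -> str:
        return f"{self.participant_id}-{self.day}"

    @property
    def duration(self) -> float:
        return len(self.ppg_raw) / self.fs_ppg


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

# Beat template: Gaussian systolic lobe plus a delayed, scaled Gaussian for
# the dicrotic wave on the falling (catacrotic) edge.
_SYS_DELAY, _SYS_WIDTH = 0.18, 0.065  # s
_DIC_DELAY, _DIC_WIDTH, _DIC_FRAC = 0.42, 0.09, 0.35


def _beat_times(
    duration: float,
    hr_fn,
    hrv_fn,
    resp_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequential interbeat-interval integration with band-limited HRV.

    IBI(t) = 60/HR(t) + sigma(t) * [LF sine at 0.1 Hz + HF sine at the
    respiratory rate + small white term], clipped to physiological bounds.
    """
    ph_lf, ph_hf = rng.uniform(0.0, 2 * math.pi, size=2)
    times: list[float] = []
    t = 0.0
    while t < duration:
        times.append(t)
        hr = hr_fn(t)
        sd = hrv_fn(t)
        pert = sd * (
            0.8 * math.sin(2 * math.pi * 0.1 * t + ph_lf)
            + 0.5 * math.sin(2 * math.pi * resp_rate * t + ph_hf)
            + 0.3 * rng.standard_normal()
        )
        ibi = min(max(60.0 / hr + pert, 0.33), 2.0)
        t += ibi
    return np.asarray(times)


def _render_pulses(
    beat_times: np.ndarray,
    amps: np.ndarray,
    duration: float,
    fs: float,
) -> np.ndarray:
    n = int(round(duration * fs))
    sig = np.zeros(n)
    support = 0.9  # s of template support per beat
    for tk, a in zip(beat_times, amps):
        i0 = max(0, int(math.floor(tk * fs)))
        i1 = min(n, int(math.ceil((tk + support) * fs)))
        if i1 <= i0:
            continue
        t = np.arange(i0, i1) / fs - tk
        sig[i0:i1] += a * (
            np.exp(-0.5 * ((t - _SYS_DELAY) / _SYS_WIDTH) ** 2)
            + _DIC_FRAC * np.exp(-0.5 * ((t - _DIC_DELAY) / _DIC_WIDTH) ** 2)
        )
    return sig


def generate_beat_train(
    base_hr: float,
    hrv_sd: float,
    resp_rate: float,
    amp: float,
    duration: float,
    fs: float,
    seed: int,
    resp_depth: float = 0.15,
    noise_floor: float = 0.0,
) -> np.ndarray:
    """Generate a quasi-periodic pulsatile PPG signal with constant parameters.

    ``resp_depth`` is the fractional amplitude modulation at the respiratory
    rate; with ``hrv_sd = 0`` and ``resp_depth = 0`` the output is a strictly
    periodic train of identical beats.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if not (30.0 <= base_hr <= 200.0):
        raise ValueError(f"base_hr must lie in [30, 200] bpm, got {base_hr}")
    if resp_rate <= 0:
        raise ValueError(f"resp_rate must be positive, got {resp_rate}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if hrv_sd < 0:
        raise ValueError(f"hrv_sd must be >= 0, got {hrv_sd}")
    rng = np.random.default_rng(seed)
    if hrv_sd == 0.0:
        # exact integer-step beat grid so every beat shape is identical
        beats = np.arange(0.0, duration, 60.0 / base_hr)
        rng.uniform(0.0, 2 * math.pi, size=2)  # keep stream alignment
    else:
        beats = _beat_times(duration, lambda t: base_hr, lambda t: hrv_sd, resp_rate, rng)
    ph = 0.0 if resp_depth == 0.0 else rng.uniform(0.0, 2 * math.pi)
    amps = amp * (1.0 + resp_depth * np.sin(2 * math.pi * resp_rate * beats + ph))
    sig = _render_pulses(beats, amps, duration, fs)
    if resp_depth > 0:
        t = np.arange(len(sig)) / fs
        sig += 0.25 * amp * resp_depth * np.sin(2 * math.pi * resp_rate * t + ph)
    if noise_floor > 0:
        sig += noise_floor * rng.standard_normal(len(sig))
    return sig


# ---------------------------------------------------------------------------
# motion artifacts
# ---------------------------------------------------------------------------

def _gait_component(
    n: int, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Periodic walking component for one accelerometer channel set."""
    f_gait = rng.uniform(1.5, 2.2)
    t = np.arange(n) / fs
    comp = np.empty((3, n))
    for ax in range(3):
        a1 = rng.uniform(0.6, 1.2)
        a2 = rng.uniform(0.1, 0.3)
        p1, p2 = rng.uniform(0.0, 2 * math.pi, size=2)
        comp[ax] = a1 * np.sin(2 * math.pi * f_gait * t + p1) + a2 * np.sin(
            2 * math.pi * 2 * f_gait * t + p2
        )
    return comp, f_gait


def _upsample2(x: np.ndarray, n_out: int) -> np.ndarray:
    """Linear interpolation from fs to 2*fs (helper mirroring the denoiser)."""
    n_in = len(x)
    t_in = np.arange(n_in)
    t_out = np.arange(n_out) / 2.0
    return np.interp(t_out, t_in, x)


def inject_motion(
    ppg_clean: np.ndarray,
    acc: np.ndarray,
    motion_gain: float,
    walking: bool,
    seed: int,
    fs_ppg: float = 64.0,
    fs_acc: float = 32.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Add accelerometer-coupled interference to a clean PPG signal.

    The artifact is a short causal FIR mixture of the (mean-removed)
    accelerometer channels, resampled to the PPG rate, normalized so that
    ``motion_gain`` equals the artifact-to-signal RMS ratio (``motion_gain=1``
    is 0 dB SNR).  With ``walking=True`` a 1.5-2.2 Hz periodic gait component
    is first added to the accelerometer channels.
    """
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    if acc.shape[0] != 3:
        raise ValueError(f"expected 3 accelerometer channels, got {acc.shape[0]}")
    ppg_clean = np.asarray(ppg_clean, dtype=float)
    rng = np.random.default_rng(seed)
    acc_out = acc.copy()
    if walking:
        comp, _ = _gait_component(acc.shape[1], fs_acc, rng)
        acc_out = acc_out + comp
    if motion_gain == 0.0:
        return ppg_clean.copy(), acc_out
    n = len(ppg_clean)
    taps = rng.standard_normal((3, 5))
    mix = np.zeros(n)
    for ax in range(3):
        up = _upsample2(acc_out[ax] - acc_out[ax].mean(), n)
        mix += np.convolve(up, taps[ax], mode="full")[:n]
    rms_mix = np.sqrt(np.mean(mix**2))
    rms_sig = np.sqrt(np.mean((ppg_clean - ppg_clean.mean()) ** 2))
    if rms_mix == 0.0 or rms_sig == 0.0:
        return ppg_clean.copy(), acc_out
    artifact = motion_gain * (rms_sig / rms_mix) * mix
    return ppg_clean + artifact, acc_out


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def generate_labels(
    sections: Sequence[tuple[float, float, str, str, str]],
    miscorroboration_rate: float,
    seed: int,
    fs_valence: float = 4.0,
    lag_tau: float = 3.0,
    noise_sd: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Produce the continuous valence trace and retrospective section words.

    ``sections`` rows are ``(start, end, method, quadrant, true_state)``.  The
    valence trace is a lagged, smoothed, noisy tracking of each section's
    target valence; with probability ``miscorroboration_rate`` an emotion
    section's word is drawn from a quadrant of the opposite valence sign, so
    the downstream corroboration screen rejects it.
    """
    if not (0.0 <= miscorroboration_rate <= 1.0):
        raise ValueError("miscorroboration_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    total = max(end for _, end, *_ in sections)
    n = int(round(total * fs_valence))
    target = np.zeros(n)
    words: list[str] = []
    for start, end, method, quadrant, true_state in sections:
        i0, i1 = int(round(start * fs_valence)), min(n, int(round(end * fs_valence)))
        target[i0:i1] = QUADRANT_VALENCE[quadrant]
        vocab = QUADRANT_WORDS[quadrant]
        word = vocab[rng.integers(len(vocab))]
        if (
            method in _EMOTION_METHODS
            and rng.random() < miscorroboration_rate
        ):
            # draw from a quadrant with mismatching valence sign
            sign = QUADRANT_VALENCE[quadrant]
            wrong = [
                q
                for q in QUADRANTS
                if q != "neutral" and QUADRANT_VALENCE[q] * sign <= 0
            ] or ["neutral"]
            q_wrong = wrong[rng.integers(len(wrong))]
            vocab = QUADRANT_WORDS[q_wrong]
            word = vocab[rng.integers(len(vocab))]
        words.append(word)
    # first-order lag (slider reaction time) + smoothed noise
    alpha = 1.0 - math.exp(-1.0 / (lag_tau * fs_valence))
    trace = np.empty(n)
    v = 0.0
    for i in range(n):
        v += alpha * (target[i] - v)
        trace[i] = v
    noise = rng.standard_normal(n)
    kernel = np.ones(int(fs_valence * 2)) / (fs_valence * 2)
    trace += noise_sd * np.convolve(noise, kernel, mode="same")
    return np.clip(trace, -1.0, 1.0), words


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _realize_sections(
    schedule: ScheduleConfig, rng: np.random.Generator
) -> list[tuple[float, float, SectionSpec]]:
    """Lay the schedule on the session timeline, shuffling picture blocks."""
    specs = list(schedule.sections)
    if schedule.randomize_blocks:
        # shuffle quadrants within each picture block (triples neutral_pre /
        # pictures / neutral_post stay glued together)
        for meth in ("pictures", "pictures_walking"):
            idx = [i for i, s in enumerate(specs) if s.method == meth]
            if len(idx) > 1:
                quads = [specs[i].quadrant for i in idx]
                perm = rng.permutation(len(idx))
                for j, i in enumerate(idx):
                    specs[i] = replace(specs[i], quadrant=quads[perm[j]])
    out = []
    t = 0.0
    for s in specs:
        out.append((t, t + s.duration, s))
        t += s.duration
    return out


def _generate_session(
    cfg: GeneratorConfig,
    participant: dict,
    day: str,
    rng: np.random.Generator,
) -> SessionRecording:
    drift = np.exp(cfg.day_drift_sd * rng.standard_normal(3))
    hr0 = participant["base_hr"] * drift[0]
    amp0 = participant["amp"] * drift[1]
    noise0 = cfg.noise_floor * drift[2]
    hrv0 = participant["hrv_sd"]
    resp = participant["resp_rate"]
    eff = cfg.tbi_effect_scale if participant["group"] == "TBI" else 1.0

    layout = _realize_sections(cfg.schedule, rng)
    duration = layout[-1][1]
    starts = np.array([s for s, _, _ in layout])

    def _sec_at(t: float) -> SectionSpec:
        i = int(np.searchsorted(starts, t, side="right") - 1)
        return layout[i][2]

    def _is_anger(spec: SectionSpec) -> bool:
        return spec.is_emotion and spec.quadrant == "LVHA"

    def hr_fn(t: float) -> float:
        return hr0 + (cfg.anger_hr_delta * eff if _is_anger(_sec_at(t)) else 0.0)

    def hrv_fn(t: float) -> float:
        if _is_anger(_sec_at(t)):
            return hrv0 * (1.0 - (1.0 - cfg.anger_hrv_scale) * eff)
        return hrv0

    def amp_fn(t: float) -> float:
        if _is_anger(_sec_at(t)):
            return amp0 * (1.0 - (1.0 - cfg.anger_amp_scale) * eff)
        return amp0

    beats = _beat_times(duration, hr_fn, hrv_fn, resp, rng)
    ph = rng.uniform(0.0, 2 * math.pi)
    resp_depth = 0.15
    amps = np.array([amp_fn(tk) for tk in beats]) * (
        1.0 + resp_depth * np.sin(2 * math.pi * resp * beats + ph)
    )
    clean = _render_pulses(beats, amps, duration, cfg.fs_ppg)
    t_grid = np.arange(len(clean)) / cfg.fs_ppg
    clean += 0.25 * amp0 * resp_depth * np.sin(2 * math.pi * resp * t_grid + ph)
    clean += noise0 * rng.standard_normal(len(clean))

    # accelerometer: resting tremor noise everywhere, gait during walking
    n_acc = int(round(duration * cfg.fs_acc))
    acc = 0.02 * rng.standard_normal((3, n_acc))
    gait_freq = None
    for start, end, spec in layout:
        if spec.walking:
            i0, i1 = int(round(start * cfg.fs_acc)), int(round(end * cfg.fs_acc))
            comp, gait_freq = _gait_component(i1 - i0, cfg.fs_acc, rng)
            acc[:, i0:i1] += comp

    ppg_raw, acc = inject_motion(
        clean,
        acc,
        cfg.motion_gain,
        walking=False,  # gait already embedded in acc
        seed=int(rng.integers(2**31)),
        fs_ppg=cfg.fs_ppg,
        fs_acc=cfg.fs_acc,
    )

    sec_rows = [
        (start, end, spec.method, spec.quadrant,
         "anger" if _is_anger(spec) else ("neutral" if not spec.is_emotion else "non-anger"))
        for start, end, spec in layout
    ]
    valence, words = generate_labels(
        sec_rows,
        cfg.miscorroboration_rate,
        seed=int(rng.integers(2**31)),
        fs_valence=cfg.fs_valence,
    )
    sections = [
        Section(start, end, method, quadrant, word, state, walking=(method == "pictures_walking"))
        for (start, end, method, quadrant, state), word in zip(sec_rows, words)
    ]
    truth = {
        "hr_base": hr0,
        "hr_anger": hr0 + cfg.anger_hr_delta * eff,
        "amp_base": amp0,
        "amp_anger": amp0 * (1.0 - (1.0 - cfg.anger_amp_scale) * eff),
        "hrv_base": hrv0,
        "hrv_anger": hrv0 * (1.0 - (1.0 - cfg.anger_hrv_scale) * eff),
        "resp_rate": resp,
        "noise_floor": noise0,
        "gait_freq": gait_freq,
    }
    return SessionRecording(
        participant_id=participant["id"],
        group=participant["group"],
        age=participant["age"],
        gender=participant["gender"],
        day=day,
        fs_ppg=cfg.fs_ppg,
        fs_acc=cfg.fs_acc,
        fs_valence=cfg.fs_valence,
        ppg_raw=ppg_raw,
        ppg_clean_truth=clean,
        acc=acc,
        valence=valence,
        sections=sections,
        truth=truth,
    )


def generate_cohort(config: GeneratorConfig) -> list[SessionRecording]:
    """Generate the full cohort: ``n_participants`` x 2 day sessions.

    Subject-level parameters are drawn once per participant and perturbed per
    day by the log-normal day drift; the TBI flag is assigned to the first
    ``round(n * tbi_fraction)`` participants.
    """
    master = np.random.default_rng(config.seed)
    n_tbi = int(round(config.n_participants * config.tbi_fraction))
    sessions: list[SessionRecording] = []
    for p in range(config.n_participants):
        is_tbi = p < n_tbi
        pid = f"PT{p + 1:02d}" if is_tbi else f"P{p + 1:02d}"
        participant = {
            "id": pid,
            "group": "TBI" if is_tbi else "nonTBI",
            "age": float(np.round(master.uniform(19, 65), 1)),
            "gender": "F" if master.random() < 0.5 else "M",
            "base_hr": master.uniform(*config.base_hr_range),
            "hrv_sd": master.uniform(*config.hrv_sd_range),
            "resp_rate": master.uniform(*config.resp_rate_range),
            "amp": master.uniform(*config.amp_range),
        }
        day_rngs = [
            np.random.default_rng(int(master.integers(2**31))) for _ in "AB"
        ]
        for day, rng in zip("AB", day_rngs):
            sessions.append(_generate_session(config, participant, day, rng))
    return sessions
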