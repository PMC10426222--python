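"""Emotion-label validation, fixed-length windowing, and binary anger labels.

Sections are screened for corroboration between their retrospective word and
the real-time valence trace (an anger word must coincide with predominantly
negative valence); non-corroborating sections are excluded.  Gated PPG within
each corroborated section is cut into 70-s windows with 30-s overlap (stride
40 s); each window carries exactly ``length_s * fs`` samples and a binary
anger/non-anger label, with all elicitation methods pooled identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import LabeledWindow
from .ppg_denoise import GateRecord
from .synthetic_cohort import ANGER_WORDS, QUADRANT_WORDS, Section, SessionRecording

__all__ = [
    "WindowingConfig",
    "validate_section",
    "segment",
    "label_window",
    "window_session",
    "exclusion_filter",
]

_WORD_VALENCE: dict[str, float] = {}
for _q, _ws in QUADRANT_WORDS.items():
    for _w in _ws:
        _WORD_VALENCE[_w] = {"HVHA": 1.0, "HVLA": 1.0, "LVHA": -1.0, "LVLA": -1.0, "neutral": 0.0}[_q]


@dataclass(frozen=True)
class WindowingConfig:
    length_s: float = 70.0
    overlap_s: float = 30.0
    fs: float = 64.0
    #: fraction of a window's 2-s gate hops that must pass for the window to count
    min_pass_fraction: float = 1.0
    #: fraction of section time whose valence sign must match the word
    majority_fraction: float = 0.5
    #: half-width of the neutral valence band, as a fraction of full scale
    neutral_band: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.overlap_s < self.length_s):
            raise ValueError("require 0 < overlap_s < length_s")
        if not (0 < self.min_pass_fraction <= 1.0):
            raise ValueError("min_pass_fraction must lie in (0, 1]")

    @property
    def stride_s(self) -> float:
        return self.length_s - self.overlap_s

    @property
    def n_samples(self) -> int:
        return int(round(self.length_s * self.fs))


def validate_section(
    section: Section,
    valence: np.ndarray,
    fs_valence: float = 4.0,
    config: WindowingConfig = WindowingConfig(),
) -> bool:
    """Corroboration screen between retrospective word and valence trace.

    Emotion words corroborate when the valence sign matches the word's sign
    for more than ``majority_fraction`` of the section; neutral words require
    the trace to stay inside the neutral band for the majority of it.
    """
    if section.word not in _WORD_VALENCE:
        raise ValueError(f"word {section.word!r} outside the rating vocabulary")
    i0 = int(round(section.start * fs_valence))
    i1 = int(round(section.end * fs_valence))
    seg = np.asarray(valence[i0:i1], dtype=float)
    if len(seg) == 0:
        raise ValueError("valence trace does not cover the section")
    sign = _WORD_VALENCE[section.word]
    if sign == 0.0:
        frac = np.mean(np.abs(seg) <= config.neutral_band)
    else:
        frac = np.mean(np.sign(seg) == sign)
    return bool(frac > config.majority_fraction)


def label_window(word: str) -> int:
    """Binary anger label: 1 iff the section's word is in the anger set."""
    return int(word in ANGER_WORDS)


def _hop_mask(gate: list[GateRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    starts = np.array([g.t_start for g in gate])
    ends = np.array([g.t_end for g in gate])
    passed = np.array([g.passed for g in gate], dtype=bool)
    return starts, ends, passed


def segment(
    session: SessionRecording,
    gate: list[GateRecord] | None,
    config: WindowingConfig = WindowingConfig(),
    corroborated: list[bool] | None = None,
    signal: np.ndarray | None = None,
) -> list[LabeledWindow]:
    """Cut corroborated sections into labelled fixed-length windows.

    Windows start at stride multiples from each section start, must be fully
    contained in one section (windows never cross section boundaries), and are
    emitted only if at least ``min_pass_fraction`` of the 2-s gate hops they
    cover passed the quality gate.  ``signal`` defaults to the raw PPG (the
    cleaned signal is a reference only).
    """
    sig = session.ppg_raw if signal is None else signal
    fs = config.fs
    n = len(sig)
    if gate:
        g_start, g_end, g_pass = _hop_mask(gate)
    out: list[LabeledWindow] = []
    idx = 0
    for s_i, sec in enumerate(session.sections):
        if corroborated is not None and not corroborated[s_i]:
            continue
        t = sec.start
        while t + config.length_s <= sec.end + 1e-9:
            i0 = int(round(t * fs))
            i1 = i0 + config.n_samples
            if i1 > n:
                break
            if gate:
                covered = (g_start < t + config.length_s) & (g_end > t)
                frac = g_pass[covered].mean() if covered.any() else 0.0
                ok = frac >= config.min_pass_fraction
            else:
                ok = True
            if ok:
                out.append(
                    LabeledWindow(
                        window_id=f"{session.session_id}-w{idx:03d}",
                        participant_id=session.participant_id,
                        day=session.day,
                        group=session.group,
                        samples=np.asarray(sig[i0:i1], dtype=float).copy(),
                        anger=label_window(sec.word),
                        section_method=sec.method,
                        t_start=t,
                    )
                )
                idx += 1
            t += config.stride_s
    return out


def window_session(
    session: SessionRecording,
    gate: list[GateRecord] | None = None,
    config: WindowingConfig = WindowingConfig(),
) -> list[LabeledWindow]:
    """Corroboration screen + segmentation for one session."""
    corroborated = [
        validate_section(sec, session.valence, session.fs_valence, config)
        for sec in session.sections
    ]
    return segment(session, gate, config, corroborated)


def exclusion_filter(
    windows_by_session: dict[str, list[LabeledWindow]],
    required_methods: frozenset[str] = frozenset(
        {"pictures", "pictures_walking", "self_statements", "video", "recall"}
    ),
) -> dict[str, list[LabeledWindow]]:
    """Drop participants whose validated data no longer span all elicitation
    methods, or who have a session with zero anger windows."""
    by_participant: dict[str, list[str]] = {}
    for sid in windows_by_session:
        by_participant.setdefault(sid.rsplit("-", 1)[0], []).append(sid)
    keep: set[str] = set()
    for pid, sids in by_participant.items():
        methods = {
            w.section_method for sid in sids for w in windows_by_session[sid]
        }
        ok = required_methods <= methods
        for sid in sids:
            if not any(w.anger for w in windows_by_session[sid]):
                ok = False
        if ok:
            keep.add(pid)
    return {
        sid: ws
        for sid, ws in windows_by_session.items()
        if sid.rsplit("-", 1)[0] in keep
    }
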