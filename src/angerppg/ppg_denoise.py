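"""Motion-artifact reduction for raw PPG with an accelerometer noise reference.

The cleaner runs a cascade of one LMS-Newton adaptive canceller per
accelerometer axis (regularized inverse-correlation update, initialized with
``delta``) followed by an adaptive notch stage centred on the dominant motion
frequency of the accelerometer frame.  Frames of ``window_s`` seconds advance
by ``window_s - overlap_s`` so each hop contributes the newest 2 s of cleaned
reference signal; filter state persists across frames within a session.

The cleaned signal is used only as a *reference*: raw PPG segments are passed
downstream when their Pearson correlation to the reference within the hop
exceeds ``r_min`` (strictly), otherwise they are discarded as motion-corrupt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .synthetic_cohort import SessionRecording

__all__ = [
    "FilterConfig",
    "GateRecord",
    "resample_acc",
    "anc_filter",
    "reconstruct",
    "quality_gate",
    "denoise_session",
]


@dataclass(frozen=True)
class FilterConfig:
    window_s: float = 10.0
    overlap_s: float = 8.0
    M: int = 17  # adaptive filter order (taps per axis)
    mu: float = 9e-5  # LMS-Newton step size
    alpha: float = 2e-4  # regularization of the inverse-correlation update
    delta: float = 400.0  # inverse-correlation matrix initialization
    r_min: float = 0.6  # Pearson gate threshold (strict)
    notch_q: float = 8.0  # quality factor of the adaptive notch
    notch_min_prominence: float = 4.0  # peak-to-median PSD ratio to engage notch

    def __post_init__(self) -> None:
        if not (0 < self.overlap_s < self.window_s):
            raise ValueError("require 0 < overlap_s < window_s")
        if self.M < 1:
            raise ValueError("filter order M must be >= 1")
        if min(self.mu, self.alpha, self.delta) <= 0:
            raise ValueError("mu, alpha, delta must be positive")
        if not (0.0 < self.r_min < 1.0):
            raise ValueError("r_min must lie in (0, 1)")

    @property
    def hop_s(self) -> float:
        return self.window_s - self.overlap_s


@dataclass
class GateRecord:
    hop_index: int
    t_start: float
    t_end: float
    passed: bool
    r: float
    reason: str = ""


def resample_acc(acc: np.ndarray, fs_in: float = 32.0, fs_out: float = 64.0) -> np.ndarray:
    """Linearly interpolate accelerometer channels from 32 Hz to 64 Hz.

    Original sample instants are preserved exactly; the output is twice the
    input length (the trailing half-step is extrapolated by edge-holding).
    """
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    if acc.shape[1] == 0:
        raise ValueError("empty accelerometer input")
    ratio = fs_out / fs_in
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("fs_out must be an integer multiple of fs_in")
    n_out = int(acc.shape[1] * ratio)
    t_in = np.arange(acc.shape[1])
    t_out = np.arange(n_out) / ratio
    out = np.vstack([np.interp(t_out, t_in, ch) for ch in acc])
    return out[0] if out.shape[0] == 1 and acc.ndim == 1 else out


class _LMSNewton:
    """Single-reference LMS-Newton canceller with persistent state."""

    def __init__(self, M: int, mu: float, alpha: float, delta: float) -> None:
        self.M = M
        self.mu = mu
        self.alpha = alpha
        self.w = np.zeros(M)
        self.P = delta * np.eye(M)  # running inverse-correlation estimate
        self.buf = np.zeros(M)

    def process(self, d: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Filter desired signal ``d`` against reference ``x``; returns error.

        P tracks the inverse of the exponentially-weighted reference
        correlation matrix R = (1-alpha) R + alpha x x' via the matrix
        inversion lemma, and the weights take curvature-corrected steps
        w += mu * e * P x (the Newton direction).
        """
        out = np.empty_like(d)
        w, P, buf = self.w, self.P, self.buf
        mu, alpha = self.mu, self.alpha
        beta = 1.0 - alpha
        ratio = beta / alpha
        for i in range(len(d)):
            buf[1:] = buf[:-1]
            buf[0] = x[i]
            y = w @ buf
            e = d[i] - y
            Px = P @ buf
            P -= np.outer(Px, Px) / (ratio + buf @ Px)
            P /= beta
            w += mu * e * (P @ buf)
            out[i] = e
        self.w, self.P, self.buf = w, P, buf
        return out


class _DenoiseState:
    def __init__(self, config: FilterConfig) -> None:
        self.anc = [
            _LMSNewton(config.M, config.mu, config.alpha, config.delta) for _ in range(3)
        ]
        self.notch_zi: np.ndarray | None = None
        self.notch_freq: float | None = None


def _dominant_motion_freq(acc_frame: np.ndarray, fs: float, cfg: FilterConfig) -> float | None:
    """Dominant accelerometer frequency in the motion band, if prominent."""
    pxx_sum = None
    for ch in acc_frame:
        f, pxx = sps.periodogram(ch - ch.mean(), fs=fs)
        pxx_sum = pxx if pxx_sum is None else pxx_sum + pxx
    band = (f >= 0.8) & (f <= 5.0)
    if not band.any() or pxx_sum is None:
        return None
    peak = pxx_sum[band].max()
    med = np.median(pxx_sum[band]) + 1e-30
    if peak / med < cfg.notch_min_prominence:
        return None
    return float(f[band][np.argmax(pxx_sum[band])])


def anc_filter(
    ppg_frame: np.ndarray,
    acc_frame: np.ndarray,
    config: FilterConfig = FilterConfig(),
    fs: float = 64.0,
    state: _DenoiseState | None = None,
) -> np.ndarray:
    """Clean one frame: per-axis LMS-Newton cancellers, then adaptive notch.

    ``acc_frame`` must already be resampled to the PPG rate (3 x frame
    length).  With all-zero accelerometer input the adaptive stage is an
    identity (there is no reference energy to subtract).
    """
    ppg_frame = np.asarray(ppg_frame, dtype=float)
    acc_frame = np.atleast_2d(np.asarray(acc_frame, dtype=float))
    if acc_frame.shape[0] != 3:
        raise ValueError(f"expected 3 accelerometer channels, got {acc_frame.shape[0]}")
    if acc_frame.shape[1] != len(ppg_frame):
        raise ValueError("PPG and accelerometer frame lengths differ")
    if not (np.isfinite(ppg_frame).all() and np.isfinite(acc_frame).all()):
        raise ValueError("non-finite samples in input frame")
    if state is None:
        state = _DenoiseState(config)
    out = ppg_frame
    for ax in range(3):
        out = state.anc[ax].process(out, acc_frame[ax])
    freq = _dominant_motion_freq(acc_frame, fs, config)
    if freq is not None and 0 < freq < fs / 2:
        b, a = sps.iirnotch(freq, config.notch_q, fs=fs)
        if state.notch_zi is None or state.notch_freq != freq:
            state.notch_zi = sps.lfilter_zi(b, a) * out[0]
            state.notch_freq = freq
        out, state.notch_zi = sps.lfilter(b, a, out, zi=state.notch_zi)
    return out


def reconstruct(
    ppg: np.ndarray,
    acc64: np.ndarray,
    config: FilterConfig = FilterConfig(),
    fs: float = 64.0,
) -> np.ndarray:
    """Run the sliding 10-s/8-s scheme over a session; return the reference.

    Frames advance by the 2-s hop; from each frame the newest hop of cleaned
    samples is kept (the first frame contributes in full).  Filter state
    carries across frames, so the cancellers converge over the session.
    """
    ppg = np.asarray(ppg, dtype=float)
    n = len(ppg)
    win = int(round(config.window_s * fs))
    hop = int(round(config.hop_s * fs))
    if n < win:
        raise ValueError(
            f"session of {n / fs:.1f} s shorter than one {config.window_s:.0f}-s window"
        )
    state = _DenoiseState(config)
    out = np.empty(n)
    # Frame starts at hop multiples; the adaptive stage is causal, so instead
    # of re-running the overlap we stream each new hop through the persistent
    # filters (equivalent to keeping only the newest samples of each frame).
    first = anc_filter(ppg[:win], acc64[:, :win], config, fs, state)
    out[:win] = first
    pos = win
    while pos < n:
        end = min(pos + hop, n)
        out[pos:end] = anc_filter(ppg[pos:end], acc64[:, pos:end], config, fs, state)
        pos = end
    return out


def quality_gate(
    raw_segment: np.ndarray,
    reference_segment: np.ndarray,
    r_min: float = 0.6,
) -> tuple[bool, float, str]:
    """Pass the raw segment iff Pearson r to the reference exceeds ``r_min``.

    The threshold is strict: r equal to ``r_min`` fails.  Constant segments
    fail with reason "zero variance".
    """
    raw_segment = np.asarray(raw_segment, dtype=float)
    reference_segment = np.asarray(reference_segment, dtype=float)
    if len(raw_segment) != len(reference_segment) or len(raw_segment) < 2:
        raise ValueError("segments must have equal length >= 2")
    if np.ptp(raw_segment) == 0.0 or np.ptp(reference_segment) == 0.0:
        return False, float("nan"), "zero variance"
    r = float(np.corrcoef(raw_segment, reference_segment)[0, 1])
    return (r > r_min), r, ""


def denoise_session(
    session: SessionRecording,
    config: FilterConfig = FilterConfig(),
) -> tuple[np.ndarray, list[GateRecord]]:
    """Full per-session pipeline: resample, reconstruct, gate every hop."""
    fs = session.fs_ppg
    acc64 = resample_acc(session.acc, session.fs_acc, fs)
    n = len(session.ppg_raw)
    if acc64.shape[1] < n:
        acc64 = np.pad(acc64, ((0, 0), (0, n - acc64.shape[1])), mode="edge")
    acc64 = acc64[:, :n]
    reference = reconstruct(session.ppg_raw, acc64, config, fs)
    hop = int(round(config.hop_s * fs))
    records: list[GateRecord] = []
    for k, start in enumerate(range(0, n, hop)):
        end = min(start + hop, n)
        if end - start < 2:
            break
        passed, r, reason = quality_gate(
            session.ppg_raw[start:end], reference[start:end], config.r_min
        )
        records.append(GateRecord(k, start / fs, end / fs, passed, r, reason))
    return reference, records
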