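"""On-disk formats and the shared in-memory data model.

A session directory holds four CSV files (``ppg.csv``, ``acc.csv``,
``valence.csv``, ``sections.csv``).  Signal files use a tiny wearable-export
dialect: row 1 is the start epoch in seconds, row 2 the sampling rate in Hz,
and every following row one sample (one column for PPG and valence, three for
the accelerometer).  Times are seconds from session start, intervals are
half-open ``[start, end)``, sample indexing is 0-based.  Readers reject
malformed input rather than silently coercing it.

The generator additionally writes a ground-truth sidecar (``truth.json`` and
``ppg_clean.csv``) consumed only by tests.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_cohort import Section, SessionRecording

__all__ = [
    "Cohort",
    "LabeledWindow",
    "read_session",
    "write_session",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_report",
    "read_report",
    "validate_session_dir",
]

SCHEMA_VERSION = "1"
_SIGNAL_FILES = ("ppg.csv", "acc.csv", "valence.csv", "sections.csv")


@dataclass
class LabeledWindow:
    """A fixed-length PPG vector with its binary anger label and metadata."""

    window_id: str
    participant_id: str
    day: str
    group: str
    samples: np.ndarray
    anger: int
    section_method: str
    t_start: float  # seconds within the session

    def __post_init__(self) -> None:
        if self.anger not in (0, 1):
            raise ValueError("anger label must be 0 or 1")


@dataclass
class Cohort:
    """Participant roster plus session references."""

    participants: list[dict]
    sessions: list[SessionRecording]
    provenance: str = "external"

    def __post_init__(self) -> None:
        ids = {p["id"] for p in self.participants}
        seen: set[tuple[str, str]] = set()
        for s in self.sessions:
            if s.participant_id not in ids:
                raise ValueError(
                    f"session references unknown participant {s.participant_id!r}"
                )
            key = (s.participant_id, s.day)
            if key in seen:
                raise ValueError(f"duplicate (participant, day) pair {key}")
            seen.add(key)

    @staticmethod
    def from_sessions(sessions: list[SessionRecording], provenance: str = "generator") -> "Cohort":
        roster: dict[str, dict] = {}
        for s in sessions:
            roster.setdefault(
                s.participant_id,
                {"id": s.participant_id, "group": s.group, "age": s.age, "gender": s.gender},
            )
        return Cohort(list(roster.values()), sessions, provenance)


# ---------------------------------------------------------------------------
# signal CSV dialect
# ---------------------------------------------------------------------------

def _write_signal(path: Path, data: np.ndarray, fs: float, t0: float = 0.0) -> None:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] > data.shape[1]:  # column-major input
        data = data.T
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([repr(t0)] * data.shape[0])
        w.writerow([repr(float(fs))] * data.shape[0])
        for row in data.T:
            w.writerow([repr(float(v)) for v in row])


def _read_signal(path: Path, expect_cols: int) -> tuple[np.ndarray, float, float]:
    if not path.exists():
        raise FileNotFoundError(f"missing channel: {path.name}")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2:
        raise ValueError(f"dialect error: {path.name} lacks header rows")
    try:
        t0 = float(rows[0][0])
        fs = float(rows[1][0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"dialect error: bad header in {path.name}") from exc
    if fs <= 0:
        raise ValueError(f"dialect error: non-positive sampling rate in {path.name}")
    out = np.empty((expect_cols, len(rows) - 2))
    for i, row in enumerate(rows[2:]):
        if len(row) != expect_cols:
            raise ValueError(
                f"dialect error: {path.name} row {i + 2} has {len(row)} columns, expected {expect_cols}"
            )
        for c in range(expect_cols):
            v = float(row[c])
            if not math.isfinite(v):
                raise ValueError(f"dialect error: non-finite sample in {path.name}")
            out[c, i] = v
    return (out[0] if expect_cols == 1 else out), fs, t0


def write_session(session: SessionRecording, out_dir: str | Path, truth: bool = True) -> Path:
    """Write one session to a directory in the package's CSV dialect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_signal(out / "ppg.csv", session.ppg_raw, session.fs_ppg)
    _write_signal(out / "acc.csv", session.acc, session.fs_acc)
    _write_signal(out / "valence.csv", session.valence, session.fs_valence)
    with open(out / "sections.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start", "end", "method", "quadrant", "word"])
        for s in session.sections:
            w.writerow([repr(s.start), repr(s.end), s.method, s.quadrant, s.word])
    meta = {
        "participant_id": session.participant_id,
        "group": session.group,
        "age": session.age,
        "gender": session.gender,
        "day": session.day,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    if truth:
        _write_signal(out / "ppg_clean.csv", session.ppg_clean_truth, session.fs_ppg)
        sidecar = {
            "clean_signal": "ppg_clean.csv",
            "true_states": [s.true_state for s in session.sections],
            "params": {k: v for k, v in session.truth.items() if v is not None},
        }
        (out / "truth.json").write_text(json.dumps(sidecar, indent=1))
    return out


def read_session(session_dir: str | Path) -> SessionRecording:
    """Load a session directory; rejects malformed dialects."""
    d = Path(session_dir)
    for name in _SIGNAL_FILES:
        if not (d / name).exists():
            raise FileNotFoundError(f"missing channel: {name}")
    ppg, fs_ppg, _ = _read_signal(d / "ppg.csv", 1)
    acc, fs_acc, _ = _read_signal(d / "acc.csv", 3)
    valence, fs_val, _ = _read_signal(d / "valence.csv", 1)

    sections: list[Section] = []
    with open(d / "sections.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"start", "end", "method", "quadrant", "word"} <= set(
            reader.fieldnames
        ):
            raise ValueError("dialect error: sections.csv header")
        prev_end = -math.inf
        for row in reader:
            start, end = float(row["start"]), float(row["end"])
            if end <= start:
                raise ValueError(f"time error: section end {end} <= start {start}")
            if start < prev_end:
                raise ValueError("time error: non-monotone section timestamps")
            prev_end = end
            true_state = row.get("true_state", "unknown")
            sections.append(
                Section(
                    start, end, row["method"], row["quadrant"], row["word"],
                    true_state, walking=(row["method"] == "pictures_walking"),
                )
            )

    meta_path = d / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    truth_path = d / "truth.json"
    clean = ppg
    truth: dict = {}
    if truth_path.exists():
        sidecar = json.loads(truth_path.read_text())
        truth = sidecar.get("params", {})
        states = sidecar.get("true_states")
        if states and len(states) == len(sections):
            sections = [
                Section(s.start, s.end, s.method, s.quadrant, s.word, st, s.walking)
                for s, st in zip(sections, states)
            ]
        clean_file = d / sidecar.get("clean_signal", "ppg_clean.csv")
        if clean_file.exists():
            clean, _, _ = _read_signal(clean_file, 1)
    return SessionRecording(
        participant_id=meta.get("participant_id", d.name),
        group=meta.get("group", "nonTBI"),
        age=float(meta.get("age", float("nan"))),
        gender=meta.get("gender", "unknown"),
        day=meta.get("day", "A"),
        fs_ppg=fs_ppg,
        fs_acc=fs_acc,
        fs_valence=fs_val,
        ppg_raw=ppg,
        ppg_clean_truth=clean,
        acc=acc,
        valence=valence,
        sections=sections,
        truth=truth,
    )


def validate_session_dir(session_dir: str | Path) -> list[str]:
    """Return a list of dialect problems (empty list = valid)."""
    try:
        read_session(session_dir)
    except (FileNotFoundError, ValueError) as exc:
        return [str(exc)]
    return []


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix, path: str | Path) -> Path:
    """Write a FeatureMatrix as TSV (first column window_id) + JSON sidecar."""
    path = Path(path)
    df = matrix.values.copy()
    df.insert(0, "window_id", df.index)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "normalization": matrix.normalization,
        "metadata": matrix.metadata.reset_index().to_dict(orient="list"),
    }
    path.with_suffix(".labels.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_feature_matrix(path: str | Path):
    from .tsfeatures import FeatureMatrix

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"window_id": str})
    if "window_id" not in df.columns:
        raise ValueError("dialect error: feature TSV lacks window_id column")
    df = df.set_index("window_id")
    df.index.name = "window_id"
    sidecar = json.loads(path.with_suffix(".labels.json").read_text())
    meta = pd.DataFrame(sidecar["metadata"])
    if len(meta):
        meta = meta.set_index("window_id")
    else:
        meta = pd.DataFrame(index=df.index)
    return FeatureMatrix(values=df, metadata=meta, normalization=sidecar["normalization"])


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return None
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_report(report, path: str | Path) -> Path:
    """Serialize a report object (or plain dict) to schema-versioned JSON."""
    path = Path(path)
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    doc = {"schema_version": SCHEMA_VERSION, **_round_floats(payload)}
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
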