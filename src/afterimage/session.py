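"""Trial-structured recording sessions and their on-disk dialect.

A :class:`RecordingSession` is the single entry point for every analysis in
this package: a list of units (projection neurons or glomerular ROIs), a list
of :class:`TrialRecord` objects carrying either per-unit spike times or
per-unit sampled fluorescence traces, and free-form metadata.  Sessions are
stored in a self-describing plain-text dialect -- one ``session.yaml`` with
the trial table plus one long-format ``activity.csv`` -- so that synthetic
and real data flow through one interface.  An HDF5 mirror of the same schema
is provided for large trace sessions.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "RecordingSession",
    "TrialRecord",
    "WindowSpec",
    "SessionValidationError",
    "SessionFormatError",
    "read_session",
    "write_session",
    "read_figshare_deposit",
]

#: spike times are stored with microsecond precision in the text dialect
_TIME_FMT = "%.6f"


class SessionValidationError(ValueError):
    """A session or trial violates a documented invariant."""


class SessionFormatError(ValueError):
    """An on-disk session file is malformed (missing column, bad row...)."""


@dataclass
class WindowSpec:
    """Half-open analysis window [start, end) relative to an odor event.

    ``reference`` selects the anchoring event, ``odor_index`` which odor of a
    sequential trial anchors it (0 = first, -1 = last).
    """

    name: str  # ON, OFF, ITI, BASELINE or custom
    start_s: float
    end_s: float
    reference: Literal["odor_onset", "odor_offset"] = "odor_onset"
    odor_index: int = 0

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise SessionValidationError(
                f"window {self.name!r}: start_s ({self.start_s}) must be < end_s ({self.end_s})"
            )

    def resolve(self, trial: "TrialRecord") -> tuple[float, float]:
        """Absolute (session-time) [start, end) of this window for one trial."""
        _, onset, offset = trial.odor_sequence[self.odor_index]
        anchor = onset if self.reference == "odor_onset" else offset
        return anchor + self.start_s, anchor + self.end_s


@dataclass
class TrialRecord:
    """One odor presentation (or odor sequence) and its recorded activity.

    ``activity`` maps unit id to a 1-D float array: spike times in seconds
    (session clock) for spike sessions, or the sampled trace segment for
    trace sessions (frame k at ``t_start_s + k / sample_rate_hz``).
    """

    trial_id: str
    odor: str
    t_start_s: float
    t_end_s: float
    odor_sequence: list[tuple[str, float, float]]  # (label, onset_s, offset_s)
    activity: dict[str, np.ndarray]
    block_id: int = 0
    trial_index_in_block: int = 0

    @property
    def onset_s(self) -> float:
        return self.odor_sequence[0][1]

    @property
    def offset_s(self) -> float:
        return self.odor_sequence[0][2]

    def validate(self, units: Sequence[str], modality: str) -> None:
        if not self.odor:
            raise SessionValidationError(f"trial {self.trial_id}: empty odor label")
        if not self.odor_sequence:
            raise SessionValidationError(f"trial {self.trial_id}: empty odor_sequence")
        if len(self.odor_sequence) == 1 and self.odor_sequence[0][0] != self.odor:
            raise SessionValidationError(
                f"trial {self.trial_id}: solitary odor_sequence label "
                f"{self.odor_sequence[0][0]!r} != odor {self.odor!r}"
            )
        for label, onset, offset in self.odor_sequence:
            if not (onset < offset <= self.t_end_s):
                raise SessionValidationError(
                    f"trial {self.trial_id}: odor {label!r} window "
                    f"[{onset}, {offset}) not within trial ending {self.t_end_s}"
                )
        unit_set = set(units)
        for uid, arr in self.activity.items():
            if uid not in unit_set:
                raise SessionValidationError(
                    f"trial {self.trial_id}: unknown unit {uid!r}"
                )
            if modality == "spikes" and arr.size:
                if arr.min() < self.t_start_s or arr.max() > self.t_end_s:
                    raise SessionValidationError(
                        f"trial {self.trial_id}, unit {uid}: spike outside "
                        f"[{self.t_start_s}, {self.t_end_s}]"
                    )


@dataclass
class RecordingSession:
    """A full trial-structured recording (spikes or calcium traces)."""

    modality: Literal["spikes", "traces"]
    units: list[str]
    trials: list[TrialRecord]
    sample_rate_hz: float | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.modality not in ("spikes", "traces"):
            raise SessionValidationError(f"unknown modality {self.modality!r}")
        if self.modality == "traces":
            if not (self.sample_rate_hz and self.sample_rate_hz > 0):
                raise SessionValidationError("trace sessions need sample_rate_hz > 0")
        if not self.trials:
            raise SessionValidationError("session has no trials")
        if len(set(self.units)) != len(self.units):
            raise SessionValidationError("duplicate unit ids")
        for trial in self.trials:
            trial.validate(self.units, self.modality)

    @property
    def odors(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.odor, None)
        return list(seen)

    def trials_for(self, odor: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.odor == odor]

    def n_units(self) -> int:
        return len(self.units)


# ---------------------------------------------------------------------------
# text dialect: session.yaml + activity.csv in a directory
# ---------------------------------------------------------------------------

def _trial_to_row(t: TrialRecord) -> dict:
    return {
        "trial_id": t.trial_id,
        "odor": t.odor,
        "t_start_s": float(t.t_start_s),
        "t_end_s": float(t.t_end_s),
        "block_id": int(t.block_id),
        "trial_index_in_block": int(t.trial_index_in_block),
        "odor_sequence": [
            {"odor": o, "onset_s": float(a), "offset_s": float(b)}
            for o, a, b in t.odor_sequence
        ],
    }


def _write_text(session: RecordingSession, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    trials = sorted(session.trials, key=lambda t: t.t_start_s)
    meta = {
        "modality": session.modality,
        "units": sorted(session.units),
        "sample_rate_hz": session.sample_rate_hz,
        "meta": dict(sorted(session.meta.items())),
        "trials": [_trial_to_row(t) for t in trials],
    }
    with open(path / "session.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["unit_id", "trial_id", "t_s", "value"])
    for trial in trials:
        for uid in sorted(trial.activity):
            arr = np.asarray(trial.activity[uid], dtype=float)
            if session.modality == "spikes":
                for t_s in np.sort(arr):
                    writer.writerow([uid, trial.trial_id, _TIME_FMT % t_s, ""])
            else:
                dt = 1.0 / session.sample_rate_hz
                for k, v in enumerate(arr):
                    writer.writerow(
                        [uid, trial.trial_id, _TIME_FMT % (trial.t_start_s + k * dt),
                         "%.9g" % v]
                    )
    (path / "activity.csv").write_text(buf.getvalue())


def _read_text(path: Path) -> RecordingSession:
    yml = path / "session.yaml"
    act = path / "activity.csv"
    if not yml.exists():
        raise SessionFormatError(f"missing {yml}")
    if not act.exists():
        raise SessionFormatError(f"missing {act}")
    meta = yaml.safe_load(yml.read_text())
    for key in ("modality", "units", "trials"):
        if key not in meta:
            raise SessionFormatError(f"session.yaml: missing required key {key!r}")

    trials: dict[str, TrialRecord] = {}
    for row in meta["trials"]:
        for col in ("trial_id", "odor", "t_start_s", "t_end_s"):
            if col not in row:
                raise SessionFormatError(
                    f"trial table: missing required column {col!r}"
                )
        seq = [
            (s["odor"], float(s["onset_s"]), float(s["offset_s"]))
            for s in row.get("odor_sequence", [])
        ]
        trials[str(row["trial_id"])] = TrialRecord(
            trial_id=str(row["trial_id"]),
            odor=row["odor"],
            t_start_s=float(row["t_start_s"]),
            t_end_s=float(row["t_end_s"]),
            odor_sequence=seq,
            activity={},
            block_id=int(row.get("block_id", 0)),
            trial_index_in_block=int(row.get("trial_index_in_block", 0)),
        )

    modality = meta["modality"]
    per_trial_unit: dict[tuple[str, str], list[float]] = {}
    with open(act, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[:3] != ["unit_id", "trial_id", "t_s"]:
            raise SessionFormatError(
                "activity.csv: expected header unit_id,trial_id,t_s,value"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(row):
                continue
            try:
                uid, tid, t_s = row[0], row[1], float(row[2])
                value = float(row[3]) if (modality == "traces") else None
            except (IndexError, ValueError) as exc:
                raise SessionFormatError(
                    f"activity.csv line {lineno}: unparseable row {row!r} ({exc})"
                ) from None
            if tid not in trials:
                raise SessionFormatError(
                    f"activity.csv line {lineno}: unknown trial_id {tid!r}"
                )
            per_trial_unit.setdefault((tid, uid), []).append(
                value if modality == "traces" else t_s
            )

    for (tid, uid), vals in per_trial_unit.items():
        trials[tid].activity[uid] = np.asarray(vals, dtype=float)
    # units with no events in a spike trial still participate (silent units)
    for trial in trials.values():
        for uid in meta["units"]:
            trial.activity.setdefault(uid, np.zeros(0))

    session = RecordingSession(
        modality=modality,
        units=[str(u) for u in meta["units"]],
        trials=sorted(trials.values(), key=lambda t: t.t_start_s),
        sample_rate_hz=meta.get("sample_rate_hz"),
        meta={str(k): str(v) for k, v in (meta.get("meta") or {}).items()},
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# HDF5 mirror of the same schema
# ---------------------------------------------------------------------------

def _write_hdf5(session: RecordingSession, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["modality"] = session.modality
        if session.sample_rate_hz is not None:
            f.attrs["sample_rate_hz"] = float(session.sample_rate_hz)
        f.create_dataset("units", data=[u.encode() for u in sorted(session.units)])
        mg = f.create_group("meta")
        for k, v in sorted(session.meta.items()):
            mg.attrs[k] = v
        tg = f.create_group("trials")
        for trial in sorted(session.trials, key=lambda t: t.t_start_s):
            g = tg.create_group(trial.trial_id)
            g.attrs["odor"] = trial.odor
            g.attrs["t_start_s"] = trial.t_start_s
            g.attrs["t_end_s"] = trial.t_end_s
            g.attrs["block_id"] = trial.block_id
            g.attrs["trial_index_in_block"] = trial.trial_index_in_block
            g.create_dataset(
                "odor_sequence_labels",
                data=[o.encode() for o, _, _ in trial.odor_sequence],
            )
            g.create_dataset(
                "odor_sequence_times",
                data=np.array([[a, b] for _, a, b in trial.odor_sequence]),
            )
            ag = g.create_group("activity")
            for uid in sorted(trial.activity):
                ag.create_dataset(uid, data=np.asarray(trial.activity[uid], float))


def _read_hdf5(path: Path) -> RecordingSession:
    import h5py

    with h5py.File(path, "r") as f:
        modality = f.attrs["modality"]
        rate = float(f.attrs["sample_rate_hz"]) if "sample_rate_hz" in f.attrs else None
        units = [u.decode() for u in f["units"][...]]
        meta = {k: str(v) for k, v in f["meta"].attrs.items()}
        trials = []
        for tid, g in f["trials"].items():
            labels = [o.decode() for o in g["odor_sequence_labels"][...]]
            times = g["odor_sequence_times"][...]
            seq = [(o, float(a), float(b)) for o, (a, b) in zip(labels, times)]
            trials.append(
                TrialRecord(
                    trial_id=tid,
                    odor=str(g.attrs["odor"]),
                    t_start_s=float(g.attrs["t_start_s"]),
                    t_end_s=float(g.attrs["t_end_s"]),
                    odor_sequence=seq,
                    activity={u: d[...] for u, d in g["activity"].items()},
                    block_id=int(g.attrs["block_id"]),
                    trial_index_in_block=int(g.attrs["trial_index_in_block"]),
                )
            )
    session = RecordingSession(
        modality=str(modality),
        units=units,
        trials=sorted(trials, key=lambda t: t.t_start_s),
        sample_rate_hz=rate,
        meta=meta,
    )
    session.validate()
    return session


def write_session(session: RecordingSession, path: str | Path,
                  format_spec: str = "text") -> None:
    """Write a validated session; byte-deterministic for fixed input."""
    session.validate()
    path = Path(path)
    if format_spec == "text":
        _write_text(session, path)
    elif format_spec == "hdf5":
        _write_hdf5(session, path)
    else:
        raise SessionFormatError(f"unknown format_spec {format_spec!r}")


def read_session(path: str | Path, format_spec: str = "text") -> RecordingSession:
    """Read and validate a session from the text or HDF5 dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_spec == "text":
        return _read_text(path)
    if format_spec == "hdf5":
        return _read_hdf5(path)
    raise SessionFormatError(f"unknown format_spec {format_spec!r}")


def read_figshare_deposit(path: str | Path) -> RecordingSession:
    """Adapter hook for the deposited locust/mouse datasets.

    The deposit's on-disk layout is not machine-documented; this hook exists
    so a concrete reader can be added without touching any analysis code.
    Until then it raises with guidance.
    """
    raise NotImplementedError(
        "The deposited-data layout has not been inspected; convert the "
        "deposit to the text dialect (session.yaml + activity.csv) and use "
        "read_session, or implement this adapter."
    )
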