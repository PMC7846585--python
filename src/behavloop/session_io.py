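"""Session-table serialization.

Sessions are exported as a comma-separated, frame-indexed table: one
row per frame with the estimated position and confidence of every
tracked body part, the experiment status (whether an output channel is
active), a free-text trial column, and a time column holding the
per-frame interval (the simulated inference time).  Floats are written
with six decimals, UTF-8, '\n' newlines; '#'-prefixed header lines
carry a compact metadata record (protocol, seed, config hash).  A
sidecar JSON document (``<path>.meta.json``) stores the full config,
event list, actions and counters, so a written session round-trips
field-by-field.

Reading recomputes the event list from status transitions and, when the
sidecar is present, validates it against the serialized events.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from .engine import Action, SessionLog, StimulationEvent
from .synthetic import GroundTruthTrack

__all__ = [
    "write_session_table",
    "read_session_table",
    "write_truth_table",
    "events_from_status",
    "config_hash",
    "SessionTableError",
]

MAGIC = "# behavloop-session-table v1"
FLOAT_FMT = "%.6f"


class SessionTableError(ValueError):
    """Malformed session table (header, ordering or column problems)."""


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config document."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _fmt(v: float) -> str:
    if isinstance(v, float) and np.isnan(v):
        return "nan"
    return FLOAT_FMT % v


def write_session_table(log: SessionLog, path, *, source: str = "session") -> None:
    """Write a session log as a frame-indexed comma-separated table."""
    meta = {
        "protocol": log.protocol,
        "seed": log.seed,
        "config_hash": config_hash(log.config),
        "fps": log.fps,
        "skeleton": list(log.skeleton),
        "end_reason": log.end_reason,
        "source": source,
        "n_frames": int(log.n_frames),
        "n_events": len(log.events),
    }
    lines = [MAGIC, "# meta " + json.dumps(meta, sort_keys=True)]
    cols = list(log.records.columns)
    lines.append(",".join(cols))
    for row in log.records.itertuples(index=False):
        vals = []
        for col, v in zip(cols, row):
            if col == "frame_id":
                vals.append(str(int(v)))
            elif col == "experiment_status":
                vals.append("true" if v else "false")
            elif col == "trial":
                vals.append("" if (v is None or (isinstance(v, float) and np.isnan(v))) else str(v))
            else:
                vals.append(_fmt(float(v)))
        lines.append(",".join(vals))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")

    sidecar = {
        "meta": meta,
        "config": log.config,
        "counters": log.counters,
        "events": [e.to_dict() for e in log.events],
        "actions": [
            {"name": a.name, "frame_id": a.frame_id, "t": a.t, "info": dict(a.info)}
            for a in log.actions
        ],
    }
    with open(str(path) + ".meta.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_session_table(path) -> SessionLog:
    """Read a session table back into a :class:`SessionLog`.

    Validates the dialect (magic line, monotonic unique frame ids,
    expected columns) and recomputes the event list from status
    transitions; a sidecar, when present, supplies the full config and
    event payloads and is cross-checked against the recomputed events.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if first != MAGIC:
            raise SessionTableError(f"not a session table (bad magic): {path}")
        meta = None
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("# meta "):
                meta = json.loads(line[len("# meta "):])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, dtype={"trial": str}, keep_default_na=False,
                         na_values=["nan"])
    if meta is None:
        raise SessionTableError("missing '# meta' header line")

    required = {"frame_id", "t", "experiment_status", "trial", "time"}
    if not required.issubset(df.columns):
        raise SessionTableError(
            f"missing columns: {sorted(required - set(df.columns))}"
        )
    fid = df["frame_id"].to_numpy()
    for i in range(1, len(fid)):
        if fid[i] <= fid[i - 1]:
            raise SessionTableError(
                f"frame_id not strictly increasing at row {i + 1} "
                f"(frame {fid[i]} after {fid[i - 1]})"
            )
    df["experiment_status"] = df["experiment_status"].map(
        {"true": True, "false": False, True: True, False: False}
    )
    if df["experiment_status"].isna().any():
        raise SessionTableError("experiment_status must be 'true' or 'false'")
    df["trial"] = df["trial"].fillna("")

    sidecar_path = str(path) + ".meta.json"
    config: dict = {}
    counters: dict = {}
    actions: list[Action] = []
    events: list[StimulationEvent]
    fps = float(meta.get("fps", 30.0))
    recomputed = events_from_status(df, fps=fps)
    if os.path.exists(sidecar_path):
        with open(sidecar_path, "r", encoding="utf-8") as fh:
            sidecar = json.load(fh)
        config = sidecar.get("config", {})
        counters = sidecar.get("counters", {})
        events = [StimulationEvent.from_dict(d) for d in sidecar.get("events", [])]
        actions = [
            Action(a["name"], int(a["frame_id"]), float(a["t"]), a.get("info", {}))
            for a in sidecar.get("actions", [])
        ]
        _check_events_match(events, recomputed)
    else:
        events = recomputed

    return SessionLog(
        protocol=meta.get("protocol", "unknown"),
        seed=int(meta.get("seed", 0)),
        config=config,
        fps=fps,
        skeleton=tuple(meta.get("skeleton", ())),
        records=df,
        events=events,
        actions=actions,
        counters=counters,
        end_reason=meta.get("end_reason", "unknown"),
    )


def events_from_status(records: pd.DataFrame, *, fps: float,
                       channel: str = "stim") -> list[StimulationEvent]:
    """Reconstruct channel events from runs of true experiment_status.

    A run of consecutive true rows [a..b] maps to an event with onset at
    frame a and offset at the frame following b (events are half-open).
    """
    status = records["experiment_status"].to_numpy(dtype=bool)
    fid = records["frame_id"].to_numpy(dtype=int)
    t = records["t"].to_numpy(dtype=float)
    events = []
    open_i = None
    for i in range(len(status)):
        if status[i] and open_i is None:
            open_i = i
        elif not status[i] and open_i is not None:
            events.append(_run_event(fid, t, open_i, i, fps, channel))
            open_i = None
    if open_i is not None:
        events.append(_run_event(fid, t, open_i, len(status), fps, channel))
    return events


def _run_event(fid, t, a, b, fps, channel):
    if b < len(fid):
        off_f, off_t = int(fid[b]), float(t[b])
    else:  # run reaches the end of the table: close one frame after
        off_f, off_t = int(fid[-1]) + 1, float(t[-1]) + 1.0 / fps
    return StimulationEvent(
        channel=channel,
        onset_frame=int(fid[a]),
        onset_t=float(t[a]),
        offset_frame=off_f,
        offset_t=off_t,
    )


def _check_events_match(events, recomputed):
    if len(events) != len(recomputed):
        raise SessionTableError(
            f"status columns imply {len(recomputed)} events but sidecar "
            f"lists {len(events)}"
        )
    for e, r in zip(events, recomputed):
        if e.onset_frame != r.onset_frame or e.offset_frame != r.offset_frame:
            raise SessionTableError(
                f"event frames disagree with status columns: "
                f"({e.onset_frame}, {e.offset_frame}) vs "
                f"({r.onset_frame}, {r.offset_frame})"
            )


def write_truth_table(track: GroundTruthTrack, path) -> None:
    """Export a ground-truth track in the session-table dialect.

    The header carries ``source=truth``; confidences are 1, status is
    false and the trial column empty (no experiment was run).
    """
    df = track.to_dataframe()
    meta = {
        "protocol": "none",
        "seed": None,
        "config_hash": config_hash(track.arena.to_dict()),
        "fps": track.fps,
        "skeleton": ["nose", "neck", "tail_root"],
        "end_reason": "truth_export",
        "source": "truth",
        "n_frames": int(track.n_frames),
        "n_events": 0,
    }
    lines = [MAGIC, "# meta " + json.dumps(meta, sort_keys=True)]
    cols = ["frame_id", "t"]
    for p in ("nose", "neck", "tail_root"):
        cols += [f"{p}_x", f"{p}_y", f"{p}_conf"]
    cols += ["experiment_status", "trial", "time"]
    lines.append(",".join(cols))
    dt = 1.0 / track.fps
    for i in range(track.n_frames):
        vals = [str(int(df["frame_id"][i])), _fmt(float(df["t"][i]))]
        for p in ("nose", "neck", "tail_root"):
            vals += [_fmt(float(df[f"{p}_x"][i])), _fmt(float(df[f"{p}_y"][i])),
                     _fmt(1.0)]
        vals += ["false", "", _fmt(dt)]
        lines.append(",".join(vals))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
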