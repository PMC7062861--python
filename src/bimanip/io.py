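"""Readers/writers for the marker-table and force-segment text formats.

Marker tables are delimited text with one header line and columns
``frame_index, marker_name, x, y, z`` (metres, world frame).  Force
segments are delimited text with columns ``t, fx, fy, fz`` (seconds,
newtons, task frame; optional torque columns are ignored) plus a JSON
sidecar carrying the segment metadata (success flag, subject, segment
id).  The synthetic generator writes the same formats the readers
consume, so synthetic and recorded inputs are interchangeable.
"""

from __future__ import annotations

import json
import pathlib
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .skeleton import MarkerFrame
from .task_demand import ForceSegment

MARKER_COLUMNS = ("frame_index", "marker_name", "x", "y", "z")


def write_marker_table(frames: Dict[int, MarkerFrame] | MarkerFrame,
                       path, sep: str = "\t") -> None:
    if isinstance(frames, MarkerFrame):
        frames = {0: frames}
    rows = []
    for idx, mf in sorted(frames.items()):
        for name, p in sorted(mf.positions.items()):
            rows.append((idx, name, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(path, sep=sep, index=False)


def read_marker_table(path, sep: str = "\t") -> Dict[int, MarkerFrame]:
    df = pd.read_csv(path, sep=sep)
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    out: Dict[int, MarkerFrame] = {}
    for idx, grp in df.groupby("frame_index"):
        pos = {str(r.marker_name): np.array([r.x, r.y, r.z])
               for r in grp.itertuples()}
        out[int(idx)] = MarkerFrame(pos, timestamp=float(idx))
    return out


def write_force_segment(segment: ForceSegment, path, sep: str = "\t") -> None:
    path = pathlib.Path(path)
    df = pd.DataFrame({"t": segment.timestamps,
                       "fx": segment.forces[:, 0],
                       "fy": segment.forces[:, 1],
                       "fz": segment.forces[:, 2]})
    df.to_csv(path, sep=sep, index=False)
    meta = {"success": segment.success, "subject": segment.subject,
            "segment_id": segment.segment_id}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2))


def read_force_segment(path, sep: str = "\t") -> ForceSegment:
    path = pathlib.Path(path)
    df = pd.read_csv(path, sep=sep)
    for col in ("t", "fx", "fy", "fz"):
        if col not in df.columns:
            raise ValueError(f"force segment missing column {col!r}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ForceSegment(
        timestamps=df["t"].to_numpy(),
        forces=df[["fx", "fy", "fz"]].to_numpy(),
        success=bool(meta.get("success", True)),
        subject=str(meta.get("subject", "")),
        segment_id=str(meta.get("segment_id", path.stem)))


def write_subject_files(subject, outdir) -> None:
    """Write one synthetic subject's markers and force segments to disk."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for side, mf in subject.markers.items():
        write_marker_table(mf, out / f"markers_{side}.tsv")
    for seg in subject.force_segments:
        write_force_segment(seg, out / f"{seg.segment_id}.tsv")


def read_force_segments(directory, pattern: str = "*seg*.tsv") -> List[ForceSegment]:
    directory = pathlib.Path(directory)
    return [read_force_segment(p)
            for p in sorted(directory.glob(pattern))
            if not p.name.endswith(".meta.json")]
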