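"""Reading and writing the pipeline's table formats.

All tables are UTF-8 comma-delimited text with a one-line header. A recording
is stored as three files under a common prefix:

* ``<prefix>_tracks.csv``   — frame, time_s, object, x_um, y_um (long format;
  one row per tracked structure per frame it exists in)
* ``<prefix>_contours.csv`` — frame, object, point_index, x_um, y_um
  (per-frame eggshell polygons; daughter/whole-cell polygons carry
  frame = -1 and their own object label)
* ``<prefix>_meta.json``    — event times, temperature, group, and the
  sampling time of the daughter-cell contours

Floats round-trip exactly (shortest-repr serialisation), so
read(write(x)) == x.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import TRACK_NAMES, EmbryoRecording

__all__ = ["write_recording", "read_recording", "write_table", "read_table",
           "read_feature_table"]


def write_recording(rec: EmbryoRecording, prefix: str | Path) -> dict[str, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    t = np.asarray(rec.timestamps, dtype=float)

    rows = []
    for name in TRACK_NAMES:
        xy = np.asarray(rec.tracks[name], dtype=float)
        present = np.isfinite(xy).all(axis=1)
        for i in np.nonzero(present)[0]:
            rows.append((int(i), t[i], name, xy[i, 0], xy[i, 1]))
    tracks = pd.DataFrame(rows, columns=["frame", "time_s", "object", "x_um", "y_um"])

    crows = []
    shell = np.asarray(rec.eggshell_contour, dtype=float)
    for i in range(shell.shape[0]):
        if not np.isfinite(shell[i]).all():
            continue
        for j, (x, y) in enumerate(shell[i]):
            crows.append((int(i), "eggshell", int(j), x, y))
    for name, poly in rec.cell_contours.items():
        for j, (x, y) in enumerate(np.asarray(poly, dtype=float)):
            crows.append((-1, name, int(j), x, y))
    contours = pd.DataFrame(crows, columns=["frame", "object", "point_index",
                                            "x_um", "y_um"])

    meta = {
        "timestamps": t.tolist(),
        "events": rec.events,
        "temperature": rec.temperature,
        "group": rec.group,
        "cell_contours_time": rec.cell_contours_time,
        "n_contour_vertices": int(shell.shape[1]),
    }
    paths = {
        "tracks": prefix.with_name(prefix.name + "_tracks.csv"),
        "contours": prefix.with_name(prefix.name + "_contours.csv"),
        "meta": prefix.with_name(prefix.name + "_meta.json"),
    }
    tracks.to_csv(paths["tracks"], index=False)
    contours.to_csv(paths["contours"], index=False)
    paths["meta"].write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return paths


def read_recording(prefix: str | Path) -> EmbryoRecording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_name(prefix.name + "_meta.json").read_text("utf-8"))
    t = np.asarray(meta["timestamps"], dtype=float)
    if not np.all(np.diff(t) > 0):
        bad = int(np.nonzero(np.diff(t) <= 0)[0][0]) + 1
        raise ValueError(f"non-monotone timestamp at index {bad} "
                         f"(meta line {bad + 2})")
    n = len(t)

    tracks_df = pd.read_csv(prefix.with_name(prefix.name + "_tracks.csv"),
                            float_precision="round_trip")
    tracks = {name: np.full((n, 2), np.nan) for name in TRACK_NAMES}
    for lineno, row in enumerate(tracks_df.itertuples(index=False), start=2):
        i = int(row.frame)
        if not 0 <= i < n or row.object not in tracks:
            raise ValueError(f"malformed track row at line {lineno}: {tuple(row)}")
        tracks[row.object][i] = (row.x_um, row.y_um)

    contours_df = pd.read_csv(prefix.with_name(prefix.name + "_contours.csv"),
                              float_precision="round_trip")
    v = int(meta["n_contour_vertices"])
    shell = np.full((n, v, 2), np.nan)
    cells: dict[str, list] = {}
    for lineno, row in enumerate(contours_df.itertuples(index=False), start=2):
        if row.object == "eggshell":
            i, j = int(row.frame), int(row.point_index)
            if not (0 <= i < n and 0 <= j < v):
                raise ValueError(f"malformed contour row at line {lineno}: {tuple(row)}")
            shell[i, j] = (row.x_um, row.y_um)
        else:
            cells.setdefault(row.object, []).append((row.x_um, row.y_um))

    rec = EmbryoRecording(
        timestamps=t,
        tracks=tracks,
        eggshell_contour=shell,
        events={k: float(val) for k, val in meta["events"].items()},
        temperature=float(meta["temperature"]),
        group=str(meta["group"]),
        cell_contours={k: np.asarray(val, dtype=float) for k, val in cells.items()},
        cell_contours_time=meta.get("cell_contours_time"),
    )
    rec.validate()
    return rec


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy feature table, checking the required columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"feature", "temperature", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} lacks columns: {sorted(missing)}")
    return df
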