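"""File contracts: TIFF stacks, spots/tracks CSV tables, JSON sidecars.

All CSVs may carry leading ``#`` comment lines (used for the run's config
hash); readers skip them.  Coordinates are 0-based pixel-center pixels,
times are seconds from acquisition (or treatment) start.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import Spot
from .tracking import Track

__all__ = ["write_stack", "read_stack", "spots_to_frame", "write_spots_csv",
           "read_spots_csv", "tracks_to_frame", "write_tracks_csv",
           "read_tracks_csv", "write_csv", "read_csv", "write_json"]


def write_stack(path, data: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def spots_to_frame(spots: list[Spot]) -> pd.DataFrame:
    rows = [{
        "frame": s.frame, "channel": s.channel, "x": s.x, "y": s.y,
        "z": np.nan if s.z is None else s.z, "amplitude": s.amplitude,
        "sigma_x": s.sigma_x, "sigma_y": s.sigma_y,
        "sigma_z": np.nan if s.sigma_z is None else s.sigma_z,
        "background": s.background,
        "integrated_intensity": s.integrated_intensity,
        "edge": s.edge,
    } for s in spots]
    return pd.DataFrame(rows)


def frame_to_spots(df: pd.DataFrame) -> list[Spot]:
    spots = []
    for row in df.itertuples(index=False):
        z = getattr(row, "z", np.nan)
        sz = getattr(row, "sigma_z", np.nan)
        spots.append(Spot(
            frame=int(row.frame), x=float(row.x), y=float(row.y),
            z=None if pd.isna(z) else float(z),
            amplitude=float(row.amplitude), sigma_x=float(row.sigma_x),
            sigma_y=float(row.sigma_y),
            sigma_z=None if pd.isna(sz) else float(sz),
            background=float(row.background),
            integrated_intensity=float(row.integrated_intensity),
            channel=str(row.channel), edge=bool(getattr(row, "edge", False))))
    return spots


def write_csv(path, df: pd.DataFrame, config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_spots_csv(path, spots: list[Spot],
                    config_hash: str | None = None) -> None:
    write_csv(path, spots_to_frame(spots), config_hash)


def read_spots_csv(path) -> list[Spot]:
    return frame_to_spots(read_csv(path))


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f, s in t.spots:
            rows.append({
                "track_id": t.id, "channel": t.channel, "frame": f,
                "x": s.x, "y": s.y,
                "intensity": s.integrated_intensity,
                "status": t.status, "reason": t.reason or "",
            })
    return pd.DataFrame(rows)


def write_tracks_csv(path, tracks: list[Track],
                     config_hash: str | None = None) -> None:
    write_csv(path, tracks_to_frame(tracks), config_hash)


def read_tracks_csv(path) -> list[Track]:
    df = read_csv(path)
    tracks: list[Track] = []
    for (tid, channel), g in df.groupby(["track_id", "channel"], sort=True):
        g = g.sort_values("frame")
        spots = [(int(r.frame), Spot(
            frame=int(r.frame), x=float(r.x), y=float(r.y), amplitude=1.0,
            sigma_x=1.3, sigma_y=1.3, background=0.0,
            integrated_intensity=float(r.intensity), channel=str(channel)))
            for r in g.itertuples(index=False)]
        t = Track(id=int(tid), channel=str(channel), spots=spots,
                  status=str(g.iloc[0]["status"]))
        reason = str(g.iloc[0]["reason"])
        t.reason = reason or None
        tracks.append(t)
    return tracks


def write_json(path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
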