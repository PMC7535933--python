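"""Core containers shared across the pipeline.

Physical conventions used throughout the package:

* coordinates are physical micrometres with the origin at the stack corner;
  ``z`` increases apically (toward the explant surface),
* voxel indices are 0-based and a voxel's physical position is
  ``index * calibration`` (voxel centres),
* frames are 0-based; all frame intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionGeometry",
    "CentrioleTrack",
    "TRACK_COLUMNS",
    "tracks_to_table",
    "tracks_from_table",
    "write_tracks_csv",
    "read_tracks_csv",
]

#: canonical column order of the track table / CSV schema
TRACK_COLUMNS = [
    "cell_id",
    "track_id",
    "role",
    "frame",
    "t_min",
    "x_um",
    "y_um",
    "z_um",
    "interpolated",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical calibration of a two-channel 3D time-lapse acquisition.

    Defaults correspond to a 63x confocal recording of utricular explants:
    0.216 um x-y pixels, 0.5 um z step and one z-stack every 10 minutes.
    """

    pixel_size_xy: float = 0.216  # um / pixel
    z_step: float = 0.5  # um / plane
    frame_interval: float = 10.0  # min / frame
    stack_shape: tuple[int, int, int] = (12, 128, 128)  # (planes, rows, cols)
    n_frames: int = 250

    def __post_init__(self) -> None:
        for name in ("pixel_size_xy", "z_step", "frame_interval"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if len(self.stack_shape) != 3 or any(int(s) <= 0 for s in self.stack_shape):
            raise ValueError("stack_shape must be three positive integers")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be strictly positive")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths (z, y, x) in micrometres."""
        return (self.z_step, self.pixel_size_xy, self.pixel_size_xy)

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) of the stack in micrometres."""
        nz, ny, nx = self.stack_shape
        return (nz * self.z_step, ny * self.pixel_size_xy, nx * self.pixel_size_xy)

    def frame_time_min(self, frame: int | np.ndarray) -> float | np.ndarray:
        return np.asarray(frame) * self.frame_interval

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stack_shape"] = list(self.stack_shape)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionGeometry":
        d = dict(d)
        d["stack_shape"] = tuple(int(s) for s in d["stack_shape"])
        return cls(**d)


@dataclass
class CentrioleTrack:
    """One centriole's time-indexed 3D positions in physical units.

    ``xyz`` is an ``(n, 3)`` array of ``(x, y, z)`` micrometre coordinates,
    one row per entry of ``frames``.  ``interpolated`` flags gap-filled
    frames (excluded from speed statistics downstream).
    """

    track_id: int
    cell_id: int
    role: str  # "MC", "DC" or "unknown"
    frames: np.ndarray
    xyz: np.ndarray
    interpolated: np.ndarray = None  # type: ignore[assignment]
    ambiguous: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if len(self.frames) != len(self.xyz):
            raise ValueError("frames and xyz length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")
        if self.role not in ("MC", "DC", "unknown"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.frames), dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def xy(self) -> np.ndarray:
        return self.xyz[:, :2]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def at_frames(self, frames: np.ndarray) -> np.ndarray:
        """Positions at the requested frames (must all be present)."""
        idx = np.searchsorted(self.frames, frames)
        if np.any(idx >= len(self.frames)) or np.any(self.frames[idx] != frames):
            raise KeyError("requested frames not all present in track")
        return self.xyz[idx]

    def common_frames(self, other: "CentrioleTrack") -> np.ndarray:
        return np.intersect1d(self.frames, other.frames)


def tracks_to_table(
    tracks: Sequence[CentrioleTrack], frame_interval: float = 10.0
) -> pd.DataFrame:
    """Flatten tracks into the canonical long-format table."""
    rows = []
    for tr in tracks:
        for i, f in enumerate(tr.frames):
            rows.append(
                (
                    tr.cell_id,
                    tr.track_id,
                    tr.role,
                    int(f),
                    float(f) * frame_interval,
                    tr.xyz[i, 0],
                    tr.xyz[i, 1],
                    tr.xyz[i, 2],
                    bool(tr.interpolated[i]),
                )
            )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


#: default mapping accepted by :func:`tracks_from_table`; keys are canonical
#: names, values are candidate source-column names (first match wins).  The
#: candidates cover TrackMate-style exports (``POSITION_X`` ...) and plain
#: coordinate tables.
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "cell_id": ("cell_id", "CELL_ID", "cell"),
    "track_id": ("track_id", "TRACK_ID", "track"),
    "role": ("role", "ROLE", "label", "name"),
    "frame": ("frame", "FRAME", "t", "POSITION_T", "Time"),
    "x_um": ("x_um", "x", "X", "POSITION_X", "Position X"),
    "y_um": ("y_um", "y", "Y", "POSITION_Y", "Position Y"),
    "z_um": ("z_um", "z", "Z", "POSITION_Z", "Position Z"),
    "interpolated": ("interpolated",),
}


def tracks_from_table(
    table: pd.DataFrame, column_map: Mapping[str, str] | None = None
) -> list[CentrioleTrack]:
    """Build tracks from a long-format table.

    ``column_map`` maps canonical column names to the table's column names
    for importing external (Imaris/TrackMate-like) spot tables; columns not
    found fall back to the candidates in :data:`DEFAULT_COLUMN_MAP`.
    Missing ``cell_id``/``role`` default to 0/"unknown".
    """
    resolved: dict[str, str | None] = {}
    for canon, candidates in DEFAULT_COLUMN_MAP.items():
        if column_map and canon in column_map:
            resolved[canon] = column_map[canon]
            continue
        resolved[canon] = next((c for c in candidates if c in table.columns), None)
    for required in ("track_id", "frame", "x_um", "y_um", "z_um"):
        if resolved[required] is None:
            raise KeyError(f"no column found for {required!r}")

    tracks = []
    for track_id, grp in table.groupby(resolved["track_id"], sort=True):
        grp = grp.sort_values(resolved["frame"])
        cell = int(grp[resolved["cell_id"]].iloc[0]) if resolved["cell_id"] else 0
        role = str(grp[resolved["role"]].iloc[0]) if resolved["role"] else "unknown"
        if role not in ("MC", "DC"):
            role = "unknown"
        interp = (
            grp[resolved["interpolated"]].to_numpy(dtype=bool)
            if resolved["interpolated"]
            else None
        )
        tracks.append(
            CentrioleTrack(
                track_id=int(track_id),
                cell_id=cell,
                role=role,
                frames=grp[resolved["frame"]].to_numpy(dtype=int),
                xyz=grp[[resolved["x_um"], resolved["y_um"], resolved["z_um"]]].to_numpy(
                    dtype=float
                ),
                interpolated=interp,
            )
        )
    return tracks


def write_tracks_csv(
    tracks: Sequence[CentrioleTrack], path: str | Path, frame_interval: float = 10.0
) -> Path:
    path = Path(path)
    tracks_to_table(tracks, frame_interval).to_csv(path, index=False)
    return path


def read_tracks_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[CentrioleTrack]:
    return tracks_from_table(pd.read_csv(path), column_map=column_map)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
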