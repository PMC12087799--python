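"""File formats: multi-page TIFF videos, CSV trajectories, field archives, masks.

All round-trips are lossless at the stored bit depth.  Binary array
archives (displacement fields) are NumPy ``.npz`` files accompanied by a
JSON sidecar describing the grid geometry and the PIV configuration, so
the archive is self-documenting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = [
    "VideoStack",
    "Trajectory",
    "RoiStack",
    "write_video",
    "read_video",
    "write_trajectory",
    "read_trajectory",
    "write_fields",
    "read_fields",
    "write_mask_png",
    "read_mask_png",
]


@dataclass
class VideoStack:
    """An ordered grayscale frame stack with acquisition metadata.

    ``frame_khz`` optionally maps each frame to the stimulation frequency
    active while it was recorded (clip bookkeeping).
    """

    frames: np.ndarray  # (T, H, W), uint8 or uint16
    frame_rate: float = 20.0
    pixel_size_um: float = 0.45
    frame_khz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) stack with T >= 1")
        if self.frame_khz is not None:
            self.frame_khz = np.asarray(self.frame_khz, dtype=float)
            if self.frame_khz.size != self.frames.shape[0]:
                raise ValueError("frame_khz length must equal frame count")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class Trajectory:
    """Per-frame centroid track of one cell.

    ``flagged`` marks frames where the tracker carried the previous
    position forward (no component found).
    """

    cell_id: str
    frames: np.ndarray  # strictly increasing frame indices
    xy: np.ndarray  # (T, 2) centroid (x, y), px
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.shape != (self.frames.size, 2):
            raise ValueError("xy must be (T, 2) matching frames")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")
        if self.flagged is None:
            self.flagged = np.zeros(self.frames.size, dtype=bool)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool)

    def __len__(self) -> int:
        return int(self.frames.size)


@dataclass
class RoiStack:
    """Square centroid-centered regions of one cell, one per retained frame."""

    frames: np.ndarray  # (T, side, side)
    side: int
    centroids: np.ndarray  # (T, 2) rounded centers (x, y) in source coords
    padded: np.ndarray  # per-frame flag: ROI needed edge replication
    frame_khz: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.frames.shape[1:] != (self.side, self.side):
            raise ValueError("all ROIs must be side x side")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


# ---------------------------------------------------------------------------


def write_video(path: str | Path, video: VideoStack) -> None:
    """Write a stack as multi-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, video.frames, photometric="minisblack")
    meta = {
        "frame_rate": video.frame_rate,
        "pixel_size_um": video.pixel_size_um,
        "frame_khz": None
        if video.frame_khz is None
        else [float(v) for v in video.frame_khz],
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_video(path: str | Path) -> VideoStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    khz = meta.get("frame_khz")
    return VideoStack(
        frames=frames,
        frame_rate=meta.get("frame_rate", 20.0),
        pixel_size_um=meta.get("pixel_size_um", 0.45),
        frame_khz=None if khz is None else np.asarray(khz),
    )


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    df = pd.DataFrame(
        {
            "cell_id": traj.cell_id,
            "frame": traj.frames,
            "x": traj.xy[:, 0],
            "y": traj.xy[:, 1],
            "flagged": traj.flagged.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        cell_id=str(df["cell_id"].iloc[0]),
        frames=df["frame"].to_numpy(),
        xy=df[["x", "y"]].to_numpy(),
        flagged=df["flagged"].to_numpy().astype(bool),
    )


def write_fields(path: str | Path, fields, meta: dict | None = None) -> None:
    """Store a displacement-field sequence as .npz plus a JSON sidecar.

    ``fields`` is a list of :class:`~odepkit.piv.DisplacementField` sharing
    one grid.
    """
    path = Path(path)
    u = np.stack([f.u for f in fields])
    v = np.stack([f.v for f in fields])
    valid = np.stack([f.valid for f in fields])
    np.savez_compressed(
        path,
        u=u,
        v=v,
        valid=valid,
        grid_rows=fields[0].grid_rows,
        grid_cols=fields[0].grid_cols,
    )
    sidecar = {
        "window": int(fields[0].window),
        "overlap": 0.5,
        "passes": 2,
        "n_fields": len(fields),
        "grid_shape": list(u.shape[1:]),
    }
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_fields(path: str | Path):
    from .piv import DisplacementField

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz") if path.suffix else path.with_suffix(".npz")
    data = np.load(path)
    meta = json.loads(Path(str(path)[: -len(".npz")] + ".json").read_text())
    return [
        DisplacementField(
            u=data["u"][t],
            v=data["v"][t],
            valid=data["valid"][t],
            grid_rows=data["grid_rows"],
            grid_cols=data["grid_cols"],
            window=meta["window"],
        )
        for t in range(data["u"].shape[0])
    ], meta


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 1-bit PNG."""
    Image.fromarray(np.asarray(mask, dtype=bool)).convert("1").save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.array(Image.open(path).convert("1"), dtype=bool)
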