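"""Clip concatenation, centroid tracking and ROI extraction.

The tracker is a deliberately simple substitute for a full tracking suite:
per frame, the image is binarized at Otsu's threshold, connected components
are labeled, and the component centroid nearest the previous estimate is
linked.  It is validated against synthetic ground truth only; it does not
resolve crossing cells.

Coordinates are 0-based with x = column and y = row.  Centroid rounding is
half-away-from-zero.  ROI borders are filled by edge replication (not
zeros) to avoid spurious intensity gradients in downstream PIV, and padded
frames are flagged so users may exclude them.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import RoiStack, Trajectory, VideoStack

__all__ = [
    "round_half_away",
    "concatenate_clips",
    "trim_to_window",
    "track_centroid",
    "extract_roi_stack",
]


def round_half_away(x) -> np.ndarray:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def concatenate_clips(clips: list[VideoStack]) -> VideoStack:
    """Concatenate per-frequency clips into one video, preserving order.

    All clips must share frame dimensions and frame rate; frequency
    bookkeeping is concatenated when every clip carries it.
    """
    if not clips:
        raise ValueError("empty clip list")
    shape = clips[0].shape
    rate = clips[0].frame_rate
    for c in clips[1:]:
        if c.shape != shape:
            raise ValueError(f"frame dimension mismatch: {c.shape} vs {shape}")
        if c.frame_rate != rate:
            raise ValueError("frame rate mismatch")
    khz = None
    if all(c.frame_khz is not None for c in clips):
        khz = np.concatenate([c.frame_khz for c in clips])
    return VideoStack(
        frames=np.concatenate([c.frames for c in clips]),
        frame_rate=rate,
        pixel_size_um=clips[0].pixel_size_um,
        frame_khz=khz,
    )


def trim_to_window(
    video: VideoStack, trajectory: Trajectory, n_frames: int = 1000
) -> tuple[VideoStack, Trajectory]:
    """Keep the first ``n_frames`` of a synchronized video/trajectory pair."""
    avail = min(video.n_frames, len(trajectory))
    if n_frames < 1 or n_frames > avail:
        raise ValueError(f"n_frames={n_frames} outside [1, {avail}] available frames")
    vid = VideoStack(
        frames=video.frames[:n_frames],
        frame_rate=video.frame_rate,
        pixel_size_um=video.pixel_size_um,
        frame_khz=None if video.frame_khz is None else video.frame_khz[:n_frames],
    )
    traj = Trajectory(
        cell_id=trajectory.cell_id,
        frames=trajectory.frames[:n_frames],
        xy=trajectory.xy[:n_frames],
        flagged=trajectory.flagged[:n_frames],
    )
    return vid, traj


def track_centroid(
    video: VideoStack,
    init_position: tuple[float, float],
    cell_id: str = "cell",
) -> Trajectory:
    """Track one cell by thresholding + nearest-component linking.

    For each frame the component centroid nearest the previous estimate is
    taken.  A frame with no component above threshold keeps the previous
    position and is flagged.
    """
    prev = np.asarray(init_position, dtype=float)
    xy = np.empty((video.n_frames, 2))
    flagged = np.zeros(video.n_frames, dtype=bool)
    for t, frame in enumerate(video.frames):
        f = frame.astype(float)
        if f.max() == f.min():
            xy[t] = prev
            flagged[t] = True
            continue
        th = threshold_otsu(f)
        bw = f > th
        labels, n = ndimage.label(bw)
        if n == 0:
            xy[t] = prev
            flagged[t] = True
            continue
        centers = ndimage.center_of_mass(bw, labels, index=np.arange(1, n + 1))
        centers = np.array(centers)[:, ::-1]  # (row, col) -> (x, y)
        d = np.linalg.norm(centers - prev, axis=1)
        lab = int(d.argmin()) + 1
        # refine with the intensity-weighted centroid of the chosen component:
        # above-threshold excess weighting is markedly less noisy than the
        # binary-mask centroid
        weights = np.where(labels == lab, f - th, 0.0)
        cy, cx = ndimage.center_of_mass(weights)
        prev = np.array([cx, cy])
        xy[t] = prev
    return Trajectory(
        cell_id=cell_id, frames=np.arange(video.n_frames), xy=xy, flagged=flagged
    )


def extract_roi_stack(
    video: VideoStack, trajectory: Trajectory, side: int = 151
) -> RoiStack:
    """Square centroid-centered ROIs, one per frame of the trajectory.

    Each ROI is centered at the rounded centroid; pixels outside the frame
    are filled by edge replication and the frame is flagged as padded.
    """
    if side % 2 == 0 or side < 1:
        raise ValueError("side must be odd and positive")
    half = side // 2
    h, w = video.shape
    n = len(trajectory)
    if n > video.n_frames:
        raise ValueError("trajectory longer than video")
    rois = np.empty((n, side, side), dtype=video.frames.dtype)
    centroids = round_half_away(trajectory.xy)
    padded = np.zeros(n, dtype=bool)
    for i, fidx in enumerate(trajectory.frames):
        cx, cy = centroids[i]
        r0, r1 = cy - half, cy + half + 1
        c0, c1 = cx - half, cx + half + 1
        pr0, pr1 = max(0, -r0), max(0, r1 - h)
        pc0, pc1 = max(0, -c0), max(0, c1 - w)
        crop = video.frames[fidx, max(0, r0) : min(h, r1), max(0, c0) : min(w, c1)]
        if pr0 or pr1 or pc0 or pc1:
            crop = np.pad(crop, ((pr0, pr1), (pc0, pc1)), mode="edge")
            padded[i] = True
        rois[i] = crop
    khz = None
    if video.frame_khz is not None:
        khz = video.frame_khz[trajectory.frames]
    return RoiStack(
        frames=rois, side=side, centroids=centroids, padded=padded, frame_khz=khz
    )
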