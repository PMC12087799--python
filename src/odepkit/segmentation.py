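"""Cell motion-area segmentation from the cumulative ROI image.

A suspended cell under ODEP stimulation sweeps a neighbourhood over the
time lapse.  Summing the histogram-stretched ROIs pixel by pixel gives a
cumulative image in which the bright defocus halo traces an annular motion
band around the darker cytoplasmic region.  Thresholding that image and
applying component rules yields three reference masks: the cell motion
area (``bw_cell``), the cytoplasmic area (``bw_cyt``, restricted to a
circle of the Hough-estimated cell radius) and the boundary band
(``bw_bound = bw_cell & ~bw_cyt``, an exact identity).  If the boundary
band is empty or degenerate at Otsu's threshold, the threshold is swept
downward (p = 1 - 0.1 n, n = 1..10) then upward (p = 1 + 0.1 n while
p * th_O < 1) until the conditions hold; on total failure the Otsu cell
mask is returned with ``converged=False``.

The motion area only gates PIV vectors; it is not a cell-boundary
segmentation and is never used to measure shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.transform import hough_circle

from .io import RoiStack

__all__ = [
    "CumulativeImage",
    "MotionMasks",
    "cumulative_motion_image",
    "estimate_radius_cht",
    "compute_masks",
    "segment_motion_area",
]

logger = logging.getLogger(__name__)


@dataclass
class CumulativeImage:
    """Min-max scaled pixelwise sum of percentile-stretched ROIs."""

    image: np.ndarray  # in [0, 1]
    degenerate: bool  # constant input, no scaling possible
    flagged_frames: np.ndarray  # frames whose stretch was degenerate


@dataclass
class MotionMasks:
    """Binary reference masks of one cell with convergence metadata.

    The identity ``bw_bound == bw_cell & ~bw_cyt`` holds exactly for every
    instance, and ``bw_bound & bw_cyt`` is empty by construction.
    """

    bw_cell: np.ndarray
    bw_cyt: np.ndarray
    bw_bound: np.ndarray
    bw_circ: np.ndarray
    threshold_used: float
    p_used: float
    converged: bool
    cht_radius: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not np.array_equal(self.bw_bound, self.bw_cell & ~self.bw_cyt):
            raise ValueError("mask identity bw_bound = bw_cell & ~bw_cyt violated")


def cumulative_motion_image(rois: RoiStack | np.ndarray) -> CumulativeImage:
    """Sum percentile-stretched ROIs and rescale to [0, 1].

    Each frame is stretched by its own 1st/99th percentiles and clipped to
    [0, 1] before summation; a frame whose percentiles coincide contributes
    a zero image and is flagged.  A constant result is flagged degenerate.
    """
    frames = np.asarray(getattr(rois, "frames", rois), dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("need a non-empty (T, n, m) stack")
    total = np.zeros(frames.shape[1:], dtype=float)
    flagged = []
    for t, f in enumerate(frames):
        lo, hi = np.percentile(f, [1, 99])
        if hi == lo:
            flagged.append(t)
            continue
        total += np.clip((f - lo) / (hi - lo), 0.0, 1.0)
    lo, hi = total.min(), total.max()
    if hi == lo:
        return CumulativeImage(
            image=np.zeros_like(total), degenerate=True, flagged_frames=np.array(flagged)
        )
    return CumulativeImage(
        image=(total - lo) / (hi - lo),
        degenerate=False,
        flagged_frames=np.array(flagged, dtype=int),
    )


def estimate_radius_cht(
    frame: np.ndarray,
    r_min: int = 30,
    r_max: int = 80,
    accumulator_floor: float = 0.3,
) -> float:
    """Radius (px) of the strongest circular edge response in ``[r_min, r_max]``.

    Raises
    ------
    ValueError
        If no circle reaches ``accumulator_floor`` (prompting a manual radius).
    """
    if not r_min < r_max:
        raise ValueError("require r_min < r_max")
    f = np.asarray(frame, dtype=float)
    if f.max() > f.min():
        f = (f - f.min()) / (f.max() - f.min())
    edges = canny(f, sigma=2.0)
    radii = np.arange(int(r_min), int(r_max) + 1)
    if not edges.any():
        raise ValueError("no edges found; supply the radius manually")
    acc = hough_circle(edges, radii)
    peaks = acc.reshape(radii.size, -1).max(axis=1)
    if peaks.max() < accumulator_floor:
        raise ValueError(
            f"no circular structure above accumulator floor {accumulator_floor}; "
            "supply the radius manually"
        )
    return float(radii[int(peaks.argmax())])


def _component_containing(
    bw: np.ndarray, c: tuple[int, int], exclude_border: bool = True
) -> np.ndarray:
    """Hole-filled connected component of ``bw`` whose filled extent contains c.

    Border-touching components are excluded first; among candidates whose
    hole-filled mask contains ``c`` the largest is returned.  Selection
    precedes hole filling.  Returns an all-false mask when no component
    qualifies.
    """
    cx, cy = int(c[0]), int(c[1])
    labels, n = ndimage.label(bw)
    if n == 0:
        return np.zeros_like(bw, dtype=bool)
    border = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border = set(border[border > 0]) if exclude_border else set()
    best = None
    best_area = -1
    for lab in range(1, n + 1):
        if lab in border:
            continue
        comp = labels == lab
        filled = ndimage.binary_fill_holes(comp)
        if filled[cy, cx]:
            area = int(filled.sum())
            if area > best_area:
                best, best_area = filled, area
    if best is None:
        return np.zeros_like(bw, dtype=bool)
    return best


def compute_masks(
    i_cum: CumulativeImage | np.ndarray,
    c: tuple[int, int],
    bw_circ: np.ndarray,
    th: float,
    cht_radius: float = float("nan"),
) -> MotionMasks:
    """Reference masks at one threshold.

    ``bw_cell`` is the hole-filled largest non-border component of the
    binarized cumulative image containing ``c``; ``bw_cyt`` the analogous
    component of the complement intersected with the circular
    initialization; ``bw_bound`` their exact set difference.
    """
    img = np.asarray(getattr(i_cum, "image", i_cum), dtype=float)
    if not 0.0 < th < 1.0:
        raise ValueError("th must be in (0, 1)")
    cx, cy = int(c[0]), int(c[1])
    if not (0 <= cy < img.shape[0] and 0 <= cx < img.shape[1]):
        raise ValueError("c outside grid")
    bw_th = img > th
    bw_cell = _component_containing(bw_th, c)
    flagged = not bw_cell.any()
    bw_cyt = _component_containing(~bw_th, c) & np.asarray(bw_circ, dtype=bool)
    bw_cyt &= bw_cell  # cytoplasm lies within the motion area by construction
    bw_bound = bw_cell & ~bw_cyt
    return MotionMasks(
        bw_cell=bw_cell,
        bw_cyt=bw_cyt,
        bw_bound=bw_bound,
        bw_circ=np.asarray(bw_circ, dtype=bool),
        threshold_used=float(th),
        p_used=float("nan"),
        converged=False,
        cht_radius=cht_radius,
        flagged=flagged,
    )


def _circle_mask(shape: tuple[int, int], c: tuple[int, int], radius: float) -> np.ndarray:
    yy, xx = np.indices(shape)
    return (xx - c[0]) ** 2 + (yy - c[1]) ** 2 <= radius**2


def _conditions_met(m: MotionMasks) -> bool:
    return bool(m.bw_bound.any()) and not np.array_equal(m.bw_bound, m.bw_cell)


def segment_motion_area(
    rois: RoiStack | np.ndarray,
    c: tuple[int, int] | None = None,
    radius: float | None = None,
    r_min: int = 30,
    r_max: int = 80,
    delta_p: float = 0.1,
) -> MotionMasks:
    """Full adaptive segmentation: cumulative image, CHT radius, threshold sweep.

    ``c`` defaults to the ROI center (ROIs are centroid-centered).  When
    ``radius`` is not given it is estimated by the circular Hough transform
    on the first frame; if that fails a radius of one third of the ROI side
    is used and logged.
    """
    frames = np.asarray(getattr(rois, "frames", rois), dtype=float)
    side_y, side_x = frames.shape[1:]
    if c is None:
        c = (side_x // 2, side_y // 2)
    cum = cumulative_motion_image(frames)
    if radius is None:
        try:
            radius = estimate_radius_cht(frames[0], r_min=r_min, r_max=r_max)
        except ValueError:
            radius = min(side_x, side_y) / 3.0
            logger.warning("CHT failed; falling back to radius %.1f px", radius)
    bw_circ = _circle_mask(frames.shape[1:], c, radius)

    if cum.degenerate:
        empty = np.zeros(frames.shape[1:], dtype=bool)
        return MotionMasks(
            bw_cell=empty,
            bw_cyt=empty.copy(),
            bw_bound=empty.copy(),
            bw_circ=bw_circ,
            threshold_used=float("nan"),
            p_used=float("nan"),
            converged=False,
            cht_radius=radius,
            flagged=True,
        )

    th_otsu = float(threshold_otsu(cum.image, nbins=256))
    # sweep order: Otsu first, then decreasing, then increasing multipliers
    ps = [1.0]
    ps += [1.0 - n * delta_p for n in range(1, 11)]
    n = 1
    while (1.0 + n * delta_p) * th_otsu < 1.0:
        ps.append(1.0 + n * delta_p)
        n += 1
    fallback = None
    for p in ps:
        th = p * th_otsu
        if not 0.0 < th < 1.0:
            continue
        masks = compute_masks(cum, c, bw_circ, th, cht_radius=radius)
        masks.p_used = p
        if p == 1.0:
            fallback = masks
        if _conditions_met(masks):
            masks.converged = True
            return masks
    assert fallback is not None
    fallback.converged = False
    return fallback
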