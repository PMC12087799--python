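"""Particle-image-velocimetry engine for centroid-frame deformation fields.

Local displacements between consecutive centroid-centered ROIs are
estimated by windowed FFT cross-correlation in two coarse-to-fine passes
(window 2w then w, 50% overlap).  The first-pass field is applied to the
second frame by bilinear image shifting before the final pass, and each
correlation peak is refined to sub-pixel precision with a 1-D three-point
Gaussian fit per dimension.  Because the ROIs follow the cell centroid, a
recovered displacement is a local deformation of the cell, not its bulk
motion.

Sign convention: a feature located at (x, y) in the first frame and at
(x + u, y + v) in the second yields (u, v) at that grid node; u is along
columns (x), v along rows (y).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import map_coordinates
from skimage import exposure

__all__ = ["DisplacementField", "preprocess_roi", "piv_pair", "piv_series"]


@dataclass
class DisplacementField:
    """Gridded (u, v) displacements in px with a per-node validity mask.

    ``grid_rows``/``grid_cols`` hold the window-center coordinates (px) of
    the N rows and M columns of the grid.  Invalid nodes (correlation peak
    on the border, degenerate window, or masked-out center) carry no
    numeric guarantee.
    """

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    grid_rows: np.ndarray
    grid_cols: np.ndarray
    window: int

    def __post_init__(self) -> None:
        if not (self.u.shape == self.v.shape == self.valid.shape):
            raise ValueError("u, v, valid must share shape")
        if self.u.shape != (self.grid_rows.size, self.grid_cols.size):
            raise ValueError("grid coordinates inconsistent with field shape")


def preprocess_roi(
    frame: np.ndarray, clip_limit: float = 0.01, n_tiles: int = 8
) -> tuple[np.ndarray, bool]:
    """Linear min-max intensity mapping followed by CLAHE.

    Returns the equalized frame in [0, 1] and a degeneracy flag; a constant
    frame is returned unchanged with the flag set.
    """
    f = np.asarray(frame, dtype=float)
    lo, hi = f.min(), f.max()
    if hi == lo:
        return f.copy(), True
    f = (f - lo) / (hi - lo)
    kernel = (max(1, f.shape[0] // n_tiles), max(1, f.shape[1] // n_tiles))
    return exposure.equalize_adapthist(f, kernel_size=kernel, clip_limit=clip_limit), False


def _grid_centers(length: int, window: int) -> np.ndarray:
    """Window-center coordinates with 50% overlap, windows fully inside."""
    half = window // 2
    return np.arange(half, length - half + 1, half, dtype=int)


def _window_stack(img: np.ndarray, rows: np.ndarray, cols: np.ndarray, w: int):
    half = w // 2
    r0 = rows - half
    c0 = cols - half
    # gather (N*M, w, w) stack of interrogation windows
    out = np.empty((rows.size * cols.size, w, w), dtype=float)
    k = 0
    for r in r0:
        for c in c0:
            out[k] = img[r : r + w, c : c + w]
            k += 1
    return out


def _correlate(stack_a: np.ndarray, stack_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Circular FFT cross-correlation of window stacks with sub-pixel peak fit.

    Returns per-window (u, v) and validity.  Peaks landing on the
    correlation border are invalid; a degenerate Gaussian fit (non-positive
    neighbour correlations) falls back to the integer peak.
    """
    k, w, _ = stack_a.shape
    a = stack_a - stack_a.mean(axis=(1, 2), keepdims=True)
    b = stack_b - stack_b.mean(axis=(1, 2), keepdims=True)
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    corr = np.fft.irfft2(np.conj(fa) * fb, s=(w, w))
    corr = np.fft.fftshift(corr, axes=(1, 2))  # zero displacement at (w//2, w//2)
    center = w // 2
    flat = corr.reshape(k, -1)
    peak = flat.argmax(axis=1)
    pi, pj = np.divmod(peak, w)
    valid = (pi > 0) & (pi < w - 1) & (pj > 0) & (pj < w - 1)
    # degenerate (zero-variance) windows: correlation identically ~0
    valid &= flat.max(axis=1) > 0

    u = (pj - center).astype(float)
    v = (pi - center).astype(float)

    idx = np.arange(k)
    c0 = corr[idx, pi, pj]
    safe_pi = np.clip(pi, 1, w - 2)
    safe_pj = np.clip(pj, 1, w - 2)
    cu_m = corr[idx, safe_pi, safe_pj - 1]
    cu_p = corr[idx, safe_pi, safe_pj + 1]
    cv_m = corr[idx, safe_pi - 1, safe_pj]
    cv_p = corr[idx, safe_pi + 1, safe_pj]

    def gauss_offset(cm, cc, cp):
        ok = (cm > 0) & (cc > 0) & (cp > 0)
        num = np.log(np.where(ok, cm, 1.0)) - np.log(np.where(ok, cp, 1.0))
        den = (
            2.0 * np.log(np.where(ok, cm, 1.0))
            - 4.0 * np.log(np.where(ok, cc, 1.0))
            + 2.0 * np.log(np.where(ok, cp, 1.0))
        )
        ok &= den != 0
        off = np.where(ok, num / np.where(den == 0, 1.0, den), 0.0)
        return np.clip(off, -1.0, 1.0)

    u += np.where(valid, gauss_offset(cu_m, c0, cu_p), 0.0)
    v += np.where(valid, gauss_offset(cv_m, c0, cv_p), 0.0)
    return u, v, valid


def _shift_image(img: np.ndarray, du: np.ndarray, dv: np.ndarray) -> np.ndarray:
    """Bilinear resampling of ``img`` at positions displaced by (du, dv)."""
    h, wd = img.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(wd), indexing="ij")
    return map_coordinates(img, [rr + dv, cc + du], order=1, mode="nearest")


def piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    final_window: int = 10,
    preprocess: bool = False,
) -> DisplacementField:
    """Two-pass FFT cross-correlation PIV between two frames.

    Pass 1 runs at twice ``final_window``; its field is applied to
    ``frame_b`` by bilinear shifting before the final pass at
    ``final_window`` with 50% overlap, and the two contributions are summed.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frame dimensions must match")
    if final_window < 4:
        raise ValueError("final_window must be >= 4")
    if preprocess:
        a, _ = preprocess_roi(a)
        b, _ = preprocess_roi(b)

    h, wd = a.shape
    w1 = 2 * final_window

    # --- pass 1 (coarse) ---
    rows1 = _grid_centers(h, w1)
    cols1 = _grid_centers(wd, w1)
    if rows1.size >= 2 and cols1.size >= 2:
        u1, v1, ok1 = _correlate(
            _window_stack(a, rows1, cols1, w1), _window_stack(b, rows1, cols1, w1)
        )
        u1 = np.where(ok1, u1, 0.0).reshape(rows1.size, cols1.size)
        v1 = np.where(ok1, v1, 0.0).reshape(rows1.size, cols1.size)
        interp_u = RegularGridInterpolator(
            (rows1, cols1), u1, bounds_error=False, fill_value=None
        )
        interp_v = RegularGridInterpolator(
            (rows1, cols1), v1, bounds_error=False, fill_value=None
        )
        rr, cc = np.meshgrid(np.arange(h), np.arange(wd), indexing="ij")
        pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
        du = interp_u(pts).reshape(h, wd)
        dv = interp_v(pts).reshape(h, wd)
        b2 = _shift_image(b, du, dv)
    else:  # image too small for the coarse pass
        du = dv = np.zeros_like(a)
        b2 = b

    # --- pass 2 (final) ---
    rows2 = _grid_centers(h, final_window)
    cols2 = _grid_centers(wd, final_window)
    u2, v2, ok2 = _correlate(
        _window_stack(a, rows2, cols2, final_window),
        _window_stack(b2, rows2, cols2, final_window),
    )
    shape = (rows2.size, cols2.size)
    rrg, ccg = np.meshgrid(rows2, cols2, indexing="ij")
    u = u2.reshape(shape) + du[rrg, ccg]
    v = v2.reshape(shape) + dv[rrg, ccg]
    return DisplacementField(
        u=u,
        v=v,
        valid=ok2.reshape(shape),
        grid_rows=rows2,
        grid_cols=cols2,
        window=final_window,
    )


def piv_series(
    rois,
    mask: np.ndarray | None = None,
    final_window: int = 10,
    preprocess: bool = True,
) -> list[DisplacementField]:
    """Displacement fields between all consecutive ROI pairs of one cell.

    ``rois`` is a (T, side, side) array (or an object exposing ``.frames``);
    ``mask`` is the fixed cell-motion-area mask: grid nodes whose window
    center falls outside it are marked invalid in every field.
    """
    frames = np.asarray(getattr(rois, "frames", rois), dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of at least 2 frames")
    if preprocess:
        frames = np.stack([preprocess_roi(f)[0] for f in frames])
    fields: list[DisplacementField] = []
    node_mask = None
    for t in range(frames.shape[0] - 1):
        fld = piv_pair(frames[t], frames[t + 1], final_window=final_window)
        if mask is not None:
            if node_mask is None:
                rrg, ccg = np.meshgrid(fld.grid_rows, fld.grid_cols, indexing="ij")
                node_mask = np.asarray(mask, dtype=bool)[rrg, ccg]
            fld.valid &= node_mask
        fields.append(fld)
    return fields
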