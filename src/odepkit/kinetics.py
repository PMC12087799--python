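"""Deformation-kinetics time series and their 21 statistical descriptors.

Each displacement field (local deformations in the reference frame of the
cell centroid) is reduced to three scalars per frame interval: the spatial
means of the u and v components and the spatial mean of the cosine of the
local phase (orientation) field.  The three series, referenced to their
first sample, are the cell's local electrokinetic fingerprint; seven
descriptors per series (SD, mean absolute deviation, skewness, non-excess
kurtosis, maximum, minimum, approximate entropy) give 21 values per cell.

Approximate entropy (ApEn) follows the standard regularity statistic:
length-m blocks of the series are compared under the Chebyshev distance at
radius r = r_factor * SD, self-matches excluded, and ApEn is the difference
of the log-average match rates at block lengths m and m+1.  Low values mean
the series is predictable (deformations follow the stimulation pattern);
irregular off-stimulus deformation events raise it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .piv import DisplacementField

__all__ = [
    "KineticsSeries",
    "spatial_mean_components",
    "mean_cos_phase",
    "relative_series",
    "approximate_entropy",
    "distribution_stats",
    "local_descriptors",
    "kinetics_from_fields",
    "LOCAL_DESCRIPTOR_NAMES",
]

logger = logging.getLogger(__name__)

STAT_NAMES = ("sd", "mad", "skew", "kurt", "max", "min", "apen")
SERIES_NAMES = ("dx", "dy", "dtheta")
#: Fixed order of the 21 local descriptors: 7 statistics for each of dx, dy, dtheta.
LOCAL_DESCRIPTOR_NAMES = tuple(f"{s}_{ser}" for ser in SERIES_NAMES for s in STAT_NAMES)


@dataclass
class KineticsSeries:
    """Per-frame-interval spatially averaged deformation series.

    ``x_mu``/``y_mu`` are mean local displacements (px), ``theta_mu`` the
    mean cosine of the local phase (dimensionless, in [-1, 1]); ``dx``,
    ``dy``, ``dtheta`` are the same series referenced to their first sample.
    ``valid`` flags intervals where at least one field node was valid;
    invalid intervals carry NaN.
    """

    x_mu: np.ndarray
    y_mu: np.ndarray
    theta_mu: np.ndarray
    frame_rate: float
    valid: np.ndarray

    @property
    def dx(self) -> np.ndarray:
        return relative_series(self.x_mu)

    @property
    def dy(self) -> np.ndarray:
        return relative_series(self.y_mu)

    @property
    def dtheta(self) -> np.ndarray:
        return relative_series(self.theta_mu)

    def to_frame(self):
        """Tabular view (one row per frame interval), ready for ``to_csv``."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(self.x_mu.size),
                "x_mu": self.x_mu,
                "y_mu": self.y_mu,
                "theta_mu": self.theta_mu,
                "dx": self.dx,
                "dy": self.dy,
                "dtheta": self.dtheta,
                "valid": self.valid.astype(int),
            }
        )


def spatial_mean_components(field: DisplacementField) -> tuple[float, float]:
    """Arithmetic mean of u and v over the valid nodes of one field.

    Returns ``(nan, nan)`` when no node is valid (flagged upstream).
    """
    m = field.valid
    if not m.any():
        return float("nan"), float("nan")
    return float(field.u[m].mean()), float(field.v[m].mean())


def mean_cos_phase(field: DisplacementField) -> float:
    """Mean cosine of the per-node phase (orientation) of one field.

    The phase of a node is the four-quadrant angle of its (u, v) vector;
    zero-magnitude nodes have no orientation and contribute cos(theta) = 0.
    Returns NaN when no node is valid.
    """
    m = field.valid
    if not m.any():
        return float("nan")
    u, v = field.u[m], field.v[m]
    mag = np.hypot(u, v)
    c = np.zeros_like(u, dtype=float)
    nz = mag > 0
    c[nz] = u[nz] / mag[nz]  # cos(atan2(v, u)) = u / |U|
    return float(c.mean())


def relative_series(raw: np.ndarray) -> np.ndarray:
    """Series referenced to its first finite sample: delta(t) = raw(t) - raw(t1)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty series")
    finite = np.flatnonzero(np.isfinite(raw))
    ref = raw[finite[0]] if finite.size else np.nan
    return raw - ref


def approximate_entropy(
    u: np.ndarray, m: int = 2, r_factor: float = 0.2
) -> float:
    """Approximate entropy of a time series (block length ``m``, radius ``r_factor``·SD).

    Counts, for every length-m block, the other blocks within Chebyshev
    distance r (self-matches excluded); phi_m is the average log of the
    normalized counts and ApEn = phi_m - phi_{m+1}.  A block with no
    neighbour keeps its self-match so the logarithm stays finite (logged).
    A constant series (SD = 0) returns 0 by convention.
    """
    u = np.asarray(u, dtype=float)
    n = u.size
    if n <= m + 1:
        raise ValueError(f"series length {n} must exceed m+1 = {m + 1}")
    sigma = float(u.std())
    if sigma == 0.0:
        return 0.0
    r = r_factor * sigma

    def phi(mm: int) -> float:
        blocks = sliding_window_view(u, mm)  # (B, mm), B = n - mm + 1
        b = blocks.shape[0]
        # Pairwise Chebyshev distances between blocks.
        d = np.abs(blocks[:, None, :] - blocks[None, :, :]).max(axis=2)
        counts = (d < r).sum(axis=1) - 1  # exclude self-match
        zero = counts == 0
        if zero.any():
            logger.debug("ApEn: %d blocks had no neighbour at r=%.3g", zero.sum(), r)
            counts = np.where(zero, 1, counts)
        return float(np.mean(np.log(counts / (b - 1))))

    return phi(m) - phi(m + 1)


def distribution_stats(series: np.ndarray) -> dict[str, float]:
    """Population dispersion/shape statistics of a series.

    SD and moments use population (1/N) normalisation; kurtosis is
    non-excess (a Gaussian scores 3).  A constant series returns 0 for
    skewness and kurtosis by convention.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    sd = x.std()
    mad = np.abs(x - mu).mean()
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        z = (x - mu) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    return {
        "sd": float(sd),
        "mad": float(mad),
        "skew": float(skew),
        "kurt": float(kurt),
        "max": float(x.max()),
        "min": float(x.min()),
    }


def local_descriptors(
    k: KineticsSeries, m: int = 2, r_factor: float = 0.2
) -> tuple[np.ndarray, list[str]]:
    """The 21 local-displacement descriptors of one cell, in fixed order.

    Frames whose field had no valid node are dropped from each series
    before computing statistics (their count is logged).
    """
    values: list[float] = []
    for series in (k.dx, k.dy, k.dtheta):
        s = series[np.isfinite(series)]
        dropped = series.size - s.size
        if dropped:
            logger.debug("dropping %d invalid frames from a kinetics series", dropped)
        stats = distribution_stats(s)
        values.extend(stats[name] for name in STAT_NAMES[:-1])
        values.append(approximate_entropy(s, m=m, r_factor=r_factor))
    return np.array(values), list(LOCAL_DESCRIPTOR_NAMES)


def kinetics_from_fields(
    fields: list[DisplacementField], frame_rate: float = 20.0
) -> KineticsSeries:
    """Reduce a displacement-field sequence to the three kinetics series."""
    if not fields:
        raise ValueError("empty field sequence")
    x_mu = np.empty(len(fields))
    y_mu = np.empty(len(fields))
    th = np.empty(len(fields))
    ok = np.empty(len(fields), dtype=bool)
    for i, f in enumerate(fields):
        x_mu[i], y_mu[i] = spatial_mean_components(f)
        th[i] = mean_cos_phase(f)
        ok[i] = bool(f.valid.any())
    return KineticsSeries(x_mu=x_mu, y_mu=y_mu, theta_mu=th, frame_rate=frame_rate, valid=ok)
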