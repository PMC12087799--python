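"""Synthetic ODEP time-lapse videos and labeled multi-patient cohorts.

The real acquisitions are available only on request, so every stage of the
analysis is exercised against a generator that emulates what the analysis
assumes: a speckle-textured cell (bright defocus halo, dark membrane ring,
textured cytoplasm) oscillating between two virtual electrodes under a
decreasing-frequency schedule, with small local electrodeformations applied
in the centroid frame, class-dependent orientation statistics, defocus
drift, sensor noise, and a cells-within-patients-within-classes hierarchy.

Motion regimes follow the qualitative dielectrophoretic phenomenology:
above the crossover frequency the cell relaxes toward the currently active
electrode with an oscillatory factor at the ~0.2 Hz base rate (pDEP, with a
frequency-dependent amplitude profile); near crossover it is quasi-static;
below crossover it drifts away from the electrode axis (nDEP).  The
amplitude-vs-frequency profile is a configurable monotone placeholder, not
a Maxwell-stress computation.

Every quantity the generator applies is exported as ground truth: the
continuous centroid track and, per consecutive ROI pair, the exact apparent
displacement field (deformation increment plus the sub-pixel residual of
ROI re-centering) on the PIV grid, so the PIV engine can be validated
end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .io import VideoStack
from .schedule import StimulusSchedule, build_stimulus_schedule
from .tracking import round_half_away

__all__ = [
    "SyntheticCellParams",
    "SyntheticCohortConfig",
    "GroundTruth",
    "CohortItem",
    "simulate_cell_video",
    "simulate_cohort",
    "iter_cohort",
    "class_recipes",
]

_BACKGROUND = 0.35
_CYTOPLASM = 0.45
_MEMBRANE = 0.08
_HALO = 0.85


@dataclass(frozen=True)
class SyntheticCellParams:
    """Per-cell physical and behavioural parameters.

    ``oscillation_gain`` is the peak centroid excursion (px) at the highest
    schedule frequency; the excursion scales linearly down to zero at
    ``crossover_khz`` and turns into a slow perpendicular drift below it.
    ``orientation_mode`` selects the angular law of the local deformation
    bumps: ``"bimodal"`` (toward either electrode along the stimulation
    axis) or ``"diffuse"`` (near-uniform).  ``off_stimulus_event_rate`` is
    the Poisson rate (events/s) of randomly oriented deformation bursts
    decoupled from the stimulation windows.
    """

    radius_um: float = 22.5
    crossover_khz: float = 50.0
    oscillation_gain: float = 12.0
    base_oscillation_hz: float = 0.2
    deformation_amplitude: float = 2.5
    orientation_mode: str = "bimodal"
    off_stimulus_event_rate: float = 0.02
    defocus_drift: float = 0.3
    centroid_jitter: float = 0.01
    texture_seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.off_stimulus_event_rate < 0:
            raise ValueError("off_stimulus_event_rate must be >= 0")
        if self.orientation_mode not in ("bimodal", "diffuse"):
            raise ValueError("orientation_mode must be 'bimodal' or 'diffuse'")


def class_recipes() -> dict[str, dict]:
    """Default per-class parameter overrides.

    The classes differ in the two properties the dominant discriminators
    respond to: the orientation regularity of local deformations (kurtosis
    of the phase series) and the rate of off-stimulus deformation events
    (approximate entropy of the phase series).
    """
    return {
        "CTRL": {"orientation_mode": "bimodal", "off_stimulus_event_rate": 0.02},
        "RIF": {"orientation_mode": "diffuse", "off_stimulus_event_rate": 0.02},
        "uRPL": {"orientation_mode": "diffuse", "off_stimulus_event_rate": 1.0},
    }


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Cohort layout and acquisition geometry.

    Defaults emulate the reference study scale: 3 classes x 6 patients x 30
    cells at 0.45 um/px and 20 fps with electrodes 60 um apart.  Identical
    config and ``master_seed`` reproduce the cohort bit-exactly.
    """

    classes: tuple[str, ...] = ("CTRL", "RIF", "uRPL")
    patients_per_class: int = 6
    cells_per_patient: int = 30
    inter_patient_sd: float = 0.1
    noise_sd: float = 0.01
    pixel_size_um: float = 0.45
    electrode_separation_um: float = 60.0
    canvas: tuple[int, int] = (200, 340)
    cells_per_video: int = 3
    schedule: StimulusSchedule = field(default_factory=build_stimulus_schedule)
    base_params: SyntheticCellParams = field(default_factory=SyntheticCellParams)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("empty class set")
        if self.patients_per_class < 1 or self.cells_per_patient < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator applied to one cell's video.

    ``centroid_track`` is the continuous (x, y) centroid per frame in
    canvas coordinates.  ``true_fields`` is a (T-1, N, M, 2) array with the
    exact apparent (u, v) displacement between consecutive centroid-centered
    ROIs at the PIV grid nodes: the local deformation increment plus the
    sub-pixel residual of ROI re-centering (rounded centroid minus true
    centroid), which is what a displacement estimator sees in the ROI frame.
    """

    centroid_track: np.ndarray
    true_fields: np.ndarray
    grid_rows: np.ndarray
    grid_cols: np.ndarray
    roi_side: int
    params: SyntheticCellParams
    frame_khz: np.ndarray


@dataclass
class CohortItem:
    video: VideoStack
    truth: GroundTruth
    cell_id: str
    patient_id: str
    video_id: str
    class_label: str


# ---------------------------------------------------------------------------
# deformation bumps


@dataclass(frozen=True)
class _Bump:
    cx: float  # center, cell frame (x)
    cy: float
    sigma: float
    amp: float
    ux: float  # unit displacement direction
    uy: float
    t0: float  # envelope support / parameters (s)
    t1: float
    kind: str  # "stim" (half-sine^2 over [t0, t1]) or "event" (Gaussian at t0)
    width: float = 0.15

    def envelope(self, t: float) -> float:
        if self.kind == "stim":
            if self.t0 <= t < self.t1:
                return float(np.sin(np.pi * (t - self.t0) / (self.t1 - self.t0)) ** 2)
            return 0.0
        # transient event
        if abs(t - self.t0) > 4 * self.width:
            return 0.0
        return float(np.exp(-0.5 * ((t - self.t0) / self.width) ** 2))


def _draw_bumps(
    params: SyntheticCellParams,
    schedule: StimulusSchedule,
    radius_px: float,
    rng: np.random.Generator,
) -> list[_Bump]:
    bumps: list[_Bump] = []
    fps = schedule.frame_rate
    frames = schedule.frames_per_entry()
    edges = np.concatenate([[0], np.cumsum(frames)]) / fps
    # stimulation-locked bumps, one batch per clip
    for k, entry in enumerate(schedule.entries):
        sign = 1.0 if entry.electrode == "B" else -1.0  # toward active electrode
        if params.orientation_mode == "bimodal":
            # mostly toward the active electrode, along the stimulation axis
            angles = [
                (0.0 if rng.random() < 0.8 else np.pi) + rng.normal(0.0, 0.25)
                for _ in range(6)
            ]
            angles = [a if sign > 0 else a + np.pi for a in angles]
        else:
            # near-uniform directions in antipodal pairs: heterogeneous local
            # orientations with near-zero net displacement, so the bulk
            # centroid stays put while local phases scatter
            halves = [rng.uniform(0, 2 * np.pi) for _ in range(3)]
            angles = halves + [a + np.pi for a in halves]
        for ang in angles:
            rho = rng.uniform(0.45, 0.95) * radius_px
            phi = rng.uniform(0, 2 * np.pi)
            bumps.append(
                _Bump(
                    cx=rho * np.cos(phi),
                    cy=rho * np.sin(phi),
                    sigma=0.45 * radius_px,
                    amp=params.deformation_amplitude * rng.uniform(0.7, 1.0),
                    ux=float(np.cos(ang)),
                    uy=float(np.sin(ang)),
                    t0=float(edges[k]),
                    t1=float(edges[k + 1]),
                    kind="stim",
                )
            )
    # off-stimulus events, Poisson over the whole acquisition
    total_s = float(edges[-1])
    n_events = rng.poisson(params.off_stimulus_event_rate * total_s)
    for _ in range(n_events):
        rho = rng.uniform(0.3, 0.95) * radius_px
        phi = rng.uniform(0, 2 * np.pi)
        ang = rng.uniform(0, 2 * np.pi)
        bumps.append(
            _Bump(
                cx=rho * np.cos(phi),
                cy=rho * np.sin(phi),
                sigma=0.8 * radius_px,
                amp=2.0 * params.deformation_amplitude,
                ux=float(np.cos(ang)),
                uy=float(np.sin(ang)),
                t0=rng.uniform(0, total_s),
                t1=0.0,
                kind="event",
                width=0.2,
            )
        )
    return bumps


def _deformation(
    bumps: list[_Bump], t: float, xs: np.ndarray, ys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative deformation (ux, uy) at cell-frame points, at time t (s)."""
    ux = np.zeros_like(xs, dtype=float)
    uy = np.zeros_like(ys, dtype=float)
    for b in bumps:
        e = b.envelope(t)
        if e == 0.0:
            continue
        g = e * b.amp * np.exp(
            -0.5 * ((xs - b.cx) ** 2 + (ys - b.cy) ** 2) / b.sigma**2
        )
        ux += g * b.ux
        uy += g * b.uy
    return ux, uy


# ---------------------------------------------------------------------------
# centroid motion


def _centroid_track(
    params: SyntheticCellParams,
    schedule: StimulusSchedule,
    canvas: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous (x, y) centroid per frame, canvas coordinates."""
    h, w = canvas
    fps = schedule.frame_rate
    cx0, cy0 = w / 2.0, h / 2.0
    f_top = schedule.entries[0].frequency_khz
    tau = 0.15  # relaxation time constant, s
    quasi = 0.05  # |profile| below which the cell is quasi-static
    track = []
    x, y = cx0, cy0
    t_global = 0.0
    for entry, n_frames in zip(schedule.entries, schedule.frames_per_entry()):
        s = (entry.frequency_khz - params.crossover_khz) / max(
            f_top - params.crossover_khz, 1e-9
        )
        sign = -1.0 if entry.electrode == "A" else 1.0
        if s > quasi:  # pDEP: damped approach toward the active electrode
            target = cx0 + sign * params.oscillation_gain * s
            x0 = x
            for i in range(n_frames):
                t = (i + 1) / fps
                osc = np.exp(-t / tau) * np.cos(
                    2 * np.pi * params.base_oscillation_hz * t
                )
                x = target + (x0 - target) * osc
                y += rng.normal(0, params.centroid_jitter)
                x += rng.normal(0, params.centroid_jitter)
                track.append((x, y))
        elif s < -quasi:  # nDEP: straight drift away from the electrode axis
            speed = 0.15 * params.oscillation_gain * (-s)  # px / s
            for _ in range(n_frames):
                y += speed / fps + rng.normal(0, params.centroid_jitter)
                x += rng.normal(0, params.centroid_jitter)
                track.append((x, y))
        else:  # crossover: quasi-static
            for _ in range(n_frames):
                x += rng.normal(0, params.centroid_jitter)
                y += rng.normal(0, params.centroid_jitter)
                track.append((x, y))
        t_global += n_frames / fps
    return np.array(track)


# ---------------------------------------------------------------------------
# rendering


def _make_texture(radius_px: float, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    ext = int(np.ceil(2 * radius_px + 16))
    tex = rng.standard_normal((ext, ext))
    tex = gaussian_filter(tex, 1.5)
    tex /= max(np.abs(tex).max(), 1e-12)
    return tex, ext / 2.0


def _appearance(
    xs: np.ndarray,
    ys: np.ndarray,
    radius_px: float,
    texture: np.ndarray,
    tex_center: float,
) -> np.ndarray:
    """Cell intensity at cell-frame points: halo ring, membrane, cytoplasm."""
    r = np.hypot(xs, ys)
    ring_w = max(2.0, 0.08 * radius_px)
    halo_w = max(3.0, 0.14 * radius_px)

    def smoothstep(e0, e1, v):
        t = np.clip((v - e0) / (e1 - e0), 0.0, 1.0)
        return t * t * (3 - 2 * t)

    img = np.full_like(r, _BACKGROUND, dtype=float)
    # halo (outside the membrane), fading into background
    halo = smoothstep(radius_px + halo_w, radius_px + halo_w - 1.5, r) * smoothstep(
        radius_px - 1.0, radius_px + 0.5, r
    )
    img += (_HALO - _BACKGROUND) * halo
    # dark membrane ring
    mem = smoothstep(radius_px - ring_w - 1.0, radius_px - ring_w + 0.5, r) * smoothstep(
        radius_px + 0.5, radius_px - 1.0, r
    )
    img = img * (1 - mem) + _MEMBRANE * mem
    # cytoplasm with speckle
    cyt = smoothstep(radius_px - ring_w + 0.5, radius_px - ring_w - 1.0, r)
    spk = map_coordinates(
        texture, [ys + tex_center, xs + tex_center], order=1, mode="nearest"
    )
    img = img * (1 - cyt) + (_CYTOPLASM + 0.18 * spk) * cyt
    # faint texture on the halo so PIV has signal in the boundary band
    img += 0.08 * spk * halo
    return img


def simulate_cell_video(
    params: SyntheticCellParams,
    schedule: StimulusSchedule | None = None,
    canvas: tuple[int, int] = (200, 340),
    seed: int = 0,
    *,
    pixel_size_um: float = 0.45,
    electrode_separation_um: float = 60.0,
    noise_sd: float = 0.01,
    roi_side: int = 151,
    piv_window: int = 10,
) -> tuple[VideoStack, GroundTruth]:
    """Render one cell's full time-lapse video plus its ground truth.

    The returned truth carries the continuous centroid track and the exact
    apparent displacement field between consecutive centroid-centered ROIs
    of side ``roi_side`` on the 50%-overlap PIV grid for ``piv_window``.

    Raises
    ------
    ValueError
        If the canvas cannot contain the cell plus its maximal excursion.
    """
    if schedule is None:
        schedule = build_stimulus_schedule()
    radius_px = params.radius_um / pixel_size_um
    h, w = canvas
    halo_w = max(3.0, 0.14 * radius_px)
    margin = radius_px + halo_w + 4
    # worst-case excursions: pDEP amplitude along x, nDEP drift along y
    fps = schedule.frame_rate
    f_top = schedule.entries[0].frequency_khz
    drift = 0.0
    for entry, n in zip(schedule.entries, schedule.frames_per_entry()):
        s = (entry.frequency_khz - params.crossover_khz) / max(
            f_top - params.crossover_khz, 1e-9
        )
        if s < -0.05:
            drift += 0.15 * params.oscillation_gain * (-s) * n / fps
    if w / 2.0 < params.oscillation_gain + margin or h / 2.0 < drift + margin + 2:
        raise ValueError(
            f"canvas {canvas} too small for cell radius {radius_px:.0f} px, "
            f"oscillation {params.oscillation_gain} px and drift {drift:.0f} px"
        )

    ss = np.random.SeedSequence([seed, params.texture_seed])
    r_motion, r_bumps, r_tex, r_noise = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    track = _centroid_track(params, schedule, canvas, r_motion)
    bumps = _draw_bumps(params, schedule, radius_px, r_bumps)
    texture, tex_center = _make_texture(radius_px, r_tex)

    n_frames = track.shape[0]
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    reach = int(np.ceil(margin))
    for t in range(n_frames):
        cx, cy = track[t]
        tt = t / fps
        # render window around the cell
        r0 = max(0, int(np.floor(cy)) - reach)
        r1 = min(h, int(np.ceil(cy)) + reach + 1)
        c0 = max(0, int(np.floor(cx)) - reach)
        c1 = min(w, int(np.ceil(cx)) + reach + 1)
        yy, xx = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        xs = xx - cx
        ys = yy - cy
        dux, duy = _deformation(bumps, tt, xs, ys)
        patch = _appearance(xs - dux, ys - duy, radius_px, texture, tex_center)
        if params.defocus_drift > 0:
            sigma = 0.4 + params.defocus_drift * 0.5 * (
                1 + np.sin(2 * np.pi * tt / max(n_frames / fps, 1.0) * 2)
            )
            patch = gaussian_filter(patch, sigma)
        img = np.full((h, w), _BACKGROUND)
        img[r0:r1, c0:c1] = patch
        if noise_sd > 0:
            img = img + r_noise.normal(0.0, noise_sd, size=img.shape)
        frames[t] = np.clip(img * 255.0, 0, 255).astype(np.uint8)

    truth = _ground_truth_fields(
        track, bumps, params, schedule, roi_side, piv_window
    )
    video = VideoStack(
        frames=frames,
        frame_rate=fps,
        pixel_size_um=pixel_size_um,
        frame_khz=schedule.frame_frequency_map(),
    )
    return video, truth


def _ground_truth_fields(
    track: np.ndarray,
    bumps: list[_Bump],
    params: SyntheticCellParams,
    schedule: StimulusSchedule,
    roi_side: int,
    piv_window: int,
) -> GroundTruth:
    from .piv import _grid_centers  # same grid geometry as the engine

    fps = schedule.frame_rate
    rows = _grid_centers(roi_side, piv_window)
    cols = _grid_centers(roi_side, piv_window)
    center = roi_side // 2
    rounded = round_half_away(track)
    n = track.shape[0]
    fields = np.zeros((n - 1, rows.size, cols.size, 2))
    gy, gx = np.meshgrid(rows - center, cols - center, indexing="ij")
    for t in range(n - 1):
        # cell-frame coordinates of the grid nodes in the two ROIs
        resid_t = rounded[t] - track[t]
        resid_n = rounded[t + 1] - track[t + 1]
        xs_t = gx + resid_t[0]
        ys_t = gy + resid_t[1]
        u_t = _deformation(bumps, t / fps, xs_t, ys_t)
        u_n = _deformation(bumps, (t + 1) / fps, xs_t, ys_t)
        fields[t, :, :, 0] = (u_n[0] - u_t[0]) + (resid_t[0] - resid_n[0])
        fields[t, :, :, 1] = (u_n[1] - u_t[1]) + (resid_t[1] - resid_n[1])
    return GroundTruth(
        centroid_track=track,
        true_fields=fields,
        grid_rows=rows,
        grid_cols=cols,
        roi_side=roi_side,
        params=params,
        frame_khz=schedule.frame_frequency_map(),
    )


# ---------------------------------------------------------------------------
# cohorts


def _jitter(
    params: SyntheticCellParams, sd: float, rng: np.random.Generator
) -> SyntheticCellParams:
    """Multiplicative log-normal jitter on the continuous cell parameters."""
    g = lambda: float(np.exp(rng.normal(0.0, sd)))
    return replace(
        params,
        radius_um=params.radius_um * g(),
        deformation_amplitude=params.deformation_amplitude * g(),
        oscillation_gain=params.oscillation_gain * g(),
        off_stimulus_event_rate=params.off_stimulus_event_rate * g(),
        crossover_khz=params.crossover_khz + rng.normal(0.0, 2.0 * sd * 10),
    )


def iter_cohort(config: SyntheticCohortConfig, *, roi_side: int = 151, piv_window: int = 10):
    """Yield :class:`CohortItem` per cell, patient-level then cell-level draws.

    Seeding: the master seed spawns one child sequence per patient, which
    spawns one per cell, so any subset of the cohort can be regenerated
    identically.
    """
    recipes = class_recipes()
    master = np.random.SeedSequence(config.master_seed)
    patient_seeds = master.spawn(len(config.classes) * config.patients_per_class)
    k = 0
    for label in config.classes:
        overrides = recipes.get(label, {})
        base = replace(config.base_params, **overrides)
        for p in range(config.patients_per_class):
            pseq = patient_seeds[k]
            k += 1
            prng = np.random.default_rng(pseq)
            patient_params = _jitter(base, config.inter_patient_sd, prng)
            patient_id = f"{label}_P{p + 1}"
            cell_seeds = pseq.spawn(config.cells_per_patient)
            for c in range(config.cells_per_patient):
                crng = np.random.default_rng(cell_seeds[c])
                cell_params = _jitter(patient_params, config.inter_patient_sd / 2, crng)
                cell_params = replace(
                    cell_params, texture_seed=int(crng.integers(0, 2**31 - 1))
                )
                video, truth = simulate_cell_video(
                    cell_params,
                    config.schedule,
                    canvas=config.canvas,
                    seed=int(crng.integers(0, 2**31 - 1)),
                    pixel_size_um=config.pixel_size_um,
                    electrode_separation_um=config.electrode_separation_um,
                    noise_sd=config.noise_sd,
                    roi_side=roi_side,
                    piv_window=piv_window,
                )
                yield CohortItem(
                    video=video,
                    truth=truth,
                    cell_id=f"{patient_id}_C{c + 1}",
                    patient_id=patient_id,
                    video_id=f"{patient_id}_V{c // config.cells_per_video + 1}",
                    class_label=label,
                )


def simulate_cohort(
    config: SyntheticCohortConfig, *, roi_side: int = 151, piv_window: int = 10
) -> list[CohortItem]:
    """Materialize the whole cohort in memory (use :func:`iter_cohort` for large runs)."""
    return list(iter_cohort(config, roi_side=roi_side, piv_window=piv_window))
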