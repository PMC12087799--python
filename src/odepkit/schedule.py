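"""Stimulation schedules for optically-induced dielectrophoresis (ODEP) runs.

A measurement session applies a voltage (default 10 Vpp) to one of two
virtual electrodes at a time, stepping through a decreasing sequence of
frequencies (default 150 kHz down to 25 kHz in 5 kHz steps, i.e. 26 clips)
while the electrodes alternate A, B, A, ...  One video clip is recorded per
frequency; the schedule is the single source of truth for the
frame-to-frequency bookkeeping used by both the simulator and the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScheduleEntry", "StimulusSchedule", "build_stimulus_schedule"]


@dataclass(frozen=True)
class ScheduleEntry:
    """One stimulation step: a frequency applied on one electrode for ``dwell_s``."""

    frequency_khz: float
    electrode: str  # "A" or "B"
    dwell_s: float

    def __post_init__(self) -> None:
        if self.electrode not in ("A", "B"):
            raise ValueError(f"electrode must be 'A' or 'B', got {self.electrode!r}")
        if self.dwell_s <= 0:
            raise ValueError("dwell_s must be > 0")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulation steps plus acquisition constants.

    Invariants: frequencies strictly decrease by a constant step and the
    active electrode strictly alternates starting at A.
    """

    entries: tuple[ScheduleEntry, ...]
    amplitude_vpp: float = 10.0
    frame_rate: float = 20.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("schedule must contain at least one entry")
        freqs = [e.frequency_khz for e in self.entries]
        if len(freqs) > 1:
            steps = np.diff(freqs)
            if not np.all(steps < 0) or not np.allclose(steps, steps[0]):
                raise ValueError("frequencies must strictly decrease by a constant step")
        for i, e in enumerate(self.entries):
            expected = "A" if i % 2 == 0 else "B"
            if e.electrode != expected:
                raise ValueError("electrodes must alternate A, B, A, ...")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def frequencies_khz(self) -> np.ndarray:
        return np.array([e.frequency_khz for e in self.entries], dtype=float)

    def frames_per_entry(self) -> np.ndarray:
        """Number of frames recorded for each clip at ``frame_rate``."""
        return np.array(
            [int(round(e.dwell_s * self.frame_rate)) for e in self.entries], dtype=int
        )

    @property
    def total_frames(self) -> int:
        return int(self.frames_per_entry().sum())

    def frame_frequency_map(self) -> np.ndarray:
        """Per-frame stimulation frequency (kHz) for the concatenated video."""
        return np.repeat(self.frequencies_khz, self.frames_per_entry())

    def frame_electrode_map(self) -> np.ndarray:
        """Per-frame active electrode (+1 for A, -1 for B)."""
        signs = np.array(
            [1 if e.electrode == "A" else -1 for e in self.entries], dtype=int
        )
        return np.repeat(signs, self.frames_per_entry())

    def clip_slices(self) -> list[slice]:
        """Frame index range of each clip in the concatenated video."""
        edges = np.concatenate([[0], np.cumsum(self.frames_per_entry())])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def build_stimulus_schedule(
    start_khz: float = 150.0,
    stop_khz: float = 25.0,
    step_khz: float = 5.0,
    dwell_s: float = 1.9,
    amplitude_vpp: float = 10.0,
    frame_rate: float = 20.0,
) -> StimulusSchedule:
    """Build the decreasing-frequency, alternating-electrode schedule.

    Defaults reproduce the standard acquisition: 26 frequencies from 150 to
    25 kHz in 5 kHz steps with alternating electrode activation at 10 Vpp.

    Raises
    ------
    ValueError
        If ``step_khz <= 0``, the range is inverted, or ``start-stop`` is not
        an integer multiple of ``step_khz``.
    """
    if step_khz <= 0:
        raise ValueError("step_khz must be > 0")
    if not (start_khz >= stop_khz > 0):
        raise ValueError("require start_khz >= stop_khz > 0")
    span = start_khz - stop_khz
    n_steps = span / step_khz
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"(start - stop) = {span} kHz is not divisible by step = {step_khz} kHz"
        )
    n = int(round(n_steps)) + 1
    entries = tuple(
        ScheduleEntry(
            frequency_khz=start_khz - i * step_khz,
            electrode="A" if i % 2 == 0 else "B",
            dwell_s=dwell_s,
        )
        for i in range(n)
    )
    return StimulusSchedule(
        entries=entries, amplitude_vpp=amplitude_vpp, frame_rate=frame_rate
    )
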