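"""End-to-end orchestration: simulate -> track -> segment -> PIV -> descriptors -> classify.

A single :class:`RunConfig` drives the whole chain with deterministic
seeding; every persisted artifact embeds a hash of the configuration so a
downstream stage can refuse inputs produced under a different one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import VideoStack
from .kinetics import LOCAL_DESCRIPTOR_NAMES, kinetics_from_fields, local_descriptors
from .learning import (
    CohortDataset,
    EvaluationReport,
    lopo_evaluate,
    majority_vote_curve,
)
from .piv import piv_series
from .scattering import scattering_config, wst_descriptors
from .schedule import build_stimulus_schedule
from .segmentation import segment_motion_area
from .synthetic import SyntheticCellParams, SyntheticCohortConfig, iter_cohort
from .tracking import extract_roi_stack, track_centroid, trim_to_window

__all__ = [
    "RunConfig",
    "extract_cell_features",
    "build_feature_table",
    "save_features",
    "load_features",
    "run_full",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters in one serializable object.

    The synthetic-cohort block defines the study conditions; the analysis
    block mirrors the acquisition defaults (151-px ROI, 10-px PIV windows,
    1,000-frame window, ApEn m=2 / r=0.2 sigma, filter thresholds 0.6 /
    0.75, SFS tolerance 1e-6 over 5 steps, 1,000 voting repetitions).
    """

    # cohort / simulation
    classes: tuple[str, ...] = ("CTRL", "RIF", "uRPL")
    patients_per_class: int = 6
    cells_per_patient: int = 30
    inter_patient_sd: float = 0.1
    noise_sd: float = 0.01
    canvas: tuple[int, int] = (200, 340)
    radius_um: float = 22.5
    oscillation_gain: float = 12.0
    deformation_amplitude: float = 0.8
    pixel_size_um: float = 0.45
    # schedule
    start_khz: float = 150.0
    stop_khz: float = 25.0
    step_khz: float = 5.0
    dwell_s: float = 1.9
    frame_rate: float = 20.0
    # analysis
    roi_side: int = 151
    piv_window: int = 10
    n_frames: int = 1000
    apen_m: int = 2
    apen_r_factor: float = 0.2
    th_centroid: float = 0.6
    th_local: float = 0.75
    sfs_tol: float = 1e-6
    sfs_window: int = 5
    sfs_max_steps: int = 30
    voting_reps: int = 1000
    # stage toggles
    classify: bool = True
    vote: bool = True
    seed: int = 0

    def cohort_config(self) -> SyntheticCohortConfig:
        return SyntheticCohortConfig(
            classes=self.classes,
            patients_per_class=self.patients_per_class,
            cells_per_patient=self.cells_per_patient,
            inter_patient_sd=self.inter_patient_sd,
            noise_sd=self.noise_sd,
            pixel_size_um=self.pixel_size_um,
            canvas=tuple(self.canvas),
            schedule=build_stimulus_schedule(
                self.start_khz,
                self.stop_khz,
                self.step_khz,
                self.dwell_s,
                frame_rate=self.frame_rate,
            ),
            base_params=SyntheticCellParams(
                radius_um=self.radius_um,
                oscillation_gain=self.oscillation_gain,
                deformation_amplitude=self.deformation_amplitude,
            ),
            master_seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classes"] = list(d["classes"])
        d["canvas"] = list(d["canvas"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "classes" in d:
            d["classes"] = tuple(d["classes"])
        if "canvas" in d:
            d["canvas"] = tuple(d["canvas"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def extract_cell_features(
    video: VideoStack, config: RunConfig
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """The full per-cell descriptor vector (scattering + 21 local) from one video."""
    h, w = video.shape
    traj = track_centroid(video, init_position=(w / 2.0, h / 2.0))
    n = min(config.n_frames, video.n_frames)
    video_t, traj_t = trim_to_window(video, traj, n)
    rois = extract_roi_stack(video_t, traj_t, side=config.roi_side)

    expected_r = config.radius_um / config.pixel_size_um
    masks = segment_motion_area(
        rois,
        r_min=max(4, int(0.5 * expected_r)),
        r_max=max(6, int(1.8 * expected_r)),
    )
    fields = piv_series(rois, mask=masks.bw_cell, final_window=config.piv_window)
    kin = kinetics_from_fields(fields, frame_rate=video.frame_rate)
    local_vals, local_names = local_descriptors(
        kin, m=config.apen_m, r_factor=config.apen_r_factor
    )

    cfg = scattering_config(fs=video.frame_rate, n_samples=n)
    rel = traj_t.xy - traj_t.xy[0]
    wst_vals, wst_names = wst_descriptors(rel[:, 0], rel[:, 1], cfg)

    names = wst_names + local_names
    values = np.concatenate([wst_vals, local_vals])
    families = {n_: "centroid" for n_ in wst_names}
    families.update({n_: "local" for n_ in local_names})
    return values, names, families


def build_feature_table(config: RunConfig) -> CohortDataset:
    """Simulate the cohort and extract every cell's descriptor vector."""
    cohort_cfg = config.cohort_config()
    records, labels, patients, videos, index = [], [], [], [], []
    names: list[str] | None = None
    families: dict[str, str] = {}
    for item in iter_cohort(
        cohort_cfg, roi_side=config.roi_side, piv_window=config.piv_window
    ):
        values, names, families = extract_cell_features(item.video, config)
        records.append(values)
        labels.append(item.class_label)
        patients.append(item.patient_id)
        videos.append(item.video_id)
        index.append(item.cell_id)
        logger.debug("features extracted for %s", item.cell_id)
    features = pd.DataFrame(records, index=index, columns=names)
    return CohortDataset(
        features=features,
        labels=pd.Series(labels, index=index),
        patients=pd.Series(patients, index=index),
        videos=pd.Series(videos, index=index),
        feature_families=families,
    )


def save_features(path: str | Path, dataset: CohortDataset, config: RunConfig) -> None:
    """Persist the feature table as CSV with a provenance JSON sidecar."""
    path = Path(path)
    df = dataset.features.copy()
    df.insert(0, "class", dataset.labels)
    df.insert(0, "video_id", dataset.videos)
    df.insert(0, "patient_id", dataset.patients)
    df.to_csv(path, index_label="cell_id")
    sidecar = {
        "config_hash": config.config_hash,
        "data_digest": hashlib.sha256(path.read_bytes()).hexdigest(),
        "config": config.to_dict(),
        "feature_families": dataset.feature_families,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_features(path: str | Path, config: RunConfig | None = None) -> CohortDataset:
    """Load a persisted feature table, refusing a config-hash mismatch."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if config is not None and sidecar["config_hash"] != config.config_hash:
        raise ValueError(
            "feature table was produced under a different configuration "
            f"(hash {sidecar['config_hash']} != {config.config_hash})"
        )
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != sidecar.get("data_digest", digest):
        raise ValueError("feature table content does not match its recorded hash")
    df = pd.read_csv(path, index_col="cell_id")
    meta_cols = ["patient_id", "video_id", "class"]
    return CohortDataset(
        features=df.drop(columns=meta_cols),
        labels=df["class"],
        patients=df["patient_id"],
        videos=df["video_id"],
        feature_families=sidecar["feature_families"],
    )


def run_full(
    config: RunConfig, out_dir: str | Path
) -> tuple[CohortDataset, EvaluationReport | None, pd.DataFrame | None]:
    """Execute the configured stages and persist every intermediate.

    Returns the feature table, the LOPO report (None when classification is
    disabled) and the majority-voting curve (None when voting is disabled).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = build_feature_table(config)
    save_features(out / "features.csv", dataset, config)
    if not config.classify:
        return dataset, None, None
    report = lopo_evaluate(
        dataset,
        th_centroid=config.th_centroid,
        th_local=config.th_local,
        tol=config.sfs_tol,
        window=config.sfs_window,
        max_steps=config.sfs_max_steps,
    )
    report_payload = {
        "config_hash": config.config_hash,
        "classes": report.classes,
        "balanced_accuracy_cell": report.balanced_accuracy_cell,
        "balanced_accuracy_experiment": report.balanced_accuracy_experiment,
        "confusion_cell": report.confusion_cell.tolist(),
        "confusion_experiment": report.confusion_experiment.tolist(),
        "selections": report.selections,
        "most_selected": report.most_selected,
    }
    report.predictions.to_csv(out / "predictions.csv", index_label="cell_id")
    curve = None
    if config.vote:
        max_cells = int(report.predictions.groupby("patient").size().min())
        curve = majority_vote_curve(
            report, max_cells=max_cells, n_rep=config.voting_reps, seed=config.seed
        )
        curve.to_csv(out / "voting_curve.csv", index=False)
        report_payload["voting_curve"] = curve.to_dict(orient="list")
    (out / "report.json").write_text(json.dumps(report_payload, indent=1))
    return dataset, report, curve
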