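"""Phase-series descriptors distinguish deformation behaviours.

Simulates one cell per class recipe and prints the kurtosis and
approximate entropy of its mean-cosine orientation series.  The control
recipe (deformations aligned with the electrode axis) is markedly
platykurtic; the entropy contrast driven by off-stimulus deformation
events is a population-level effect and is demonstrated on a full cohort
in example 05.
"""

import numpy as np

from odepkit import (
    SyntheticCellParams,
    extract_roi_stack,
    kinetics_from_fields,
    local_descriptors,
    piv_series,
    segment_motion_area,
    simulate_cell_video,
    track_centroid,
)
from odepkit.schedule import build_stimulus_schedule
from odepkit.synthetic import class_recipes

schedule = build_stimulus_schedule(dwell_s=0.8)  # 416-frame scaled-down run

print("class   K_theta   ApEn_theta")
for label, overrides in class_recipes().items():
    params = SyntheticCellParams(
        radius_um=9 * 0.45, oscillation_gain=10.0, texture_seed=7, **overrides
    )
    video, _ = simulate_cell_video(
        params, schedule, canvas=(96, 160), seed=7, roi_side=41
    )
    traj = track_centroid(video, init_position=(80, 48))
    rois = extract_roi_stack(video, traj, side=41)
    masks = segment_motion_area(rois, r_min=4, r_max=16)
    fields = piv_series(rois, mask=masks.bw_cell)
    values, names = local_descriptors(kinetics_from_fields(fields))
    d = dict(zip(names, values))
    print(f"{label:6s}  {d['kurt_dtheta']:.3f}     {d['apen_dtheta']:.3f}")
print(
    "\nLower kurtosis marks electrode-aligned (bimodal) deformation."
    "\nSingle cells vary; the entropy contrast between RIF and uRPL"
    "\nbecomes significant at cohort scale (see example 05)."
)
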