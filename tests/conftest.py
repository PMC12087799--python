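"""Shared fixtures: small textured images and the reference synthetic cohort.

The cohort fixture is the package's scaled-down study: 3 classes x 3
patients x 8 cells with 0.8 s clips (416 frames) and a 9 px cell in a
41 px ROI, under a fixed master seed.  It is built once per session and
shared by the evaluation-level tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from odepkit.learning import lopo_evaluate, majority_vote_curve
from odepkit.pipeline import RunConfig, build_feature_table


def make_speckle(shape=(64, 64), seed=0, smooth=1.2):
    """A smooth random texture suitable for PIV correlation."""
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal(shape), smooth)
    img -= img.min()
    img /= img.max()
    return img


@pytest.fixture(scope="session")
def speckle():
    return make_speckle()


@pytest.fixture(scope="session")
def cohort_config() -> RunConfig:
    return RunConfig(
        patients_per_class=3,
        cells_per_patient=8,
        canvas=(96, 160),
        radius_um=9 * 0.45,
        oscillation_gain=10.0,
        dwell_s=0.8,
        roi_side=41,
        n_frames=416,
        seed=7,
    )


@pytest.fixture(scope="session")
def cohort_dataset(cohort_config):
    return build_feature_table(cohort_config)


@pytest.fixture(scope="session")
def cohort_report(cohort_dataset):
    return lopo_evaluate(cohort_dataset)


@pytest.fixture(scope="session")
def cohort_voting_curve(cohort_report):
    return majority_vote_curve(cohort_report, max_cells=8, n_rep=300, seed=1)
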