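"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from socialgrid.grid import GridConsistency
from socialgrid.simulate import SimConfig, simulate_subject
from socialgrid.space import SocialSpace, sample_avatar_layout


@pytest.fixture(scope="session")
def space():
    return SocialSpace()


@pytest.fixture(scope="session")
def avatars(space):
    return sample_avatar_layout(space, rng_seed=11)


@pytest.fixture(scope="session")
def small_subject():
    """One cheap subject: 4 runs × 16 trials, 10 voxels, known orientation."""
    cfg = SimConfig(
        n_trials=16,
        n_grid_voxels=6,
        n_distance_voxels=2,
        n_noise_voxels=2,
        grid_orientation_deg=20.0,
        seed=7,
    )
    return simulate_subject(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """Twenty subjects at the study design (4 runs × 80 trials, 50 grid
    voxels) with leave-one-run-out consistency at the hexadirectional and
    control folds — computed once and shared by the acceptance tests."""
    folds = (4, 5, 6, 7, 8)
    subjects = []
    for s in range(20):
        sub = simulate_subject(SimConfig(seed=1000 + s))
        roi = np.where(sub.truth["voxel_kinds"] == "grid")[0]
        rec = {
            "phi_true_deg": sub.truth["phi_true_deg"],
            "contrasts": {},
            "orientations": {},
        }
        for f in folds:
            model = GridConsistency(f).fit(sub.runs, sub.trials, roi)
            rec["contrasts"][f] = model.contrast_
            if f == 6:
                rec["orientations"] = {
                    r: ori.phi_deg for r, ori in model.orientations_.items()
                }
        subjects.append(rec)
    return subjects
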