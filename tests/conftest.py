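"""Shared fixtures: small phantom cohorts analyzed once per session."""

import numpy as np
import pytest

from dtivba.gradients import default_scheme
from dtivba.mask import compute_brain_mask, compute_idwi
from dtivba.phantom import default_spec, generate_cohort
from dtivba.tensor import fit_tensors, scalar_maps

VOXEL_SIZE = (0.35, 0.35, 0.35)


def analyze_cohort(cohort):
    """Mask, fit and map every subject; returns (maps, masks, groups)."""
    maps, masks, groups = [], [], []
    for s in cohort.subjects:
        bm = compute_brain_mask(compute_idwi(s.dwi), s.dwi.voxel_size)
        tf = fit_tensors(s.dwi, bm)
        maps.append(scalar_maps(tf))
        masks.append(bm)
        groups.append(s.record.group)
    return maps, masks, groups


@pytest.fixture(scope="session")
def small_spec():
    return default_spec(grid_shape=(24, 24, 24))


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec, n_per_group=4, scheme=default_scheme(15), seed=7)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    return analyze_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
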