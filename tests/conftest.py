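"""Shared fixtures: synthetic datasets are generated once per session and
reused across modules, since the 300x300 persistence computation dominates
the suite's runtime."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from microholes.pipeline import patches_to_panel
from microholes.synthetic import (
    KO_LIKE,
    NULL_A,
    NULL_B,
    WT_LIKE,
    GroupParams,
    make_group_dataset,
)


@pytest.fixture(scope="session")
def ko_wt_data():
    """Full-scale contrast dataset: 50 test-like + 50 control-like patches."""
    patches, specs = make_group_dataset(KO_LIKE, WT_LIKE, n_patches=50, seed=42)
    panel, diagrams = patches_to_panel(patches, return_diagrams=True)
    return {"patches": patches, "specs": specs, "panel": panel, "diagrams": diagrams}


@pytest.fixture(scope="session")
def null_panel():
    """Two groups drawn from identical generator parameters (no signal)."""
    patches, _ = make_group_dataset(NULL_A, NULL_B, n_patches=50, seed=43)
    return patches_to_panel(patches)


SMALL_A = GroupParams(n_holes=6, radius_mean=6.0, radius_sd=1.2, min_gap=14.0, canvas=150)
SMALL_B = GroupParams(n_holes=12, radius_mean=3.0, radius_sd=0.8, min_gap=7.0, canvas=150)


@pytest.fixture(scope="session")
def small_contrast():
    """Fast 150x150 contrast dataset for unit-level classifier/suite tests."""
    patches, specs = make_group_dataset(SMALL_A, SMALL_B, n_patches=20, seed=7)
    panel, diagrams = patches_to_panel(patches, return_diagrams=True)
    return {"patches": patches, "specs": specs, "panel": panel, "diagrams": diagrams}


@pytest.fixture(scope="session")
def small_null_panel():
    patches, _ = make_group_dataset(SMALL_B, replace(SMALL_B), n_patches=20, seed=8)
    return patches_to_panel(patches)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
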