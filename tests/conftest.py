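"""Shared fixtures: synthetic plates and a recomputed baseline.

Profile-accuracy fixtures use hole-free plates (vignette, pixel noise and
agar specks retained): painted interior holes are literally agar-colored
and score high against the red pigment target once filled, an artifact of
the hole model rather than of the pipeline.  Masking tests generate their
own plates with holes and specks enabled.
"""

from __future__ import annotations

import numpy as np
import pytest

from patchpigment.profiling import BaselineDistribution, baseline_from_images
from patchpigment.synthetic import PlateSimParams, flat_profile, generate_plate

N_BASELINE_IMAGES = 12  # isolated wild-type replicates in the study design


@pytest.fixture(scope="session")
def baseline12() -> BaselineDistribution:
    """Baseline recomputed from 12 unpigmented synthetic plates."""
    images = [
        generate_plate(PlateSimParams(profile_fn=flat_profile(), hole_count=0, seed=100 + i))[0]
        for i in range(N_BASELINE_IMAGES)
    ]
    return baseline_from_images(images)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
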