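"""Shared fixtures: a small rendered cohort and a classifier trained on it.

Session-scoped so the expensive stages (rendering, forest training) run
once and are reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import neuromorph as nm


@pytest.fixture(scope="session")
def small_spec() -> nm.CohortSpec:
    """Default cohort conditions at the smallest supported image size."""
    return nm.default_cohort_spec(image_size=256, seed=0)


@pytest.fixture(scope="session")
def small_cohort(small_spec) -> list[nm.GroundTruthSample]:
    return list(nm.iter_samples(small_spec))


@pytest.fixture(scope="session")
def trained_model(small_cohort) -> nm.TrainedModel:
    return nm.train_classifier(
        [s.image for s in small_cohort],
        [s.truth_mask for s in small_cohort],
        n_trees=50,
        seed=0,
        max_pixels_per_class=2000,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
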