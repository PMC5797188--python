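"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from larvreg.config import PipelineConfig
from larvreg.deformable import DeformableConfig
from larvreg.model import Grid, VolumetricImage
from larvreg.phantom import generate_phantom, phantom_cohort
from larvreg.template import build_template


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_phantom():
    return generate_phantom(seed=41, deform_amplitude=6.0)


@pytest.fixture(scope="session")
def rigid_phantom():
    """Undeformed phantom (applied transform is the identity)."""
    return generate_phantom(seed=42, deform_amplitude=0.0)


def fast_deformable_config(**overrides) -> DeformableConfig:
    """Registration settings scaled down for the test budget."""
    base = dict(
        metric="global_random_NCC", levels=4, iterations_per_level=100,
        samples_per_iteration=1024, seed=7,
    )
    base.update(overrides)
    return DeformableConfig(**base)


def fast_pipeline_config(seed: int = 3) -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.global_.levels = 3
    cfg.deformable = fast_deformable_config(
        metric="masked_local_NCC", iterations_per_level=150, seed=seed
    )
    return cfg


@pytest.fixture(scope="session")
def template_cohort():
    return phantom_cohort(3, seed=100, deform_amplitude=(4.0, 8.0))


@pytest.fixture(scope="session")
def template_package(template_cohort):
    """A small but real population-based template (built once per session)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_template(
            [p.scan for p in template_cohort],
            [p.landmarks for p in template_cohort],
            fusion="median",
            cfg=fast_deformable_config(),
            linear_levels=3,
        )


@pytest.fixture()
def small_image():
    rng = np.random.default_rng(0)
    data = rng.integers(0, 255, size=(24, 20, 8), dtype=np.uint8)
    return VolumetricImage(data, spacing=(0.5, 0.5, 2.0), channel_label="NP")
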