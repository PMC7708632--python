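"""Shared fixtures: small synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from nucarch.simulate import NucleusSceneSpec, generate_nucleus_scene

SMALL = dict(grid_shape=(16, 64, 64), lobe_semiaxes_um=(0.7, 1.0, 1.0))


@pytest.fixture(scope="session")
def small_scene():
    """A compact noisy scene with known truth (sigma = half the mean gap)."""
    spec = NucleusSceneSpec(**SMALL, seed=11)
    channels, truth = generate_nucleus_scene(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene: emissions equal the class means exactly."""
    spec = NucleusSceneSpec(**SMALL, class_sigma=0.0, seed=5)
    channels, truth = generate_nucleus_scene(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def medium_scene():
    """One 128x128x32 scene at study conditions for accuracy checks."""
    spec = NucleusSceneSpec(grid_shape=(32, 128, 128), seed=7)
    channels, truth = generate_nucleus_scene(spec)
    return spec, channels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
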