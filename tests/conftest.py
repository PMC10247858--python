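"""Shared fixtures: small deterministic scenes and random pixel blobs."""

from __future__ import annotations

import numpy as np
import pytest

from mitomorph.benchmarks import desk_scene_params
from mitomorph.synthetic import generate_mito_scene


@pytest.fixture(scope="session")
def small_scene():
    """One 256×256 desk-scale scene with a balanced class mix."""
    return generate_mito_scene(desk_scene_params(seed=11))


@pytest.fixture(scope="session")
def noiseless_scene():
    """Zero-noise variant for exact ground-truth checks."""
    return generate_mito_scene(
        desk_scene_params(seed=12, noise_model={"gaussian_sd": 0.0, "poisson_scale": 0.0})
    )


def random_blob(rng: np.random.Generator, size: int = 12, p: float = 0.45) -> np.ndarray:
    """A random connected pixel blob inside a size×size window."""
    from skimage.measure import label

    while True:
        mask = rng.uniform(size=(size, size)) < p
        lab = label(mask, connectivity=2)
        if lab.max() == 0:
            continue
        counts = np.bincount(lab.ravel())[1:]
        keep = int(np.argmax(counts)) + 1
        blob = lab == keep
        if blob.sum() >= 2:
            return blob
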