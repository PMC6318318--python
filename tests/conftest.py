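"""Shared fixtures: small seeded scenes reused across test modules."""

import numpy as np
import pytest

from immunoquant.config import (FollicleConfig, FollicleSceneParams,
                                SceneParams, SegmentationConfig)
from immunoquant.synthetic import generate_foci_scene, generate_follicle_scene


@pytest.fixture(scope="session")
def foci_scene():
    """Default zero-noise co-culture scene: 50 B cells, 3 feeders, 2 dumbbells."""
    params = SceneParams(seed=7)
    return params, generate_foci_scene(params)


@pytest.fixture(scope="session")
def follicle_scene():
    """Default tissue scene: 200 GC + 300 FO cells, planted ratio 2.0."""
    params = FollicleSceneParams(seed=11)
    return params, generate_follicle_scene(params)


@pytest.fixture()
def seg_cfg():
    return SegmentationConfig()


@pytest.fixture()
def follicle_cfg():
    return FollicleConfig(typical_cell_area_px=100.0)


def random_blob(rng: np.random.Generator, shape=(64, 64), n_seeds=1,
                n_grow=40) -> np.ndarray:
    """A random 8-connected blob grown from seed pixels, for oracles."""
    mask = np.zeros(shape, dtype=bool)
    r = rng.integers(8, shape[0] - 8)
    c = rng.integers(8, shape[1] - 8)
    mask[r, c] = True
    frontier = [(r, c)]
    for _ in range(n_grow):
        r0, c0 = frontier[rng.integers(len(frontier))]
        dr, dc = rng.integers(-1, 2, size=2)
        r1, c1 = np.clip(r0 + dr, 0, shape[0] - 1), np.clip(c0 + dc, 0, shape[1] - 1)
        if not mask[r1, c1]:
            mask[r1, c1] = True
            frontier.append((int(r1), int(c1)))
    return mask
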