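"""Shared fixtures: rendered scenes and a small generated study."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from saucelife import imgen


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0


@pytest.fixture(scope="session")
def default_scene():
    """Default scene, seed 1: the canonical single-image fixture."""
    return imgen.render_pizza(imgen.SceneSpec(seed=1))


@pytest.fixture(scope="session")
def noiseless_scene():
    spec = dataclasses.replace(imgen.SceneSpec(seed=1), noise_sd=0.0)
    return imgen.render_pizza(spec)


@pytest.fixture(scope="session")
def small_study():
    """A reduced 12-sample study on small frames, for fast end-to-end tests."""
    scene = imgen.SceneSpec(width=192, height=192, seed=0)
    times = tuple(np.linspace(0.0, 200.0, 6))
    spec = dataclasses.replace(
        imgen.default_study_spec(seed=5),
        n_samples=12,
        sample_temperatures=(-12.0,) * 6 + (-18.0,) * 6,
        time_grid=times + times,
        scene=scene,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return imgen.generate_study(spec)
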