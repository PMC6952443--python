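"""Shared fixtures: small synthetic movies with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from astroca import synthetic as syn


@pytest.fixture(scope="session")
def small_movie():
    """64×64×120 movie with motion, drift, transients and noise."""
    params = syn.SyntheticMovieParams(height=64, width=64, n_frames=120,
                                      seed=17)
    movie, truth = syn.generate_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def still_movie():
    """Motion-free movie for baseline/segmentation tests."""
    params = syn.SyntheticMovieParams(height=64, width=64, n_frames=150,
                                      rigid_shift_amplitude=0.0,
                                      nonrigid_amplitude=0.0, seed=2)
    movie, truth = syn.generate_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def textured_frame():
    rng = np.random.default_rng(0)
    from scipy.ndimage import gaussian_filter
    return gaussian_filter(rng.standard_normal((64, 64)), 2.0)
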