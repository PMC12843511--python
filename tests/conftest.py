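"""Shared fixtures: small seeded synthetic datasets and geometric masks."""

import numpy as np
import pytest

from orgfate.synthetic_acquisition import (AcquisitionConfig, FateSpec,
                                           simulate_experiment, simulate_study)


@pytest.fixture(scope="session")
def small_cfg():
    """A fast 8-well, 12-loop, 96-px acquisition."""
    return AcquisitionConfig(n_experiments=2, wells_per_plate=8, duration_h=6,
                             interval_min=30, frame_px=96, seed=7,
                             exclusion_prob=0.0)


@pytest.fixture(scope="session")
def small_fate():
    return FateSpec(signal_strength=1.0, rpe_visible_loop=9, lens_visible_loop=8)


@pytest.fixture(scope="session")
def small_wells(small_cfg, small_fate):
    return simulate_experiment(small_cfg, small_fate)


@pytest.fixture(scope="session")
def small_study(small_cfg, small_fate):
    return simulate_study(small_cfg, small_fate)


@pytest.fixture()
def disc_mask():
    """Centred rasterised disc of radius 20 in a 64x64 frame."""
    yy, xx = np.mgrid[0:64, 0:64]
    return (yy - 32) ** 2 + (xx - 32) ** 2 <= 20 ** 2


def random_blob_mask(rng, size=24):
    """Small random single-component blob mask for oracle fixtures."""
    from scipy import ndimage

    while True:
        field = ndimage.gaussian_filter(rng.normal(size=(size, size)), 3.0)
        mask = field > np.percentile(field, 70)
        labels, n = ndimage.label(mask)
        if n >= 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       range(1, n + 1))
            mask = labels == 1 + int(np.argmax(sizes))
            if 10 < mask.sum() < size * size * 0.6:
                return mask
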