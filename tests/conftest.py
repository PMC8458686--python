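"""Shared fixtures: tiny synthetic scenes and helper factories."""

import numpy as np
import pytest

from brightnuc import synthetic_data as S


def tiny_scene_config(seed=0, **overrides):
    """A 64x64 low-density scene; small enough for fast CPU training."""
    kw = dict(height=64, width=64, n_nuclei=5, radius_mean_px=7,
              radius_sd_px=1.5, min_center_spacing_px=14,
              contrast=0.5, noise_sd=0.05, out_of_focus_fraction=0.0,
              seed=seed)
    kw.update(overrides)
    return S.SceneConfig(**kw)


def scene_pairs(n, seed=0, **overrides):
    """List of (brightfield 2-D image, binary mask) training pairs."""
    pairs = []
    for i in range(n):
        sc = S.make_scene(tiny_scene_config(seed=seed * 1000 + i, **overrides))
        pairs.append((sc.brightfield[..., 0],
                      (sc.gt > 0).astype(np.float32)))
    return pairs


@pytest.fixture(scope="session")
def eight_scenes():
    return scene_pairs(8, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_label_pair(rng, size=48, blobs=6):
    """A random pair of label maps for metric oracle comparisons."""
    from brightnuc.postprocessing import label_objects

    def one(r):
        mask = np.zeros((size, size), bool)
        for _ in range(blobs):
            cy, cx = r.integers(0, size, 2)
            rad = int(r.integers(2, 7))
            yy, xx = np.ogrid[:size, :size]
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad ** 2
        return label_objects(mask)

    return one(rng), one(rng)
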