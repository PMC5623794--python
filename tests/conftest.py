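"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import radiopos as rp


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_image(rng, shape=(10, 10), lo=0, hi=65535, bit_depth=16):
    pix = rng.integers(lo, hi + 1, size=shape)
    return rp.RadiographImage(pixels=pix, bit_depth=bit_depth)


def sweep_template(rows=60, cols=24, seed=2017):
    """Deterministic high-contrast binary localization test pattern.

    A two-level random pattern has variance comparable to its squared mean,
    so the energy-normalized matrix-product score of a misaligned window
    stays well below the aligned value of 1 — both score maps then peak
    exactly at the true offset for every exact crop.
    """
    rng = np.random.default_rng(seed)
    pix = np.where(rng.random((rows, cols)) < 0.5, 1000, 64000).astype(np.int64)
    return rp.RadiographImage(pixels=pix)


@pytest.fixture(scope="session")
def small_cfg():
    """Fast study conditions: small canvas, few images, coarse signature."""
    return rp.SynthConfig(
        seed=7, template_shape=(250, 100), n_per_position=3, n_library=2
    )


@pytest.fixture(scope="session")
def small_template(small_cfg):
    return rp.make_phantom(small_cfg)


@pytest.fixture(scope="session")
def small_dataset(small_template, small_cfg):
    records, samples = rp.make_dataset(small_template, small_cfg)
    return records, samples


@pytest.fixture(scope="session")
def small_library(small_dataset):
    records, samples = small_dataset
    groups = {p: [] for p in rp.POSITIONS}
    for rec, s in zip(records, samples):
        if rec.split == "library":
            groups[s.position].append(s.image)
    return rp.build_library(groups, fraction=0.1, n_bins=32)


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory, small_cfg, small_library):
    """The small study written to disk: atlas, regions, dataset, library."""
    out = tmp_path_factory.mktemp("study")
    rp.simulate(small_cfg, out)
    small_library.save(out / "library.json")
    return out
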