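"""Shared fixtures: synthetic nuclei are generated once per session."""

import numpy as np
import pytest

from nucland.classify import class_distribution, classify_voxels, fit_mixture
from nucland.model import VoxelGrid
from nucland.synth import MarkerDesign, default_phenotype, generate_nucleus

ANC_DESIGN = (2.5, 1.2, 0.4, -0.2, -0.6, -0.9, -1.0)
INC_DESIGN = (-0.9, -0.6, -0.3, 0.1, 0.4, 0.8, 1.2)


@pytest.fixture(scope="session")
def progenitor_nucleus():
    """(channels, truth) for a progenitor nucleus with ANC + INC markers."""
    channels, truth = generate_nucleus(
        default_phenotype("progenitor"),
        [MarkerDesign("anc", ANC_DESIGN), MarkerDesign("inc", INC_DESIGN)],
        seed=1,
    )
    return channels, truth


@pytest.fixture(scope="session")
def fitted_progenitor(progenitor_nucleus):
    """(params, classmap, distribution) of the progenitor DAPI channel."""
    channels, truth = progenitor_nucleus
    dapi = channels[0]
    params = fit_mixture(dapi.data[truth.mask.data], K=7)
    cmap = classify_voxels(dapi, truth.mask, params)
    return params, cmap, class_distribution(cmap)


@pytest.fixture(scope="session")
def small_granulocyte():
    channels, truth = generate_nucleus(
        default_phenotype("granulocyte"), seed=2, shape=(32, 96, 72)
    )
    return channels, truth


def make_ellipsoid_grid(shape=(40, 64, 64), semi=(15, 26, 26), value=1000.0,
                        background=40.0, noise_sd=5.0, seed=0,
                        voxel_size=(125.0, 39.5, 39.5)):
    """Solid bright ellipsoid on noisy background; returns (grid, truth_mask)."""
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    c = [(s - 1) / 2 for s in shape]
    ell = (((zz - c[0]) / semi[0]) ** 2 + ((yy - c[1]) / semi[1]) ** 2
           + ((xx - c[2]) / semi[2]) ** 2) <= 1.0
    img = np.where(ell, value, background) + rng.normal(0, noise_sd, shape)
    return VoxelGrid(np.clip(img, 0, None), voxel_size, "DAPI"), ell
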