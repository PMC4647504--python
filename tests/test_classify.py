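"""Density classification: EM fit, MAP/ICM labeling, class distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from nucland.classify import (
    ClassMap,
    MixtureParams,
    _log_component_densities,
    _neighbor_offsets,
    _shift,
    class_distribution,
    classify_voxels,
    fit_mixture,
    log_likelihood,
)
from nucland.model import NuclearMask, VoxelGrid


def full_mask(shape, voxel_size=(100.0, 50.0, 50.0)):
    m = np.zeros(shape, dtype=bool)
    m[1:-1, 1:-1, 1:-1] = True
    return NuclearMask(m, voxel_size)


class TestFitMixture:
    def test_three_component_recovery(self):
        rng = np.random.default_rng(11)
        true_mu, true_sd, true_pi = (100.0, 300.0, 500.0), 40.0, (0.5, 0.3, 0.2)
        n = 100_000
        x = np.concatenate([
            rng.normal(mu, true_sd, int(round(p * n))) for mu, p in zip(true_mu, true_pi)
        ])
        params = fit_mixture(x, K=3)
        assert np.allclose(params.weights, true_pi, atol=0.01)
        assert np.allclose(params.means, true_mu, rtol=0.02)
        assert params.shared_sd == pytest.approx(true_sd, rel=0.05)

    def test_fitted_likelihood_beats_truth(self):
        # independent oracle: mixture likelihood at the true parameters,
        # evaluated directly in probability space with scipy.stats.norm
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(100, 40, 5000), rng.normal(300, 40, 5000)])
        params = fit_mixture(x, K=2)
        dens = 0.5 * norm.pdf(x, 100, 40) + 0.5 * norm.pdf(x, 300, 40)
        ll_truth = float(np.log(dens).sum())
        assert params.log_likelihood >= ll_truth - 1e-6
        assert params.log_likelihood == pytest.approx(ll_truth, rel=1e-3)
        # and the params object reproduces its own reported likelihood
        assert log_likelihood(x, params) == pytest.approx(params.log_likelihood, rel=1e-9)

    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 7, 2000)
        params = fit_mixture(x, K=1)
        assert params.means[0] == pytest.approx(x.mean())
        assert params.shared_sd == pytest.approx(x.std())
        assert params.weights[0] == 1.0

    def test_degenerate_histogram_errors(self):
        with pytest.raises(ValueError, match="degenerate histogram"):
            fit_mixture(np.full(1000, 7.0), K=2)

    def test_too_few_voxels_errors(self):
        with pytest.raises(ValueError, match="at least"):
            fit_mixture(np.arange(10.0), K=3)

    def test_log_likelihood_monotone_within_phases(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 3000), rng.normal(5, 1, 3000),
                            rng.normal(10, 1, 3000)])
        params = fit_mixture(x, K=3)
        for trace in params.ll_traces:
            diffs = np.diff(trace)
            assert np.all(diffs >= -1e-9 * np.abs(trace[:-1]))

    def test_means_sorted_ascending(self):
        rng = np.random.default_rng(9)
        x = rng.gamma(2.0, 100.0, 20_000)
        params = fit_mixture(x, K=5)
        assert np.all(np.diff(params.means) >= 0)

    def test_progenitor_class1_mean_near_background(self, progenitor_nucleus, fitted_progenitor):
        _, truth = progenitor_nucleus
        params, _, _ = fitted_progenitor
        assert params.K == 7
        # class 1 must sit in the generator's background-intensity band
        assert abs(params.means[0] - truth.intensity_levels[0]) < 60
        assert params.means[0] < truth.intensity_levels[1] / 2


class TestClassifyVoxels:
    def brute_force_map(self, x, params):
        """Per-voxel posterior argmax computed in probability space."""
        labels = np.empty(x.size, dtype=np.int32)
        for i, xi in enumerate(x.ravel()):
            post = [w * norm.pdf(xi, mu, params.shared_sd)
                    for w, mu in zip(params.weights, params.means)]
            labels[i] = int(np.argmax(post)) + 1
        return labels

    def test_beta0_equals_bruteforce(self):
        rng = np.random.default_rng(21)
        shape = (10, 10, 10)
        mask = full_mask(shape)
        params = MixtureParams(3, [50.0, 150.0, 260.0], 40.0, [0.2, 0.5, 0.3])
        data = rng.uniform(0, 300, shape)
        grid = VoxelGrid(data, mask.voxel_size)
        cmap = classify_voxels(grid, mask, params)
        expected = self.brute_force_map(data[mask.data], params)
        assert np.array_equal(cmap.labels[mask.data], expected)

    def test_uniform_intensity_tie_breaks_low(self):
        shape = (6, 6, 6)
        mask = full_mask(shape)
        grid = VoxelGrid(np.full(shape, 100.0), mask.voxel_size)
        params = MixtureParams(2, [50.0, 150.0], 30.0, [0.5, 0.5])
        cmap = classify_voxels(grid, mask, params)
        assert np.all(cmap.labels[mask.data] == 1)

    def test_salt_noise_voxel_absorbed_by_icm(self):
        # hand evaluation: center voxel value 100 in a value-500 region,
        # K=3, mu=(100,300,500), sd=50, uniform pi.
        # beta=0: data term prefers class 1 by (500-100)^2/(2*50^2) = 32.
        # beta=2: relabeling to 3 saves 2*26 = 52 > 32 -> class 3.
        shape = (7, 7, 7)
        mask = full_mask(shape)
        data = np.full(shape, 500.0)
        data[3, 3, 3] = 100.0
        grid = VoxelGrid(data, mask.voxel_size)
        p0 = MixtureParams(3, [100.0, 300.0, 500.0], 50.0, [1 / 3, 1 / 3, 1 / 3], beta=0.0)
        cmap0 = classify_voxels(grid, mask, p0)
        assert cmap0.labels[3, 3, 3] == 1
        p2 = MixtureParams(3, [100.0, 300.0, 500.0], 50.0, [1 / 3, 1 / 3, 1 / 3], beta=2.0)
        cmap2 = classify_voxels(grid, mask, p2)
        assert cmap2.labels[3, 3, 3] == 3
        assert np.all(cmap2.labels[mask.data] == 3)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        shape = (8, 8, 8)
        mask = full_mask(shape)
        data = rng.uniform(10, 500, shape)
        params = MixtureParams(3, [50.0, 200.0, 400.0], 60.0, [0.3, 0.4, 0.3])
        a, b = 3.5, 120.0
        scaled = MixtureParams(3, a * params.means + b, a * params.shared_sd, params.weights)
        c1 = classify_voxels(VoxelGrid(data, mask.voxel_size), mask, params)
        c2 = classify_voxels(VoxelGrid(a * data + b, mask.voxel_size), mask, scaled)
        assert np.array_equal(c1.labels, c2.labels)

    def test_icm_output_is_fixed_point(self):
        rng = np.random.default_rng(13)
        shape = (9, 9, 9)
        mask = full_mask(shape)
        data = rng.choice([100.0, 500.0], size=shape, p=[0.3, 0.7])
        grid = VoxelGrid(data, mask.voxel_size)
        params = MixtureParams(2, [100.0, 500.0], 80.0, [0.5, 0.5], beta=1.5)
        cmap = classify_voxels(grid, mask, params)
        # one more synchronous sweep using the module's own energy terms
        m = mask.data
        logpost = (_log_component_densities(data[m].astype(float), params.means,
                                            params.shared_sd)
                   + np.log(params.weights)[None, :])
        full_logpost = np.full(m.shape + (2,), -np.inf)
        full_logpost[m] = logpost
        offsets = _neighbor_offsets(params.neighborhood)
        n_neighbors = np.zeros(m.shape, dtype=np.int32)
        for off in offsets:
            n_neighbors += _shift(m.astype(np.int32), off)
        same = np.zeros(m.shape + (2,), dtype=np.int32)
        for off in offsets:
            shifted = _shift(cmap.labels, off)
            for c in (1, 2):
                same[..., c - 1] += shifted == c
        energy = -full_logpost + params.beta * (n_neighbors[..., None] - same)
        resweep = np.argmin(energy[m], axis=1).astype(np.int32) + 1
        assert np.array_equal(resweep, cmap.labels[m])

    def test_shape_mismatch_errors(self):
        mask = full_mask((6, 6, 6))
        grid = VoxelGrid(np.zeros((5, 6, 6)), mask.voxel_size)
        params = MixtureParams(2, [0.0, 1.0], 1.0, [0.5, 0.5])
        with pytest.raises(ValueError, match="mismatch"):
            classify_voxels(grid, mask, params)


class TestClassDistribution:
    def test_simple_counting(self):
        params = MixtureParams(2, [0.0, 1.0], 1.0, [0.5, 0.5])
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels.ravel()[:10] = 1
        labels.ravel()[10:40] = 2
        dist = class_distribution(ClassMap(labels, params))
        assert np.allclose(dist.fractions, [0.25, 0.75])
        assert dist.n_voxels == 40

    @given(counts=st.lists(st.integers(0, 500), min_size=2, max_size=7).filter(lambda c: sum(c) > 0))
    @settings(max_examples=50, deadline=None)
    def test_fractions_always_sum_to_one(self, counts):
        K = len(counts)
        params = MixtureParams(K, np.arange(K, dtype=float), 1.0, np.full(K, 1.0 / K))
        labels = np.repeat(np.arange(1, K + 1), counts)
        pad = np.zeros(max(0, 8 - labels.size % 8), dtype=labels.dtype)
        labels = np.concatenate([labels, pad]).reshape(1, 1, -1)
        dist = class_distribution(ClassMap(labels, params))
        assert dist.fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(dist.fractions >= 0)

    def test_synthetic_class_volume_recovery(self, progenitor_nucleus, fitted_progenitor):
        _, truth = progenitor_nucleus
        _, _, dist = fitted_progenitor
        assert np.all(np.abs(dist.fractions - truth.class_volumes) <= 0.03)

    def test_phenotype_contrast(self, fitted_progenitor, small_granulocyte):
        channels, truth = small_granulocyte
        params = fit_mixture(channels[0].data[truth.mask.data], K=7)
        cmap = classify_voxels(channels[0], truth.mask, params)
        gran = class_distribution(cmap)
        _, _, prog = fitted_progenitor
        assert gran.fractions[4:].sum() > prog.fractions[4:].sum()
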