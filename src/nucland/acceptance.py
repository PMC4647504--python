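"""Acceptance-check computations.

Each function recomputes one headline quantity from scratch by running the
package against synthetic ground truth or an independent oracle (brute-force
enumeration, closed-form geometry, exhaustive search). They are shared by
the acceptance test suite and the standalone report script.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from .classify import MixtureParams, class_distribution, classify_voxels, fit_mixture
from .enrichment import enrichment_profile, threshold_marker
from .interface import interface_length
from .model import NuclearMask, SectionImage, VoxelGrid
from .radial import (
    border_distance_map,
    compare_radial_profiles,
    signal_radial_profile,
    weighted_mean_relative_distance,
)
from .spots import find_spots
from .stats import rank_sum_test
from .synth import (
    MarkerDesign,
    default_phenotype,
    generate_nucleus,
    generate_radial_fixture,
    generate_spot_channel,
    generate_tem_section,
)


def mixture_recovery(seed: int) -> dict:
    """EM recovery of a 3-component mixture (mu 100/300/500, sd 40, pi .5/.3/.2)."""
    rng = np.random.default_rng(seed)
    true_mu = np.array([100.0, 300.0, 500.0])
    true_pi = np.array([0.5, 0.3, 0.2])
    n = 100_000
    x = np.concatenate([
        rng.normal(mu, 40.0, int(round(p * n))) for mu, p in zip(true_mu, true_pi)
    ])
    params = fit_mixture(x, K=3)
    return {
        "max_pi_abs_err": float(np.max(np.abs(params.weights - true_pi))),
        "max_mu_rel_err": float(np.max(np.abs(params.means - true_mu) / true_mu)),
        "sd_rel_err": float(abs(params.shared_sd - 40.0) / 40.0),
        "n": n,
    }


def classification_oracle(seed: int, n_fixtures: int = 100, size: int = 16) -> dict:
    """beta=0 MAP labels vs exhaustive per-voxel posterior argmax (exact)."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    voxels = 0
    for _ in range(n_fixtures):
        K = int(rng.integers(2, 8))
        means = np.sort(rng.uniform(0, 1000, K))
        sd = float(rng.uniform(20, 120))
        w = rng.dirichlet(np.ones(K))
        params = MixtureParams(K, means, sd, w)
        shape = (size, size, size)
        m = np.zeros(shape, dtype=bool)
        m[1:-1, 1:-1, 1:-1] = True
        mask = NuclearMask(m, (100.0, 50.0, 50.0))
        data = rng.uniform(0, 1000, shape)
        cmap = classify_voxels(VoxelGrid(data, mask.voxel_size), mask, params)
        # independent oracle: probability-space argmax, voxel by voxel
        x = data[m]
        got = cmap.labels[m]
        norm = 1.0 / (sd * math.sqrt(2.0 * math.pi))
        for xi, gi in zip(x, got):
            best_c, best_p = 0, -1.0
            for c in range(K):
                p = w[c] * norm * math.exp(-0.5 * ((xi - means[c]) / sd) ** 2)
                if p > best_p:
                    best_p, best_c = p, c
            voxels += 1
            if best_c + 1 != gi:
                mismatches += 1
    return {"n_mismatches": mismatches, "n_voxels": voxels, "n_fixtures": n_fixtures}


def enrichment_identity(seed: int, n_profiles: int = 200) -> dict:
    """sum_c D_c E_c == 0 on random profiles; marker == DAPI gives E == 0."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_profiles):
        K = int(rng.integers(2, 8))
        sizes = rng.integers(1, 400, K)
        labels = np.repeat(np.arange(1, K + 1), sizes)
        labels = np.concatenate([labels, [0, 0]]).reshape(1, 1, -1)
        params = MixtureParams(K, np.arange(K, dtype=float), 1.0, np.full(K, 1.0 / K))
        from .classify import ClassMap

        cmap = ClassMap(labels.astype(np.int32), params)
        positive = np.zeros_like(labels, dtype=bool)
        flat = positive.reshape(-1)
        n_inside = int(sizes.sum())
        k = int(rng.integers(1, n_inside + 1))
        flat[rng.choice(n_inside, size=k, replace=False)] = True
        prof = enrichment_profile(positive, cmap)
        defined = ~np.isnan(prof.E)
        worst = max(worst, abs(float(np.dot(prof.D[defined], prof.E[defined]))))
    # marker == DAPI
    sizes = np.array([40, 60, 100])
    labels = np.repeat(np.arange(1, 4), sizes).reshape(1, 1, -1)
    params = MixtureParams(3, np.arange(3.0), 1.0, np.full(3, 1 / 3))
    from .classify import ClassMap

    cmap = ClassMap(labels.astype(np.int32), params)
    prof = enrichment_profile(labels > 0, cmap)
    worst_identity_E = float(np.max(np.abs(prof.E)))
    return {"max_weighted_sum": worst, "max_E_marker_eq_dapi": worst_identity_E,
            "n_profiles": n_profiles}


def enrichment_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Mean absolute error of recovered per-class enrichment vs design."""
    rng = np.random.default_rng(seed)
    designs = [
        (2.5, 1.2, 0.4, -0.2, -0.6, -0.9, -1.0),   # ANC-skewed
        (-0.9, -0.6, -0.3, 0.1, 0.4, 0.8, 1.2),    # INC-skewed
        (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),       # flat
    ]
    maes = []
    n_voxels = 0
    for i in range(n_seeds):
        design = designs[i % len(designs)]
        s = int(rng.integers(0, 2**31))
        channels, truth = generate_nucleus(
            default_phenotype("progenitor"), [MarkerDesign("m", design)], seed=s
        )
        n_voxels = truth.mask.n_voxels
        dapi = channels[0]
        params = fit_mixture(dapi.data[truth.mask.data], K=7)
        cmap = classify_voxels(dapi, truth.mask, params)
        positive = threshold_marker(channels[1], truth.mask)
        prof = enrichment_profile(positive, cmap)
        e_true = truth.marker_enrichment["m"]
        maes.append(float(np.nanmean(np.abs(prof.E - e_true))))
    return {"mean_mae": float(np.mean(maes)), "max_mae": float(np.max(maes)),
            "n_seeds": n_seeds, "n_masked_voxels": n_voxels}


def phenotype_ordering(seed: int, n_seeds: int = 20,
                       shape: tuple = (32, 80, 80)) -> dict:
    """Granulocyte > monocyte > progenitor in classes 5-7 mass, per seed."""
    rng = np.random.default_rng(seed)
    correct = 0
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31))
        masses = {}
        for name in ("progenitor", "monocyte", "granulocyte"):
            chs, truth = generate_nucleus(default_phenotype(name), seed=s, shape=shape)
            params = fit_mixture(chs[0].data[truth.mask.data], K=7)
            dist = class_distribution(classify_voxels(chs[0], truth.mask, params))
            masses[name] = dist.fractions[4:].sum()
        if masses["granulocyte"] > masses["monocyte"] > masses["progenitor"]:
            correct += 1
    return {"n_correct": correct, "n_seeds": n_seeds}


def interface_analytics(seed: int, n_seeds: int = 20) -> dict:
    """Disk-with-hole vs 2*pi*r and many-holes > single-lacuna ordering."""
    size, R, r, px = 512, 150.0, 50.0, 10.0
    yy, xx = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float),
                         indexing="ij")
    c = size / 2.0
    nucleus = (yy - c) ** 2 + (xx - c) ** 2 <= R**2
    hole = (yy - c) ** 2 + (xx - c) ** 2 <= r**2
    img = np.where(nucleus & ~hole, 200.0, 30.0)
    m = interface_length(SectionImage(img, px), nucleus, 100.0)
    rel_err = abs(m.interface_length - 2 * np.pi * r * px) / (2 * np.pi * r * px)
    rng = np.random.default_rng(seed)
    ordered = 0
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31))
        sec_m, tru_m = generate_tem_section("many-small-holes", seed=s)
        sec_s, tru_s = generate_tem_section("single-lacuna", seed=s)
        im = interface_length(sec_m, tru_m["nuclear_mask"])
        js = interface_length(sec_s, tru_s["nuclear_mask"])
        if im.normalized_interface > js.normalized_interface:
            ordered += 1
    return {"disk_hole_rel_err": float(rel_err), "n_ordered": ordered,
            "n_seeds": n_seeds}


def distance_oracle(seed: int, n_masks: int = 50, size: int = 20) -> dict:
    """EDT vs exhaustive all-pairs border distance on random masks."""
    rng = np.random.default_rng(seed)
    voxel_size = (2.0, 1.0, 1.0)
    vs = np.array(voxel_size)
    diag = float(np.linalg.norm(vs))
    worst = 0.0
    checked = 0
    while checked < n_masks:
        field = ndi.gaussian_filter(rng.normal(size=(size,) * 3), 2.5)
        m = field > np.quantile(field, rng.uniform(0.5, 0.8))
        m[0] = m[-1] = False
        m[:, 0] = m[:, -1] = False
        m[:, :, 0] = m[:, :, -1] = False
        labels, n = ndi.label(m, structure=np.ones((3, 3, 3), bool))
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        m = labels == counts.argmax()
        mask = NuclearMask(m, voxel_size)
        dmap = border_distance_map(mask)
        inside = np.argwhere(m) * vs
        outside = np.argwhere(~m) * vs
        brute = cdist(inside, outside).min(axis=1)
        worst = max(worst, float(np.max(np.abs(dmap[m] - brute))))
        checked += 1
    return {"max_abs_dev": worst, "voxel_diagonal": diag, "n_masks": n_masks}


def radial_profile_checks(seed: int, n_replicates: int = 100,
                          n_nuclei: int = 20) -> dict:
    """Shell-volume law on a uniform ball + two-channel separation power."""
    # shell law
    shape = (101, 101, 101)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    ball = ((zz - 50) ** 2 + (yy - 50) ** 2 + (xx - 50) ** 2) <= 48.0**2
    mask = NuclearMask(ball, (1.0, 1.0, 1.0))
    prof = signal_radial_profile(VoxelGrid(np.ones(shape), mask.voxel_size), mask,
                                 n_bins=10)
    t = prof.bin_edges
    expected = (1 - t[:-1]) ** 3 - (1 - t[1:]) ** 3
    shell_err = float(np.max(np.abs(prof.weights - expected)))

    # separation power: designed means 0.3 vs 0.7, 20 nuclei per replicate
    channels, fmask, _ = generate_radial_fixture(channel_means=(0.3, 0.7),
                                                 spread=0.1, seed=seed, poisson=False)
    dmap = border_distance_map(fmask)
    rel = dmap[fmask.data] / dmap.max()
    base = [ch.data[fmask.data].astype(np.float64) for ch in channels]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        means_a, means_b = [], []
        for _n in range(n_nuclei):
            wa = rng.poisson(base[0]).astype(float)
            wb = rng.poisson(base[1]).astype(float)
            means_a.append(float((wa * rel).sum() / wa.sum()))
            means_b.append(float((wb * rel).sum() / wb.sum()))
        if compare_radial_profiles(means_a, means_b).p_value < 0.005:
            hits += 1
    return {"max_shell_bin_err": shell_err, "n_detected": hits,
            "n_replicates": n_replicates}


def spot_counting(seed: int) -> dict:
    """Exact recovery of 50 separated spots + offset monotonicity sweep."""
    rng = np.random.default_rng(seed)
    shape = (40, 96, 96)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    ell = (((zz - 20) / 17) ** 2 + ((yy - 48) / 44) ** 2 + ((xx - 48) / 44) ** 2) <= 1
    mask = NuclearMask(ell, (125.0, 39.5, 39.5))
    channel, _pos = generate_spot_channel(
        mask, 50, sigma_nm=80.0, peak=1000.0, background=100.0,
        min_separation_nm=500.0, seed=int(rng.integers(0, 2**31)),
    )
    n_found = len(find_spots(channel, mask, offset=500.0))
    counts = [len(find_spots(channel, mask, offset=o))
              for o in np.linspace(150.0, 1150.0, 10)]
    monotone = all(a >= b for a, b in zip(counts, counts[1:]))
    return {"n_found": n_found, "n_expected": 50, "offset_sweep_monotone": monotone}


def rank_test_agreement(max_size: int = 5) -> dict:
    """Continuity-corrected asymptotic p vs exact enumeration, 3 <= m,n <= 5.

    Sizes below 3 are outside the operations' stated domain (every rank test
    in the pipeline requires >= 3 nuclei per group).
    """
    worst = 0.0
    n_cases = 0
    for m in range(3, max_size + 1):
        for n in range(3, max_size + 1):
            N = m + n
            ranks = np.arange(1, N + 1)
            sums = np.array([sum(c) for c in combinations(ranks, m)])
            for c in combinations(ranks, m):
                x = np.array(c, dtype=float)
                y = np.array(sorted(set(ranks) - set(c)), dtype=float)
                W = x.sum()
                lo = float((sums <= W).mean())
                hi = float((sums >= W).mean())
                p_exact = min(1.0, 2.0 * min(lo, hi))
                p_asym = rank_sum_test(x, y).p_value
                worst = max(worst, abs(p_exact - p_asym))
                n_cases += 1
    return {"max_abs_p_diff": worst, "n_cases": n_cases}
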