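"""Synthetic nuclei, TEM-like sections and radial fixtures with ground truth.

The generator emits multi-channel 3D stacks that emulate the chromatin
landscapes of myelopoietic phenotypes — a progenitor-like network of
chromatin domain cluster (CDC) cores permeated by interchromatin channels,
through to a granulocyte-like peripheral high-density shell around a central
low-intensity lacuna — together with the exact ground truth (mask, class
labels, class volumes, marker voxel sets, designed enrichment) needed to
bound every downstream pipeline error.

DAPI construction: a continuous structural field (clustered smoothed blobs,
an optional peripheral shell term and a central lacuna term) is rank-remapped
so that the noiseless class-volume vector matches the target exactly (to one
voxel); each class is then written at a fixed intensity level, PSF-blurred
and degraded with Poisson + Gaussian read noise, quantized to 16 bit.
Everything is deterministic for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .classify import MixtureParams
from .model import NuclearMask, SectionImage, VoxelGrid
from .interface import InterfaceMeasure

__all__ = [
    "PhenotypeSpec",
    "MarkerDesign",
    "NoiseModel",
    "SyntheticTruth",
    "default_phenotype",
    "generate_nucleus",
    "generate_spot_channel",
    "generate_tem_section",
    "generate_radial_fixture",
]

PHENOTYPES = ("progenitor", "precursor", "monocyte", "granulocyte")


@dataclass
class PhenotypeSpec:
    """Morphology controls and target class-volume vector for one nucleus."""

    phenotype: str
    target_class_volumes: tuple
    n_lobes: int = 1
    cdc_count: int = 60
    cdc_radius_nm: float = 300.0
    cdc_clustering: float = 0.0
    peripheral_shell_fraction: float = 0.0
    ic_lacuna_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        v = np.asarray(self.target_class_volumes, dtype=np.float64)
        if np.any(v < 0) or np.any(v > 1) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("target_class_volumes must be fractions summing to 1")
        for name in ("cdc_clustering", "peripheral_shell_fraction", "ic_lacuna_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_lobes < 1:
            raise ValueError("n_lobes must be >= 1")
        if self.phenotype == "granulocyte" and self.n_lobes < 2:
            raise ValueError("granulocyte phenotype requires n_lobes > 1")
        self.target_class_volumes = tuple(float(x) for x in v)

    @property
    def K(self) -> int:
        return len(self.target_class_volumes)


def default_phenotype(name: str, K: int = 7) -> PhenotypeSpec:
    """Built-in phenotype presets (K = 7 only).

    The class-volume targets encode the qualitative differentiation shift:
    high-class (5-7) mass grows progenitor < precursor < monocyte <
    granulocyte while the class-1 fraction stays comparable.
    """
    if K != 7:
        raise ValueError("presets are defined for K = 7")
    presets = {
        "progenitor": PhenotypeSpec(
            "progenitor", (0.16, 0.18, 0.17, 0.16, 0.13, 0.11, 0.09),
            cdc_count=70, cdc_clustering=0.2, ic_lacuna_fraction=0.02,
        ),
        "precursor": PhenotypeSpec(
            "precursor", (0.16, 0.16, 0.15, 0.15, 0.14, 0.13, 0.11),
            cdc_count=60, cdc_clustering=0.4, ic_lacuna_fraction=0.03,
        ),
        "monocyte": PhenotypeSpec(
            "monocyte", (0.15, 0.13, 0.13, 0.15, 0.15, 0.15, 0.14),
            cdc_count=40, cdc_clustering=0.7, peripheral_shell_fraction=0.25,
            ic_lacuna_fraction=0.08,
        ),
        "granulocyte": PhenotypeSpec(
            "granulocyte", (0.15, 0.08, 0.08, 0.12, 0.17, 0.20, 0.20),
            n_lobes=2, cdc_count=25, peripheral_shell_fraction=0.8,
            ic_lacuna_fraction=0.2,
        ),
    }
    try:
        return presets[name]
    except KeyError:
        raise ValueError(f"unknown phenotype {name!r}") from None


@dataclass
class MarkerDesign:
    """A marker channel defined by its per-class enrichment target.

    ``enrichment[c-1]`` is the designed E_c relative to the realized DAPI
    class volumes; the implied marker fractions ``M_c = D_c (1 + E_c)`` are
    renormalized if the design is not exactly consistent.
    """

    name: str
    enrichment: tuple
    fraction_positive: float = 0.03
    amplitude: float = 3000.0
    background: float = 30.0

    def __post_init__(self) -> None:
        e = np.asarray(self.enrichment, dtype=np.float64)
        if np.any(e < -1.0):
            raise ValueError("enrichment values must be >= -1")
        if not 0 < self.fraction_positive < 1:
            raise ValueError("fraction_positive must be in (0, 1)")
        self.enrichment = tuple(float(x) for x in e)


@dataclass
class NoiseModel:
    """Fluorescence camera model: PSF blur, shot noise, read noise."""

    psf_sigma_nm: float = 10.0
    read_noise_sd: float = 3.0
    poisson: bool = True


@dataclass
class SyntheticTruth:
    """Ground truth written by the generator before noise."""

    mask: NuclearMask
    class_labels: np.ndarray
    class_volumes: np.ndarray
    intensity_levels: np.ndarray
    background: float
    marker_positive: dict = field(default_factory=dict)
    marker_enrichment: dict = field(default_factory=dict)
    spot_positions: np.ndarray | None = None
    radial_means: dict = field(default_factory=dict)
    seed: int = 0

    def summary(self) -> dict:
        out = {
            "seed": self.seed,
            "n_voxels": self.mask.n_voxels,
            "class_volumes": [float(x) for x in self.class_volumes],
            "intensity_levels": [float(x) for x in self.intensity_levels],
            "background": self.background,
            "marker_enrichment": {k: [float(x) for x in v] for k, v in self.marker_enrichment.items()},
            "radial_means": {k: float(v) for k, v in self.radial_means.items()},
        }
        if self.spot_positions is not None:
            out["n_spots"] = int(len(self.spot_positions))
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


# ---------------------------------------------------------------------------
# helpers


def _largest_cc(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _lobed_mask(shape, voxel_size, n_lobes: int, rng) -> np.ndarray:
    """One 26-connected nucleus of ``n_lobes`` ellipsoids joined by bridges."""
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")
    margin = 3
    if n_lobes == 1:
        center = np.array([s / 2.0 for s in shape])
        semi = np.array([shape[0] / 2.0 - margin, shape[1] / 2.0 - margin, shape[2] / 2.0 - margin]) * 0.92
        mask = (
            ((zz - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((xx - center[2]) / semi[2]) ** 2
        ) <= 1.0
        return mask
    mask = np.zeros(shape, dtype=bool)
    semi = np.array(
        [shape[0] / 2.0 - margin, shape[1] / (2.0 * n_lobes) - margin / 2.0, shape[2] / 2.0 - margin]
    ) * 0.92
    centers = []
    for i in range(n_lobes):
        cy = (2 * i + 1) * shape[1] / (2.0 * n_lobes)
        center = np.array([shape[0] / 2.0, cy, shape[2] / 2.0])
        centers.append(center)
        mask |= (
            ((zz - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((xx - center[2]) / semi[2]) ** 2
        ) <= 1.0
    # bridges: thin cylinders between consecutive lobe centers
    r_bridge = max(2.0, 0.25 * min(semi))
    for a, b in zip(centers[:-1], centers[1:]):
        ab = b - a
        t = np.clip(
            ((zz - a[0]) * ab[0] + (yy - a[1]) * ab[1] + (xx - a[2]) * ab[2]) / (ab @ ab), 0, 1
        )
        dz = zz - (a[0] + t * ab[0])
        dy = yy - (a[1] + t * ab[1])
        dx = xx - (a[2] + t * ab[2])
        mask |= (dz * dz + dy * dy + dx * dx) <= r_bridge**2
    return _largest_cc(mask)


def _rank_remap(field_vals: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Assign classes 1..K to values by rank so class volumes match v exactly."""
    n = field_vals.size
    order = np.argsort(field_vals, kind="stable")
    bounds = np.round(np.cumsum(v) * n).astype(int)
    bounds[-1] = n
    labels = np.empty(n, dtype=np.int32)
    start = 0
    for c, stop in enumerate(bounds, start=1):
        labels[order[start:stop]] = c
        start = stop
    return labels


def _apply_noise(img: np.ndarray, noise: NoiseModel, voxel_size, rng) -> np.ndarray:
    out = img.astype(np.float64)
    if noise.psf_sigma_nm > 0:
        sig = [noise.psf_sigma_nm / v for v in voxel_size]
        out = ndi.gaussian_filter(out, sigma=sig)
    if noise.poisson:
        out = rng.poisson(np.maximum(out, 0)).astype(np.float64)
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, size=out.shape)
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# main generators


def generate_nucleus(
    spec: PhenotypeSpec,
    markers: list[MarkerDesign] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = (40, 96, 96),
    voxel_size: tuple[float, float, float] = (125.0, 39.5, 39.5),
    background: float = 40.0,
    level_base: float = 60.0,
    level_spacing: float = 380.0,
) -> tuple[list[VoxelGrid], SyntheticTruth]:
    """Generate one multi-channel nucleus with exact ground truth.

    Returns the DAPI channel followed by one channel per marker design, and
    the :class:`SyntheticTruth` (written before noise). Class ``c`` voxels of
    the noiseless DAPI carry intensity ``level_base + (c-1) * level_spacing``
    and the outside carries ``background``, so class 1 sits just above the
    background band.
    """
    markers = markers or []
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    K = spec.K
    v = np.asarray(spec.target_class_volumes)
    if spec.ic_lacuna_fraction > 0 and spec.ic_lacuna_fraction > v[: max(1, K // 2)].sum() + 1e-9:
        raise ValueError(
            "inconsistent spec: ic_lacuna_fraction exceeds the low-class volume budget"
        )

    mask_arr = _lobed_mask(shape, voxel_size, spec.n_lobes, rng)
    mask = NuclearMask(mask_arr, voxel_size, nucleus_id=seed)
    midx = np.flatnonzero(mask_arr.ravel())
    n = midx.size

    depth = ndi.distance_transform_edt(mask_arr, sampling=voxel_size)
    rel_depth = depth / depth.max()

    # CDC blob field, optionally clustered
    n_seeds = max(1, spec.cdc_count // 8)
    seed_centers = rng.choice(midx, size=n_seeds, replace=False)
    impulses = np.zeros(shape, dtype=np.float64)
    coords = np.array(np.unravel_index(midx, shape)).T
    seed_coords = np.array(np.unravel_index(seed_centers, shape)).T
    for _ in range(spec.cdc_count):
        if rng.random() < spec.cdc_clustering:
            base = seed_coords[rng.integers(n_seeds)]
            c = np.round(base + rng.normal(0, 3.0, size=3)).astype(int)
            c = np.clip(c, 0, np.array(shape) - 1)
            if not mask_arr[tuple(c)]:
                c = coords[rng.integers(n)]
        else:
            c = coords[rng.integers(n)]
        impulses[tuple(c)] += rng.uniform(0.5, 1.5)
    sigma_blob = [spec.cdc_radius_nm / vs for vs in voxel_size]
    blobs = ndi.gaussian_filter(impulses, sigma=sigma_blob)

    def _z(a):
        vals = a[mask_arr]
        sd = vals.std()
        return (a - vals.mean()) / (sd if sd > 0 else 1.0)

    s_field = (1.0 - spec.peripheral_shell_fraction) * _z(blobs)
    if spec.peripheral_shell_fraction > 0:
        shell = np.exp(-rel_depth / 0.15)
        s_field = s_field + spec.peripheral_shell_fraction * _z(shell)
    if spec.ic_lacuna_fraction > 0:
        t_thr = np.quantile(rel_depth[mask_arr], 1.0 - spec.ic_lacuna_fraction)
        lacuna = 1.0 / (1.0 + np.exp(-(rel_depth - t_thr) / 0.02))
        s_field = s_field - 3.0 * lacuna
    s_field = s_field + 0.01 * rng.standard_normal(shape)

    labels_flat = _rank_remap(s_field.ravel()[midx], v)
    class_labels = np.zeros(shape, dtype=np.int32)
    class_labels.ravel()[midx] = labels_flat
    counts = np.bincount(labels_flat, minlength=K + 1)[1:]
    realized_v = counts / n

    levels = level_base + level_spacing * np.arange(K)
    dapi0 = np.full(shape, background, dtype=np.float64)
    dapi0.ravel()[midx] = levels[labels_flat - 1]

    truth = SyntheticTruth(
        mask=mask,
        class_labels=class_labels,
        class_volumes=realized_v,
        intensity_levels=levels,
        background=background,
        seed=seed,
    )

    channels = [VoxelGrid(_apply_noise(dapi0, noise, voxel_size, rng), voxel_size, "DAPI")]

    for md in markers:
        e = np.asarray(md.enrichment, dtype=np.float64)
        if e.shape != (K,):
            raise ValueError("marker enrichment length must equal K")
        m = realized_v * (1.0 + e)
        if m.sum() <= 0:
            raise ValueError("inconsistent spec: marker design has no mass")
        m = m / m.sum()
        n_pos = max(1, int(round(md.fraction_positive * n)))
        per_class = np.floor(m * n_pos).astype(int)
        # largest-remainder rounding, capped by class availability
        rem = m * n_pos - per_class
        for c in np.argsort(-rem):
            if per_class.sum() >= n_pos:
                break
            per_class[c] += 1
        per_class = np.minimum(per_class, counts)
        pos_flat = []
        for c in range(1, K + 1):
            if per_class[c - 1] == 0:
                continue
            pool = midx[labels_flat == c]
            pos_flat.append(rng.choice(pool, size=per_class[c - 1], replace=False))
        pos_flat = np.concatenate(pos_flat) if pos_flat else np.array([], dtype=int)
        pos_mask = np.zeros(shape, dtype=bool)
        pos_mask.ravel()[pos_flat] = True
        m_real = per_class / max(per_class.sum(), 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            e_real = np.where(realized_v > 0, (m_real - realized_v) / np.where(realized_v > 0, realized_v, 1), np.nan)
        truth.marker_positive[md.name] = pos_mask
        truth.marker_enrichment[md.name] = e_real
        marker0 = np.full(shape, md.background, dtype=np.float64)
        marker0[pos_mask] = md.amplitude
        channels.append(VoxelGrid(_apply_noise(marker0, noise, voxel_size, rng), voxel_size, md.name))

    return channels, truth


def mixture_params_for_truth(truth: SyntheticTruth, sd: float) -> MixtureParams:
    """Ideal mixture parameters implied by the generator's intensity levels."""
    return MixtureParams(
        K=len(truth.intensity_levels),
        means=truth.intensity_levels,
        shared_sd=sd,
        weights=truth.class_volumes / truth.class_volumes.sum(),
    )


def generate_spot_channel(
    mask: NuclearMask,
    n_spots: int,
    sigma_nm: float = 80.0,
    peak: float = 1000.0,
    background: float = 100.0,
    min_separation_nm: float = 500.0,
    border_margin_nm: float = 300.0,
    seed: int = 0,
    poisson: bool = False,
) -> tuple[VoxelGrid, np.ndarray]:
    """Channel of well-separated Gaussian spots at known positions.

    Spot centers lie inside the mask at a physical pairwise distance of at
    least ``min_separation_nm`` and at least ``border_margin_nm`` from the
    border. Returns the channel and the (n_spots, 3) array of center
    positions in nm (z, y, x).
    """
    rng = np.random.default_rng(seed)
    vs = np.asarray(mask.voxel_size)
    depth = ndi.distance_transform_edt(mask.data, sampling=vs)
    candidates = np.array(np.nonzero(depth >= border_margin_nm)).T
    if candidates.shape[0] < n_spots:
        raise ValueError("mask too small for requested border margin")
    positions = []
    order = rng.permutation(candidates.shape[0])
    for i in order:
        p = candidates[i] * vs
        if all(np.linalg.norm(p - q) >= min_separation_nm for q in positions):
            positions.append(p)
            if len(positions) == n_spots:
                break
    if len(positions) < n_spots:
        raise ValueError(f"could not place {n_spots} spots at the requested separation")
    positions = np.array(positions)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in mask.data.shape), indexing="ij")
    img = np.full(mask.data.shape, background, dtype=np.float64)
    for p in positions:
        r2 = ((zz * vs[0] - p[0]) ** 2 + (yy * vs[1] - p[1]) ** 2 + (xx * vs[2] - p[2]) ** 2)
        img += peak * np.exp(-r2 / (2.0 * sigma_nm**2))
    if poisson:
        img = rng.poisson(img).astype(np.float64)
    return VoxelGrid(np.clip(np.round(img), 0, 65535).astype(np.uint16), tuple(vs), "spots"), positions


def generate_tem_section(
    layout: str = "many-small-holes",
    hole_radii: list[float] | None = None,
    pixel_size: float = 10.0,
    seed: int = 0,
    size: int = 512,
    nucleus_radius: float = 200.0,
    chromatin_level: float = 200.0,
    ic_level: float = 30.0,
    noise_sd: float = 5.0,
) -> tuple[SectionImage, dict]:
    """TEM-like section: a disk nucleus with circular IC holes in the chromatin.

    ``layout`` selects the default hole set: ``"many-small-holes"`` (20 holes
    of radius 10 px) or ``"single-lacuna"`` (one hole of equal total area,
    radius ``10 * sqrt(20)``); ``hole_radii`` overrides it. Holes are
    non-overlapping and strictly interior, so the analytic interface length
    is exactly ``sum_i 2 pi r_i * pixel_size``.

    Returns the section and a truth dict with the nuclear mask, chromatin
    mask and the analytic :class:`InterfaceMeasure`.
    """
    if hole_radii is None:
        if layout == "many-small-holes":
            hole_radii = [10.0] * 20
        elif layout == "single-lacuna":
            hole_radii = [10.0 * np.sqrt(20.0)]
        elif layout == "no-holes":
            hole_radii = []
        else:
            raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)
    c = size / 2.0
    yy, xx = np.meshgrid(np.arange(size, dtype=np.float64), np.arange(size, dtype=np.float64), indexing="ij")
    nucleus = (yy - c) ** 2 + (xx - c) ** 2 <= nucleus_radius**2
    chromatin = nucleus.copy()
    placed: list[tuple[float, float, float]] = []
    for r in sorted(hole_radii, reverse=True):
        for _ in range(10000):
            rho = (nucleus_radius - r - 4.0) * np.sqrt(rng.random())
            phi = rng.random() * 2 * np.pi
            hy, hx = c + rho * np.sin(phi), c + rho * np.cos(phi)
            if all(np.hypot(hy - py, hx - px) >= r + pr + 3.0 for py, px, pr in placed):
                placed.append((hy, hx, r))
                chromatin &= (yy - hy) ** 2 + (xx - hx) ** 2 > r**2
                break
        else:
            raise ValueError("could not place non-overlapping holes")
    img = np.where(chromatin, chromatin_level, ic_level)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    section = SectionImage(np.clip(img, 0, None), pixel_size, modality="TEM")
    analytic = InterfaceMeasure(
        P_nucleus=2 * np.pi * nucleus_radius * pixel_size,
        P_chromatin=(2 * np.pi * nucleus_radius + sum(2 * np.pi * r for r in hole_radii)) * pixel_size,
        A_nucleus=np.pi * nucleus_radius**2 * pixel_size**2,
    )
    truth = {
        "nuclear_mask": nucleus,
        "chromatin_mask": chromatin,
        "analytic": analytic,
        "holes": placed,
    }
    return section, truth


def generate_radial_fixture(
    mask_shape: tuple[int, int, int] = (32, 64, 64),
    channel_means: tuple = (0.3, 0.7),
    spread: float = 0.1,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    scale: float = 1000.0,
    poisson: bool = True,
) -> tuple[list[VoxelGrid], NuclearMask, dict]:
    """Channels whose intensity mass sits at designed relative depths.

    The mask is the inscribed ellipsoid of ``mask_shape``. Each channel's
    noiseless intensity at relative depth ``t`` is a Gaussian bump
    ``exp(-(t - mean)^2 / (2 spread^2))``; ``spread = 0`` concentrates all
    mass at the deepest interior point. The truth dict maps channel names to
    realized (noiseless) intensity-weighted mean relative depths.
    """
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in mask_shape), indexing="ij")
    center = [(s - 1) / 2.0 for s in mask_shape]
    semi = [s / 2.0 - 2.0 for s in mask_shape]
    mask_arr = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0
    mask = NuclearMask(mask_arr, voxel_size)
    depth = ndi.distance_transform_edt(mask_arr, sampling=voxel_size)
    rel = depth / depth.max()
    channels = []
    truth: dict[str, float] = {}
    for i, mu in enumerate(channel_means):
        if not 0.0 <= mu <= 1.0:
            raise ValueError("channel means must lie in [0, 1]")
        name = f"ch{i}"
        if spread == 0:
            w = (rel == rel.max()) & mask_arr
            noiseless = np.where(w, scale, 0.0)
        else:
            noiseless = scale * np.exp(-((rel - mu) ** 2) / (2.0 * spread**2))
            noiseless = np.where(mask_arr, noiseless, 0.0)
        tot = noiseless.sum()
        truth[name] = float((noiseless * rel).sum() / tot)
        img = rng.poisson(noiseless).astype(np.float64) if poisson else noiseless
        channels.append(
            VoxelGrid(np.clip(np.round(img), 0, 65535).astype(np.uint16), voxel_size, name)
        )
    return channels, mask, truth
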