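"""Marker topology over density classes.

Thresholded marker voxels are correlated with the density class of the
corresponding DAPI voxel. The per-class marker fraction ``M_c`` is compared
to the DAPI reference fraction ``D_c`` through the relative
enrichment/depletion

    ``E_c = (M_c - D_c) / D_c``

(positive = overrepresentation, negative = depletion; ``E_c >= -1`` always,
and ``sum_c D_c * E_c = 0`` identically). Classes with ``D_c = 0`` are
reported as missing rather than infinite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .classify import ClassMap
from .model import NuclearMask, VoxelGrid
from .stats import RankTestResult, rank_sum_test

__all__ = [
    "EnrichmentProfile",
    "threshold_marker",
    "enrichment_profile",
    "compare_marker_to_dapi",
]


@dataclass
class EnrichmentProfile:
    """Per-class marker distribution M, DAPI reference D and enrichment E.

    ``empty`` flags the degenerate case of zero marker-positive voxels, in
    which M and E carry NaNs and the sum invariants do not apply.
    """

    marker_name: str
    M: np.ndarray
    D: np.ndarray
    E: np.ndarray
    n_marker_voxels: int = 0
    nucleus_id: int = 0
    empty: bool = False

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.float64)
        self.D = np.asarray(self.D, dtype=np.float64)
        self.E = np.asarray(self.E, dtype=np.float64)
        if not (self.M.shape == self.D.shape == self.E.shape):
            raise ValueError("M, D, E must share length K")
        if self.empty:
            return
        if abs(self.M.sum() - 1.0) > 1e-9 or abs(self.D.sum() - 1.0) > 1e-9:
            raise ValueError("M and D must each sum to 1")
        defined = ~np.isnan(self.E)
        if np.any(self.E[defined] < -1.0 - 1e-12):
            raise ValueError("E_c >= -1 violated")

    @property
    def K(self) -> int:
        return len(self.D)

    def marker_mean_class(self) -> float:
        """Class-index-weighted mean of the marker distribution."""
        c = np.arange(1, self.K + 1)
        return float(np.dot(c, self.M))

    def dapi_mean_class(self) -> float:
        c = np.arange(1, self.K + 1)
        return float(np.dot(c, self.D))


def threshold_marker(
    marker: VoxelGrid, mask: NuclearMask, method: float | str = "otsu"
) -> np.ndarray:
    """Binary marker-positive voxel set inside the nuclear mask.

    ``method='otsu'`` thresholds on the within-mask histogram; a float is an
    absolute threshold (voxels strictly above are positive). A constant
    channel cannot be Otsu-thresholded (degenerate histogram); an all-zero
    result is returned with a warning, not an error.
    """
    if marker.shape != mask.data.shape:
        raise ValueError("marker/mask shape mismatch")
    inside = marker.data[mask.data].astype(np.float64)
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown threshold method {method!r}")
        if np.ptp(inside) == 0:
            raise ValueError("degenerate histogram: constant marker channel")
        thr = threshold_otsu(inside)
    else:
        thr = float(method)
    positive = (marker.data > thr) & mask.data
    if not positive.any():
        warnings.warn("no marker-positive voxels above threshold", stacklevel=2)
    return positive


def enrichment_profile(
    marker_positive: np.ndarray, classmap: ClassMap, marker_name: str = ""
) -> EnrichmentProfile:
    """Per-class marker fractions and enrichment relative to DAPI.

    ``marker_positive`` must lie inside the class map's mask. Returns an
    explicit empty profile (``empty=True``) when the marker set is empty.
    """
    marker_positive = np.asarray(marker_positive, dtype=bool)
    if marker_positive.shape != classmap.labels.shape:
        raise ValueError("marker/classmap shape mismatch")
    if np.any(marker_positive & (classmap.labels == 0)):
        raise ValueError("marker-positive voxels outside the class map")
    K = classmap.K
    d_counts = classmap.class_counts()
    D = d_counts / d_counts.sum()
    m_counts = np.bincount(classmap.labels[marker_positive], minlength=K + 1)[1:]
    n_marker = int(m_counts.sum())
    if n_marker == 0:
        nan = np.full(K, np.nan)
        return EnrichmentProfile(marker_name, nan, D, nan, 0, classmap.nucleus_id, empty=True)
    M = m_counts / n_marker
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.where(D > 0, (M - D) / np.where(D > 0, D, 1.0), np.nan)
    return EnrichmentProfile(marker_name, M, D, E, n_marker, classmap.nucleus_id)


def compare_marker_to_dapi(profiles: list[EnrichmentProfile]) -> RankTestResult:
    """Wilcoxon rank-sum test of marker vs DAPI class distributions.

    Each nucleus contributes one exchangeable value per channel: the
    class-index-weighted mean class of its distribution. Requires at least
    3 (non-empty) per-nucleus profiles.
    """
    usable = [p for p in profiles if not p.empty]
    if len(usable) < 3:
        raise ValueError("need at least 3 nuclei with non-empty profiles")
    marker_vals = [p.marker_mean_class() for p in usable]
    dapi_vals = [p.dapi_mean_class() for p in usable]
    return rank_sum_test(marker_vals, dapi_vals)


def mean_profile(profiles: list[EnrichmentProfile]) -> dict:
    """Across-nuclei mean and sd of M, D and E (empty profiles excluded)."""
    usable = [p for p in profiles if not p.empty]
    if not usable:
        raise ValueError("no non-empty profiles")
    M = np.array([p.M for p in usable])
    D = np.array([p.D for p in usable])
    E = np.array([p.E for p in usable])
    return {
        "n_nuclei": len(usable),
        "M_mean": M.mean(axis=0), "M_sd": M.std(axis=0, ddof=1) if len(usable) > 1 else np.zeros(M.shape[1]),
        "D_mean": D.mean(axis=0), "D_sd": D.std(axis=0, ddof=1) if len(usable) > 1 else np.zeros(D.shape[1]),
        "E_mean": np.nanmean(E, axis=0), "E_sd": np.nanstd(E, axis=0, ddof=1) if len(usable) > 1 else np.zeros(E.shape[1]),
    }
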