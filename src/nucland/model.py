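"""Core image data model, TIFF I/O and 3D nuclear mask generation.

Conventions (fixed package-wide):

* arrays are indexed ``(z, y, x)``, 0-based; physical positions refer to
  voxel centers;
* foreground connectivity is 26 (full 3x3x3 neighborhood), background
  connectivity is 6;
* voxel sizes are edge lengths in nanometers, ordered ``(dz, dy, dx)``.
"""

from __future__ import annotations

import json
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

__all__ = [
    "VoxelGrid",
    "NuclearMask",
    "SectionImage",
    "MaskParams",
    "read_stack",
    "write_stack",
    "generate_nuclear_mask",
    "write_mask",
]

#: structuring element for 26-connected component labeling
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelGrid:
    """One channel of a 3D acquisition with anisotropic voxel sizes.

    Parameters
    ----------
    data
        3D array of non-negative, finite intensities, axes ``(z, y, x)``.
    voxel_size
        Physical edge lengths ``(dz, dy, dx)`` in nm, all strictly positive.
    channel_name
        Free-text channel label (e.g. ``"DAPI"``).
    bit_origin
        Bit depth of the source data (8, 16 or 32).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_name: str = ""
    bit_origin: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D (z, y, x) data, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data.astype(np.float64, copy=False))):
            raise ValueError("intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three strictly positive lengths (dz, dy, dx)")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def masked(self, mask: "NuclearMask") -> np.ndarray:
        """Intensities with everything outside the mask set to 0."""
        if mask.data.shape != self.data.shape:
            raise ValueError("mask/grid shape mismatch")
        return np.where(mask.data, self.data, 0)


@dataclass
class NuclearMask:
    """Binary 3D mask of a single nucleus.

    Exactly one 26-connected foreground component (lobed nuclei remain
    connected through their bridges) that does not touch the volume border.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    nucleus_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask is empty")
        _, n = ndi.label(self.data, structure=STRUCT_26)
        if n != 1:
            raise ValueError(f"mask must be one 26-connected component, found {n}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def touches_border(self) -> bool:
        d = self.data
        return bool(
            d[0].any() or d[-1].any()
            or d[:, 0].any() or d[:, -1].any()
            or d[:, :, 0].any() or d[:, :, -1].any()
        )

    def bounding_box(self) -> tuple[slice, slice, slice]:
        return ndi.find_objects(self.data.astype(np.int8))[0]


@dataclass
class SectionImage:
    """Single 2D grayscale section (TEM or a SIM mid-section)."""

    data: np.ndarray
    pixel_size: float
    modality: str = "TEM"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("section must be 2D")
        if not np.all(np.isfinite(self.data.astype(np.float64, copy=False))):
            raise ValueError("intensities must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.modality not in ("TEM", "SIM-midsection"):
            raise ValueError(f"unknown modality {self.modality!r}")


# ---------------------------------------------------------------------------
# TIFF I/O


def write_stack(path, channels: list[VoxelGrid]) -> None:
    """Write channels as an OME-TIFF volume (axes CZYX) with voxel sizes in nm.

    All channels must share shape and voxel size. 8/16-bit data round-trips
    bit-exactly through :func:`read_stack`.
    """
    if not channels:
        raise ValueError("no channels to write")
    shape = channels[0].shape
    vs = channels[0].voxel_size
    for ch in channels[1:]:
        if ch.shape != shape or ch.voxel_size != vs:
            raise ValueError("channels must share shape and voxel_size")
    stack = np.stack([ch.data for ch in channels])
    dz, dy, dx = vs
    tifffile.imwrite(
        str(path),
        stack,
        ome=True,
        photometric="minisblack",  # small X would otherwise be guessed as RGBA
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "nm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "nm",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "nm",
            "Channel": {"Name": [ch.channel_name for ch in channels]},
        },
    )


_UNIT_TO_NM = {"nm": 1.0, "µm": 1e3, "um": 1e3, "mm": 1e6, "m": 1e9, "Å": 0.1}


def _voxel_size_from_ome(xml: str) -> tuple[float, float, float] | None:
    root = ET.fromstring(xml)
    ns = root.tag.partition("}")[0].lstrip("{")
    px = root.find(f".//{{{ns}}}Pixels")
    if px is None:
        return None
    out = []
    for axis in "ZYX":
        val = px.get(f"PhysicalSize{axis}")
        if val is None:
            return None
        unit = px.get(f"PhysicalSize{axis}Unit", "µm")
        if unit not in _UNIT_TO_NM:
            raise ValueError(f"unsupported physical-size unit {unit!r}")
        out.append(float(val) * _UNIT_TO_NM[unit])
    return tuple(out)


def read_stack(
    path,
    channel_layout: dict[int, str],
    voxel_size: tuple[float, float, float] | None = None,
) -> list[VoxelGrid]:
    """Read a TIFF/OME-TIFF volume into one :class:`VoxelGrid` per channel.

    Parameters
    ----------
    path
        TIFF or OME-TIFF file with axes (C)ZYX.
    channel_layout
        Mapping channel index -> channel name; must name every channel.
    voxel_size
        ``(dz, dy, dx)`` in nm; overrides/replaces file metadata. If the
        file has no physical-size metadata and no override is given this is
        a hard error.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        if voxel_size is None and tf.ome_metadata:
            voxel_size = _voxel_size_from_ome(tf.ome_metadata)
    if voxel_size is None:
        raise ValueError(
            "missing voxel_size: file carries no PhysicalSizeX/Y/Z metadata "
            "and no voxel_size override was provided"
        )
    if axes.startswith("C") or (data.ndim == 4 and not axes.startswith("Z")):
        stack = data
    elif data.ndim == 3:
        stack = data[None]
    else:
        raise ValueError(f"unsupported axes layout {axes!r}")
    n_channels = stack.shape[0]
    if set(channel_layout) != set(range(n_channels)):
        raise ValueError(
            f"channel layout names {sorted(channel_layout)} but file has "
            f"{n_channels} channels (indices 0..{n_channels - 1})"
        )
    bit = stack.dtype.itemsize * 8
    return [
        VoxelGrid(stack[i], voxel_size, channel_name=channel_layout[i], bit_origin=bit)
        for i in range(n_channels)
    ]


# ---------------------------------------------------------------------------
# Nuclear mask generation


@dataclass
class MaskParams:
    """Parameters for :func:`generate_nuclear_mask`.

    ``threshold=None`` selects Otsu on the smoothed field; a float is an
    absolute threshold applied to the smoothed image. ``sigma_lateral`` is in
    voxels; axial smoothing is scaled down by the voxel anisotropy so the
    physical smoothing length is roughly isotropic.
    """

    threshold: float | None = None
    sigma_lateral: float = 2.0
    closing_radius: int = 1


def generate_nuclear_mask(
    dapi: VoxelGrid, params: MaskParams | None = None, nucleus_id: int = 0
) -> NuclearMask:
    """Segment the nucleus from a DAPI channel.

    Steps: Gaussian smoothing, global threshold (Otsu by default), largest
    26-connected component, morphological closing, then exterior-aware hole
    filling: only cavities fully enclosed in 3D are sealed, so surface
    invaginations and tunnels open to the exterior (a tunnel through the
    nucleus along z included) are never sealed.
    """
    params = params or MaskParams()
    dz, dy, dx = dapi.voxel_size
    sig = (params.sigma_lateral * dy / dz, params.sigma_lateral, params.sigma_lateral * dy / dx)
    # support-normalized smoothing: exact zeros (an already-masked field) do
    # not drag boundary values down, which makes re-application idempotent
    data = dapi.data.astype(np.float64)
    support = data > 0
    if not support.any():
        raise ValueError("no nucleus found")
    num = ndi.gaussian_filter(data, sigma=sig)
    den = ndi.gaussian_filter(support.astype(np.float64), sigma=sig)
    smoothed = np.where(support, num / np.maximum(den, 1e-12), 0.0)
    if params.threshold is None:
        if np.ptp(smoothed) == 0:
            raise ValueError("no nucleus found: constant image")
        thr = threshold_otsu(smoothed)
    else:
        thr = float(params.threshold)
    fg = smoothed > thr
    if not fg.any():
        raise ValueError("no nucleus found")
    labels, n = ndi.label(fg, structure=STRUCT_26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == counts.argmax()
    r = params.closing_radius
    if r > 0:
        selem = np.ones((2 * r + 1,) * 3, dtype=bool)
        fg = ndi.binary_closing(fg, structure=selem)
        # closing can fragment nothing but can merge; re-extract largest CC
        labels, n = ndi.label(fg, structure=STRUCT_26)
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            fg = labels == counts.argmax()
    # exterior-aware hole filling: only cavities fully enclosed in 3D are
    # sealed (6-connected background), so invaginations and tunnels that
    # open to the exterior anywhere -- including along z -- stay open
    fg = ndi.binary_fill_holes(fg)
    mask = NuclearMask(fg, dapi.voxel_size, nucleus_id=nucleus_id)
    if mask.touches_border():
        warnings.warn(
            "nuclear mask touches the volume border; clearing a 1-voxel shell",
            stacklevel=2,
        )
        fg = mask.data.copy()
        fg[0] = fg[-1] = False
        fg[:, 0] = fg[:, -1] = False
        fg[:, :, 0] = fg[:, :, -1] = False
        labels, n = ndi.label(fg, structure=STRUCT_26)
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            fg = labels == counts.argmax()
        mask = NuclearMask(fg, dapi.voxel_size, nucleus_id=nucleus_id)
    return mask


def write_mask(path, mask: NuclearMask, sidecar: bool = True) -> None:
    """Write a mask as 8-bit TIFF (0/255) plus a JSON sidecar."""
    tifffile.imwrite(str(path), (mask.data.astype(np.uint8) * 255))
    if sidecar:
        bb = mask.bounding_box()
        meta = {
            "nucleus_id": mask.nucleus_id,
            "n_voxels": mask.n_voxels,
            "voxel_size_nm": list(mask.voxel_size),
            "bounding_box": [[s.start, s.stop] for s in bb],
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def read_mask(path, voxel_size: tuple[float, float, float], nucleus_id: int = 0) -> NuclearMask:
    """Read a 0/255 8-bit TIFF mask written by :func:`write_mask`."""
    data = tifffile.imread(str(path))
    return NuclearMask(data > 0, voxel_size, nucleus_id=nucleus_id)
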