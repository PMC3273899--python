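"""Z-stack reading/writing with physical voxel metadata, and isotropic resampling.

Confocal stacks are anisotropic (the axial sampling distance is typically two to
three times the lateral one); all geometry downstream (surface extraction,
curvature) assumes an isotropic grid, so stacks are resampled before analysis.

Axis order is fixed as ``(z, y, x)``; voxel coordinates are voxel-centred and
0-based; spacings are in nanometres.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage

__all__ = ["ImageStack", "read_stack", "write_stack", "resample_isotropic"]

#: relative spread below which the three spacings count as isotropic
_ISO_RTOL = 1e-3


@dataclass
class ImageStack:
    """A single-channel 3D intensity grid with per-axis physical voxel size.

    Parameters
    ----------
    voxels
        Non-negative intensity grid, axis order ``(z, y, x)``.
    spacing
        Physical voxel size per axis in nm, order ``(z, y, x)``.
    channel_label
        Free-text channel description (e.g. ``"lamin A-GFP"``).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) grid, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("voxel values must be >= 0")

    @property
    def is_isotropic(self) -> bool:
        s = np.asarray(self.spacing)
        return bool((s.max() - s.min()) <= _ISO_RTOL * s.min())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_nm3(self) -> float:
        return float(np.prod(self.spacing))

    def physical_extent_nm(self) -> tuple[float, float, float]:
        """Size of the imaged volume along each axis in nm."""
        return tuple(n * s for n, s in zip(self.voxels.shape, self.spacing))


def _spacing_from_ome(ome_xml: str) -> tuple[float, float, float] | None:
    """Extract (z, y, x) spacing in nm from OME-XML Pixels attributes (µm units)."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            try:
                z = float(el.attrib["PhysicalSizeZ"])
                y = float(el.attrib["PhysicalSizeY"])
                x = float(el.attrib["PhysicalSizeX"])
            except (KeyError, ValueError):
                return None
            # OME default unit is µm unless stated otherwise
            units = [el.attrib.get(f"PhysicalSize{a}Unit", "µm") for a in "ZYX"]
            scale = {"µm": 1e3, "um": 1e3, "nm": 1.0}
            try:
                return tuple(v * scale[u] for v, u in zip((z, y, x), units))
            except KeyError:
                return None
    return None


def read_stack(
    path,
    spacing_override: tuple[float, float, float] | None = None,
    channel_label: str = "",
) -> ImageStack:
    """Read a single-channel multi-plane TIFF/OME-TIFF as an :class:`ImageStack`.

    Spacing is taken from OME ``PhysicalSize*`` metadata (µm, converted to nm);
    ``spacing_override`` (nm, z/y/x order) takes precedence when given.  A plain
    TIFF without metadata and without an override is an error: downstream
    geometry is meaningless without a physical calibration.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome = tif.ome_metadata
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel Z-stack, got shape {data.shape}; "
            "select a channel before reading"
        )
    spacing = spacing_override
    if spacing is None and ome is not None:
        spacing = _spacing_from_ome(ome)
    if spacing is None:
        raise ValueError(f"{path}: spacing unresolved (no OME metadata and no override)")
    return ImageStack(np.asarray(data, dtype=np.float64), spacing, channel_label)


def write_stack(stack: ImageStack, path) -> None:
    """Write an OME-TIFF carrying the stack's voxel spacing (µm in metadata)."""
    sz, sy, sx = (s / 1e3 for s in stack.spacing)
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": sz,
            "PhysicalSizeY": sy,
            "PhysicalSizeX": sx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def resample_isotropic(stack: ImageStack, target_nm: float | None = None) -> ImageStack:
    """Resample an anisotropic stack onto an isotropic grid.

    The default target spacing is the smallest input spacing, i.e. the axial
    direction is upsampled rather than degrading the lateral resolution —
    curvature estimation is resolution-sensitive.  Interpolation is a
    third-order spline; negative overshoot is clipped at zero because
    intensities are physical counts.  Physical extent is preserved to within
    one voxel per axis.
    """
    if any(n < 4 for n in stack.shape):
        raise ValueError(f"degenerate stack: every axis needs >= 4 voxels, got {stack.shape}")
    if target_nm is None:
        target_nm = min(stack.spacing)
    if target_nm <= 0:
        raise ValueError("target_nm must be > 0")
    target = (float(target_nm),) * 3
    if stack.is_isotropic and all(
        abs(s - target_nm) <= _ISO_RTOL * target_nm for s in stack.spacing
    ):
        return replace(stack, voxels=stack.voxels.copy(), spacing=target)
    zoom = [s / target_nm for s in stack.spacing]
    out = ndimage.zoom(stack.voxels, zoom, order=3, mode="nearest", grid_mode=True)
    np.clip(out, 0.0, None, out=out)
    return ImageStack(out, target, stack.channel_label)
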