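"""Multidimensional TIFF stack input/output and map export.

Stacks are carried internally in a fixed canonical axis order (T, C, Z, Y, X);
readers permute incoming data once so the rest of the pipeline never has to
reason about dimension order.  Voxel coordinates are 0-based and voxel
(z, y, x) occupies the half-open physical box
[x*dx, (x+1)*dx) x [y*dy, (y+1)*dy) x [z*dz, (z+1)*dz) in micrometers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "VoxelSpacing",
    "ImageStack",
    "read_tiff_stack",
    "write_tiff_stack",
    "export_map",
    "get_lut",
    "LUT_NAMES",
]

_CANONICAL = "TCZYX"


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in micrometers (dx, dy lateral; dz axial)."""

    dx: float = 1.0
    dy: float = 1.0
    dz: float = 1.0

    def __post_init__(self):
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite")

    @property
    def min(self) -> float:
        return min(self.dx, self.dy, self.dz)


@dataclass
class ImageStack:
    """Up-to-5D intensity grid in canonical (T, C, Z, Y, X) order."""

    values: np.ndarray
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    axis_labels: str = "TCZYX"

    def __post_init__(self):
        arr = np.asarray(self.values)
        labels = "".join(self.axis_labels).upper()
        if not (2 <= arr.ndim <= 5):
            raise ValueError("stack must have between 2 and 5 axes")
        if arr.ndim != len(labels):
            raise ValueError("axis_labels length must match array rank")
        if "X" not in labels or "Y" not in labels:
            raise ValueError("X and Y axes are mandatory")
        if len(set(labels)) != len(labels) or any(a not in _CANONICAL for a in labels):
            raise ValueError(f"axis labels must be a subset of {_CANONICAL}")
        # normalize to canonical order, inserting missing axes with size 1
        order = [labels.index(a) for a in _CANONICAL if a in labels]
        arr = np.transpose(arr, order)
        for i, a in enumerate(_CANONICAL):
            if a not in labels:
                arr = np.expand_dims(arr, i)
        if not np.all(np.isfinite(arr)):
            raise ValueError("stack intensities must be finite")
        if np.issubdtype(arr.dtype, np.integer) and arr.min() < 0:
            raise ValueError("integer stacks must be non-negative")
        self.values = arr
        self.axis_labels = _CANONICAL

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def n_t(self) -> int:
        return self.values.shape[0]

    @property
    def n_c(self) -> int:
        return self.values.shape[1]

    def bounds_um(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) of the volume in um."""
        _, _, nz, ny, nx = self.values.shape
        sp = self.spacing
        return (nx * sp.dx, ny * sp.dy, nz * sp.dz)


def _parse_imagej_axes(tif: tifffile.TiffFile) -> str | None:
    series = tif.series
    if series:
        axes = series[0].axes.upper().replace("S", "C").replace("Q", "")
        if axes and all(a in _CANONICAL for a in axes):
            return axes
    return None


def _spacing_from_metadata(tif: tifffile.TiffFile) -> VoxelSpacing | None:
    ij = tif.imagej_metadata or {}
    dz = ij.get("spacing")
    page = tif.pages[0]
    xres = page.tags.get("XResolution")
    yres = page.tags.get("YResolution")
    if xres is None or yres is None:
        return None
    def _as_um(tag):
        num, den = tag.value
        return den / num if num else None
    dx, dy = _as_um(xres), _as_um(yres)
    if dx is None or dy is None:
        return None
    # a bare default (1, 1) resolution tag without any unit declaration is
    # not a calibration; treat it as absent rather than as 1 um spacing
    if dz is None and "unit" not in ij and dx == 1.0 and dy == 1.0:
        return None
    return VoxelSpacing(dx=dx, dy=dy, dz=dz if dz else 1.0)


def read_tiff_stack(path, dim_order: str | None = None, spacing: VoxelSpacing | None = None) -> ImageStack:
    """Read a multi-page or ImageJ-hyperstack TIFF into an :class:`ImageStack`.

    Axis order is taken from TIFF/ImageJ metadata when present, else from
    ``dim_order``.  Spacing comes from metadata when recorded, else from the
    ``spacing`` argument, else defaults to 1 um isotropic with a warning so
    that plain pre-existing stacks remain usable.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    try:
        tif = tifffile.TiffFile(p)
    except Exception as exc:
        raise ValueError(f"{p} is not a readable TIFF: {exc}") from exc
    with tif:
        data = tif.asarray()
        axes = _parse_imagej_axes(tif)
        meta_spacing = _spacing_from_metadata(tif)
    if dim_order is not None:
        dim_order = dim_order.upper()
        if len(dim_order) != data.ndim:
            raise ValueError(
                f"dim_order {dim_order!r} has {len(dim_order)} axes but data has {data.ndim}"
            )
        axes = dim_order
    if axes is None:
        raise ValueError("TIFF declares no axes and no dim_order was given")
    if len(axes) != data.ndim:
        raise ValueError(f"declared axes {axes!r} inconsistent with data rank {data.ndim}")
    if meta_spacing is not None:
        sp = meta_spacing
    elif spacing is not None:
        sp = spacing
    else:
        warnings.warn("no voxel spacing in metadata or arguments; assuming 1 um isotropic")
        sp = VoxelSpacing()
    return ImageStack(values=data, spacing=sp, axis_labels=axes)


def write_tiff_stack(stack: ImageStack, path) -> None:
    """Write an ImageJ-compatible hyperstack TIFF with axes and spacing metadata.

    Lossless for integer and float32 data; float64 is narrowed to float32
    with a warning (the hyperstack dialect stores 32-bit floats).
    """
    data = stack.values
    if data.dtype == np.float64:
        warnings.warn("float64 narrowed to float32 for TIFF storage")
        data = data.astype(np.float32)
    # ImageJ hyperstack page order is TZCYX
    data_ij = np.transpose(data, (0, 2, 1, 3, 4))
    sp = stack.spacing
    tifffile.imwrite(
        Path(path),
        data_ij,
        imagej=True,
        resolution=(1.0 / sp.dx, 1.0 / sp.dy),
        metadata={"spacing": sp.dz, "unit": "um", "axes": "TZCYX"},
    )


# ---------------------------------------------------------------------------
# map export

LUT_NAMES = ("gray", "rainbow", "hypsometric")


def get_lut(name: str) -> np.ndarray:
    """Return a (256, 3) float RGB lookup table by name.

    ``hypsometric`` is a diverging elevation table: bathymetric blues below
    the baseline, a neutral light midpoint at zero, greens to browns above.
    """
    name = name.lower()
    if name not in LUT_NAMES:
        raise ValueError(f"unknown lut {name!r}; choose from {LUT_NAMES}")
    n = 256
    x = np.linspace(0.0, 1.0, n)
    if name == "gray":
        return np.repeat(x[:, None], 3, axis=1)
    if name == "rainbow":
        from matplotlib import colormaps

        return np.asarray(colormaps["rainbow"](x))[:, :3]
    # hypsometric: piecewise-linear anchors (position, rgb)
    anchors = [
        (0.00, (0.03, 0.11, 0.35)),  # deep indentation: dark blue
        (0.25, (0.25, 0.48, 0.75)),
        (0.50, (0.94, 0.94, 0.90)),  # baseline: neutral light
        (0.70, (0.47, 0.70, 0.38)),
        (0.88, (0.72, 0.58, 0.32)),
        (1.00, (0.55, 0.33, 0.20)),  # high protrusion: brown
    ]
    pos = np.array([a[0] for a in anchors])
    rgb = np.array([a[1] for a in anchors])
    return np.column_stack([np.interp(x, pos, rgb[:, k]) for k in range(3)])


def _map_values_and_mask(obj):
    # accepts MapImage / HeightMap (duck-typed) or a bare array
    if hasattr(obj, "elevation"):
        return np.asarray(obj.elevation, dtype=float), np.asarray(obj.mask, dtype=bool)
    if hasattr(obj, "values") and hasattr(obj, "mask"):
        return np.asarray(obj.values, dtype=float), np.asarray(obj.mask, dtype=bool)
    arr = np.asarray(obj, dtype=float)
    return arr, np.isfinite(arr)


def export_map(map_obj, path, lut: str = "gray", background=(0, 0, 0)) -> None:
    """Export a rendered map as a 16-bit grayscale TIFF plus an RGBA rendering.

    The grayscale TIFF stores raw map values under a linear fixed-point
    scaling recorded in the image description as ``scale``/``offset``
    (value = raw/scale + offset).  The companion ``<stem>_<lut>.png`` holds
    an 8-bit RGBA rendering; pixels outside the projection domain get the
    background color and zero alpha.
    """
    lut_table = get_lut(lut)
    values, mask = _map_values_and_mask(map_obj)
    path = Path(path)
    if not mask.any():
        raise ValueError("empty mask: nothing to export")

    vmin = float(values[mask].min())
    vmax = float(values[mask].max())
    span = vmax - vmin
    scale = 65535.0 / span if span > 0 else 1.0
    raw = np.zeros(values.shape, dtype=np.uint16)
    raw[mask] = np.round((values[mask] - vmin) * scale).astype(np.uint16)
    tifffile.imwrite(
        path,
        raw,
        description=f"spheremap map export; scale={scale!r}; offset={vmin!r}",
    )

    norm = np.zeros_like(values)
    norm[mask] = (values[mask] - vmin) / span if span > 0 else 0.5
    idx = np.clip(np.round(norm * (len(lut_table) - 1)).astype(int), 0, len(lut_table) - 1)
    rgba = np.zeros(values.shape + (4,), dtype=np.uint8)
    rgba[..., :3] = np.round(lut_table[idx] * 255).astype(np.uint8)
    rgba[..., 3] = np.where(mask, 255, 0)
    rgba[~mask, :3] = np.asarray(background, dtype=np.uint8)
    import imageio.v3 as iio

    iio.imwrite(path.with_name(path.stem + f"_{lut}.png"), rgba)


def read_exported_map(path) -> tuple[np.ndarray, float, float]:
    """Re-read a 16-bit map export; returns (raw uint16 array, scale, offset)."""
    with tifffile.TiffFile(path) as tif:
        raw = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        scale, offset = 1.0, 0.0
        if desc is not None:
            for part in str(desc.value).split(";"):
                part = part.strip()
                if part.startswith("scale="):
                    scale = float(part[6:])
                elif part.startswith("offset="):
                    offset = float(part[7:])
    return raw, scale, offset
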