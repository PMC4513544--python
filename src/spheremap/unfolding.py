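"""Unfold stack surface signal onto 2D map rasters around the reference ellipsoid.

Each map pixel center is pulled back through the inverse projection to a
spherical direction, a radial ray is cast from the ellipsoid center through
that direction, and the stack is sampled along the ray inside a fractional
radial window around the ellipsoid surface.  The per-pixel provenance
(source voxel, sampled radius, spherical coordinates, elevation above the
ellipsoid) is recorded in a cross-reference table so that measurements drawn
on the map can be executed on the original voxel data.

This module is fully deterministic: identical inputs and options produce
bit-identical maps and tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .ellipsoid import ReferenceEllipsoid, direction_from_latlon, ellipsoid_radius
from .projections import ProjectionSpec, inverse_project, map_pixel_centers
from .stack_io import ImageStack, get_lut

__all__ = [
    "UnfoldOptions",
    "MapImage",
    "HeightMap",
    "build_direction_grid",
    "sample_radial_ray",
    "unfold_intensity",
    "unfold_height",
    "apply_hypsometric_lut",
    "save_crossref_table",
    "load_crossref_table",
]

CROSSREF_COLUMNS = [
    "map_x", "map_y", "phi", "lam", "r_star", "elevation_um", "t", "c", "z", "y", "x",
]


@dataclass(frozen=True)
class UnfoldOptions:
    """Options controlling rasterization and radial sampling.

    ``radial_window`` is a pair of fractions of the local ellipsoid radius;
    the ray at direction (phi, lam) samples r in [r_lo*R, r_hi*R] with step
    ``radial_step`` (um; default half the smallest voxel edge).  The
    ``interpolated`` flag selects trilinear (True) versus nearest-voxel
    stack sampling.
    """

    projection: ProjectionSpec = field(default_factory=lambda: ProjectionSpec("equirectangular"))
    unfold_axis: str = "Z"
    map_width: int = 360
    map_height: int = 180
    radial_window: tuple[float, float] = (0.5, 1.5)
    radial_step: float | None = None  # um; None -> min voxel edge / 2
    ray_statistic: str = "max"
    interpolated: bool = True

    def __post_init__(self):
        r_lo, r_hi = self.radial_window
        if not (0 < r_lo < 1 < r_hi):
            raise ValueError("radial_window must satisfy 0 < r_lo < 1 < r_hi")
        if self.map_width < 2 or self.map_height < 2:
            raise ValueError("map sizes must be >= 2")
        if self.radial_step is not None and self.radial_step <= 0:
            raise ValueError("radial_step must be positive")
        if self.ray_statistic not in ("max", "mean", "sum"):
            raise ValueError("ray_statistic must be max, mean or sum")
        if self.unfold_axis.upper() not in ("X", "Y", "Z"):
            raise ValueError("unfold_axis must be X, Y or Z")
        object.__setattr__(self, "unfold_axis", self.unfold_axis.upper())

    def step_um(self, spacing) -> float:
        return self.radial_step if self.radial_step is not None else spacing.min / 2.0


@dataclass
class MapImage:
    """Rendered 2D intensity map with validity mask and provenance table."""

    values: np.ndarray  # (H, W) float
    mask: np.ndarray  # (H, W) bool
    options: UnfoldOptions
    crossref: pd.DataFrame  # one row per valid map pixel
    t: int = 0
    c: int = 0


@dataclass
class HeightMap:
    """Signed surface elevation (um) relative to the reference ellipsoid."""

    elevation: np.ndarray  # (H, W) float, NaN outside mask
    mask: np.ndarray
    options: UnfoldOptions


def build_direction_grid(options: UnfoldOptions):
    """Per-pixel spherical coordinates and unit directions of the map raster.

    Returns ``(phi, lam, directions, mask)`` with shapes (H, W), (H, W),
    (H, W, 3) and (H, W).  Pixel centers span the projection's natural
    bounding box; ``mask`` is True where the pull-back lands on the sphere.
    """
    x, y = map_pixel_centers(options.projection, options.map_width, options.map_height)
    phi, lam = inverse_project(options.projection, x, y)
    mask = ~np.isnan(phi)
    u = np.zeros(phi.shape + (3,))
    u[mask] = direction_from_latlon(options.unfold_axis, phi[mask], lam[mask])
    return phi, lam, u, mask


def _sample_rays(stack: ImageStack, e: ReferenceEllipsoid, phi, lam, u, options: UnfoldOptions, t: int, c: int):
    """Cast radial rays for flat arrays of directions; vectorized core.

    Returns a dict of flat arrays: value, r_star, voxel (n, 3) as (z, y, x),
    valid.  Invalid rays (entirely outside the volume) have valid=False.
    """
    vol = np.asarray(stack.values[t, c], dtype=float)
    nz, ny, nx = vol.shape
    sp = stack.spacing
    step = options.step_um(sp)
    r_lo, r_hi = options.radial_window

    R = ellipsoid_radius(e, phi, lam)
    R = np.atleast_1d(R)
    n_rays = R.shape[0]
    n_steps = int(np.ceil((r_hi - r_lo) * float(R.max()) / step)) + 1
    radii = r_lo * R[:, None] + step * np.arange(n_steps)[None, :]
    in_window = radii <= r_hi * R[:, None] + 1e-12

    pos = e.center[None, None, :] + radii[:, :, None] * u[:, None, :]
    # continuous voxel indices: voxel i has its center at (i + 0.5) * d
    cx = pos[..., 0] / sp.dx - 0.5
    cy = pos[..., 1] / sp.dy - 0.5
    cz = pos[..., 2] / sp.dz - 0.5
    inside = (
        (cx > -0.5) & (cx < nx - 0.5)
        & (cy > -0.5) & (cy < ny - 0.5)
        & (cz > -0.5) & (cz < nz - 0.5)
    )
    valid_sample = in_window & inside

    # nearest-voxel indices (half-up rounding), shared by sampling and the
    # cross-reference table so both always agree exactly
    ix = np.clip(np.floor(cx + 0.5).astype(int), 0, nx - 1)
    iy = np.clip(np.floor(cy + 0.5).astype(int), 0, ny - 1)
    iz = np.clip(np.floor(cz + 0.5).astype(int), 0, nz - 1)
    if options.interpolated:
        coords = np.stack([cz.ravel(), cy.ravel(), cx.ravel()])
        samples = ndimage.map_coordinates(vol, coords, order=1, mode="nearest").reshape(radii.shape)
    else:
        samples = vol[iz, iy, ix]
    samples = np.where(valid_sample, samples, -np.inf)

    valid_ray = valid_sample.any(axis=1)
    k_max = np.argmax(samples, axis=1)  # first occurrence -> smallest radius on ties
    rows = np.arange(n_rays)
    r_star = radii[rows, k_max]

    if options.ray_statistic == "max":
        value = samples[rows, k_max]
        k_vox = k_max
    else:
        finite = np.where(valid_sample, samples, np.nan)
        with np.errstate(invalid="ignore"):
            value = np.nanmean(finite, axis=1) if options.ray_statistic == "mean" else np.nansum(finite, axis=1)
        # voxel reference: valid sample nearest the window-center radius
        r_mid = 0.5 * (r_lo + r_hi) * R
        dist = np.abs(radii - r_mid[:, None])
        dist[~valid_sample] = np.inf
        k_vox = np.argmin(dist, axis=1)

    vx = ix[rows, k_vox]
    vy = iy[rows, k_vox]
    vz = iz[rows, k_vox]
    return {
        "value": value,
        "r_star": r_star,
        "voxel": np.column_stack([vz, vy, vx]),
        "valid": valid_ray,
        "R": R,
    }


def sample_radial_ray(stack: ImageStack, e: ReferenceEllipsoid, phi: float, lam: float, options: UnfoldOptions, t: int = 0, c: int = 0):
    """Sample one radial ray; returns (value, r_star, (z, y, x)) or None.

    ``None`` signals that the whole ray exits the volume ("no valid sample").
    """
    u = direction_from_latlon(options.unfold_axis, phi, lam)[None, :]
    res = _sample_rays(stack, e, np.atleast_1d(phi), np.atleast_1d(lam), u, options, t, c)
    if not res["valid"][0]:
        return None
    return float(res["value"][0]), float(res["r_star"][0]), tuple(int(v) for v in res["voxel"][0])


def unfold_intensity(stack: ImageStack, e: ReferenceEllipsoid, options: UnfoldOptions, t: int = 0, c: int = 0) -> MapImage:
    """Rasterize the map for one (t, c) and record the cross-reference table."""
    phi, lam, u, mask = build_direction_grid(options)
    idx = np.nonzero(mask)
    res = _sample_rays(stack, e, phi[idx], lam[idx], u[idx], options, t, c)
    if not res["valid"].any():
        raise ValueError("ellipsoid entirely outside the stack: no ray produced a sample")

    values = np.full(mask.shape, np.nan)
    out_mask = np.zeros_like(mask)
    rows, cols = idx[0][res["valid"]], idx[1][res["valid"]]
    values[rows, cols] = res["value"][res["valid"]]
    out_mask[rows, cols] = True

    v = res["valid"]
    elev = res["r_star"][v] - res["R"][v]
    table = pd.DataFrame({
        "map_x": cols,
        "map_y": rows,
        "phi": phi[idx][v],
        "lam": lam[idx][v],
        "r_star": res["r_star"][v],
        "elevation_um": elev,
        "t": t,
        "c": c,
        "z": res["voxel"][v, 0],
        "y": res["voxel"][v, 1],
        "x": res["voxel"][v, 2],
    })
    return MapImage(values=values, mask=out_mask, options=options, crossref=table, t=t, c=c)


def unfold_height(stack: ImageStack, e: ReferenceEllipsoid, options: UnfoldOptions, t: int = 0, c: int = 0) -> HeightMap:
    """Height map: elevation of the radial intensity peak above the ellipsoid.

    The ray statistic is forced to ``max`` (the detected surface is the
    radial intensity maximum); positive elevation = protrusion, negative =
    indentation.
    """
    opts = replace(options, ray_statistic="max")
    m = unfold_intensity(stack, e, opts, t, c)
    elevation = np.full(m.mask.shape, np.nan)
    elevation[m.crossref["map_y"], m.crossref["map_x"]] = m.crossref["elevation_um"]
    return HeightMap(elevation=elevation, mask=m.mask, options=opts)


def apply_hypsometric_lut(h: HeightMap, symmetric_range: float | None = None) -> np.ndarray:
    """Render a height map with a diverging hypsometric color table.

    Zero elevation maps exactly to the table's neutral midpoint; the color
    range spans +-max|elevation| unless ``symmetric_range`` overrides it.
    Returns an (H, W, 3) uint8 raster; pixels outside the mask are black.
    """
    if not h.mask.any():
        raise ValueError("empty mask: nothing to render")
    elev = h.elevation
    if symmetric_range is None:
        symmetric_range = float(np.nanmax(np.abs(elev[h.mask])))
        if symmetric_range == 0:
            symmetric_range = 1.0
    # odd-length table so elevation 0 hits the neutral midpoint entry exactly
    base = get_lut("hypsometric")
    n = 255
    xs = np.linspace(0, 1, n)
    table = np.column_stack([
        np.interp(xs, np.linspace(0, 1, len(base)), base[:, k]) for k in range(3)
    ])
    norm = np.clip((elev + symmetric_range) / (2 * symmetric_range), 0.0, 1.0)
    idx = np.round(np.nan_to_num(norm, nan=0.0) * (n - 1)).astype(int)
    rgb = np.zeros(elev.shape + (3,), dtype=np.uint8)
    rgb[h.mask] = np.round(table[idx[h.mask]] * 255).astype(np.uint8)
    return rgb


def save_crossref_table(table: pd.DataFrame, path) -> None:
    """Serialize a cross-reference table as tab-separated text."""
    table.to_csv(Path(path), sep="\t", index=False, columns=CROSSREF_COLUMNS)


def load_crossref_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
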