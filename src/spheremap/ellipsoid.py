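"""Surface segmentation and axis-aligned reference-ellipsoid fitting.

The reference ellipsoid is the geometric baseline of the whole pipeline: the
map is rasterized by casting rays around it, and surface elevation is
measured relative to it (the cartographic analogue of mean sea level).
Only axis-aligned ellipsoids are fitted; the unfold axis (X, Y or Z) selects
which semi-axis acts as the pole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "SurfacePointCloud",
    "ReferenceEllipsoid",
    "extract_surface_points",
    "fit_ellipsoid",
    "ellipsoid_radius",
    "direction_from_latlon",
    "latlon_from_direction",
    "save_ellipsoid",
    "load_ellipsoid",
]

_AXES = ("X", "Y", "Z")

# pole convention: lat = +pi/2 points along +pole_axis; (lat=0, lon=0) points
# along the first remaining axis in X<Y<Z order, (lat=0, lon=pi/2) along the
# second.  Component order below is (x, y, z).
_FRAME = {
    # pole_axis: (index of pole, index of lon-0 axis, index of lon-90 axis)
    "X": (0, 1, 2),
    "Y": (1, 0, 2),
    "Z": (2, 0, 1),
}


@dataclass
class SurfacePointCloud:
    """Weighted 3D points (physical um) marking the labeled surface."""

    points: np.ndarray  # (n, 3) as (x, y, z) um
    weights: np.ndarray  # (n,) non-negative

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if self.weights.shape != (self.points.shape[0],):
            raise ValueError("weights must be (n,)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points must be finite")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class ReferenceEllipsoid:
    """Axis-aligned ellipsoid: center (um), semi-axes (a, b, c) along X, Y, Z."""

    center: np.ndarray  # (3,) um, (x, y, z)
    semi_axes: np.ndarray  # (3,) um
    pole_axis: str = "Z"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float).reshape(3)
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be strictly positive")
        self.pole_axis = self.pole_axis.upper()
        if self.pole_axis not in _AXES:
            raise ValueError("pole_axis must be one of X, Y, Z")

    def check_inside(self, bounds_um: tuple[float, float, float]) -> float:
        """Fraction of surface directions whose surface point lies inside the
        physical box [0, bounds_um]; warns when more than half exit."""
        rng = np.random.default_rng(0)
        u = rng.normal(size=(2048, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = 1.0 / np.sqrt(np.sum((u / self.semi_axes) ** 2, axis=1))
        p = self.center + r[:, None] * u
        inside = np.all((p >= 0) & (p <= np.asarray(bounds_um)), axis=1)
        frac = float(inside.mean())
        if frac < 0.5:
            warnings.warn(
                f"only {frac:.0%} of the ellipsoid surface lies inside the stack",
                stacklevel=2,
            )
        return frac


def direction_from_latlon(pole_axis: str, lat, lon):
    """Unit direction(s) (x, y, z) for latitude/longitude under the pole convention."""
    ip, i0, i1 = _FRAME[pole_axis.upper()]
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    lat, lon = np.broadcast_arrays(lat, lon)
    u = np.zeros(lat.shape + (3,))
    u[..., ip] = np.sin(lat)
    u[..., i0] = np.cos(lat) * np.cos(lon)
    u[..., i1] = np.cos(lat) * np.sin(lon)
    return u


def latlon_from_direction(pole_axis: str, v):
    """Inverse of :func:`direction_from_latlon` for arbitrary nonzero vectors."""
    ip, i0, i1 = _FRAME[pole_axis.upper()]
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1)
    lat = np.arcsin(np.clip(v[..., ip] / np.where(n == 0, 1.0, n), -1.0, 1.0))
    lon = np.arctan2(v[..., i1], v[..., i0])
    return lat, lon


def ellipsoid_radius(e: ReferenceEllipsoid, lat, lon):
    """Distance from the center to the surface along direction (lat, lon), um.

    Closed form r = 1 / sqrt(ux^2/a^2 + uy^2/b^2 + uz^2/c^2).
    """
    u = direction_from_latlon(e.pole_axis, lat, lon)
    r = 1.0 / np.sqrt(np.sum((u / e.semi_axes) ** 2, axis=-1))
    return float(r) if np.ndim(lat) == 0 and np.ndim(lon) == 0 else r


def extract_surface_points(
    stack,
    t: int = 0,
    c: int = 0,
    method: str | float = "otsu",
    keep_largest_component: bool = True,
) -> SurfacePointCloud:
    """Threshold one (t, c) volume into an intensity-weighted point cloud.

    ``method`` is either ``"otsu"`` (automatic) or an absolute threshold.
    Voxels strictly above the threshold become points at their physical
    voxel-center coordinates, weighted by intensity.  With
    ``keep_largest_component`` (default) only the largest 26-connected
    component survives, discarding debris and hot pixels.
    """
    vol = stack.values[t, c]  # (z, y, x)
    if method == "otsu":
        thr = float(threshold_otsu(np.asarray(vol, dtype=float)))
    else:
        thr = float(method)
    mask = vol > thr
    if not mask.any():
        raise ValueError("empty result: no voxel above the threshold")
    if keep_largest_component:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    zz, yy, xx = np.nonzero(mask)
    sp = stack.spacing
    pts = np.column_stack([
        (xx + 0.5) * sp.dx,
        (yy + 0.5) * sp.dy,
        (zz + 0.5) * sp.dz,
    ])
    return SurfacePointCloud(points=pts, weights=np.asarray(vol[mask], dtype=float))


def fit_ellipsoid(cloud: SurfacePointCloud, pole_axis: str = "Z") -> ReferenceEllipsoid:
    """Weighted least-squares fit of an axis-aligned ellipsoid to a point cloud.

    Solves the linear quadric A x^2 + B y^2 + C z^2 + D x + E y + F z = 1 in
    the weighted least-squares sense, then converts to center/semi-axes:
    center = (-D/2A, -E/2B, -F/2C), a = sqrt(G/A) with
    G = 1 + D^2/4A + E^2/4B + F^2/4C.

    Raises ``ValueError`` for fewer than 9 points or a degenerate fit
    (non-positive quadratic coefficient, reported per axis).
    """
    if len(cloud) < 9:
        raise ValueError("ellipsoid fit requires at least 9 points")
    p = cloud.points
    spread = p.max(axis=0) - p.min(axis=0)
    for axis, s in zip(_AXES, spread):
        if s <= 1e-9 * max(spread.max(), 1.0):
            raise ValueError(f"degenerate ellipsoid fit: points are coplanar along axis {axis}")
    w = np.sqrt(np.maximum(cloud.weights, 0.0))
    if not np.any(w > 0):
        w = np.ones(len(cloud))
    design = np.column_stack([p**2, p])  # [x^2, y^2, z^2, x, y, z]
    coef, *_ = np.linalg.lstsq(design * w[:, None], np.ones(len(cloud)) * w, rcond=None)
    quad, lin = coef[:3], coef[3:]
    # the quadric is defined up to the fixed right-hand side 1, so a valid
    # ellipsoid may come out with all-negative quadratic coefficients
    # (whenever |center|^2 exceeds the squared mean radius); only a zero or
    # sign-inconsistent coefficient is degenerate
    majority = np.sign(np.sum(np.sign(quad))) or 1.0
    for axis, q in zip(_AXES, quad):
        if q == 0 or np.sign(q) != majority:
            raise ValueError(f"degenerate ellipsoid fit: bad quadratic coefficient on axis {axis}")
    center = -lin / (2.0 * quad)
    g = 1.0 + np.sum(lin**2 / (4.0 * quad))
    semi2 = g / quad
    if np.any(semi2 <= 0):
        axis = _AXES[int(np.argmin(semi2))]
        raise ValueError(f"degenerate ellipsoid fit: imaginary semi-axis on axis {axis}")
    semi = np.sqrt(semi2)
    return ReferenceEllipsoid(center=center, semi_axes=semi, pole_axis=pole_axis)


def save_ellipsoid(e: ReferenceEllipsoid, path) -> None:
    """Write the ellipsoid as a plain-text key/value sidecar (units: um)."""
    lines = [
        "# reference ellipsoid sidecar (units: um)",
        f"center_x = {float(e.center[0])!r}",
        f"center_y = {float(e.center[1])!r}",
        f"center_z = {float(e.center[2])!r}",
        f"semi_a = {float(e.semi_axes[0])!r}",
        f"semi_b = {float(e.semi_axes[1])!r}",
        f"semi_c = {float(e.semi_axes[2])!r}",
        f"pole_axis = {e.pole_axis}",
        "units = um",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_ellipsoid(path) -> ReferenceEllipsoid:
    """Read an ellipsoid sidecar written by :func:`save_ellipsoid`."""
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()
    center = [float(kv[f"center_{a}"]) for a in "xyz"]
    semi = [float(kv[f"semi_{a}"]) for a in "abc"]
    return ReferenceEllipsoid(center=center, semi_axes=semi, pole_axis=kv.get("pole_axis", "Z"))
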