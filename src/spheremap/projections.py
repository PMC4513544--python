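"""Forward and inverse map-projection mathematics on the unit sphere.

Nine classical projections are supported: equirectangular, Mercator, Braun,
Miller, Lambert-cylindrical, sinusoidal, Mollweide, Wagner VI and Bonne.
All formulas use the unit sphere; physical scale enters the pipeline only
when the stack is sampled around the reference ellipsoid.

Conventions
-----------
Latitude ``phi`` in [-pi/2, pi/2], longitude ``lam`` normalized into
(-pi, pi]; the map seam sits at the lam = -pi side.  Map coordinates are
dimensionless reals.  All functions are vectorized over numpy arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProjectionSpec",
    "list_projections",
    "normalize_lon",
    "forward_project",
    "inverse_project",
    "solve_mollweide_theta",
    "projection_domain_mask",
    "projection_extent",
]

_PROJECTION_NAMES = (
    "equirectangular",
    "mercator",
    "braun",
    "miller",
    "lambert_cylindrical",
    "sinusoidal",
    "mollweide",
    "wagner6",
    "bonne",
)

_SQRT2 = np.sqrt(2.0)


def list_projections() -> list[str]:
    """Return the names of the nine supported projections, stable order."""
    return list(_PROJECTION_NAMES)


def normalize_lon(lam):
    """Normalize longitude(s) into (-pi, pi]."""
    lam = np.asarray(lam, dtype=float)
    out = np.mod(-lam + np.pi, 2.0 * np.pi)
    out = np.pi - out
    # mod can yield -pi for inputs at the seam; fold onto +pi
    out = np.where(out <= -np.pi, np.pi, out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ProjectionSpec:
    """A named projection plus its free parameters.

    Parameters
    ----------
    name:
        One of the nine registry names (case-insensitive).
    standard_parallel:
        Bonne standard parallel phi_1 in (0, pi/2); ignored elsewhere.
    lat_clamp:
        Latitude clamp for the unbounded Mercator/Braun maps, in (0, pi/2).
    """

    name: str
    standard_parallel: float = np.pi / 4
    lat_clamp: float = np.deg2rad(85.0)

    def __post_init__(self):
        object.__setattr__(self, "name", self.name.lower())
        if self.name not in _PROJECTION_NAMES:
            raise ValueError(
                f"unknown projection {self.name!r}; choose from {_PROJECTION_NAMES}"
            )
        if not 0.0 < self.standard_parallel < np.pi / 2:
            raise ValueError("standard_parallel must lie in (0, pi/2)")
        if not 0.0 < self.lat_clamp < np.pi / 2:
            raise ValueError("lat_clamp must lie in (0, pi/2)")


def solve_mollweide_theta(phi, tol: float = 1e-12, max_iter: int = 50):
    """Solve the Mollweide auxiliary equation 2*theta + sin(2*theta) = pi*sin(phi).

    Newton iteration from theta0 = phi; the poles are short-circuited to
    +-pi/2 where the derivative vanishes.  Raises ``RuntimeError`` on
    non-convergence (a defect, not an expected path).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    phi_in = np.asarray(phi, dtype=float)
    scalar = phi_in.ndim == 0
    shape = phi_in.shape
    phi_arr = np.atleast_1d(phi_in).ravel()
    theta = phi_arr.copy()
    target = np.pi * np.sin(phi_arr)
    pole = np.isclose(np.abs(phi_arr), np.pi / 2)
    theta[pole] = np.sign(phi_arr[pole]) * np.pi / 2
    active = ~pole
    for _ in range(max_iter):
        if not active.any():
            break
        t = theta[active]
        resid = 2.0 * t + np.sin(2.0 * t) - target[active]
        conv = np.abs(resid) < tol
        deriv = 2.0 + 2.0 * np.cos(2.0 * t)
        theta[active] = t - np.where(conv, 0.0, resid / np.maximum(deriv, 1e-300))
        idx = np.flatnonzero(active)
        active[idx[conv]] = False
    else:
        resid = 2.0 * theta + np.sin(2.0 * theta) - target
        if np.any(np.abs(resid[~pole]) >= tol):
            raise RuntimeError("Mollweide theta iteration failed to converge")
    return float(theta[0]) if scalar else theta.reshape(shape)


def _mercator_y(phi):
    return np.log(np.tan(np.pi / 4 + phi / 2))


def forward_project(spec: ProjectionSpec, phi, lam):
    """Map spherical (phi, lam) [rad] to planar (x, y) under ``spec``.

    Mercator and Braun latitudes are clamped to ``spec.lat_clamp`` (with a
    warning) because their y-extent is unbounded at the poles.
    Returns a pair of arrays (or floats for scalar input).
    """
    phi = np.asarray(phi, dtype=float)
    lam = np.asarray(normalize_lon(lam), dtype=float)
    scalar = phi.ndim == 0 and lam.ndim == 0
    phi, lam = np.atleast_1d(phi), np.atleast_1d(lam)
    phi, lam = np.broadcast_arrays(phi, lam)
    name = spec.name

    if name in ("mercator", "braun"):
        if np.any(np.abs(phi) > spec.lat_clamp + 1e-12):
            warnings.warn(
                f"latitudes beyond the {np.rad2deg(spec.lat_clamp):.1f} deg clamp "
                f"were clamped for the {name} projection",
                stacklevel=2,
            )
        phi = np.clip(phi, -spec.lat_clamp, spec.lat_clamp)

    if name == "equirectangular":
        x, y = lam, phi
    elif name == "mercator":
        x, y = lam, _mercator_y(phi)
    elif name == "braun":
        x, y = lam, 2.0 * np.tan(phi / 2)
    elif name == "miller":
        x, y = lam, 1.25 * np.log(np.tan(np.pi / 4 + 0.4 * phi))
    elif name == "lambert_cylindrical":
        x, y = lam, np.sin(phi)
    elif name == "sinusoidal":
        x, y = lam * np.cos(phi), phi
    elif name == "mollweide":
        theta = solve_mollweide_theta(phi)
        x = (2.0 * _SQRT2 / np.pi) * lam * np.cos(theta)
        y = _SQRT2 * np.sin(theta)
    elif name == "wagner6":
        x = lam * np.sqrt(1.0 - 3.0 * (phi / np.pi) ** 2)
        y = phi
    elif name == "bonne":
        # y is offset by +phi1 relative to the textbook form so the equator
        # center maps to the origin; a rigid shift, so equal-area is kept
        phi1 = spec.standard_parallel
        cot1 = 1.0 / np.tan(phi1)
        rho = cot1 + phi1 - phi
        e = lam * np.cos(phi) / rho
        x = rho * np.sin(e)
        y = (cot1 + phi1) - rho * np.cos(e)
    else:  # pragma: no cover
        raise AssertionError(name)

    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if scalar:
        return float(x[()] if x.ndim == 0 else x[0]), float(y[()] if y.ndim == 0 else y[0])
    return x + 0.0, y + 0.0


def inverse_project(spec: ProjectionSpec, x, y):
    """Pull planar (x, y) back to spherical (phi, lam); NaN outside the domain.

    All nine inverses are exact and analytic.  Points whose pull-back falls
    outside [-pi/2, pi/2] x (-pi, pi] are flagged by NaN in both outputs
    ("outside domain").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0 and y.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    x, y = np.broadcast_arrays(x, y)
    x, y = x.astype(float), y.astype(float)
    name = spec.name
    tol = 1e-9  # admit boundary points up to round-off

    with np.errstate(invalid="ignore", divide="ignore"):
        if name == "equirectangular":
            phi, lam = y.copy(), x.copy()
        elif name == "mercator":
            phi = 2.0 * np.arctan(np.exp(y)) - np.pi / 2
            lam = x.copy()
        elif name == "braun":
            phi = 2.0 * np.arctan(y / 2.0)
            lam = x.copy()
        elif name == "miller":
            phi = 2.5 * np.arctan(np.exp(0.8 * y)) - 0.625 * np.pi
            lam = x.copy()
        elif name == "lambert_cylindrical":
            phi = np.arcsin(np.clip(y, -1.0, 1.0))
            phi = np.where(np.abs(y) > 1.0 + tol, np.nan, phi)
            lam = x.copy()
        elif name == "sinusoidal":
            phi = y.copy()
            phi = np.where(np.abs(phi) > np.pi / 2 + tol, np.nan, phi)
            cosphi = np.cos(phi)
            lam = np.where(cosphi > 0, x / cosphi, np.where(np.abs(x) <= tol, 0.0, np.nan))
        elif name == "mollweide":
            s = y / _SQRT2
            theta = np.arcsin(np.clip(s, -1.0, 1.0))
            theta = np.where(np.abs(s) > 1.0 + tol, np.nan, theta)
            phi = np.arcsin(np.clip((2.0 * theta + np.sin(2.0 * theta)) / np.pi, -1.0, 1.0))
            costheta = np.cos(theta)
            lam = np.where(
                costheta > 0,
                np.pi * x / (2.0 * _SQRT2 * costheta),
                np.where(np.abs(x) <= tol, 0.0, np.nan),
            )
        elif name == "wagner6":
            phi = y.copy()
            phi = np.where(np.abs(phi) > np.pi / 2 + tol, np.nan, phi)
            fac = np.sqrt(np.clip(1.0 - 3.0 * (phi / np.pi) ** 2, 0.0, None))
            lam = np.where(fac > 0, x / fac, np.where(np.abs(x) <= tol, 0.0, np.nan))
        elif name == "bonne":
            phi1 = spec.standard_parallel
            cot1 = 1.0 / np.tan(phi1)
            y0 = cot1 + phi1  # apex offset matching the forward map
            rho = np.sign(phi1) * np.hypot(x, y0 - y)
            phi = cot1 + phi1 - rho
            phi = np.where(np.abs(phi) > np.pi / 2 + tol, np.nan, phi)
            e = np.arctan2(x, y0 - y)
            cosphi = np.cos(phi)
            lam = np.where(cosphi > 0, rho * e / cosphi, np.where(np.abs(x) <= tol, 0.0, np.nan))
        else:  # pragma: no cover
            raise AssertionError(name)

        bad = (
            np.isnan(phi)
            | np.isnan(lam)
            | (np.abs(phi) > np.pi / 2 + tol)
            | (np.abs(lam) > np.pi + tol)
        )
        phi = np.where(bad, np.nan, np.clip(phi, -np.pi / 2, np.pi / 2))
        lam = np.where(bad, np.nan, normalize_lon(np.where(bad, 0.0, lam)))

    if scalar:
        return float(phi[0]), float(lam[0])
    return phi, lam


def projection_extent(spec: ProjectionSpec) -> tuple[float, float, float, float]:
    """Natural bounding box (xmin, xmax, ymin, ymax) of the full-sphere map.

    Cylindrical maps span |x| <= pi; y extent follows each projection's
    closed form (clamped for Mercator/Braun).  Bonne's outline is traced
    numerically along the lam = +-pi meridians.
    """
    name = spec.name
    if name == "equirectangular":
        return (-np.pi, np.pi, -np.pi / 2, np.pi / 2)
    if name == "mercator":
        ym = _mercator_y(spec.lat_clamp)
        return (-np.pi, np.pi, -ym, ym)
    if name == "braun":
        ym = 2.0 * np.tan(spec.lat_clamp / 2)
        return (-np.pi, np.pi, -ym, ym)
    if name == "miller":
        ym = 1.25 * np.log(np.tan(np.pi / 4 + 0.4 * np.pi / 2))
        return (-np.pi, np.pi, -ym, ym)
    if name == "lambert_cylindrical":
        return (-np.pi, np.pi, -1.0, 1.0)
    if name in ("sinusoidal", "wagner6"):
        return (-np.pi, np.pi, -np.pi / 2, np.pi / 2)
    if name == "mollweide":
        return (-2.0 * _SQRT2, 2.0 * _SQRT2, -_SQRT2, _SQRT2)
    if name == "bonne":
        phi = np.linspace(-np.pi / 2, np.pi / 2, 2001)
        xs, ys = [], []
        for lam in (-np.pi, np.pi, 0.0):
            x, y = forward_project(spec, phi, np.full_like(phi, lam))
            xs.append(x)
            ys.append(y)
        xs, ys = np.concatenate(xs), np.concatenate(ys)
        return (float(xs.min()), float(xs.max()), float(ys.min()), float(ys.max()))
    raise AssertionError(name)  # pragma: no cover


def projection_domain_mask(spec: ProjectionSpec, width: int, height: int) -> np.ndarray:
    """Boolean (height, width) raster: True where a pixel center has a preimage.

    Pixel centers are placed on the projection's natural bounding box
    (row 0 = top = +y) and pulled back with :func:`inverse_project`.
    """
    if width < 1 or height < 1:
        raise ValueError("width and height must be >= 1")
    x, y = map_pixel_centers(spec, width, height)
    phi, _ = inverse_project(spec, x, y)
    return ~np.isnan(phi)


def map_pixel_centers(spec: ProjectionSpec, width: int, height: int):
    """Planar coordinates of map pixel centers over the natural bounding box.

    Returns broadcastable (height, width) arrays (x, y); row 0 is the top of
    the map (largest y), matching image conventions.
    """
    xmin, xmax, ymin, ymax = projection_extent(spec)
    px = (np.arange(width) + 0.5) / width
    py = (np.arange(height) + 0.5) / height
    x = xmin + px * (xmax - xmin)
    y = ymax - py * (ymax - ymin)
    return np.broadcast_arrays(x[None, :], y[:, None])
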