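# Methods

## Model and procedure

`spheremap` assumes the specimen's labeled signal lies on (or near) a single
closed surface that is well approximated by an **axis-aligned ellipsoid**
with semi-axes (a, b, c) along the image X, Y, Z axes. Rotated ellipsoids
are deliberately out of scope: the unfolding axis the user chooses (X, Y or
Z) is the pole axis, which matches how stacks are acquired and keeps the
spherical coordinate frame unambiguous. One ellipsoid per (t, c) volume is
fitted by default; a fit can be pinned across time points via the plain-text
sidecar file so elevation baselines stay comparable in a time series.

The pipeline is strictly deterministic from segmentation onward: identical
inputs and options give bit-identical maps and cross-reference tables.

### Coordinate conventions

Voxel indices are 0-based; voxel (z, y, x) occupies the half-open physical
box [x·dx, (x+1)·dx) × [y·dy, (y+1)·dy) × [z·dz, (z+1)·dz) µm, so its center
is at ((x+0.5)·dx, …). Latitude φ ∈ [−π/2, π/2], longitude λ ∈ (−π, π]; the
map seam is fixed at the λ = −π side (longitudes normalize onto (−π, π], the
seam value −π folding to +π), which makes cross-referencing deterministic.
With pole axis P, φ = +π/2 points along +P and (φ=0, λ=0) points along the
first remaining axis in X<Y<Z order.

### Ellipsoid fitting

Voxels above the threshold (Otsu default; absolute override) become points
at voxel-center physical coordinates weighted by intensity, optionally
restricted to the largest 26-connected component (on by default — it removes
debris and hot pixels). The quadric A x² + B y² + C z² + D x + E y + F z = 1
is solved by weighted linear least squares and converted to center
(−D/2A, −E/2B, −F/2C) and semi-axes √(G/A) etc. with
G = 1 + D²/4A + E²/4B + F²/4C. Because the right-hand side is pinned to 1,
a valid ellipsoid whose center norm exceeds its mean radius produces an
all-negative coefficient triple; the conversion is sign-agnostic, and only
zero or sign-inconsistent coefficients (or an axis-aligned coplanar cloud)
are reported as degenerate, naming the offending axis. Intensity weighting
biases the fit toward the bright shell and makes it robust to faint haze.

### Projections

All nine projections are formulated on the unit sphere; physical scale
enters only through the ellipsoid radius during sampling. Notable choices:

- **Mercator/Braun** have unbounded y at the poles and are clamped at 85°
  by default (configurable), the common web-map convention.
- **Mollweide** solves 2θ + sin 2θ = π sin φ by Newton iteration from
  θ₀ = φ to |residual| < 1e-12 (≤ 50 iterations); the poles, where the
  derivative vanishes, short-circuit to ±π/2.
- **Bonne** (standard parallel π/4 by default, exposed as a parameter) is
  written in the apex form y = (cot φ₁ + φ₁) − ρ cos E so the equator center
  maps to the origin; this is a rigid shift of the textbook form and
  preserves the equal-area property.
- Inverses are exact and analytic for all nine; points pulling back outside
  [−π/2, π/2] × (−π, π] are flagged "outside domain" (NaN), which defines
  the per-projection raster mask (e.g. the 2:1 Mollweide ellipse).

Longitude is mathematically unrecoverable at the exact poles of the
equal-area pseudo-cylindrical projections (all meridians collapse to one
point); round-trip identity therefore holds everywhere except that λ at
|φ| = π/2 is reported as 0.

### Radial sampling and cross-referencing

Each masked map pixel's direction u is sampled at radii
r ∈ [r_lo·R, r_hi·R], default (0.5, 1.5)·R, step = min(dx, dy, dz)/2.
The window is intentionally wide: real nuclear/ER surfaces undulate around
the fitted ellipsoid. The ray statistic is max (surface = radial intensity
peak), with mean and sum available; ties at the maximum resolve to the
smallest radius (deterministic, innermost surface). "Pixel-interpolated"
selects trilinear stack sampling; the non-interpolated mode snaps each
sample to the nearest voxel (half-up rounding) using the *same* index
arithmetic for sampling and for the cross-reference table, which is what
makes the table exact in that mode: the stack value at every recorded voxel
equals the map value bit-for-bit. Rays whose samples all fall outside the
volume are removed from the mask; sampling is along central rays from the
ellipsoid center (not surface normals) — simpler, unambiguous at the poles,
and identical to normals for spheres.

Height maps force the max statistic and report r* − R(φ, λ) in µm. The
hypsometric rendering uses a 255-entry diverging table (odd length so zero
elevation hits the neutral midpoint entry exactly), spanning ±max|elevation|
unless overridden.

### Map-space ROIs measured on the stack

ROI polygons select map pixels by their centers (even-odd rule, boundary
included); the cross-reference table maps those pixels to voxels, which are
de-duplicated before averaging because rasterized projections reference a
voxel from several map pixels near the poles — without de-duplication polar
signal would be over-weighted. Means are always computed on original stack
intensities. Plot profiles, by contrast, are documented as *map-raster*
measurements (bilinear interpolation along the polyline, gaps where the line
leaves the mask), matching how such profiles are drawn in practice.

## Synthetic phantoms

The generator emulates fluorescently labeled near-spherical surfaces: a
radial Gaussian shell (σ = thickness/2; a binary option exists for
exact-value tests) whose local radius is the ellipsoid radius plus Gaussian
angular bump displacements, multiplied by an angular pattern — uniform,
4×8-style checkerboard tiles, bud-scar-like rings (bright annuli on a dark
surface), or a graticule. Every phantom returns its ground truth (true
ellipsoid, pattern function, bump list) so tests check the pipeline against
known geometry. Additive Gaussian noise and per-z-layer multiplicative
jitter (seeded `numpy` generator, mandatory seed whenever stochastic) stand
in for acquisition variability.

What the phantoms do **not** model: PSF blur, photon shot noise, spherical
aberration, depth-dependent attenuation, or multi-object scenes. Passing
tests therefore demonstrate the geometric and bookkeeping correctness of the
pipeline, not robustness to full optical realism.

The photoactivation simulator evolves a surface concentration on a
(φ, λ) cell-centered grid under the unit-sphere Laplace–Beltrami operator
with an explicit conservative finite-difference scheme: flux form in
latitude with zero flux through the poles, periodic in longitude, and the
two pole rows zonally averaged each sub-step (their longitudinal term
vanishes on zonally constant rows, which also removes the poles from the
stability constraint). A constant influx (intensity s⁻¹ sr⁻¹) is injected
inside the source cap. The frame interval dt is subdivided into sub-steps
chosen automatically to satisfy the CFL bound
dt_step ≤ [2D(1/Δφ² + 1/(cos²φ·Δλ²))]⁻¹ evaluated over the active rows;
an explicit violation raises an error naming the bound. The scheme conserves
injected mass to machine precision; the ~0.7% deviation reported against the
*analytic* cap area 2π(1−cos α) is the rasterization error of the discrete
cap on a 64×128 grid.

## Problem sizes and defaults

Tests and the acceptance script use 48³–80³ volumes, 0.75–1 µm voxels,
16–22 µm radii, 90×45 to 180×90 maps, 32×64 or 64×128 diffusion grids with
8 frames at dt = 2 s, D = 0.01–0.02 rad²/s (≈ 2.5–5 µm²/s on a 16 µm-radius
sphere, the right order for ER membrane proteins) and 8% per-layer jitter —
sizes at which a full pipeline run takes seconds while every feature spans
several voxels and map pixels. The time-series smoothness comparison uses
the package defaults for both arms (whole-map ROI cross-referenced to
voxels vs. per-frame Otsu mask on the central z-layer).

## Known limitations

- Only axis-aligned ellipsoids; strongly tilted specimens need re-slicing.
- Surface localization is the discrete radial argmax; elevation is
  quantized at the radial step (no sub-sample peak refinement, by design
  for determinism).
- One surface per stack; touching objects confuse the
  largest-component filter.
- Equal-area statistics hold at map-pixel granularity; strongly distorted
  projections (Mercator poles) remain unsuitable for area-weighted
  statistics, as in cartography.
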