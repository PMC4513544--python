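"""Tour of the nine supported map projections.

Prints, for each projection, its natural map extent, the fraction of the
bounding box with a spherical preimage (the domain mask), and whether it
preserves area (Jacobian equal to cos(latitude)).  Equal-area projections
are the right choice when surface densities or areas are compared on the
map; conformal (Mercator) preserves local shapes instead.
"""

import numpy as np

from spheremap.projections import (
    ProjectionSpec,
    forward_project,
    list_projections,
    projection_domain_mask,
    projection_extent,
)


def is_equal_area(spec, h=1e-6):
    P, L = np.meshgrid(np.linspace(-1.4, 1.4, 15), np.linspace(-2.8, 2.8, 15), indexing="ij")
    xp, yp = forward_project(spec, P + h, L)
    xm, ym = forward_project(spec, P - h, L)
    xl, yl = forward_project(spec, P, L + h)
    xr, yr = forward_project(spec, P, L - h)
    J = np.abs(((xp - xm) * (yl - yr) - (xl - xr) * (yp - ym)) / (4 * h * h))
    return np.abs(J - np.cos(P)).max() < 1e-6


print(f"{'projection':20s} {'x-extent':>10s} {'y-extent':>10s} {'mask':>6s} {'equal-area':>11s}")
for name in list_projections():
    spec = ProjectionSpec(name)
    xmin, xmax, ymin, ymax = projection_extent(spec)
    frac = projection_domain_mask(spec, 200, 100).mean()
    ea = "yes" if is_equal_area(spec) else "no"
    print(f"{name:20s} {xmax - xmin:10.3f} {ymax - ymin:10.3f} {frac:6.2f} {ea:>11s}")
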