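"""Quantitative measurements selected on the map, executed on the stack.

Regions of interest and profile lines are drawn in map pixel coordinates;
ROI statistics are computed on the *original* voxel data by following the
cross-reference table, never on map values (map-value measurement exists
only as the explicitly separate :func:`plot_profile`).  Voxels referenced by
several map pixels (common near the poles of rasterized projections) are
de-duplicated before averaging.

Pixel-coordinate convention: the center of map pixel (column x, row y) is at
(x + 0.5, y + 0.5), so an ROI polygon with vertices at integer coordinates
traces pixel boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .stack_io import ImageStack
from .unfolding import MapImage

__all__ = [
    "MapROI",
    "ProfileLine",
    "TimeSeriesMeasurement",
    "roi_to_voxels",
    "measure_roi_timeseries",
    "single_layer_measure",
    "plot_profile",
    "save_rois",
    "load_rois",
]


@dataclass
class MapROI:
    """Simple polygon in map pixel coordinates."""

    vertices: np.ndarray  # (n, 2) as (x, y)
    label: str = "roi"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("ROI needs at least 3 (x, y) vertices")
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError(f"ROI {self.label!r} polygon is self-intersecting or degenerate")

    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


@dataclass
class ProfileLine:
    """Polyline in map pixel coordinates, sampled every ``step`` pixels."""

    vertices: np.ndarray  # (n, 2) as (x, y)
    step: float = 1.0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("profile line needs at least 2 vertices")
        if self.step <= 0:
            raise ValueError("step must be positive")


@dataclass
class TimeSeriesMeasurement:
    """Mean intensity per time point, with provenance metadata."""

    t: np.ndarray  # strictly increasing time indices
    mean: np.ndarray  # stack intensity units
    n_voxels: np.ndarray
    roi_label: str
    mode: str  # "map_crossref" or "single_layer"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "mean": self.mean, "n_voxels": self.n_voxels,
            "roi": self.roi_label, "mode": self.mode,
        })


def roi_to_voxels(table: pd.DataFrame, roi: MapROI, deduplicate: bool = True) -> np.ndarray:
    """Stack voxel indices referenced by the map pixels inside an ROI.

    A map pixel belongs to the ROI when its center (x+0.5, y+0.5) lies
    inside or on the polygon boundary (even-odd rule).  Returns an (n, 3)
    integer array of (z, y, x), de-duplicated by default.
    """
    poly = roi.polygon()
    cx = table["map_x"].to_numpy() + 0.5
    cy = table["map_y"].to_numpy() + 0.5
    # covers = interior or boundary
    inside = shapely.covers(poly, shapely.points(np.column_stack([cx, cy])))
    if not inside.any():
        raise ValueError(f"ROI {roi.label!r} selects no valid map pixel")
    vox = table.loc[inside, ["z", "y", "x"]].to_numpy(dtype=int)
    if deduplicate:
        vox = np.unique(vox, axis=0)
    return vox


def measure_roi_timeseries(
    stack: ImageStack,
    tables: list[pd.DataFrame],
    roi: MapROI,
    c: int = 0,
    deduplicate: bool = True,
) -> TimeSeriesMeasurement:
    """Mean stack intensity inside a map ROI at every time point.

    ``tables`` holds one cross-reference table per t (same map geometry).
    Time points whose voxel set is empty are reported absent with a warning.
    """
    import warnings

    ts, means, counts = [], [], []
    for t, table in enumerate(tables):
        try:
            vox = roi_to_voxels(table, roi, deduplicate=deduplicate)
        except ValueError:
            warnings.warn(f"ROI {roi.label!r} empty at t={t}; point omitted")
            continue
        vals = stack.values[t, c][vox[:, 0], vox[:, 1], vox[:, 2]]
        ts.append(t)
        means.append(float(np.mean(vals)))
        counts.append(len(vox))
    return TimeSeriesMeasurement(
        t=np.asarray(ts), mean=np.asarray(means), n_voxels=np.asarray(counts),
        roi_label=roi.label, mode="map_crossref",
    )


def single_layer_measure(
    stack: ImageStack,
    z: int,
    threshold: str | float = "otsu",
    c: int = 0,
    t_range: tuple[int, int] | None = None,
) -> TimeSeriesMeasurement:
    """Mean intensity of the above-threshold area of one Z layer, per t.

    The conventional single-section alternative to map cross-referencing:
    at each time point the whole above-threshold area of layer ``z`` is
    averaged.  Raises if the threshold mask is empty at any time point.
    """
    from skimage.filters import threshold_otsu

    nt = stack.n_t
    t0, t1 = t_range if t_range is not None else (0, nt)
    ts, means, counts = [], [], []
    for t in range(t0, t1):
        layer = np.asarray(stack.values[t, c, z], dtype=float)
        thr = float(threshold_otsu(layer)) if threshold == "otsu" else float(threshold)
        m = layer > thr
        if not m.any():
            raise ValueError(f"empty threshold mask at t={t}, z={z}")
        ts.append(t)
        means.append(float(layer[m].mean()))
        counts.append(int(m.sum()))
    return TimeSeriesMeasurement(
        t=np.asarray(ts), mean=np.asarray(means), n_voxels=np.asarray(counts),
        roi_label=f"z={z}", mode="single_layer",
    )


def plot_profile(map_image: MapImage, line: ProfileLine):
    """Sample map values along a polyline by bilinear interpolation.

    Returns ``(positions, intensities, valid)``: arc position in map pixels,
    the interpolated map value, and a validity flag; positions falling
    outside the projection mask are gaps (NaN intensity, valid=False), never
    zero-filled.  Raises if no sample hits the mask.
    """
    from scipy import ndimage

    verts = line.vertices
    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seg_len.sum())
    if total == 0:
        raise ValueError("profile line has zero length")
    n_samples = int(np.floor(total / line.step)) + 1
    s = np.arange(n_samples) * line.step
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    xy = np.empty((n_samples, 2))
    for k in range(len(seg)):
        in_seg = (s >= cum[k]) & (s <= cum[k + 1] + 1e-12)
        f = np.zeros_like(s[in_seg]) if seg_len[k] == 0 else (s[in_seg] - cum[k]) / seg_len[k]
        xy[in_seg] = verts[k] + f[:, None] * seg[k]

    # map raster indexed [row=y, col=x]; pixel centers at (x+0.5, y+0.5)
    rows = xy[:, 1] - 0.5
    cols = xy[:, 0] - 0.5
    vals = np.where(map_image.mask, map_image.values, 0.0)
    intensity = ndimage.map_coordinates(vals, [rows, cols], order=1, mode="nearest")
    mask_near = ndimage.map_coordinates(
        map_image.mask.astype(float), [rows, cols], order=1, mode="constant", cval=0.0
    )
    h, w = map_image.mask.shape
    in_raster = (cols > -0.5) & (cols < w - 0.5) & (rows > -0.5) & (rows < h - 0.5)
    valid = (mask_near >= 1.0 - 1e-9) & in_raster
    if not valid.any():
        raise ValueError("profile line does not intersect the map mask")
    intensity = np.where(valid, intensity, np.nan)
    return s, intensity, valid


# ---------------------------------------------------------------------------
# plain-text ROI / polyline files: label line, then one "x y" pair per line,
# ROIs separated by blank lines


def save_rois(rois, path) -> None:
    blocks = []
    for roi in rois:
        lines = [roi.label] + [f"{x:g} {y:g}" for x, y in roi.vertices]
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")


def load_rois(path) -> list[MapROI]:
    text = Path(path).read_text()
    rois = []
    for block in text.strip().split("\n\n"):
        lines = [ln for ln in block.strip().splitlines() if ln.strip()]
        if not lines:
            continue
        label = lines[0].strip()
        verts = [tuple(map(float, ln.split())) for ln in lines[1:]]
        rois.append(MapROI(vertices=np.asarray(verts), label=label))
    return rois
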