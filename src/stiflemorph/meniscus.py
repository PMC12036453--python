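"""Regional meniscus heights and widths.

Protocol: rotate the meniscus to an anatomic frame (+x lateral, +y anterior,
+z superior), then measure three regions — the central body from the middle
three coronal slices at the arc apex, and the anterior/posterior horns from
the middle three sagittal slices split by the sign of y. Each slice yields
ten equally spaced station measurements; the slice value is the station
maximum and the region value is the mean over the three slices (max within
slice, mean across slices).

Frame recovery assumes the input cloud is roughly anatomically oriented
already (as exported segmentations are); principal-axis signs are chosen
nearest the input orientation, and the lateral axis is oriented by the
side flag via the arc's bulge direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mesh_io import SurfacePointCloud, TriangleMesh, mesh_to_points

REGIONS = ("anterior", "central", "posterior")


class MeniscusAlignmentError(ValueError):
    """Cloud is degenerate (flat or spherical) for meniscus alignment."""


class MeniscusMeasurementError(ValueError):
    """A region slice is empty or unmeasurable."""


@dataclass
class MeniscusFrame:
    """Meniscus point cloud in the anatomic frame, centered at its centroid."""

    points: np.ndarray  # (n, 3)
    side: str  # "medial" | "lateral"
    rotation: np.ndarray  # (3, 3), rows are the anatomic x, y, z directions
    centroid: np.ndarray  # original-frame centroid removed before rotating


@dataclass
class RegionSlices:
    region: str  # "anterior" | "central" | "posterior"
    plane: str  # "coronal" | "sagittal"
    slices: list[np.ndarray]  # 3 x (m, 2): columns (in-plane horizontal, height z)


@dataclass
class MeniscusRegionMeasure:
    side: str
    region: str
    height: float  # mm, mean of the 3 per-slice heights
    width: float  # mm
    per_slice: list[tuple[float, float]]  # 3 x (height, width)


def _fit_circle_center(xy: np.ndarray) -> np.ndarray:
    """Least-squares (Kasa) circle-center fit to 2D points."""
    a = np.column_stack([2.0 * xy[:, 0], 2.0 * xy[:, 1], np.ones(len(xy))])
    b = (xy**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:2]


def align_meniscus(cloud: SurfacePointCloud, side: str) -> MeniscusFrame:
    """Map the cloud's principal plane to x-y and orient the anatomic axes.

    z is the smallest-variance direction (sign nearest the input +z); the
    lateral axis x points along (lateral) or against (medial) the arc's bulge,
    found from the offset of the centroid from a fitted arc center; y = z x x.
    """
    if side not in ("medial", "lateral"):
        raise ValueError(f"side must be 'medial' or 'lateral', got {side!r}")
    pts = np.asarray(cloud.points, dtype=float)
    if len(pts) < 100:
        raise MeniscusAlignmentError(
            f"{cloud.label}: need >= 100 points, got {len(pts)}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / (len(pts) - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] < 1e-15 * evals[2]:
        raise MeniscusAlignmentError(f"{cloud.label}: flat (coplanar) cloud")
    if evals[2] / evals[0] < 2.0:
        raise MeniscusAlignmentError(
            f"{cloud.label}: near-spherical cloud, no principal plane"
        )

    z_dir = evecs[:, 0]
    if z_dir[2] < 0:
        z_dir = -z_dir

    # in-plane coordinates w.r.t. the two larger principal directions
    u, v = evecs[:, 2], evecs[:, 1]
    inplane = np.column_stack([centered @ u, centered @ v])
    center_uv = _fit_circle_center(inplane)
    bulge_uv = -center_uv  # centroid (origin of inplane coords) minus arc center
    norm = np.linalg.norm(bulge_uv)
    if norm < 1e-12:
        raise MeniscusAlignmentError(f"{cloud.label}: no detectable arc bulge")
    bulge = (bulge_uv[0] * u + bulge_uv[1] * v) / norm
    bulge -= np.dot(bulge, z_dir) * z_dir
    bulge /= np.linalg.norm(bulge)

    x_dir = bulge if side == "lateral" else -bulge
    y_dir = np.cross(z_dir, x_dir)
    rot = np.vstack([x_dir, y_dir, z_dir])
    return MeniscusFrame(
        points=centered @ rot.T, side=side, rotation=rot, centroid=centroid
    )


def _three_bins(values: np.ndarray, increment: float) -> tuple[np.ndarray, int, float]:
    """Bin indices for each value, the center-bin index (containing the
    median, clipped so one bin on each side exists), and the bin origin."""
    v_min = float(values.min())
    extent = float(values.max()) - v_min
    n_bins = max(3, math.ceil(extent / increment - 1e-9))
    idx = np.floor((values - v_min) / increment).astype(int)
    np.clip(idx, 0, n_bins - 1, out=idx)
    med = float(np.median(values))
    c = int(np.clip(math.floor((med - v_min) / increment), 1, n_bins - 2))
    return idx, c, v_min


def select_region_slices(
    frame: MeniscusFrame, region: str, increment: float
) -> RegionSlices:
    """Extract the middle three slices for one region.

    central: coronal (y) bins centered on the median y of the bulge-side
    points, keeping only bulge-side points; anterior/posterior: sagittal (x)
    bins centered on the median x of the full cloud, split by the sign of y.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if increment <= 0:
        raise ValueError("increment must be > 0")
    pts = frame.points
    sx = 1.0 if frame.side == "lateral" else -1.0

    if region == "central":
        bulge_mask = pts[:, 0] * sx > 0
        sub = pts[bulge_mask]
        if len(sub) < 3:
            raise MeniscusMeasurementError(f"central region: no bulge-side points")
        idx, c, _ = _three_bins(sub[:, 1], increment)
        slices = []
        for k in (c - 1, c, c + 1):
            sl = sub[idx == k]
            if len(sl) == 0:
                raise MeniscusMeasurementError(
                    f"central region: empty coronal bin {k}"
                )
            slices.append(np.column_stack([sl[:, 0], sl[:, 2]]))
        return RegionSlices(region="central", plane="coronal", slices=slices)

    idx, c, _ = _three_bins(pts[:, 0], increment)
    keep_y = pts[:, 1] > 0 if region == "anterior" else pts[:, 1] < 0
    slices = []
    for k in (c - 1, c, c + 1):
        sl = pts[(idx == k) & keep_y]
        if len(sl) == 0:
            raise MeniscusMeasurementError(f"{region} region: empty sagittal bin {k}")
        slices.append(np.column_stack([sl[:, 1], sl[:, 2]]))
    return RegionSlices(region=region, plane="sagittal", slices=slices)


def slice_height_width(
    slice_points: np.ndarray, n_stations: int = 10
) -> tuple[float, float, list[tuple[float, float]]]:
    """Station-based height and width of one 2D slice.

    The horizontal extent is split into ``n_stations`` equal stations; each
    station's height is the vertical extent of its points (empty stations are
    missing). Symmetrically for widths over vertical stations. The slice
    height/width is the maximum over stations.
    """
    pts = np.asarray(slice_points, dtype=float)
    if len(pts) == 0:
        raise MeniscusMeasurementError("empty slice")
    h, v = pts[:, 0], pts[:, 1]

    def station_extents(coord: np.ndarray, other: np.ndarray) -> np.ndarray:
        lo, hi = float(coord.min()), float(coord.max())
        span = hi - lo
        out = np.full(n_stations, np.nan)
        if span == 0.0:
            out[0] = float(other.max() - other.min())
            return out
        idx = np.floor((coord - lo) / span * n_stations).astype(int)
        np.clip(idx, 0, n_stations - 1, out=idx)
        for k in range(n_stations):
            sel = idx == k
            if sel.any():
                out[k] = float(other[sel].max() - other[sel].min())
        return out

    heights = station_extents(h, v)  # horizontal stations -> vertical extents
    widths = station_extents(v, h)  # vertical stations -> horizontal extents
    if np.all(np.isnan(heights)) or np.all(np.isnan(widths)):
        raise MeniscusMeasurementError("all stations empty")
    stations = [(float(heights[k]), float(widths[k])) for k in range(n_stations)]
    return float(np.nanmax(heights)), float(np.nanmax(widths)), stations


def region_measure(
    slices: RegionSlices, side: str = "", n_stations: int = 10
) -> MeniscusRegionMeasure:
    """Average the three per-slice (max-station) heights and widths."""
    if len(slices.slices) != 3:
        raise MeniscusMeasurementError(
            f"{slices.region}: expected 3 slices, got {len(slices.slices)}"
        )
    per_slice = []
    for i, sl in enumerate(slices.slices):
        try:
            height, width, _ = slice_height_width(sl, n_stations=n_stations)
        except MeniscusMeasurementError as exc:
            raise MeniscusMeasurementError(
                f"{slices.region} slice {i}: {exc}"
            ) from exc
        per_slice.append((height, width))
    hs = [h for h, _ in per_slice]
    ws = [w for _, w in per_slice]
    return MeniscusRegionMeasure(
        side=side,
        region=slices.region,
        height=float(np.mean(hs)),
        width=float(np.mean(ws)),
        per_slice=per_slice,
    )


def measure_meniscus(
    mesh: TriangleMesh, side: str, increment: float, n_stations: int = 10
) -> list[MeniscusRegionMeasure]:
    """End-to-end: mesh -> anatomic frame -> three regional measures."""
    cloud = mesh_to_points(mesh)
    frame = align_meniscus(cloud, side)
    out = []
    for region in REGIONS:
        slices = select_region_slices(frame, region, increment)
        out.append(region_measure(slices, side=side, n_stations=n_stations))
    return out
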