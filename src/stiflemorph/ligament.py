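"""Ligament cross-sectional-area profiles and midsubstance CSA.

Protocol: align the surface point cloud so its longitudinal (first principal)
axis maps to +z, section along z at the species increment (0.1 mm rat /
0.05 mm mouse), flatten each section onto its x-y plane, take the 2D convex
hull area per slice, and average the slices whose centers fall in the middle
50% of the occupied axial extent. Slices with fewer than 3 points are
recorded as missing (never zero) and excluded from the average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._geom import QhullError, convex_hull_area
from .mesh_io import SurfacePointCloud, TriangleMesh, mesh_to_points

#: First-to-second principal-variance ratio below which the cloud is flagged
#: as having no clearly preferred longitudinal axis.
NEAR_ISOTROPIC_RATIO = 1.5


class AlignmentError(ValueError):
    """Cloud is degenerate with respect to principal-axis alignment."""


class MorphometryError(ValueError):
    """Not enough valid slices to compute a midsubstance summary."""


@dataclass
class AlignedCloud:
    """Point cloud rotated so the longitudinal axis is +z."""

    points: np.ndarray  # (n, 3), centered and rotated
    rotation: np.ndarray  # (3, 3) proper orthonormal matrix applied
    axis_extent: tuple[float, float]
    label: str = ""
    warnings: list[str] = field(default_factory=list)


@dataclass
class SlicedProfile:
    """Per-slice axial positions and hull areas along the aligned z-axis."""

    increment: float
    z_centers: np.ndarray  # (k,), strictly increasing, constant spacing
    point_counts: np.ndarray  # (k,) int
    csa: np.ndarray  # (k,) float, NaN where the slice is missing
    z_min: float
    z_max: float
    label: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return len(self.z_centers)


@dataclass
class LigamentMorphometry:
    midsubstance_csa: float  # mm^2
    cv: float  # percent
    n_slices_used: int
    length: float  # mm, occupied axial extent
    label: str = ""
    warnings: list[str] = field(default_factory=list)


def _principal_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered points, eigenvalues (descending), eigenvectors (columns)."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / max(len(points) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return centered, evals[order], evecs[:, order]


def align_longitudinal(cloud: SurfacePointCloud) -> AlignedCloud:
    """Rotate so the direction of maximal variance maps to +z.

    Sign convention: the longer tail of the z-distribution about the median
    is positive. The remaining principal directions become x and y, forming
    a right-handed frame.
    """
    pts = np.asarray(cloud.points, dtype=float)
    if len(pts) < 10:
        raise AlignmentError(f"{cloud.label}: need >= 10 points, got {len(pts)}")
    centered, evals, evecs = _principal_frame(pts)
    if evals[0] <= 0 or evals[2] < 1e-12 * evals[0]:
        raise AlignmentError(f"{cloud.label}: coplanar or degenerate point cloud")

    warnings: list[str] = []
    if evals[0] / evals[1] < NEAR_ISOTROPIC_RATIO:
        warnings.append(
            f"near-isotropic cloud: principal variance ratio "
            f"{evals[0] / evals[1]:.3f} < {NEAR_ISOTROPIC_RATIO}"
        )

    # rows map old coords to (x, y, z) = (pc2, pc3, pc1)
    rot = np.vstack([evecs[:, 1], evecs[:, 2], evecs[:, 0]])
    if np.linalg.det(rot) < 0:
        rot[1] = -rot[1]
    z = centered @ rot[2]
    med = np.median(z)
    if (med - z.min()) > (z.max() - med):
        # flip z; flip x as well to stay right-handed
        rot[2] = -rot[2]
        rot[0] = -rot[0]
    aligned = centered @ rot.T
    return AlignedCloud(
        points=aligned,
        rotation=rot,
        axis_extent=(float(aligned[:, 2].min()), float(aligned[:, 2].max())),
        label=cloud.label,
        warnings=warnings,
    )


def slice_csa(slice_points: np.ndarray) -> float:
    """Area of the 2D convex hull of a slice's points projected to x-y.

    Returns NaN (missing) for < 3 points or a collinear projection.
    """
    pts = np.asarray(slice_points, dtype=float)
    if len(pts) < 3:
        return float("nan")
    try:
        return convex_hull_area(pts[:, :2])
    except QhullError:
        return float("nan")


def slice_along_axis(aligned: AlignedCloud, increment: float) -> SlicedProfile:
    """Partition points into contiguous half-open z-bins of the given width.

    Bins are [z_min + k*inc, z_min + (k+1)*inc); points exactly at z_max fall
    into the last bin. Each slice's CSA is the projected convex-hull area.
    """
    if increment <= 0:
        raise ValueError("increment must be > 0")
    pts = aligned.points
    z = pts[:, 2]
    z_min, z_max = aligned.axis_extent
    extent = z_max - z_min
    warnings = list(aligned.warnings)
    n_bins = max(1, math.ceil(extent / increment - 1e-9))
    if increment > extent:
        warnings.append(
            f"increment {increment} mm exceeds axial extent {extent:.4g} mm; "
            "single-slice profile"
        )
    idx = np.floor((z - z_min) / increment).astype(int)
    np.clip(idx, 0, n_bins - 1, out=idx)

    z_centers = z_min + (np.arange(n_bins) + 0.5) * increment
    counts = np.bincount(idx, minlength=n_bins)
    csa = np.full(n_bins, np.nan)
    for k in range(n_bins):
        if counts[k] >= 3:
            csa[k] = slice_csa(pts[idx == k])
    return SlicedProfile(
        increment=increment,
        z_centers=z_centers,
        point_counts=counts,
        csa=csa,
        z_min=z_min,
        z_max=z_max,
        label=aligned.label,
        warnings=warnings,
    )


def midsubstance_csa(profile: SlicedProfile) -> LigamentMorphometry:
    """Average CSA over slices whose centers lie in the middle 50% of the
    occupied axial extent (inclusive bounds); flared ends are excluded.

    CV is 100 * SD / mean over the included slices (n-1 denominator).
    """
    valid = ~np.isnan(profile.csa)
    if valid.sum() < 4:
        raise MorphometryError(
            f"{profile.label}: need >= 4 valid slices, got {int(valid.sum())}"
        )
    extent = profile.z_max - profile.z_min
    lo = profile.z_min + 0.25 * extent
    hi = profile.z_min + 0.75 * extent
    eps = 1e-9 * max(extent, 1.0)
    inside = (profile.z_centers >= lo - eps) & (profile.z_centers <= hi + eps) & valid
    n_used = int(inside.sum())
    if n_used < 2:
        raise MorphometryError(
            f"{profile.label}: fewer than 2 valid slices inside the middle 50%"
        )
    areas = profile.csa[inside]
    mean = float(areas.mean())
    sd = float(areas.std(ddof=1))
    return LigamentMorphometry(
        midsubstance_csa=mean,
        cv=100.0 * sd / mean if mean > 0 else float("nan"),
        n_slices_used=n_used,
        length=float(extent),
        label=profile.label,
        warnings=list(profile.warnings),
    )


def measure_ligament(
    mesh: TriangleMesh, increment: float
) -> LigamentMorphometry:
    """End-to-end: mesh -> point cloud -> alignment -> slicing -> midsubstance."""
    cloud = mesh_to_points(mesh)
    aligned = align_longitudinal(cloud)
    profile = slice_along_axis(aligned, increment)
    return midsubstance_csa(profile)
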