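"""Tibial plateau footprint area and CSA normalization.

The footprint comes either from a single-slice voxel mask (occupied volume
divided by slice height, i.e. count times in-plane voxel area) or from a
planar bone trace (shoelace polygon area times squared pixel size). Ligament
CSA is expressed as a percentage of the footprint on the 0-100 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from ._geom import shoelace_area
from .mesh_io import VoxelMask


@dataclass
class FootprintArea:
    area: float  # mm^2
    source: str  # "voxel_mask" | "planar_trace"
    voxel_size: tuple[float, float, float] | None = None
    trace_vertex_count: int | None = None

    def __post_init__(self) -> None:
        if not (self.area > 0):
            raise ValueError("footprint area must be > 0")


@dataclass
class NormalizedCSA:
    tissue: str
    csa: float  # mm^2
    footprint: float  # mm^2
    normalized: float  # percent, 100 * csa / footprint

    def __post_init__(self) -> None:
        expected = 100.0 * self.csa / self.footprint
        if self.normalized != expected:
            raise ValueError("stored normalized value does not match recomputation")


class MultiSliceMaskWarning(UserWarning):
    """Mask occupies more than one axial slice; volume/height is used anyway."""


def footprint_from_mask(mask: VoxelMask) -> FootprintArea:
    """Occupied volume divided by voxel height: count * dx * dy."""
    count = mask.occupied_count()
    if count == 0:
        raise ValueError("empty voxel mask")
    n_slices = mask.n_occupied_slices()
    if n_slices > 1:
        warnings.warn(
            f"mask occupies {n_slices} axial slices; expected a single slice "
            "(using occupied volume / voxel height regardless)",
            MultiSliceMaskWarning,
            stacklevel=2,
        )
    in_plane = tuple(
        s for i, s in enumerate(mask.voxel_size) if i != mask.axial_axis
    )
    area = count * in_plane[0] * in_plane[1]
    return FootprintArea(area=area, source="voxel_mask", voxel_size=mask.voxel_size)


def footprint_from_trace(polygon: np.ndarray, pixel_size: float = 1.0) -> FootprintArea:
    """Shoelace area of a simple planar bone trace, scaled by pixel size."""
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("trace must be an (n >= 3, 2) vertex array")
    shp = Polygon(poly)
    if not shp.is_simple or not shp.is_valid:
        raise ValueError("trace polygon is self-intersecting")
    area = shoelace_area(poly) * pixel_size**2
    return FootprintArea(
        area=area, source="planar_trace", trace_vertex_count=len(poly)
    )


def normalize_csa(csa: float, footprint: FootprintArea, tissue: str = "") -> NormalizedCSA:
    """CSA as a percentage of the tibial plateau footprint."""
    if footprint.area <= 0:
        raise ValueError("footprint area must be > 0")
    if csa < 0:
        raise ValueError("csa must be >= 0")
    return NormalizedCSA(
        tissue=tissue,
        csa=csa,
        footprint=footprint.area,
        normalized=100.0 * csa / footprint.area,
    )


def rasterize_polygon_mask(
    polygon: np.ndarray, voxel_size: tuple[float, float, float]
) -> VoxelMask:
    """Center-sampling rasterization of a planar polygon into a single-slice
    mask (validation harness for the mask-vs-trace comparison)."""
    poly = np.asarray(polygon, dtype=float)
    dx, dy, dz = voxel_size
    shp = Polygon(poly)
    x0, y0, x1, y1 = shp.bounds
    i0, i1 = int(np.floor(x0 / dx)) - 1, int(np.ceil(x1 / dx)) + 1
    j0, j1 = int(np.floor(y0 / dy)) - 1, int(np.ceil(y1 / dy)) + 1
    ii = np.arange(i0, i1 + 1)
    jj = np.arange(j0, j1 + 1)
    from shapely import contains_xy

    gx, gy = np.meshgrid((ii + 0.5) * dx, (jj + 0.5) * dy, indexing="ij")
    occ2d = contains_xy(shp, gx.ravel(), gy.ravel()).reshape(gx.shape)
    return VoxelMask(
        occupancy=occ2d[:, :, None],
        voxel_size=(dx, dy, dz),
        axis_roles={"axial_axis": 2},
    )
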