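"""Triangle-mesh and voxel-mask I/O.

All coordinates are millimetres. STL carries no unit metadata; the pipeline
declares a single mm-based convention so that the species slice increments
(0.1 mm / 0.05 mm) are meaningful.

Vertex welding is exact (bitwise coordinate match), never epsilon-based:
thin mouse-scale structures (~0.03 mm^2 sections) must not be collapsed by
tolerance merging.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Recognised tissue identifiers.
TISSUE_LABELS = ("ACL", "PCL", "MCL", "LCL", "MED_MEN", "LAT_MEN", "PLATEAU")

LIGAMENT_LABELS = ("ACL", "PCL", "MCL", "LCL")
MENISCUS_LABELS = ("MED_MEN", "LAT_MEN")

_BINARY_HEADER_BYTES = 80
_FACET_BYTES = 50  # 12 float32 + uint16 attribute


class STLFormatError(ValueError):
    """Unreadable or structurally invalid STL data."""


class DegenerateMeshError(ValueError):
    """Mesh violates the minimal nondegeneracy invariants."""


@dataclass
class TriangleMesh:
    """A welded triangle surface mesh of one segmented tissue (mm units)."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int
    label: str = ""
    species_tag: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DegenerateMeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DegenerateMeshError("faces must be an (m, 3) array")

    def validate(self) -> None:
        """Raise :class:`DegenerateMeshError` on any invariant violation."""
        if not np.all(np.isfinite(self.vertices)):
            raise DegenerateMeshError(f"{self.label}: non-finite vertex coordinates")
        if len(self.vertices) < 4 or len(self.faces) < 4:
            raise DegenerateMeshError(
                f"{self.label}: need >= 4 vertices and >= 4 faces, got "
                f"{len(self.vertices)} / {len(self.faces)}"
            )
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise DegenerateMeshError(f"{self.label}: face index out of range")
        if (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        ).any():
            raise DegenerateMeshError(f"{self.label}: face references a vertex twice")
        if self.bbox_diagonal() <= 0:
            raise DegenerateMeshError(f"{self.label}: zero bounding-box diagonal")

    def bbox_diagonal(self) -> float:
        extent = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(extent))

    def face_normals(self) -> np.ndarray:
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        a, b, c = (self.vertices[self.faces[:, i]] for i in range(3))
        fn = np.cross(b - a, c - a)  # magnitude = 2 * face area
        vn = np.zeros_like(self.vertices)
        for i in range(3):
            np.add.at(vn, self.faces[:, i], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm


@dataclass
class SurfacePointCloud:
    """The welded vertex set of a tissue mesh."""

    points: np.ndarray  # (n, 3)
    label: str = ""
    _centroid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        if self._centroid is None:
            self._centroid = self.points.mean(axis=0)
        return self._centroid

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class VoxelMask:
    """Boolean occupancy grid with physical voxel dimensions (mm)."""

    occupancy: np.ndarray  # (ni, nj, nk) bool
    voxel_size: tuple[float, float, float]
    axis_roles: dict = field(default_factory=lambda: {"axial_axis": 2})

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3D grid")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")
        if not self.occupancy.any():
            raise ValueError("voxel mask has no occupied voxel")

    @property
    def axial_axis(self) -> int:
        return int(self.axis_roles.get("axial_axis", 2))

    def occupied_count(self) -> int:
        return int(self.occupancy.sum())

    def n_occupied_slices(self) -> int:
        """Number of grid slices (along the axial axis) with any occupancy."""
        axes = tuple(i for i in range(3) if i != self.axial_axis)
        return int(self.occupancy.any(axis=axes).sum())


# ---------------------------------------------------------------------------
# STL reading / writing


def _weld(raw_vertices: np.ndarray, label: str, species_tag: str) -> TriangleMesh:
    """Build a mesh from a flat per-facet vertex list, welding exact duplicates."""
    if len(raw_vertices) == 0:
        raise DegenerateMeshError("STL contains no facets")
    unique, inverse = np.unique(raw_vertices, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriangleMesh(unique.astype(float), faces, label=label, species_tag=species_tag)


def _parse_ascii(text: str) -> np.ndarray:
    coords: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        parts = line.split()
        if parts and parts[0].lower() == "vertex":
            if len(parts) != 4:
                raise STLFormatError(f"malformed vertex line {lineno}: {line!r}")
            try:
                coords.append([float(p) for p in parts[1:]])
            except ValueError as exc:
                raise STLFormatError(f"bad coordinate on line {lineno}") from exc
    if len(coords) % 3 != 0:
        raise STLFormatError(
            f"ASCII STL vertex count {len(coords)} is not a multiple of 3"
        )
    return np.asarray(coords, dtype=np.float32)


def read_stl(path: str | Path, label: str = "", species_tag: str = "") -> TriangleMesh:
    """Read an ASCII or binary STL file into a welded :class:`TriangleMesh`.

    Duplicate vertices are merged on exact coordinate match only. Units are
    assumed to be millimetres.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < _BINARY_HEADER_BYTES + 4:
        # could still be a tiny ASCII file
        if data.lstrip().startswith(b"solid"):
            mesh = _weld(_parse_ascii(data.decode("ascii", "replace")), label, species_tag)
            mesh.validate()
            return mesh
        raise STLFormatError(
            f"{path}: file too short for STL, ends at byte offset {len(data)}"
        )

    (n_facets,) = struct.unpack_from("<I", data, _BINARY_HEADER_BYTES)
    expected = _BINARY_HEADER_BYTES + 4 + _FACET_BYTES * n_facets
    if len(data) == expected and n_facets > 0:
        body = np.frombuffer(
            data,
            dtype=np.dtype(
                [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
            ),
            count=n_facets,
            offset=_BINARY_HEADER_BYTES + 4,
        )
        raw = body["verts"].reshape(-1, 3)
        mesh = _weld(raw, label, species_tag)
        mesh.validate()
        return mesh

    if data.lstrip().startswith(b"solid") and b"facet" in data:
        mesh = _weld(_parse_ascii(data.decode("ascii", "replace")), label, species_tag)
        mesh.validate()
        return mesh

    raise STLFormatError(
        f"{path}: truncated or invalid binary STL — facet count {n_facets} implies "
        f"{expected} bytes but file ends at byte offset {len(data)}"
    )


def write_stl(mesh: TriangleMesh, path: str | Path) -> Path:
    """Write a binary STL (80-byte header, uint32 count, 50 bytes per facet)."""
    mesh.validate()
    path = Path(path)
    n = len(mesh.faces)
    body = np.zeros(
        n,
        dtype=np.dtype(
            [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")]
        ),
    )
    body["normal"] = mesh.face_normals().astype(np.float32)
    body["verts"] = mesh.vertices[mesh.faces].astype(np.float32)
    header = f"stiflemorph {mesh.label}".encode("ascii")[:80].ljust(80, b"\0")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack("<I", n))
        fh.write(body.tobytes())
    return path


def mesh_to_points(mesh: TriangleMesh) -> SurfacePointCloud:
    """Convert a mesh to its surface point cloud (the welded vertex set)."""
    mesh.validate()
    unique = np.unique(mesh.vertices, axis=0)
    return SurfacePointCloud(points=unique, label=mesh.label)


# ---------------------------------------------------------------------------
# Voxel-mask serialization: CSV of occupied indices + JSON sidecar


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_voxel_mask(mask: VoxelMask, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    idx = np.argwhere(mask.occupancy)
    lines = ["i,j,k"] + [f"{i},{j},{k}" for i, j, k in idx]
    csv_path.write_text("\n".join(lines) + "\n")
    meta = {
        "shape": list(mask.occupancy.shape),
        "voxel_size": list(mask.voxel_size),
        "axis_roles": mask.axis_roles,
    }
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=2) + "\n")
    return csv_path


def read_voxel_mask(csv_path: str | Path) -> VoxelMask:
    csv_path = Path(csv_path)
    meta = json.loads(sidecar_path(csv_path).read_text())
    occ = np.zeros(tuple(meta["shape"]), dtype=bool)
    rows = csv_path.read_text().strip().splitlines()[1:]
    if rows:
        idx = np.array([[int(v) for v in r.split(",")] for r in rows])
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return VoxelMask(
        occupancy=occ,
        voxel_size=tuple(float(v) for v in meta["voxel_size"]),
        axis_roles=meta["axis_roles"],
    )
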