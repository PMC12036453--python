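"""Seeded synthetic tissue geometries with exact ground-truth morphometry.

Generates ligament tubes, C-shaped wedge menisci, and single-slice tibial
plateau masks at rat and mouse scales so that every downstream measurement
stage can be validated against known truth without any imaging data.

Truth convention: section polygons are rescaled so the *polygon actually
built* has exactly the requested area (the regular-n-gon-vs-circle correction
is folded into the radius), so "true CSA" means the polygon area, not the
smooth-curve limit.

Generated anatomic frame: +z proximal/superior, +y anterior, +x lateral
(right-knee convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

from ._geom import rotation_about_axis, rotation_aligning
from .mesh_io import TriangleMesh, VoxelMask

AreaProfile = Callable[[float], float]
AngleField = Callable[[float], float]

#: Minimum polygon order for which an uncorrected regular n-gon is within
#: 0.5% of the smooth section area (relative deficit ~ (2*pi/n)^2 / 6).
_MIN_FIDELITY_NGON = 37
_MIN_NGON = 64


@dataclass(frozen=True)
class SpeciesPreset:
    """Scale presets for one species (ligament CSA in mm^2, lengths in mm).

    Ligament and meniscus central values follow the published rodent-knee
    morphometry table; lengths and arc geometry are plausible fill-ins.
    """

    name: str
    slice_increment: float
    ligament_csa: dict[str, float]
    ligament_csa_sd: dict[str, float]
    normalized_csa: dict[str, float]
    normalized_csa_sd: dict[str, float]
    ligament_length: float
    plateau_area: float
    plateau_area_sd: float
    meniscus_width: dict[str, float]  # region -> mm, medial/lateral average
    meniscus_width_sd: dict[str, float]
    meniscus_height: float
    meniscus_height_sd: float
    arc_radius: float
    arc_span_deg: float
    voxel_size: float


PRESETS: dict[str, SpeciesPreset] = {
    "rat": SpeciesPreset(
        name="rat",
        slice_increment=0.1,
        ligament_csa={"ACL": 0.26, "PCL": 0.35, "MCL": 0.17, "LCL": 0.24},
        ligament_csa_sd={"ACL": 0.04, "PCL": 0.08, "MCL": 0.03, "LCL": 0.09},
        normalized_csa={"ACL": 0.78, "PCL": 1.10, "MCL": 0.50, "LCL": 0.71},
        normalized_csa_sd={"ACL": 0.11, "PCL": 0.20, "MCL": 0.10, "LCL": 0.30},
        ligament_length=3.0,
        plateau_area=33.35,
        plateau_area_sd=2.80,
        meniscus_width={"anterior": 1.18, "central": 0.70, "posterior": 1.13},
        meniscus_width_sd={"anterior": 0.30, "central": 0.16, "posterior": 0.30},
        meniscus_height=0.82,
        meniscus_height_sd=0.16,
        arc_radius=2.2,
        arc_span_deg=320.0,
        voxel_size=0.1,
    ),
    "mouse": SpeciesPreset(
        name="mouse",
        slice_increment=0.05,
        ligament_csa={"ACL": 0.029, "PCL": 0.041, "MCL": 0.031, "LCL": 0.054},
        ligament_csa_sd={"ACL": 0.007, "PCL": 0.015, "MCL": 0.007, "LCL": 0.017},
        normalized_csa={"ACL": 0.52, "PCL": 0.71, "MCL": 0.54, "LCL": 0.95},
        normalized_csa_sd={"ACL": 0.15, "PCL": 0.30, "MCL": 0.14, "LCL": 0.30},
        ligament_length=1.5,
        plateau_area=5.67,
        plateau_area_sd=0.50,
        meniscus_width={"anterior": 0.49, "central": 0.35, "posterior": 0.41},
        meniscus_width_sd={"anterior": 0.17, "central": 0.07, "posterior": 0.11},
        meniscus_height=0.30,
        meniscus_height_sd=0.07,
        arc_radius=0.95,
        arc_span_deg=320.0,
        voxel_size=0.05,
    ),
}

REGIONS = ("anterior", "central", "posterior")


# ---------------------------------------------------------------------------
# Specs


@dataclass
class LigamentSpec:
    length: float
    area_profile: AreaProfile
    section_shape: Literal["circle", "ellipse"] = "circle"
    ellipse_aspect: float = 1.0  # a/b, only used for section_shape == "ellipse"
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    vertex_spacing: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.vertex_spacing <= 0:
            raise ValueError("vertex_spacing must be > 0")
        if self.section_shape == "ellipse" and self.ellipse_aspect <= 0:
            raise ValueError("ellipse_aspect must be > 0")


@dataclass
class MeniscusSpec:
    side: Literal["medial", "lateral"]
    arc_radius: float
    arc_span_deg: float
    height_field: AngleField  # arc angle (deg, 0 = central body) -> mm
    width_field: AngleField
    wedge_taper: float = 0.2  # inner-edge height as a fraction of full height
    vertex_spacing: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.arc_span_deg <= 330):
            raise ValueError("arc_span_deg must be in (0, 330]")
        if self.arc_radius <= 0 or self.vertex_spacing <= 0:
            raise ValueError("arc_radius and vertex_spacing must be > 0")
        if not (0 <= self.wedge_taper < 1):
            raise ValueError("wedge_taper must be in [0, 1)")


def constant_profile(area: float) -> AreaProfile:
    return lambda u: area


def flared_profile(
    a_mid: float, flare: float = 3.0, plateau: tuple[float, float] = (0.25, 0.75)
) -> AreaProfile:
    """Constant mid-section area with linear ramps up to ``flare * a_mid`` at the ends."""
    lo, hi = plateau

    def profile(u: float) -> float:
        if u < lo:
            return a_mid * (flare + (1.0 - flare) * u / lo)
        if u > hi:
            return a_mid * (flare + (1.0 - flare) * (1.0 - u) / (1.0 - hi))
        return a_mid

    return profile


def true_midsubstance_csa(profile: AreaProfile, n: int = 4001) -> float:
    """Average of an area profile over the middle 50% of normalized length."""
    u = np.linspace(0.25, 0.75, n)
    return float(np.trapezoid([profile(x) for x in u], u) / 0.5)


def plateau_field(
    central: float, anterior: float, posterior: float, flat_central_deg: float = 25.0,
    flat_horn_deg: float = 65.0,
) -> AngleField:
    """Piecewise field: flat central zone, flat horn zones, cosine ramps between.

    Flat zones make ground truth insensitive to the exact slab angles used by
    the measurement protocol.
    """

    def fld(theta_deg: float) -> float:
        horn = anterior if theta_deg >= 0 else posterior
        t = abs(theta_deg)
        if t <= flat_central_deg:
            return central
        if t >= flat_horn_deg:
            return horn
        frac = (t - flat_central_deg) / (flat_horn_deg - flat_central_deg)
        return central + (horn - central) * 0.5 * (1 - math.cos(math.pi * frac))

    return fld


# ---------------------------------------------------------------------------
# Ligament tubes


def _section_semi_axes(area: float, aspect: float, n_theta: int) -> tuple[float, float]:
    """Semi-axes (a, b) so the inscribed n-gon has exactly the requested area."""
    ab = 2.0 * area / (n_theta * math.sin(2.0 * math.pi / n_theta))
    b = math.sqrt(ab / aspect)
    return aspect * b, b


def make_ligament(spec: LigamentSpec) -> TriangleMesh:
    """Closed tube mesh whose section polygon at axial fraction u has exactly
    area ``area_profile(u)`` (polygon-area convention)."""
    spec.validate()
    aspect = spec.ellipse_aspect if spec.section_shape == "ellipse" else 1.0

    n_z = max(4, math.ceil(spec.length / spec.vertex_spacing) + 1)
    us = np.linspace(0.0, 1.0, n_z)
    areas = np.array([spec.area_profile(float(u)) for u in us])
    if np.any(areas <= 0):
        raise ValueError("area_profile must be > 0 everywhere")

    # Perimeter of the largest section (Ramanujan) sets the angular resolution.
    a_max, b_max = _section_semi_axes(float(areas.max()), aspect, _MIN_NGON)
    h = ((a_max - b_max) / (a_max + b_max)) ** 2
    perimeter = math.pi * (a_max + b_max) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
    required = perimeter / _MIN_FIDELITY_NGON
    if spec.vertex_spacing > required:
        raise ValueError(
            "vertex_spacing too coarse for 0.5% section-area fidelity: "
            f"need <= {required:.4g} mm, got {spec.vertex_spacing:.4g} mm"
        )
    n_theta = max(_MIN_NGON, math.ceil(perimeter / spec.vertex_spacing))

    phis = 2.0 * math.pi * np.arange(n_theta) / n_theta
    cos_p, sin_p = np.cos(phis), np.sin(phis)

    verts = np.empty((n_z * n_theta + 2, 3))
    for i, (u, area) in enumerate(zip(us, areas)):
        a, b = _section_semi_axes(float(area), aspect, n_theta)
        z = u * spec.length
        block = slice(i * n_theta, (i + 1) * n_theta)
        verts[block, 0] = a * cos_p
        verts[block, 1] = b * sin_p
        verts[block, 2] = z
    c0, c1 = n_z * n_theta, n_z * n_theta + 1
    verts[c0] = (0.0, 0.0, 0.0)
    verts[c1] = (0.0, 0.0, spec.length)

    faces = []
    for i in range(n_z - 1):
        base, nxt = i * n_theta, (i + 1) * n_theta
        for j in range(n_theta):
            k = (j + 1) % n_theta
            faces.append((base + j, nxt + j, nxt + k))
            faces.append((base + j, nxt + k, base + k))
    for j in range(n_theta):
        k = (j + 1) % n_theta
        faces.append((c0, k, j))  # bottom cap
        faces.append((c1, (n_z - 1) * n_theta + j, (n_z - 1) * n_theta + k))

    rng = np.random.default_rng(spec.seed)
    rot = rotation_aligning(np.array([0.0, 0.0, 1.0]), spec.axis_direction)
    offset = rng.uniform(-0.5, 0.5, size=3) * spec.length
    verts = verts @ rot.T + offset

    mesh = TriangleMesh(verts, np.array(faces), label="", species_tag="synthetic")
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Wedge menisci


def _edge_fractions(m: int) -> np.ndarray:
    return np.arange(m) / m


def make_meniscus(spec: MeniscusSpec) -> TriangleMesh:
    """C-shaped wedge swept along a circular arc.

    At arc angle theta (deg; 0 = central body, positive = anterior) the
    section is a wedge of radial width ``width_field(theta)`` and vertical
    extent ``height_field(theta)``, wide base facing -z (tibial side).
    Medial and lateral sides are exact mirror images through the sagittal
    (x = 0) plane.
    """
    spec.validate()
    sx = 1.0 if spec.side == "lateral" else -1.0
    half = spec.arc_span_deg / 2.0
    span_rad = math.radians(spec.arc_span_deg)

    n_arc = max(31, math.ceil(spec.arc_radius * span_rad / spec.vertex_spacing) + 1)
    thetas = np.linspace(-half, half, n_arc)
    ws = np.array([spec.width_field(float(t)) for t in thetas])
    hs = np.array([spec.height_field(float(t)) for t in thetas])
    if np.any(ws <= 0) or np.any(hs <= 0):
        raise ValueError("height_field and width_field must be > 0 over the span")

    w_max, h_max = float(ws.max()), float(hs.max())
    m_bot = max(4, math.ceil(w_max / spec.vertex_spacing))
    m_out = max(3, math.ceil(h_max / spec.vertex_spacing))
    m_top = m_bot
    m_in = max(2, math.ceil(spec.wedge_taper * h_max / spec.vertex_spacing))
    taper = spec.wedge_taper

    # Closed 2D section template in (s_frac edge parametrizations); evaluated
    # per arc station at that station's (w, h).
    def section(w: float, h: float) -> np.ndarray:
        pts = []
        for t in _edge_fractions(m_bot):  # bottom: s 0 -> w at z = -h/2
            pts.append((t * w, -h / 2))
        for t in _edge_fractions(m_out):  # outer: z -h/2 -> +h/2 at s = w
            pts.append((w, -h / 2 + t * h))
        for t in _edge_fractions(m_top):  # top: s w -> 0, slanting down
            s = (1 - t) * w
            pts.append((s, -h / 2 + h * (taper + (1 - taper) * s / w)))
        for t in _edge_fractions(m_in):  # inner: z down to -h/2 at s = 0
            pts.append((0.0, -h / 2 + h * taper * (1 - t)))
        return np.asarray(pts)

    m_sec = m_bot + m_out + m_top + m_in
    verts = np.empty((n_arc * m_sec + 2, 3))
    for i, (theta, w, h) in enumerate(zip(thetas, ws, hs)):
        sec = section(float(w), float(h))
        r = spec.arc_radius + sec[:, 0] - w / 2.0
        th = math.radians(float(theta))
        block = slice(i * m_sec, (i + 1) * m_sec)
        verts[block, 0] = sx * r * math.cos(th)
        verts[block, 1] = r * math.sin(th)
        verts[block, 2] = sec[:, 1]

    # Horn end caps: centroid of the end sections.
    cap0, cap1 = n_arc * m_sec, n_arc * m_sec + 1
    verts[cap0] = verts[0:m_sec].mean(axis=0)
    verts[cap1] = verts[(n_arc - 1) * m_sec : n_arc * m_sec].mean(axis=0)

    faces = []
    for i in range(n_arc - 1):
        base, nxt = i * m_sec, (i + 1) * m_sec
        for j in range(m_sec):
            k = (j + 1) % m_sec
            faces.append((base + j, nxt + j, nxt + k))
            faces.append((base + j, nxt + k, base + k))
    for j in range(m_sec):
        k = (j + 1) % m_sec
        faces.append((cap0, k, j))
        faces.append((cap1, (n_arc - 1) * m_sec + j, (n_arc - 1) * m_sec + k))
    faces = np.array(faces)
    if spec.side == "medial":
        faces = faces[:, ::-1]  # mirroring flips orientation

    label = "MED_MEN" if spec.side == "medial" else "LAT_MEN"
    mesh = TriangleMesh(verts, faces, label=label, species_tag="synthetic")
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Plateau masks, noise, rigid perturbation


def make_plateau_mask(
    area: float, voxel_size: tuple[float, float, float]
) -> VoxelMask:
    """Single-axial-slice disk-like mask whose occupied count * dx*dy is the
    closest achievable value to ``area``."""
    dx, dy, dz = voxel_size
    in_plane = dx * dy
    if area <= in_plane:
        raise ValueError(
            f"requested area {area} mm^2 is not larger than one voxel ({in_plane} mm^2)"
        )
    n = max(1, round(area / in_plane))
    # grid comfortably larger than the equivalent disk
    half = math.ceil(math.sqrt(n / math.pi) * (dx + dy) / (2 * min(dx, dy))) + 2
    ii, jj = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij")
    d2 = (ii * dx) ** 2 + (jj * dy) ** 2
    order = np.lexsort((jj.ravel(), ii.ravel(), d2.ravel()))
    occ2d = np.zeros(ii.shape, dtype=bool)
    occ2d.ravel()[order[:n]] = True
    occupancy = occ2d[:, :, None]
    return VoxelMask(occupancy=occupancy, voxel_size=(dx, dy, dz), axis_roles={"axial_axis": 2})


def add_surface_noise(mesh: TriangleMesh, sigma: float, seed: int) -> TriangleMesh:
    """Displace each vertex along its outward normal by N(0, sigma) mm."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return TriangleMesh(
            mesh.vertices.copy(), mesh.faces.copy(), mesh.label, mesh.species_tag
        )
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, sigma, size=len(mesh.vertices))
    verts = mesh.vertices + mesh.vertex_normals() * disp[:, None]
    return TriangleMesh(verts, mesh.faces.copy(), mesh.label, mesh.species_tag)


def random_rigid_perturbation(
    mesh: TriangleMesh, max_angle_deg: float, seed: int, max_offset: float = 0.25
) -> TriangleMesh:
    """Apply a seeded random rotation (angle <= max_angle_deg) and translation."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, math.radians(max_angle_deg))
    rot = rotation_about_axis(axis, angle)
    t = rng.uniform(-max_offset, max_offset, size=3)
    centroid = mesh.vertices.mean(axis=0)
    verts = (mesh.vertices - centroid) @ rot.T + centroid + t
    return TriangleMesh(verts, mesh.faces.copy(), mesh.label, mesh.species_tag)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class SyntheticSpecimen:
    specimen_id: str
    species: str
    meshes: dict[str, TriangleMesh]  # tissue label -> mesh
    mask: VoxelMask


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative scatter with unit mean and the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def generate_cohort(
    species: str, n: int, seed: int, cv: float = 0.25
) -> tuple[list[SyntheticSpecimen], pd.DataFrame]:
    """Generate ``n`` specimens (4 ligaments + 2 menisci + 1 plateau mask each)
    with between-specimen lognormal scatter and an exact truth table.

    Truth rows: (specimen_id, species, tissue, region, measure, value).
    Ligament truth is the constant mid-section polygon area; meniscus truth
    is the flat-zone field value for each region; plateau truth is the
    achieved voxel-count area.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    preset = PRESETS[species]
    root = np.random.SeedSequence(seed)
    truth_rows: list[dict] = []
    specimens: list[SyntheticSpecimen] = []

    lig_spacing = preset.slice_increment / 5.0
    men_spacing = preset.slice_increment / 2.0

    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        sid = f"{species}_{i:03d}"
        meshes: dict[str, TriangleMesh] = {}

        for tissue in ("ACL", "PCL", "MCL", "LCL"):
            a_mid = preset.ligament_csa[tissue] * _lognormal_factor(rng, cv)
            length = preset.ligament_length * _lognormal_factor(rng, 0.10)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            lig = make_ligament(
                LigamentSpec(
                    length=length,
                    area_profile=flared_profile(a_mid, flare=1.6, plateau=(0.2, 0.8)),
                    axis_direction=axis,
                    vertex_spacing=lig_spacing,
                    seed=int(rng.integers(2**31)),
                )
            )
            lig.label = tissue
            lig.species_tag = species
            meshes[tissue] = lig
            truth_rows.append(
                dict(specimen_id=sid, species=species, tissue=tissue, region="",
                     measure="csa_mm2", value=a_mid)
            )

        for side, label in (("medial", "MED_MEN"), ("lateral", "LAT_MEN")):
            side_factor = 1.1 if side == "medial" else 0.9
            scale = _lognormal_factor(rng, cv)
            widths = {
                r: preset.meniscus_width[r] * side_factor * scale for r in REGIONS
            }
            height = preset.meniscus_height * side_factor * scale
            heights = {"anterior": height * 0.95, "central": height, "posterior": height * 1.05}
            w_field = plateau_field(widths["central"], widths["anterior"], widths["posterior"])
            h_field = plateau_field(heights["central"], heights["anterior"], heights["posterior"])
            men = make_meniscus(
                MeniscusSpec(
                    side=side,
                    arc_radius=preset.arc_radius * (0.5 + 0.5 * scale),
                    arc_span_deg=preset.arc_span_deg,
                    height_field=h_field,
                    width_field=w_field,
                    vertex_spacing=men_spacing,
                    seed=int(rng.integers(2**31)),
                )
            )
            men = random_rigid_perturbation(
                men, max_angle_deg=15.0, seed=int(rng.integers(2**31))
            )
            men.species_tag = species
            meshes[label] = men
            for region in REGIONS:
                truth_rows.append(
                    dict(specimen_id=sid, species=species, tissue=label, region=region,
                         measure="height_mm", value=heights[region])
                )
                truth_rows.append(
                    dict(specimen_id=sid, species=species, tissue=label, region=region,
                         measure="width_mm", value=widths[region])
                )

        target_area = preset.plateau_area * _lognormal_factor(rng, 0.08)
        vox = preset.voxel_size
        mask = make_plateau_mask(target_area, (vox, vox, vox))
        achieved = mask.occupied_count() * vox * vox
        truth_rows.append(
            dict(specimen_id=sid, species=species, tissue="PLATEAU", region="",
                 measure="area_mm2", value=achieved)
        )
        specimens.append(SyntheticSpecimen(sid, species, meshes, mask))

    truth = pd.DataFrame(truth_rows)
    return specimens, truth
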