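"""Synthetic saccular-aneurysm geometry.

Watertight surrogates for 3DRA-derived aneurysm models: a tubular parent
vessel (optionally curved, optionally carrying one small side branch)
fused with an ellipsoid-of-revolution dome through a smooth fillet.  The
dome can be perturbed by a low-order lobed bump field to emulate irregular,
bleb-carrying sacs.  Ground-truth shape factors (aspect ratio = dome height /
neck diameter; size ratio = dome height / parent diameter; bulge amplitude)
are recorded per case, and cohorts draw class-conditional parameter ranges so
that "ruptured-like" cases are stochastically taller, larger relative to
their vessel, and more irregular — with the overlap of the two class
distributions controlled by a single ``separation`` knob.

All geometry is in millimetres.  Fused models are extracted from an implicit
union by marching cubes, which guarantees closed, consistently oriented
surfaces; plain vessels are built parametrically with exactly circular
cross-sections.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from skimage import measure


class GenerationError(ValueError):
    """Raised when a parameter combination cannot produce a valid surface."""


# cohort parameter ranges (mm unless dimensionless); the discriminative
# triplet (aspect ratio, size ratio, bulge) is drawn from class-conditional
# sub-ranges, the rest are shared nuisance parameters
ASPECT_RATIO_RANGE = (0.7, 2.6)
SIZE_RATIO_RANGE = (0.8, 2.8)
BULGE_RANGE = (0.0, 0.25)
NECK_RANGE = (2.0, 3.2)
NECK_TO_WIDTH_RANGE = (0.55, 0.80)   # neck diameter / dome width
LENGTH_RANGE = (18.0, 24.0)
CURVATURE_RANGE = (0.0, 0.02)        # 1/mm
VESSEL_RADIUS_CLAMP = (0.9, 2.4)

_FILLET = 0.5  # smooth-union blending width, mm


@dataclass(frozen=True)
class ShapeParams:
    """Ground-truth parameters of one synthetic aneurysm model (mm)."""

    vessel_radius: float = 1.5
    vessel_length: float = 20.0
    vessel_curvature: float = 0.0
    dome_height: float = 5.0
    neck_diameter: float = 2.5
    dome_width: float = 4.0
    bulge_amplitude: float = 0.0
    irregularity_freq: int = 3
    seed: int = 0
    branch_radius: float = 0.0   # 0 disables the optional side branch
    branch_length: float = 4.0

    def __post_init__(self) -> None:
        for name in ("vessel_radius", "vessel_length", "dome_height",
                     "neck_diameter", "dome_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.vessel_curvature < 0 or self.bulge_amplitude < 0:
            raise ValueError("vessel_curvature and bulge_amplitude must be >= 0")
        if self.irregularity_freq < 0:
            raise ValueError("irregularity_freq must be >= 0")

    @property
    def aspect_ratio(self) -> float:
        return self.dome_height / self.neck_diameter

    @property
    def size_ratio(self) -> float:
        return self.dome_height / (2.0 * self.vessel_radius)


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort: class counts, class separation and nuisance jitter."""

    n_ruptured: int
    n_unruptured: int
    separation: float = 0.8
    noise_sd: float = 0.03
    seed: int = 0
    #: which shape factors carry the class signal; any subset of
    #: ("aspect_ratio", "size_ratio", "bulge_amplitude")
    features: tuple = ("aspect_ratio", "size_ratio", "bulge_amplitude")

    def __post_init__(self) -> None:
        valid = {"aspect_ratio", "size_ratio", "bulge_amplitude"}
        if not set(self.features) <= valid:
            raise ValueError(f"features must be a subset of {sorted(valid)}")
        if self.n_ruptured < 0 or self.n_unruptured < 0:
            raise ValueError("class counts must be non-negative")
        if self.n_ruptured + self.n_unruptured < 2:
            raise ValueError("cohort needs at least 2 cases")
        if self.n_ruptured == 0 or self.n_unruptured == 0:
            raise ValueError("both classes must be non-empty")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# analytic centerline of the parent vessel


def vessel_centerline(params: ShapeParams, n: int = 200) -> np.ndarray:
    """Points of the analytic centerline, inlet to outlet."""
    s = np.linspace(-params.vessel_length / 2.0, params.vessel_length / 2.0, n)
    k = params.vessel_curvature
    if k < 1e-9:
        return np.column_stack([s, np.zeros(n), np.zeros(n)])
    rc = 1.0 / k
    phi = s * k
    return np.column_stack([rc * np.sin(phi), rc * (1.0 - np.cos(phi)),
                            np.zeros(n)])


def _arc_coords(params: ShapeParams, pts: np.ndarray):
    """(arc-length coordinate, distance to centerline) for query points."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    k = params.vessel_curvature
    if k < 1e-9:
        return x, np.hypot(y, z)
    rc = 1.0 / k
    rho = np.hypot(x, y - rc)
    s = rc * np.arctan2(x, rc - y)
    return s, np.hypot(rho - rc, z)


# ---------------------------------------------------------------------------
# implicit field of the fused model


#: clearance of the neck plane above the vessel surface (mm); the sac sits
#: on a short cylindrical neck tube of this height so the minimal
#: cross-section of the junction is exactly the requested neck diameter
NECK_CLEARANCE = 0.6


def _dome_geometry(params: ShapeParams):
    """Ellipsoid semi-axes (a, c), center height z_c, and neck plane z0.

    The sac is an ellipsoid of revolution whose section at the neck plane
    (z0 = vessel_radius + NECK_CLEARANCE) has exactly the requested neck
    diameter and whose apex sits dome_height above that plane; a cylinder of
    neck radius bridges the short gap down into the vessel.
    """
    a = params.dome_width / 2.0
    rho_n = params.neck_diameter / 2.0
    if rho_n > a:
        raise GenerationError(
            "neck_diameter exceeds dome_width: the neck cannot be wider than "
            "the dome for an ellipsoid-of-revolution sac")
    q = np.sqrt(max(1.0 - (rho_n / a) ** 2, 0.0))
    c = params.dome_height / (1.0 + q)
    z0 = params.vessel_radius + NECK_CLEARANCE
    z_c = z0 + params.dome_height - c
    bottom = z_c - c
    if bottom < -0.8 * params.vessel_radius:
        raise GenerationError(
            "dome bottom extends below the parent vessel (self-intersecting "
            "combination of dome_height, neck_diameter and dome_width)")
    if bottom < 0.0:
        # the ellipsoid dips below the vessel axis plane; it must stay
        # hidden inside the vessel there
        rho0 = a * np.sqrt(max(1.0 - (z_c / c) ** 2, 0.0))
        if rho0 > 0.95 * params.vessel_radius:
            raise GenerationError(
                "dome waist protrudes through the vessel wall below the "
                "neck (self-intersecting combination)")
    return a, c, z_c


def _bump_phases(params: ShapeParams) -> tuple[float, float]:
    rng = np.random.default_rng(params.seed)
    return tuple(rng.uniform(0.0, 2.0 * np.pi, size=2))


def _smin(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    """Polynomial smooth minimum (fillet of width ~k)."""
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b * (1.0 - h) + a * h - k * h * (1.0 - h)


def implicit_field(params: ShapeParams, pts: np.ndarray) -> np.ndarray:
    """Approximate signed distance of the fused model (negative inside)."""
    pts = np.asarray(pts, dtype=np.float64)
    s, d_axis = _arc_coords(params, pts)
    f_vessel = d_axis - params.vessel_radius

    a, c, z_c = _dome_geometry(params)
    dx, dy = pts[:, 0], pts[:, 1]
    dz = pts[:, 2] - z_c
    v = np.column_stack([dx / a, dy / a, dz / c])
    e = np.linalg.norm(v, axis=1)
    safe = np.maximum(e, 1e-12)
    w = v / safe[:, None]
    theta = np.arccos(np.clip(w[:, 2], -1.0, 1.0))
    phi = np.arctan2(w[:, 1], w[:, 0])
    m = params.irregularity_freq
    p0, p1 = _bump_phases(params)
    sin_t = np.sin(theta)
    bump = (sin_t ** 2 * np.cos(m * phi + p0)
            + 0.6 * sin_t ** 3 * np.cos((m + 1) * phi + p1))
    level = 1.0 + params.bulge_amplitude * bump
    f_dome = (e - level) * min(a, c)

    # cylindrical neck tube bridging vessel surface and sac bottom
    rho_n = params.neck_diameter / 2.0
    z0 = params.vessel_radius + NECK_CLEARANCE
    f_cyl = np.maximum(np.hypot(dx, dy) - rho_n, pts[:, 2] - z0)
    f_cyl = np.maximum(f_cyl, -pts[:, 2])
    f_sac = np.minimum(f_dome, f_cyl)

    f = _smin(f_vessel, f_sac, _FILLET)

    if params.branch_radius > 0:
        # short straight side branch leaving the vessel sideways (+y),
        # rounded (capsule) free end
        s_b = -params.vessel_length / 4.0
        cl = vessel_centerline(params, 400)
        sc = np.linspace(-params.vessel_length / 2, params.vessel_length / 2, 400)
        base = cl[np.argmin(np.abs(sc - s_b))]
        tip = base + np.array([0.0, params.branch_length, 0.0])
        ab = tip - base
        t = np.clip(((pts - base) @ ab) / (ab @ ab), 0.0, 1.0)
        f_branch = np.linalg.norm(pts - base - t[:, None] * ab, axis=1) \
            - params.branch_radius
        f = _smin(f, f_branch, 0.3)

    # clip the vessel to its length with planar end caps
    return np.maximum(f, np.abs(s) - params.vessel_length / 2.0)


def make_aneurysm_model(params: ShapeParams, pitch: float = 0.25,
                        _retry: int = 0) -> trimesh.Trimesh:
    """Watertight fused aneurysm+vessel surface via marching cubes.

    Deterministic given ``params`` (including its seed).  ``pitch`` is the
    voxel size of the extraction grid in mm.
    """
    a, c, z_c = _dome_geometry(params)
    cl = vessel_centerline(params)
    grow = (1.0 + params.bulge_amplitude)
    margin = 3.0 * pitch
    r_max = max(params.vessel_radius, a * grow) + margin \
        + (params.branch_length + params.branch_radius
           if params.branch_radius > 0 else 0.0)
    lo = cl.min(axis=0) - r_max
    hi = cl.max(axis=0) + r_max
    hi[2] = max(hi[2], z_c + c * grow + margin)
    lo[2] = min(lo[2], -params.vessel_radius - margin)
    # offset the grid by an irrational fraction of the pitch so flat features
    # (the planar end caps) never coincide with grid planes, which would
    # degenerate the marching-cubes triangulation
    lo = lo - 0.318309886 * pitch
    axes = [np.arange(lo[i], hi[i] + pitch, pitch) for i in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([g.ravel() for g in grid])
    f = implicit_field(params, pts).reshape(grid[0].shape)
    f[f == 0.0] = -1e-12
    verts, faces, _, _ = measure.marching_cubes(f, 0.0, spacing=(pitch,) * 3)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        # borderline voxelizations (surface grazing a grid vertex) are rare;
        # a finer grid resolves them deterministically
        if _retry < 2:
            return make_aneurysm_model(params, pitch=0.8 * pitch,
                                       _retry=_retry + 1)
        raise GenerationError("marching-cubes extraction is not watertight; "
                              "increase the grid margin or reduce pitch")
    mesh.metadata["id"] = f"synth_{params.seed}"
    mesh.metadata["shape_params"] = dataclasses.asdict(params)
    mesh.metadata["centerline_points"] = cl
    mesh.metadata["centerline_radius"] = params.vessel_radius
    return mesh


def make_vessel(params: ShapeParams, n_theta: int = 48,
                axial_step: float = 0.3) -> trimesh.Trimesh:
    """Parametric capped tube along the analytic centerline.

    Cross-sections perpendicular to the centerline are exact circles of
    ``vessel_radius``; the analytic centerline and radius are recorded in
    ``mesh.metadata``.
    """
    r, length = params.vessel_radius, params.vessel_length
    n_axial = max(int(np.ceil(length / axial_step)) + 1, 2)
    svals = np.linspace(-length / 2.0, length / 2.0, n_axial)
    k = params.vessel_curvature
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)

    rings = []
    for s in svals:
        if k < 1e-9:
            center = np.array([s, 0.0, 0.0])
            normal_in_plane = np.array([0.0, 1.0, 0.0])
        else:
            rc = 1.0 / k
            phi = s * k
            center = np.array([rc * np.sin(phi), rc * (1 - np.cos(phi)), 0.0])
            # unit vector from the arc center towards the point (radial)
            normal_in_plane = np.array([np.sin(phi), -np.cos(phi), 0.0]) * -1.0
        ez = np.array([0.0, 0.0, 1.0])
        ring = center + r * (np.outer(np.cos(theta), normal_in_plane)
                             + np.outer(np.sin(theta), ez))
        rings.append(ring)
    verts = np.vstack(rings)

    faces = []
    for i in range(n_axial - 1):
        base0, base1 = i * n_theta, (i + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([base0 + j, base1 + j, base0 + jn])
            faces.append([base0 + jn, base1 + j, base1 + jn])
    # end caps: fans around the ring centroids
    c0 = len(verts)
    c1 = len(verts) + 1
    verts = np.vstack([verts, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        faces.append([c0, jn, j])
        faces.append([c1, (n_axial - 1) * n_theta + j,
                      (n_axial - 1) * n_theta + jn])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces),
                           process=True)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    mesh.metadata["id"] = f"vessel_{params.seed}"
    mesh.metadata["centerline_points"] = vessel_centerline(params)
    mesh.metadata["centerline_radius"] = r
    return mesh


# ---------------------------------------------------------------------------
# cohorts


def _class_range(lo: float, hi: float, label: int, separation: float):
    """Class-conditional sub-range: identical at separation 0, disjoint at 1."""
    span = hi - lo
    if label == 1:
        return lo + 0.5 * separation * span, hi
    return lo, hi - 0.5 * separation * span


def sample_cohort_params(spec: CohortSpec) -> tuple[list[ShapeParams], np.ndarray]:
    """Draw per-case shape parameters and labels (1 = ruptured-like).

    Class 1 draws aspect ratio, size ratio and bulge amplitude from the upper
    ``separation``-shifted portion of their ranges, class 0 from the lower;
    nuisance parameters are shared and jittered by ``noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_ruptured + spec.n_unruptured
    labels = np.concatenate([np.ones(spec.n_ruptured, dtype=int),
                             np.zeros(spec.n_unruptured, dtype=int)])
    rng.shuffle(labels)

    params = []
    for lab in labels:

        def draw(name, lo, hi):
            sep = spec.separation if name in spec.features else 0.0
            return rng.uniform(*_class_range(lo, hi, lab, sep))

        ar = draw("aspect_ratio", *ASPECT_RATIO_RANGE)
        sr = draw("size_ratio", *SIZE_RATIO_RANGE)
        bulge = draw("bulge_amplitude", *BULGE_RANGE)
        neck = rng.uniform(*NECK_RANGE)
        neck *= 1.0 + spec.noise_sd * rng.standard_normal()
        height = ar * neck
        width = neck / rng.uniform(*NECK_TO_WIDTH_RANGE)
        # realize the requested size ratio through the vessel radius, clamped
        # to an anatomically plausible window (and so the dome stays above
        # the vessel floor)
        rv = height / (2.0 * sr)
        rv = float(np.clip(rv, max(VESSEL_RADIUS_CLAMP[0], height / 5.5),
                           VESSEL_RADIUS_CLAMP[1]))
        length = rng.uniform(*LENGTH_RANGE) * (1 + spec.noise_sd * rng.standard_normal())
        curv = rng.uniform(*CURVATURE_RANGE)
        params.append(ShapeParams(
            vessel_radius=rv, vessel_length=length, vessel_curvature=curv,
            dome_height=height, neck_diameter=neck, dome_width=width,
            bulge_amplitude=bulge, irregularity_freq=int(rng.integers(2, 6)),
            seed=int(rng.integers(2 ** 31))))
    return params, labels


def generate_cohort(spec: CohortSpec, pitch: float = 0.25
                    ) -> list[tuple[trimesh.Trimesh, int, ShapeParams]]:
    """Synthesize a labeled cohort of watertight aneurysm models."""
    params, labels = sample_cohort_params(spec)
    out = []
    for i, (p, lab) in enumerate(zip(params, labels)):
        mesh = make_aneurysm_model(p, pitch=pitch)
        mesh.metadata["id"] = f"case_{i:04d}"
        mesh.metadata["label"] = int(lab)
        out.append((mesh, int(lab), p))
    return out


def write_cohort(cohort, directory, cohort_tag: str = "training",
                 ascii_stl: bool = False) -> pd.DataFrame:
    """Write STL files plus a sidecar metadata CSV; returns the table."""
    import os

    os.makedirs(directory, exist_ok=True)
    rows = []
    for mesh, label, p in cohort:
        cid = mesh.metadata.get("id", f"case_{len(rows):04d}")
        path = os.path.join(directory, f"{cid}.stl")
        mesh.export(path, file_type="stl_ascii" if ascii_stl else "stl")
        row = {"id": cid, "label": label, "cohort": cohort_tag}
        row.update(dataclasses.asdict(p))
        row["aspect_ratio"] = p.aspect_ratio
        row["size_ratio"] = p.size_ratio
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(directory, "metadata.csv"), index=False)
    return table
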