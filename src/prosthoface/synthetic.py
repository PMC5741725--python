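"""Parametric synthetic faces and pre/post denture-wearing scan pairs.

Real patient scans cannot be shipped, so every pipeline stage is exercised
on a parametric stand-in: a height field z = f(x, y) over an ellipsoid cap
carrying a Gaussian nose ridge, lip and chin bulges and the intervening
creases, built directly in the canonical face frame (X left-right, Y
vertical, Z out of the face, tragus midpoint at the origin, nasal tip on
the Y = 0 line at the global Z maximum).  The surface is bilaterally
symmetric unless an asymmetry amplitude is set, and all eight anatomical
landmarks are placed analytically.

A scan pair adds a known perioral "collapse": a smooth inward (-Z)
displacement field with compact support below the nose base and above the
menton, spanned by two fixed basis fields — overall depth and a vertical
profile gradient — scaled by a 2-vector latent (mm).  The same latent
mildly modulates the pre-operative lip and chin amplitudes (collapse
severity and pre-operative perioral morphology co-vary), which is what
makes the displacement field predictable from the pre-operative template.
Support-tapered Gaussian vertex noise emulates scanner jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .geometry import FeatureTemplate, build_feature_template
from .mesh_io import LandmarkSet, TriangleMesh
from .registration import RegionMask

__all__ = [
    "FaceParams",
    "CollapseParams",
    "SyntheticPair",
    "generate_face",
    "generate_pair",
    "generate_cohort",
    "icosphere",
    "cylinder_grid",
    "plane_grid",
]

#: how the collapse latent (z1 = depth, z2 = vertical profile) shifts the
#: pre-operative perioral shape parameters (mm of amplitude per mm latent)
LATENT_SHAPE_COUPLING: dict[str, tuple[float, float]] = {
    "upper_lip": (-0.50, 0.00),
    "lower_lip": (-0.25, -0.25),
    "chin": (0.00, 0.25),
}

#: face parameters allowed to receive per-subject nuisance jitter
JITTERED_PARAMS = ("upper_lip", "lower_lip", "chin", "nose_height")


@dataclass(frozen=True)
class FaceParams:
    """Shape and sampling parameters of the synthetic face (mm)."""

    scale: float = 1.0
    half_width: float = 70.0          # x extent of the sampled patch
    y_min: float = -62.0
    y_max: float = 48.0
    dome_height: float = 40.0
    dome_rx: float = 72.0
    dome_ry: float = 88.0
    dome_cy: float = -7.0             # dome centre sits below the nose line
    nose_height: float = 14.0
    nose_sigma: tuple[float, float] = (8.0, 9.0)
    subnasale_depth: float = 2.6
    upper_lip: float = 3.5
    fissure_depth: float = 1.5
    lower_lip: float = 3.6
    mentolabial_depth: float = 0.7
    chin: float = 1.6
    nx: int = 71                      # odd, so the midline x = 0 is sampled
    ny: int = 56                      # chosen so y = 0 is sampled
    asymmetry: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.nx < 30 or self.ny < 30:
            raise ParameterError("resolution must be at least 30 x 30")
        if min(self.half_width, self.dome_rx, self.dome_ry, self.dome_height) <= 0:
            raise ParameterError("face radii must be positive")
        if self.half_width >= self.dome_rx:
            raise ParameterError("sampled patch must stay inside the dome ellipse")
        if self.nose_height <= 0:
            raise ParameterError("nose height must be positive")


# perioral feature layout: (y centre, sigma_x, sigma_y, sign) per feature
_FEATURES = {
    "subnasale_depth": (-14.0, 20.0, 3.0, -1.0),
    "upper_lip": (-24.0, 22.0, 4.0, +1.0),
    "fissure_depth": (-30.0, 22.0, 2.5, -1.0),
    "lower_lip": (-38.0, 20.0, 4.0, +1.0),
    "mentolabial_depth": (-46.0, 18.0, 3.0, -1.0),
    "chin": (-54.0, 16.0, 6.0, +1.0),
}

_MENTON_Y = -58.0
_COMMISSURE = (24.0, -30.0)
_ALA = (10.0, -8.0)


def _height(params: FaceParams, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """The face height field, before global scaling."""
    p = params
    dome_arg = 1.0 - (x / p.dome_rx) ** 2 - ((y - p.dome_cy) / p.dome_ry) ** 2
    z = p.dome_height * np.sqrt(np.clip(dome_arg, 0.0, None))
    sx, sy = p.nose_sigma
    z = z + p.nose_height * np.exp(-(x**2) / (2 * sx**2) - (y**2) / (2 * sy**2))
    for name, (cy, fsx, fsy, sign) in _FEATURES.items():
        amp = getattr(p, name)
        z = z + sign * amp * np.exp(
            -(x**2) / (2 * fsx**2) - ((y - cy) ** 2) / (2 * fsy**2)
        )
    if p.asymmetry:
        z = z + p.asymmetry * (x / p.half_width) * np.exp(
            -(((y + 30.0) / 20.0) ** 2)
        )
    return z


def generate_face(params: FaceParams = FaceParams()) -> tuple[TriangleMesh, LandmarkSet]:
    """Build the synthetic face mesh with its eight analytic landmarks.

    Deterministic given the parameters; bilaterally symmetric in X for
    ``asymmetry = 0``; the nasal-tip vertex attains the global Z maximum.
    """
    params.validate()
    p = params
    xs = np.linspace(-p.half_width, p.half_width, p.nx)
    ys = np.linspace(p.y_min, p.y_max, p.ny)
    xs = 0.5 * (xs - xs[::-1])  # exactly antisymmetric sample positions
    gx, gy = np.meshgrid(xs, ys)
    gz = _height(p, gx, gy)
    # canonical frame: the tragus midpoint (lateral extremes at y = 0) is the
    # origin, so shift the height field down by the tragus height
    gz = gz - _height(p, np.array(p.half_width), np.array(0.0))
    vertices = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) * p.scale

    idx = lambda row, col: row * p.nx + col
    faces = []
    for r in range(p.ny - 1):
        for c in range(p.nx - 1):
            v00, v01 = idx(r, c), idx(r, c + 1)
            v10, v11 = idx(r + 1, c), idx(r + 1, c + 1)
            # mirror the diagonal split across x = 0 so the triangulation is
            # bilaterally symmetric (keeps feature detection exactly mirrored)
            if xs[c] + xs[c + 1] >= 0:
                faces.append([v00, v01, v11])
                faces.append([v00, v11, v10])
            else:
                faces.append([v00, v01, v10])
                faces.append([v01, v11, v10])
    mesh = TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))

    def nearest_vertex(x0: float, y0: float) -> int:
        d2 = (gx.ravel() - x0) ** 2 + (gy.ravel() - y0) ** 2
        return int(np.argmin(d2))

    lm_xy = {
        "left_tragus": (p.half_width, 0.0),
        "right_tragus": (-p.half_width, 0.0),
        "nasal_tip": (0.0, 0.0),
        "left_ala": (_ALA[0], _ALA[1]),
        "right_ala": (-_ALA[0], _ALA[1]),
        "menton": (0.0, _MENTON_Y),
        "left_commissure": (_COMMISSURE[0], _COMMISSURE[1]),
        "right_commissure": (-_COMMISSURE[0], _COMMISSURE[1]),
    }
    points = {}
    indices = {}
    for name, (x0, y0) in lm_xy.items():
        vi = nearest_vertex(x0, y0)
        points[name] = mesh.vertices[vi].copy()
        indices[name] = vi
    return mesh, LandmarkSet(points, indices)


@dataclass(frozen=True)
class CollapseParams:
    """The latent perioral collapse field (all lengths in mm)."""

    latent: tuple[float, float] = (1.5, 0.0)  # (depth, vertical profile)
    support_x: float = 30.0                   # lateral half-extent
    support_y: tuple[float, float] = (-57.0, -12.0)
    ramp: float = 8.0                         # smoothness length scale
    noise_sd: float = 0.02                    # support-tapered vertex noise
    seed: int = 0

    @property
    def depth_bound(self) -> float:
        """Upper bound on the displacement magnitude the field can produce."""
        return abs(self.latent[0]) + abs(self.latent[1]) + 5.0 * self.noise_sd

    def validate(self, face: FaceParams) -> None:
        if self.support_y[0] >= self.support_y[1]:
            raise ParameterError("support_y must be (low, high)")
        if self.ramp <= 0 or self.support_x <= 0:
            raise ParameterError("support extents must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if abs(self.latent[0]) > face.nose_height:
            raise ParameterError(
                f"collapse depth {self.latent[0]:.2f} exceeds nose height "
                f"{face.nose_height:.2f}"
            )


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def collapse_basis(
    collapse: CollapseParams, x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """The two unit basis fields (B1 depth bump, B2 vertical gradient).

    B1 is a compactly supported bump, exactly zero outside the support box:
    a raised-cosine (sin^2) vertical window — gentle enough that the
    collapse adds negligible profile curvature and never masquerades as an
    anatomical feature — times smoothstep lateral ramps of width ``ramp``.
    B2 is B1 times a linear vertical gradient in [-1, 1].
    """
    y0, y1 = collapse.support_y
    r = collapse.ramp
    inside = (y > y0) & (y < y1)
    wy = np.where(inside, np.sin(np.pi * np.clip((y - y0) / (y1 - y0), 0, 1)) ** 2, 0.0)
    wx = _smoothstep((x + collapse.support_x) / (1.25 * r)) * _smoothstep(
        (collapse.support_x - x) / (1.25 * r)
    )
    b1 = wx * wy
    grad = np.clip(2.0 * (y - 0.5 * (y0 + y1)) / (y1 - y0), -1.0, 1.0)
    return b1, b1 * grad


@dataclass
class SyntheticPair:
    """One synthetic subject: pre/post meshes plus complete ground truth."""

    pre_mesh: TriangleMesh
    post_mesh: TriangleMesh
    pre_landmarks: LandmarkSet
    post_landmarks: LandmarkSet
    template: FeatureTemplate          # built on the pre mesh, vertex-bound
    true_field: np.ndarray             # (29, 3) post - pre at bound vertices
    support: RegionMask                # vertices inside the collapse support
    latent: np.ndarray
    face_params: FaceParams
    collapse_params: CollapseParams


def generate_pair(
    face: FaceParams = FaceParams(),
    collapse: CollapseParams = CollapseParams(),
    build_template: bool = True,
) -> SyntheticPair:
    """Generate a registered pre/post scan pair with known ground truth.

    The pre-operative face is the parametric face with its perioral
    amplitudes shifted by the latent (shape-collapse coupling); the
    post-operative face displaces it along -Z by the collapse field.
    """
    collapse.validate(face)
    z1, z2 = collapse.latent
    shaped = dict()
    for name, (c1, c2) in LATENT_SHAPE_COUPLING.items():
        shaped[name] = getattr(face, name) + c1 * z1 + c2 * z2
        if shaped[name] <= 0.2:
            raise ParameterError(f"latent collapses face parameter {name!r} below 0.2")
    pre_params = replace(face, **shaped)
    pre_mesh, pre_lm = generate_face(pre_params)

    x = pre_mesh.vertices[:, 0] / face.scale
    y = pre_mesh.vertices[:, 1] / face.scale
    b1, b2 = collapse_basis(collapse, x, y)
    dz = z1 * b1 + z2 * b2
    if collapse.noise_sd > 0:
        rng = np.random.default_rng(collapse.seed)
        dz = dz + collapse.noise_sd * rng.standard_normal(dz.size) * b1
    post_v = pre_mesh.vertices.copy()
    post_v[:, 2] -= dz * face.scale
    post_mesh = pre_mesh.with_vertices(post_v)

    post_points = {}
    for name, p in pre_lm.points.items():
        vi = pre_lm.vertex_indices[name]
        post_points[name] = post_mesh.vertices[vi].copy()
    post_lm = LandmarkSet(post_points, dict(pre_lm.vertex_indices))

    template = None
    true_field = None
    if build_template:
        template = build_feature_template(pre_mesh, landmarks=None, bind=True)
        vi = template.vertex_indices
        true_field = post_mesh.vertices[vi] - pre_mesh.vertices[vi]
    support = RegionMask(b1 > 0, label="collapse_support")
    return SyntheticPair(
        pre_mesh, post_mesh, pre_lm, post_lm,
        template, true_field, support,
        np.asarray(collapse.latent, dtype=np.float64), pre_params, collapse,
    )


def generate_cohort(
    n: int,
    face: FaceParams = FaceParams(),
    collapse: CollapseParams = CollapseParams(),
    seed: int = 0,
    shape_jitter_sd: float = 0.05,
    build_templates: bool = True,
) -> list[SyntheticPair]:
    """A cohort of independent subjects with seeded latent draws.

    Depth latents are drawn uniformly in [0.4, 1.0] x the nominal depth
    (``collapse.latent[0]``, every patient collapses inward); the vertical
    profile latent is centred Gaussian with sd 0.15 x depth.  Face
    parameters additionally receive independent Gaussian nuisance jitter.
    """
    if n < 2:
        raise ParameterError(f"cohort needs n >= 2 subjects, got {n}")
    rng = np.random.default_rng(seed)
    depth = collapse.latent[0]
    pairs = []
    for s in range(n):
        z1 = float(depth * rng.uniform(0.4, 1.0))
        z2 = float(0.15 * depth * rng.standard_normal())
        jitter = {
            name: getattr(face, name) + shape_jitter_sd * rng.standard_normal()
            for name in JITTERED_PARAMS
        }
        face_s = replace(face, **jitter)
        collapse_s = replace(
            collapse,
            latent=(z1, z2),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pairs.append(generate_pair(face_s, collapse_s, build_template=build_templates))
    return pairs


# ------------------------------------------------------- analytic primitives
def icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriangleMesh:
    """Geodesic sphere by icosahedron subdivision (5124 faces at level 4)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    v /= np.linalg.norm(v, axis=1)[:, None]
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    for _ in range(subdivisions):
        verts = list(v)
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                cache[key] = len(verts)
                verts.append(m)
            return cache[key]

        new_f = []
        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_f += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        v = np.asarray(verts)
        f = np.asarray(new_f, dtype=np.int64)
    return TriangleMesh(v * radius, f)


def cylinder_grid(
    radius: float = 2.0, height: float = 20.0, n_circ: int = 64, n_axial: int | None = None
) -> TriangleMesh:
    """Open cylinder with near-square quads split by a consistent diagonal.

    Equal axial and circumferential spacing makes the edge-averaged mean
    curvature exactly 1/(2r) away from the open ends (with exact normals).
    """
    circ_step = 2 * np.pi * radius / n_circ
    if n_axial is None:
        n_axial = max(2, int(round(height / circ_step)) + 1)
    theta = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    zs = np.linspace(-height / 2, height / 2, n_axial)
    verts = []
    for z in zs:
        for t in theta:
            verts.append([radius * np.cos(t), radius * np.sin(t), z])
    faces = []
    for r in range(n_axial - 1):
        for c in range(n_circ):
            c1 = (c + 1) % n_circ
            v00 = r * n_circ + c
            v01 = r * n_circ + c1
            v10 = (r + 1) * n_circ + c
            v11 = (r + 1) * n_circ + c1
            faces.append([v00, v01, v11])
            faces.append([v00, v11, v10])
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


def plane_grid(
    nx: int = 20, ny: int = 20, size: float = 10.0, z: float = 0.0
) -> TriangleMesh:
    """Flat rectangular grid in the XY plane at height ``z``."""
    xs = np.linspace(-size / 2, size / 2, nx)
    ys = np.linspace(-size / 2, size / 2, ny)
    gx, gy = np.meshgrid(xs, ys)
    v = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, float(z))])
    faces = []
    for r in range(ny - 1):
        for c in range(nx - 1):
            v00, v01 = r * nx + c, r * nx + c + 1
            v10, v11 = (r + 1) * nx + c, (r + 1) * nx + c + 1
            faces.append([v00, v01, v11])
            faces.append([v00, v11, v10])
    return TriangleMesh(v, np.asarray(faces, dtype=np.int64))
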