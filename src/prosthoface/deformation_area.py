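"""Signed 3D deviation analysis and deformation-area boundary statistics.

A test mesh is compared against a reference surface by point-to-triangle
distance (not point-to-point: the two scans sample the skin differently),
signed by the reference's outward normal at the foot point.  Vertices whose
absolute deviation exceeds the critical value — 0.2 mm, the smallest
distance the naked eye resolves — form the appearance-deformation region,
whose largest connected component is kept.  The region's boundary is
located relative to the ala-tragus (Camper's) plane, the soft-tissue menton
and the tragus-commissure lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import LandmarkSchemaError, MeshValidationError, RegionError
from .mesh_io import LandmarkSet, TriangleMesh
from .registration import RegionMask

__all__ = [
    "DeviationReport",
    "Plane",
    "BoundaryStats",
    "closest_on_surface",
    "signed_deviation",
    "deformation_region",
    "region_boundary",
    "ala_tragus_plane",
    "boundary_stats",
    "cohort_boundary_summary",
]

CRITICAL_MM = 0.2  # naked-eye resolution threshold


@dataclass
class DeviationReport:
    """Per-vertex signed deviation of a test mesh from a reference surface."""

    signed_distance: np.ndarray
    critical: float

    @property
    def mask(self) -> np.ndarray:
        """Super-threshold flag: |signed distance| strictly above critical."""
        return np.abs(self.signed_distance) > self.critical

    @property
    def max(self) -> float:
        return float(self.signed_distance.max())

    @property
    def min(self) -> float:
        return float(self.signed_distance.min())

    @property
    def mean_abs(self) -> float:
        return float(np.abs(self.signed_distance).mean())

    @property
    def rms_abs(self) -> float:
        return float(np.sqrt(np.mean(self.signed_distance**2)))

    def summary(self) -> dict:
        return {
            "max": self.max,
            "min": self.min,
            "mean_abs": self.mean_abs,
            "rms_abs": self.rms_abs,
            "critical": self.critical,
            "super_threshold": int(self.mask.sum()),
        }


@dataclass
class Plane:
    """Plane n . x = offset with unit normal n."""

    normal: np.ndarray
    offset: float

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.normal - self.offset


@dataclass
class BoundaryStats:
    """The deformation-area boundary measurements of one subject (mm)."""

    upper_distance: float   # boundary-to-ala-tragus-plane perpendicular distance
    lower_distance: float   # boundary-to-menton distance
    left_ratio: float       # lateral boundary->commissure / tragus->commissure, +X side
    right_ratio: float

    def as_dict(self) -> dict:
        return {
            "upper_distance": self.upper_distance,
            "lower_distance": self.lower_distance,
            "left_ratio": self.left_ratio,
            "right_ratio": self.right_ratio,
        }


# ------------------------------------------------- point-to-surface distance
def closest_on_surface(
    mesh: TriangleMesh, points: np.ndarray, k_candidates: int = 12
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closest point on the triangulated surface for each query point.

    Candidate triangles are those incident to the ``k_candidates`` nearest
    mesh vertices of each query (KD-tree prefilter); the exact closest point
    on each candidate triangle is then computed and the minimum taken.
    Returns (foot points, distances, triangle ids).
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if mesh.face_count == 0:
        raise MeshValidationError("reference mesh has no faces")
    tree = cKDTree(mesh.vertices)
    k = min(k_candidates, mesh.vertex_count)
    _, nn = tree.query(points, k=k)
    nn = np.atleast_2d(nn)

    # vertex -> incident faces (CSR layout)
    f = mesh.faces
    m = mesh.face_count
    vert_of_face = np.repeat(np.arange(m), 3)
    order = np.argsort(f.ravel(), kind="stable")
    sorted_verts = f.ravel()[order]
    incident = vert_of_face[order]
    starts = np.searchsorted(sorted_verts, np.arange(mesh.vertex_count))
    ends = np.searchsorted(sorted_verts, np.arange(mesh.vertex_count), side="right")

    q_idx: list[np.ndarray] = []
    t_idx: list[np.ndarray] = []
    for qi in range(points.shape[0]):
        faces_here = np.unique(
            np.concatenate([incident[starts[v] : ends[v]] for v in nn[qi]])
        )
        q_idx.append(np.full(faces_here.size, qi))
        t_idx.append(faces_here)
    qq = np.concatenate(q_idx)
    tt = np.concatenate(t_idx)

    feet = _closest_point_on_triangles(
        points[qq], mesh.vertices[f[tt, 0]], mesh.vertices[f[tt, 1]], mesh.vertices[f[tt, 2]]
    )
    d2 = np.einsum("ij,ij->i", points[qq] - feet, points[qq] - feet)

    best = np.full(points.shape[0], np.inf)
    np.minimum.at(best, qq, d2)
    # recover argmin deterministically (first candidate attaining the min)
    is_best = d2 <= best[qq] * (1 + 1e-12) + 1e-300
    best_at = np.full(points.shape[0], -1, dtype=np.int64)
    for pos in np.flatnonzero(is_best):
        if best_at[qq[pos]] < 0:
            best_at[qq[pos]] = pos
    dist = np.sqrt(d2[best_at].clip(min=0))
    return feet[best_at], dist, tt[best_at]


def _closest_point_on_triangles(p, a, b, c) -> np.ndarray:
    """Vectorized closest point on triangle (a, b, c) for each query p."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(p)
    done = np.zeros(p.shape[0], dtype=bool)

    def assign(cond, value):
        use = cond & ~done
        result[use] = value[use]
        done[use] = True

    assign((d1 <= 0) & (d2 <= 0), a)  # vertex a
    assign((d3 >= 0) & (d4 <= d3), b)  # vertex b
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3 + 1e-300), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge ab
    assign((d6 >= 0) & (d5 <= d6), c)  # vertex c
    vb = d5 * d2 - d1 * d6
    w_ac = d2 / (d2 - d6 + 1e-300)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge ac
    va = d3 * d6 - d5 * d4
    w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6) + 1e-300)
    assign(
        (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
        b + w_bc[:, None] * (c - b),
    )  # edge bc
    denom = va + vb + vc
    v = vb / np.where(denom == 0, 1.0, denom)
    w = vc / np.where(denom == 0, 1.0, denom)
    interior = a + v[:, None] * ab + w[:, None] * ac
    result[~done] = interior[~done]
    return result


def signed_deviation(
    reference: TriangleMesh, test: TriangleMesh, critical: float = CRITICAL_MM
) -> DeviationReport:
    """Signed distance of every test vertex to the reference surface.

    The sign follows the reference's outward face normal at the foot point:
    positive where the test surface lies outside the reference.
    """
    if reference.vertex_count == 0 or test.vertex_count == 0:
        raise MeshValidationError("empty mesh in deviation analysis")
    feet, dist, tri = closest_on_surface(reference, test.vertices)
    f = reference.faces
    v = reference.vertices
    fn = np.cross(v[f[tri, 1]] - v[f[tri, 0]], v[f[tri, 2]] - v[f[tri, 0]])
    side = np.einsum("ij,ij->i", test.vertices - feet, fn)
    signed = dist * np.where(side >= 0, 1.0, -1.0)
    return DeviationReport(signed, float(critical))


# --------------------------------------------------------- region machinery
def deformation_region(report: DeviationReport, mesh: TriangleMesh) -> RegionMask:
    """Largest edge-connected component of the super-threshold vertex set.

    An empty super-threshold set is not an error: an empty, flagged region
    is returned (``empty_flagged``).
    """
    mask = report.mask
    if mask.size != mesh.vertex_count:
        raise RegionError("deviation report does not match mesh")
    if not mask.any():
        return RegionMask(np.zeros(mesh.vertex_count, bool), "deformation", empty_flagged=True)
    idx = np.flatnonzero(mask)
    sub = mesh.adjacency[idx][:, idx]
    n_comp, labels = connected_components(sp.csr_matrix(sub), directed=False)
    counts = np.bincount(labels, minlength=n_comp)
    keep = labels == int(np.argmax(counts))
    out = np.zeros(mesh.vertex_count, dtype=bool)
    out[idx[keep]] = True
    return RegionMask(out, "deformation")


def region_boundary(mesh: TriangleMesh, region: RegionMask) -> np.ndarray:
    """Indices of region vertices adjacent to at least one outside vertex."""
    region.check_mesh(mesh)
    inside = region.mask.astype(np.float64)
    outside_neighbors = mesh.adjacency @ (1.0 - inside)
    return np.flatnonzero(region.mask & (outside_neighbors > 0))


def ala_tragus_plane(landmarks: LandmarkSet) -> Plane:
    """Total-least-squares plane through both tragus centres and both alae,
    with the normal oriented toward +Y (superior)."""
    names = ("left_tragus", "right_tragus", "left_ala", "right_ala")
    try:
        landmarks.require(*names)
    except LandmarkSchemaError:
        raise
    pts = landmarks.array(names)
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[2]
    if normal[1] < 0:
        normal = -normal
    return Plane(normal, float(normal @ centroid))


def boundary_stats(
    region: RegionMask, mesh: TriangleMesh, landmarks: LandmarkSet
) -> BoundaryStats:
    """Boundary measurements of the deformation area for one subject.

    ``upper_distance`` is the unsigned plane distance of the boundary vertex
    with the largest signed (superior-positive) distance to the ala-tragus
    plane — the most superior boundary point.  ``lower_distance`` is the
    smallest 3D distance from the boundary to the menton.  Each lateral
    ratio divides the most-lateral boundary vertex's distance to the
    ipsilateral commissure by the tragus-commissure length.
    """
    landmarks.require(
        "left_tragus", "right_tragus", "left_ala", "right_ala",
        "menton", "left_commissure", "right_commissure",
    )
    boundary = region_boundary(mesh, region)
    if boundary.size == 0:
        raise RegionError("deformation region is empty: no boundary statistics")
    bpts = mesh.vertices[boundary]
    plane = ala_tragus_plane(landmarks)
    upper = float(abs(plane.signed_distance(bpts).max()))
    lower = float(np.linalg.norm(bpts - landmarks["menton"], axis=1).min())

    def ratio(side: str, most_lateral: np.ndarray) -> float:
        com = landmarks[f"{side}_commissure"]
        tragus = landmarks[f"{side}_tragus"]
        denom = float(np.linalg.norm(tragus - com))
        if denom < 1e-12:
            raise LandmarkSchemaError(f"{side} tragus and commissure coincide")
        return float(np.linalg.norm(most_lateral - com) / denom)

    # laterality measured along the tragus-tragus axis (rigid-invariant;
    # equals the X axis in the canonical frame)
    lat_axis = landmarks["left_tragus"] - landmarks["right_tragus"]
    lat_axis = lat_axis / np.linalg.norm(lat_axis)
    proj = bpts @ lat_axis

    def most_lateral(sign: float, commissure: np.ndarray) -> np.ndarray:
        p = sign * proj
        # several boundary vertices can share the extreme projection; break
        # the tie (rigid-invariantly) toward the farthest from the commissure
        tied = bpts[p >= p.max() - 1e-6]
        d = np.linalg.norm(tied - commissure, axis=1)
        return tied[int(np.argmax(d))]

    left_most = most_lateral(+1.0, landmarks["left_commissure"])
    right_most = most_lateral(-1.0, landmarks["right_commissure"])
    return BoundaryStats(upper, lower, ratio("left", left_most), ratio("right", right_most))


def cohort_boundary_summary(stats_list: list[BoundaryStats]) -> pd.DataFrame:
    """Max / min / mean / sample standard deviation of each boundary metric."""
    if len(stats_list) < 2:
        raise ValueError(f"need >= 2 subjects, got {len(stats_list)}")
    frame = pd.DataFrame([s.as_dict() for s in stats_list])
    return pd.DataFrame(
        {
            "max": frame.max(),
            "min": frame.min(),
            "mean": frame.mean(),
            "sd": frame.std(ddof=1),
        }
    )
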