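"""Rigid registration of pre- and post-operative facial scans.

The clinical protocol is mirrored in software: a coarse 3-landmark
("n-point") alignment using the bilateral tragus centres and the nasal tip,
followed by a best-fit ICP refinement restricted to the upper third of the
face — the region complete dentures cannot move, hence shared between the
two scans.  A canonical face frame (X left-right, Y vertical, Z out of the
face) is established from the same landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, RegionError
from .mesh_io import LandmarkSet, TriangleMesh

__all__ = [
    "RigidTransform",
    "RegionMask",
    "ICPResult",
    "landmark_align",
    "kabsch",
    "upper_third_mask",
    "icp_refine",
    "canonical_transform",
    "canonical_frame",
]


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
            raise DegenerateGeometryError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise DegenerateGeometryError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def apply_mesh(self, mesh: TriangleMesh) -> TriangleMesh:
        return mesh.with_vertices(self.apply(mesh.vertices))

    def apply_landmarks(self, landmarks: LandmarkSet) -> LandmarkSet:
        return landmarks.transformed(self.rotation, self.translation)

    def rotation_angle_deg(self) -> float:
        """Rotation angle of R in degrees (0 for identity)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass
class RegionMask:
    """Boolean per-vertex membership flag with a semantic label."""

    mask: np.ndarray
    label: str = ""
    empty_flagged: bool = field(default=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool).ravel()

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    def check_mesh(self, mesh: TriangleMesh) -> None:
        if self.mask.size != mesh.vertex_count:
            raise RegionError(
                f"mask length {self.mask.size} != vertex count {mesh.vertex_count}"
            )


@dataclass
class ICPResult:
    """Refined transform plus convergence diagnostics."""

    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool


def kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping point set ``src`` onto ``dst``.

    Closed-form orthogonal-Procrustes (SVD) solution with reflection guard;
    no scale is estimated.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    if src.shape != dst.shape or src.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 corresponding points")
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    a = src - mu_s
    b = dst - mu_d
    s = np.linalg.svd(a, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise DegenerateGeometryError("point configuration is collinear")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    t = mu_d - r @ mu_s
    return RigidTransform(r, t)


def landmark_align(src: LandmarkSet, dst: LandmarkSet) -> RigidTransform:
    """Rigid transform taking ``src`` landmarks onto ``dst`` landmarks.

    Uses all landmark names present in both sets (at least the three
    mandatory ones); raises on collinear configurations.
    """
    common = [n for n in src.names if n in dst]
    if len(common) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 shared landmarks, have {len(common)}"
        )
    return kabsch(src.array(common), dst.array(common))


def upper_third_mask(mesh: TriangleMesh, landmarks: LandmarkSet) -> RegionMask:
    """Vertices above the ala-tragus level: the denture-invariant shared area.

    The cut height is the mean Y of the tragus centres and (when landmarked)
    the nasal alae — a proxy for the glabella-subnasale boundary, which is
    never landmarked in the scan protocol.
    """
    landmarks.require("left_tragus", "right_tragus", "nasal_tip")
    names = ["left_tragus", "right_tragus"]
    names += [n for n in ("left_ala", "right_ala") if n in landmarks]
    y_cut = float(landmarks.array(names)[:, 1].mean())
    mask = mesh.vertices[:, 1] > y_cut
    if not mask.any():
        raise RegionError(f"no vertex above the upper-third cut level y={y_cut:.3f}")
    return RegionMask(mask, label="upper_third")


def icp_refine(
    src: TriangleMesh,
    dst: TriangleMesh,
    mask: RegionMask,
    init: RigidTransform,
    max_iter: int = 100,
    tol: float = 1e-4,
    reject_distance: float = 5.0,
) -> ICPResult:
    """Point-to-point ICP (Besl-McKay) restricted to the masked source region.

    Correspondences are nearest neighbours in ``dst``; pairs farther than
    ``reject_distance`` mm are dropped.  The masked nearest-neighbour RMS is
    non-increasing across accepted iterations; iteration stops when the RMS
    improvement falls below ``tol`` mm (converged) or at ``max_iter``.
    """
    mask.check_mesh(src)
    if mask.count < 100:
        raise RegionError(f"ICP mask selects only {mask.count} vertices (< 100)")
    pts = src.vertices[mask.mask]
    tree = cKDTree(dst.vertices)

    def masked_rms(transform: RigidTransform) -> float:
        d, _ = tree.query(transform.apply(pts))
        return float(np.sqrt(np.mean(d**2)))

    best = init
    best_rms = masked_rms(init)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        moved = best.apply(pts)
        d, j = tree.query(moved)
        keep = d <= reject_distance
        if keep.sum() < 3:
            break
        candidate = kabsch(pts[keep], dst.vertices[j[keep]])
        rms = masked_rms(candidate)
        improvement = best_rms - rms
        if rms <= best_rms:  # accepted step: objective non-increasing
            best, best_rms = candidate, rms
        if improvement < tol:  # stalled (or fluctuating) within tolerance
            converged = True
            break
    return ICPResult(best, best_rms, iterations, converged)


def canonical_transform(mesh: TriangleMesh, landmarks: LandmarkSet) -> RigidTransform:
    """Transform into the canonical face frame.

    X runs right-to-left tragus (patient's left at +X), Z points out of the
    face (toward the nasal tip), Y = Z x X is vertical; the origin is the
    tragus midpoint.  Up/down is disambiguated by the menton when present
    (must end up below the tragus line), else by requiring the mesh centroid
    below the tragus line; this also corrects swapped left/right tragus
    labels, which would otherwise flip X and Y.
    """
    landmarks.require("left_tragus", "right_tragus", "nasal_tip")
    lt = landmarks["left_tragus"]
    rt = landmarks["right_tragus"]
    nt = landmarks["nasal_tip"]
    origin = (lt + rt) / 2.0
    x_axis = lt - rt
    nx = np.linalg.norm(x_axis)
    if nx < 1e-9:
        raise DegenerateGeometryError("tragus landmarks coincide")
    x_axis = x_axis / nx
    z0 = nt - origin
    z_axis = z0 - (z0 @ x_axis) * x_axis
    nz = np.linalg.norm(z_axis)
    if nz < 1e-9:
        raise DegenerateGeometryError("nasal tip collinear with tragus axis")
    z_axis = z_axis / nz
    y_axis = np.cross(z_axis, x_axis)

    r = np.vstack([x_axis, y_axis, z_axis])  # rows: canonical axes
    t = -r @ origin
    frame = RigidTransform(r, t)

    # up/down cue: the reference point must land below the tragus line (y<0)
    if "menton" in landmarks:
        cue_y = frame.apply(landmarks["menton"][None, :])[0, 1]
    else:
        cue_y = frame.apply(mesh.vertices).mean(axis=0)[1]
    if cue_y > 0:
        flip = RigidTransform(np.diag([-1.0, -1.0, 1.0]), np.zeros(3))
        frame = flip.compose(frame)
    return frame


def canonical_frame(
    mesh: TriangleMesh, landmarks: LandmarkSet
) -> tuple[TriangleMesh, LandmarkSet]:
    """Re-pose mesh and landmarks into the canonical face frame."""
    frame = canonical_transform(mesh, landmarks)
    return frame.apply_mesh(mesh), frame.apply_landmarks(landmarks)
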