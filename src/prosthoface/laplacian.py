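"""Laplacian (differential-coordinate) mesh deformation.

The uniform-weight mesh Laplacian L = I - D^-1 A (A the vertex adjacency
matrix, D the diagonal degree matrix) turns Cartesian vertex coordinates V
into differential coordinates delta = L V, the offset of each vertex from
its neighbourhood centroid.  Deformation solves the soft-constrained
stacked system

    [ L ]        [ delta ]
    [ C ]  V'  = [  w    ]          (least squares, per coordinate)

where C holds one weighted row per control vertex and w the weighted target
positions: the surface detail (delta) is preserved while the control
vertices are pulled toward their targets.  delta is kept from the
undeformed mesh (plain Laplacian editing; no rotation re-fitting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    ConstraintConflictError,
    DegenerateGeometryError,
    RegionError,
    SolvabilityError,
)
from .geometry import FeatureTemplate
from .mesh_io import TriangleMesh
from .registration import RegionMask

__all__ = [
    "LaplacianSystem",
    "ConstraintSet",
    "build_laplacian",
    "neighborhood_center",
    "solve_deformation",
    "propagate_template",
]


@dataclass
class LaplacianSystem:
    """Sparse uniform-weight Laplacian and the differential coordinates."""

    operator: sp.csr_matrix      # L = I - D^-1 A
    delta: np.ndarray            # (n, 3) differential coordinates L V
    degrees: np.ndarray          # vertex degrees d_i

    @property
    def size(self) -> int:
        return self.operator.shape[0]


@dataclass
class ConstraintSet:
    """Control vertices with target positions and positive weights."""

    indices: np.ndarray
    targets: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64).ravel()
        self.targets = np.asarray(self.targets, dtype=np.float64).reshape(-1, 3)
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if not (self.indices.size == self.targets.shape[0] == self.weights.size):
            raise SolvabilityError("constraint arrays have mismatched lengths")
        if np.unique(self.indices).size != self.indices.size:
            raise SolvabilityError("constraint indices must be unique")
        if np.any(self.weights <= 0):
            raise SolvabilityError("constraint weights must be positive")

    @property
    def count(self) -> int:
        return int(self.indices.size)

    @classmethod
    def concatenate(cls, *sets: "ConstraintSet") -> "ConstraintSet":
        return cls(
            np.concatenate([s.indices for s in sets]),
            np.concatenate([s.targets for s in sets]),
            np.concatenate([s.weights for s in sets]),
        )


def build_laplacian(mesh: TriangleMesh) -> LaplacianSystem:
    """Uniform-weight Laplacian of a mesh: L = I - D^-1 A, delta = L V."""
    deg = mesh.degrees
    if np.any(deg == 0):
        bad = int(np.flatnonzero(deg == 0)[0])
        raise DegenerateGeometryError(f"vertex {bad} has no neighbours")
    n = mesh.vertex_count
    inv_d = sp.diags(1.0 / deg.astype(np.float64))
    lap = (sp.eye(n, format="csr") - inv_d @ mesh.adjacency).tocsr()
    delta = lap @ mesh.vertices
    return LaplacianSystem(lap, delta, deg)


def neighborhood_center(mesh: TriangleMesh, vertex: int) -> np.ndarray:
    """Centroid of the vertices directly adjacent to ``vertex``."""
    nb = mesh.neighbors(int(vertex))
    if nb.size == 0:
        raise DegenerateGeometryError(f"vertex {vertex} has no neighbours")
    return mesh.vertices[nb].mean(axis=0)


def solve_deformation(system: LaplacianSystem, constraints: ConstraintSet) -> np.ndarray:
    """Solve the soft-constrained Laplacian system for new vertex positions.

    Minimizes ``||L V' - delta||^2 + sum_c weight_c^2 ||V'_c - w_c||^2``
    through the normal equations of the stacked sparse system, factorized
    once (sparse LU) and solved per coordinate.  Deterministic.
    """
    n = system.size
    if constraints.count < 3:
        raise SolvabilityError(
            f"need >= 3 constraints to pin the surface, got {constraints.count}"
        )
    span = np.linalg.svd(
        constraints.targets - constraints.targets.mean(axis=0), compute_uv=False
    )
    if span[1] < 1e-9 * max(span[0], 1e-300):
        raise SolvabilityError("constraint targets are collinear")
    if constraints.indices.max() >= n:
        raise SolvabilityError("constraint index out of range")

    rows = sp.coo_matrix(
        (constraints.weights, (np.arange(constraints.count), constraints.indices)),
        shape=(constraints.count, n),
    ).tocsr()
    a = sp.vstack([system.operator, rows], format="csr")
    b = np.vstack([system.delta, constraints.weights[:, None] * constraints.targets])
    normal = (a.T @ a).tocsc()
    rhs = a.T @ b
    try:
        factor = spla.splu(normal)
    except RuntimeError as exc:
        raise SolvabilityError(f"stacked system is rank deficient: {exc}") from exc
    out = np.column_stack([factor.solve(rhs[:, c]) for c in range(3)])
    if not np.all(np.isfinite(out)):
        raise SolvabilityError("singular stacked system (non-finite solution)")
    return out


def propagate_template(
    mesh: TriangleMesh,
    template: FeatureTemplate,
    predicted: np.ndarray,
    anchor_region: RegionMask,
    control_weight: float = 1.0,
    anchor_weight: float = 10.0,
) -> TriangleMesh:
    """Propagate predicted template displacements to the whole surface.

    Control constraints move the template's bound vertices by ``predicted``
    (29 x 3 mm); anchor constraints hold the given region (normally the
    upper third of the face) at its original position with a dominant
    weight, which keeps the deformation local to the perioral area.
    """
    if template.vertex_indices is None:
        raise ConstraintConflictError("template points are not bound to mesh vertices")
    anchor_region.check_mesh(mesh)
    predicted = np.asarray(predicted, dtype=np.float64).reshape(len(template), 3)
    anchor_idx = anchor_region.indices
    if anchor_idx.size == 0:
        raise RegionError("anchor region is empty; deformation would not be localized")
    overlap = np.intersect1d(anchor_idx, template.vertex_indices)
    if overlap.size:
        raise ConstraintConflictError(
            f"{overlap.size} vertices are both template controls and anchors"
        )
    controls = ConstraintSet(
        template.vertex_indices,
        mesh.vertices[template.vertex_indices] + predicted,
        np.full(len(template), float(control_weight)),
    )
    anchors = ConstraintSet(
        anchor_idx,
        mesh.vertices[anchor_idx],
        np.full(anchor_idx.size, float(anchor_weight)),
    )
    system = build_laplacian(mesh)
    new_v = solve_deformation(system, ConstraintSet.concatenate(controls, anchors))
    return mesh.with_vertices(new_v)
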