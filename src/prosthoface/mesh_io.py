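"""Triangle-mesh and landmark I/O.

Surface scans are exchanged as Wavefront OBJ (``v x y z [r g b]`` and
``f i j k`` lines, 1-based indices); anatomical landmarks travel in a JSON
sidecar mapping names to ``[x, y, z]`` millimetre coordinates, because OBJ
has no standard landmark dialect.  Internally everything is 0-based numpy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .errors import LandmarkSchemaError, MeshValidationError, ObjParseError

__all__ = [
    "TriangleMesh",
    "LandmarkSet",
    "REQUIRED_LANDMARKS",
    "OPTIONAL_LANDMARKS",
    "read_obj",
    "write_obj",
    "read_landmarks",
    "write_landmarks",
]

REQUIRED_LANDMARKS = ("left_tragus", "right_tragus", "nasal_tip")
OPTIONAL_LANDMARKS = (
    "left_ala",
    "right_ala",
    "menton",
    "left_commissure",
    "right_commissure",
)


@dataclass
class TriangleMesh:
    """A triangulated surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices (0-based)
    colors : optional (n, 3) float array, per-vertex RGB in [0, 1]
    """

    vertices: np.ndarray
    faces: np.ndarray
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.colors is not None:
            self.colors = np.ascontiguousarray(self.colors, dtype=np.float64)
        self._adjacency: sp.csr_matrix | None = None
        self.validate()

    # ---------------------------------------------------------------- basic
    @property
    def vertex_count(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def face_count(self) -> int:
        return int(self.faces.shape[0])

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (n, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshValidationError("non-finite vertex coordinate")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be (m, 3)")
        if self.face_count:
            if self.faces.min() < 0 or self.faces.max() >= self.vertex_count:
                raise MeshValidationError("face index out of range")
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise MeshValidationError(
                    f"face {int(np.flatnonzero(degenerate)[0])} repeats a vertex"
                )
        if self.colors is not None:
            if self.colors.shape != (self.vertex_count, 3):
                raise MeshValidationError("colors must match vertex count")
            if self.colors.min() < -1e-9 or self.colors.max() > 1 + 1e-9:
                raise MeshValidationError("colors must lie in [0, 1]")

    # ---------------------------------------------------- adjacency structure
    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric vertex-adjacency matrix A (1 where an edge exists)."""
        if self._adjacency is None:
            f = self.faces
            rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
            cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
            a = sp.coo_matrix(
                (np.ones(rows.size), (rows, cols)),
                shape=(self.vertex_count, self.vertex_count),
            ).tocsr()
            a.data[:] = 1.0
            self._adjacency = a
        return self._adjacency

    @property
    def degrees(self) -> np.ndarray:
        """Number of distinct neighbours of each vertex (row sums of A)."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def neighbors(self, i: int) -> np.ndarray:
        a = self.adjacency
        return a.indices[a.indptr[i] : a.indptr[i + 1]]

    def edge_face_count(self) -> np.ndarray:
        """Per undirected edge, how many faces contain it (manifold check)."""
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return counts

    def is_edge_manifold(self) -> bool:
        return bool((self.edge_face_count() <= 2).all())

    # -------------------------------------------------------------- utilities
    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.colors is None else self.colors.copy(),
        )

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity (and colors), new vertex positions."""
        return TriangleMesh(np.asarray(vertices, dtype=np.float64), self.faces.copy(),
                            None if self.colors is None else self.colors.copy())


@dataclass
class LandmarkSet:
    """Named anatomical points in mm, optionally bound to mesh vertices.

    ``left_tragus``, ``right_tragus`` and ``nasal_tip`` are mandatory; the
    nasal alae, menton and mouth commissures are optional and only needed by
    the boundary-statistics operators.
    """

    points: dict[str, np.ndarray]
    vertex_indices: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=np.float64).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise LandmarkSchemaError(f"landmark {name!r} is not finite")
            clean[name] = arr
        self.points = clean
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.points]
        if missing:
            raise LandmarkSchemaError(f"missing required landmark(s): {missing}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    @property
    def names(self) -> list[str]:
        return list(self.points)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise LandmarkSchemaError(f"operation requires landmark(s): {missing}")

    def array(self, names) -> np.ndarray:
        return np.array([self.points[n] for n in names])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LandmarkSet":
        pts = {n: rotation @ p + translation for n, p in self.points.items()}
        return LandmarkSet(pts, dict(self.vertex_indices))

    def bind_to_mesh(self, mesh: TriangleMesh) -> "LandmarkSet":
        """Attach each landmark to its nearest mesh vertex index."""
        from scipy.spatial import cKDTree

        tree = cKDTree(mesh.vertices)
        idx = {n: int(tree.query(p)[1]) for n, p in self.points.items()}
        return LandmarkSet(dict(self.points), idx)


# ------------------------------------------------------------------ OBJ I/O
def read_obj(path) -> TriangleMesh:
    """Read a triangle mesh from Wavefront OBJ.

    Supports the per-vertex-RGB dialect (6-number ``v`` lines).  Polygonal
    faces are fan-triangulated with a warning; ``f`` entries of the form
    ``i/j/k`` keep only the vertex index.  Raises :class:`ObjParseError`
    with the line number on malformed input.
    """
    vertices: list[list[float]] = []
    colors: list[list[float]] = []
    faces: list[list[int]] = []
    warned_polygon = False

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                try:
                    nums = [float(x) for x in parts[1:]]
                except ValueError as exc:
                    raise ObjParseError(f"bad vertex line: {line!r}", lineno) from exc
                if len(nums) == 3:
                    vertices.append(nums)
                    colors.append([np.nan] * 3)
                elif len(nums) == 6:
                    vertices.append(nums[:3])
                    colors.append(nums[3:])
                else:
                    raise ObjParseError(
                        f"vertex line must carry 3 or 6 numbers, got {len(nums)}", lineno
                    )
            elif tag == "f":
                try:
                    idx = [int(p.split("/")[0]) for p in parts[1:]]
                except ValueError as exc:
                    raise ObjParseError(f"bad face line: {line!r}", lineno) from exc
                if len(idx) < 3:
                    raise ObjParseError("face needs at least 3 indices", lineno)
                if any(i <= 0 for i in idx):
                    raise ObjParseError("only positive 1-based face indices supported", lineno)
                if len(idx) > 3 and not warned_polygon:
                    warnings.warn(
                        f"{path}: polygonal face at line {lineno} fan-triangulated",
                        stacklevel=2,
                    )
                    warned_polygon = True
                for k in range(1, len(idx) - 1):  # fan triangulation
                    faces.append([idx[0] - 1, idx[k] - 1, idx[k + 1] - 1])
            # silently ignore vn/vt/usemtl etc.

    if not vertices:
        raise ObjParseError("no vertices found in OBJ file")
    v = np.array(vertices, dtype=np.float64)
    c = np.array(colors, dtype=np.float64)
    f = np.array(faces, dtype=np.int64).reshape(-1, 3)
    if f.size and f.max() >= len(v):
        raise MeshValidationError(
            f"face references vertex {int(f.max()) + 1} but only {len(v)} vertices exist"
        )
    has_color = ~np.isnan(c[:, 0])
    if has_color.all():
        color_arr = c
    elif has_color.any():
        raise ObjParseError("mixed colored and uncolored vertex lines")
    else:
        color_arr = None
    return TriangleMesh(v, f, color_arr)


def write_obj(mesh: TriangleMesh, path) -> None:
    """Write a mesh as OBJ; coordinates printed with 17 significant digits so
    a read-back round-trip is bit-identical."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if mesh.colors is None:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        else:
            for v, c in zip(mesh.vertices, mesh.colors):
                fh.write(
                    f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
                    f" {c[0]:.17g} {c[1]:.17g} {c[2]:.17g}\n"
                )
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ------------------------------------------------------------ landmark I/O
def read_landmarks(path) -> LandmarkSet:
    """Read a landmark sidecar JSON ``{"nasal_tip": [x, y, z], ...}``."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise LandmarkSchemaError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(data, dict):
        raise LandmarkSchemaError(f"{path}: expected a JSON object")
    points = {}
    for name, value in data.items():
        arr = np.asarray(value, dtype=np.float64)
        if arr.shape != (3,):
            raise LandmarkSchemaError(f"{path}: landmark {name!r} is not a 3-vector")
        points[name] = arr
    return LandmarkSet(points)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    data = {n: [float(x) for x in p] for n, p in landmarks.points.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
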