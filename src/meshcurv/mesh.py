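"""Triangle-mesh substrate: validation, I/O, areas, topology, and ensembles.

Every downstream curvature statistic is computed on a :class:`TriangleMesh`,
a validated (oriented, manifold, non-degenerate) triangle surface in mm
units.  The module also provides the discrete Gauss--Bonnet angle-defect
total curvature, which serves as an exact topological oracle for the
shape-operator pipeline, and the mesh-ensemble generator used to average
out meshing/smoothing variance in specimen statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh
import trimesh.smoothing

__all__ = [
    "TriangleMesh",
    "MeshTopology",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "vertex_areas",
    "total_area_volume",
    "angle_defect_total_curvature",
    "mesh_ensemble",
]

log = logging.getLogger(__name__)

_DEGENERATE_AREA = 1e-14


class MeshValidationError(ValueError):
    """Raised when a surface violates the TriangleMesh invariants."""


@dataclass
class MeshTopology:
    """Combinatorial topology of a triangle mesh.

    ``euler_characteristic`` is V - E + F exactly; ``genus`` is defined
    only for closed surfaces (``boundary_loop_count == 0``).
    """

    euler_characteristic: int
    boundary_loop_count: int
    genus: Optional[int]

    @property
    def is_closed(self) -> bool:
        return self.boundary_loop_count == 0


@dataclass
class TriangleMesh:
    """An oriented manifold triangle surface (units: mm).

    Invariants enforced at construction:

    * every face index is a valid vertex index, faces have three distinct
      vertices and positive area;
    * the surface is consistently oriented (each interior edge appears
      once per direction across its two adjacent faces) and edge-manifold;
    * closed surfaces are oriented outward (signed volume > 0); the
      orientation is repaired by flipping all faces when necessary.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""
    _tm: Optional[trimesh.Trimesh] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be (m, 3)")
        self._validate()

    # -- validation -----------------------------------------------------

    def _validate(self) -> None:
        n = len(self.vertices)
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= n:
            raise MeshValidationError("face references a missing vertex")
        f = self.faces
        if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
            raise MeshValidationError("degenerate face: repeated vertex index")
        v = self.vertices
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        areas = 0.5 * np.linalg.norm(cross, axis=1)
        if (areas <= _DEGENERATE_AREA).any():
            raise MeshValidationError("degenerate face: zero area")

        # orientation / manifoldness via directed edges
        de = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        key = de[:, 0] * np.int64(n) + de[:, 1]
        if len(np.unique(key)) != len(key):
            raise MeshValidationError(
                "inconsistent orientation or non-manifold: repeated directed edge"
            )
        ukey = np.minimum(de[:, 0], de[:, 1]) * np.int64(n) + np.maximum(de[:, 0], de[:, 1])
        _, counts = np.unique(ukey, return_counts=True)
        if (counts > 2).any():
            raise MeshValidationError("non-manifold edge (more than two incident faces)")

        self._boundary_edge_count = int((counts == 1).sum())
        if self._boundary_edge_count == 0:
            vol = self._signed_volume()
            if vol < 0:
                self.faces = self.faces[:, ::-1].copy()
                self._tm = None

    def _signed_volume(self) -> float:
        v, f = self.vertices, self.faces
        return float(np.einsum("ij,ij->", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))) / 6.0

    # -- derived --------------------------------------------------------

    @property
    def trimesh(self) -> trimesh.Trimesh:
        if self._tm is None:
            self._tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        return self._tm

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def is_closed(self) -> bool:
        return self._boundary_edge_count == 0

    def edges_unique(self) -> np.ndarray:
        f = self.faces
        de = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        ue = np.sort(de, axis=1)
        return np.unique(ue, axis=0)

    def boundary_edges(self) -> np.ndarray:
        """Undirected edges incident to exactly one face, as (k, 2) indices."""
        f = self.faces
        de = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        ue = np.sort(de, axis=1)
        uniq, counts = np.unique(ue, axis=0, return_counts=True)
        return uniq[counts == 1]

    def boundary_vertices(self) -> np.ndarray:
        be = self.boundary_edges()
        return np.unique(be) if len(be) else np.empty(0, dtype=np.int64)

    def topology(self) -> MeshTopology:
        V = self.n_vertices
        E = len(self.edges_unique())
        F = self.n_faces
        chi = V - E + F
        loops = _count_boundary_loops(self.boundary_edges(), V)
        genus = (2 - chi) // 2 if loops == 0 else None
        return MeshTopology(chi, loops, genus)

    def scaled(self, s: float) -> "TriangleMesh":
        """Uniformly scaled copy (shape-preserving)."""
        return TriangleMesh(self.vertices * float(s), self.faces.copy(), self.label)


def _count_boundary_loops(boundary_edges: np.ndarray, n_vertices: int) -> int:
    if len(boundary_edges) == 0:
        return 0
    # union-find over boundary edges
    parent = np.arange(n_vertices)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in boundary_edges:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[ra] = rb
    roots = {find(int(a)) for a in boundary_edges.ravel()}
    return len(roots)


# -- I/O ----------------------------------------------------------------


def read_mesh(path, file_type: Optional[str] = None, label: Optional[str] = None) -> TriangleMesh:
    """Read an STL/PLY/OBJ surface and validate it.

    Duplicate vertices are merged within trimesh's default tolerance and
    unreferenced vertices dropped.  Units are assumed to be mm; no unit
    metadata is read.  Raises :class:`MeshValidationError` if the cleaned
    surface is non-manifold or inconsistently oriented.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    loaded = trimesh.load(str(path), file_type=file_type, force="mesh", process=True)
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise MeshValidationError(f"{path}: no triangle surface found")
    mesh = TriangleMesh(loaded.vertices, loaded.faces, label or path.stem)
    topo = mesh.topology()
    log.info(
        "read %s: V=%d E=%d F=%d chi=%d loops=%d",
        path, mesh.n_vertices, len(mesh.edges_unique()), mesh.n_faces,
        topo.euler_characteristic, topo.boundary_loop_count,
    )
    return mesh


def write_mesh(mesh: TriangleMesh, path) -> None:
    """Write a surface to STL/PLY/OBJ inferred from the path suffix."""
    mesh.trimesh.export(str(path))


# -- elementary geometry ------------------------------------------------


def face_areas(mesh: TriangleMesh) -> np.ndarray:
    v, f = mesh.vertices, mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Barycentric per-vertex area elements a_i (mm^2).

    Each face contributes one third of its area to each of its vertices,
    so the vertex areas are nonnegative and partition the total face area
    exactly.
    """
    fa = face_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    return out


def total_area_volume(mesh: TriangleMesh) -> tuple[float, Optional[float]]:
    """Total surface area A_T (mm^2) and enclosed volume V (mm^3).

    V is the signed-tetrahedron sum, positive for outward orientation;
    it is ``None`` for open surfaces.
    """
    a_t = float(face_areas(mesh).sum())
    vol = mesh._signed_volume() if mesh.is_closed else None
    return a_t, vol


def _corner_angles(mesh: TriangleMesh) -> np.ndarray:
    """Interior angles per face corner, shape (m, 3)."""
    v, f = mesh.vertices, mesh.faces
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    angles = np.empty((len(f), 3))
    for i, (a, b, c) in enumerate(((p0, p1, p2), (p1, p2, p0), (p2, p0, p1))):
        u = b - a
        w = c - a
        cosang = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        )
        angles[:, i] = np.arccos(np.clip(cosang, -1.0, 1.0))
    return angles


def angle_defect_total_curvature(mesh: TriangleMesh) -> float:
    """Discrete Gauss--Bonnet total curvature (steradians).

    Returns the sum over interior vertices of ``2*pi - angle sum`` plus
    the sum over boundary vertices of ``pi - angle sum``.  This equals
    ``2*pi*chi`` exactly for any mesh (a combinatorial identity), which
    makes it an independent topological oracle for the shape-operator
    based total curvature: closed genus-0 surfaces give 4*pi, tori and
    open tubes give 0.
    """
    angles = _corner_angles(mesh)
    angle_sum = np.zeros(mesh.n_vertices)
    np.add.at(angle_sum, mesh.faces.ravel(), angles.ravel())
    interior = np.ones(mesh.n_vertices, dtype=bool)
    bv = mesh.boundary_vertices()
    interior[bv] = False
    total = float(np.sum(2.0 * np.pi - angle_sum[interior]))
    if len(bv):
        total += float(np.sum(np.pi - angle_sum[bv]))
    return total


# -- mesh ensemble ------------------------------------------------------

SMOOTH_ITERATIONS = (0, 5, 15)
DENSITY_FACTORS = (1.0, 0.9, 0.8, 0.7, 0.6)


def mesh_ensemble(
    mesh: TriangleMesh,
    n_density: int = 5,
    n_smooth: int = 3,
) -> list[TriangleMesh]:
    """Meshing/smoothing variants used to average out process variance.

    ``n_density`` refinement levels (target edge lengths spanning a
    factor of the input resolution, the first being the identity) crossed
    with ``n_smooth`` volume-preserving Taubin smoothing levels
    (iteration counts 0, 5, 15, ...).  Variants that fail validation are
    logged and dropped; topology is never altered.
    """
    if n_density < 1 or n_smooth < 1:
        raise ValueError("n_density and n_smooth must be >= 1")
    factors = list(DENSITY_FACTORS)
    while len(factors) < n_density:
        factors.append(factors[-1] * 0.9)
    iters = list(SMOOTH_ITERATIONS)
    while len(iters) < n_smooth:
        iters.append(iters[-1] * 2)

    v, f = mesh.vertices, mesh.faces
    edge_vec = v[f[:, 1]] - v[f[:, 0]]
    median_edge = float(np.median(np.linalg.norm(edge_vec, axis=1)))

    out: list[TriangleMesh] = []
    for fi, factor in enumerate(factors[:n_density]):
        if fi == 0:
            dv, df = v.copy(), f.copy()
        else:
            dv, df = trimesh.remesh.subdivide_to_size(
                v, f, max_edge=factor * median_edge, max_iter=8
            )
        for it in iters[:n_smooth]:
            try:
                if it == 0:
                    sv = dv.copy()
                else:
                    tm = trimesh.Trimesh(dv.copy(), df.copy(), process=False)
                    trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=0.53, iterations=it)
                    sv = np.asarray(tm.vertices)
                variant = TriangleMesh(sv, df.copy(), f"{mesh.label}[d{fi}s{it}]")
            except MeshValidationError as err:  # pragma: no cover - defensive
                log.warning("dropping ensemble variant d=%s iters=%s: %s", factor, it, err)
                continue
            out.append(variant)
    if not out:
        raise MeshValidationError("all ensemble variants failed validation")
    return out
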