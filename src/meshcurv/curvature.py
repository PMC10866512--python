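"""Per-vertex shape operators via the Rusinkiewicz finite-difference scheme.

The second fundamental form of each triangle is estimated by least
squares from the directional derivatives of the vertex normals along the
three edges; per-vertex shape operators are the area-weighted average of
the adjacent face tensors re-expressed in the vertex tangent frame.
Principal curvatures are ordered by magnitude (|k1| <= |k2|) so that
R2 = 1/|k2| recovers the tube radius on cylindrical surfaces, the radius
measure that sets the inner partition scale downstream.

Sign convention: the shape operator is the tangential derivative of the
outward unit normal, so a sphere with outward normals has k1 = k2 = +1/r
and positive mean curvature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .mesh import TriangleMesh, face_areas, vertex_areas

__all__ = [
    "VertexCurvature",
    "FaceTensors",
    "vertex_normals",
    "per_face_second_fundamental",
    "per_vertex_shape_operator",
    "remove_rim_artifacts",
    "comparator_curvature_metrics",
    "curvature_sum_K",
]

R2_EPS = 1e-6  # |k2| below this (mm^-1) leaves R2 undefined at the vertex


@dataclass
class VertexCurvature:
    """Per-vertex principal curvatures and derived scalars.

    ``k1``/``k2`` in mm^-1 with |k1| <= |k2|; ``kappa_g = k1*k2`` (mm^-2);
    Casorati ``C = (k1^2 + k2^2)/2`` (mm^-2); ``curvedness = sqrt(C)``
    (mm^-1); ``R2 = 1/|k2|`` (mm, NaN where |k2| < R2_EPS); ``valid`` is
    False at vertices excluded from all statistics (artifacts, isolated
    vertices, vertices with no well-posed incident face tensor).
    """

    k1: np.ndarray
    k2: np.ndarray
    kappa_g: np.ndarray
    casorati: np.ndarray
    curvedness: np.ndarray
    R2: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.k1)

    @classmethod
    def from_principal(cls, k1: np.ndarray, k2: np.ndarray, valid: np.ndarray) -> "VertexCurvature":
        kappa_g = k1 * k2
        cas = 0.5 * (k1 * k1 + k2 * k2)
        curv = np.sqrt(cas)
        with np.errstate(divide="ignore"):
            R2 = np.where(np.abs(k2) >= R2_EPS, 1.0 / np.abs(k2), np.nan)
        return cls(k1, k2, kappa_g, cas, curv, R2, valid.astype(bool))

    def median_R2(self) -> float:
        """Inner scale ell: median tube radius over valid vertices."""
        r = self.R2[self.valid]
        r = r[np.isfinite(r)]
        if len(r) == 0:
            raise ValueError("no valid finite R2 values")
        return float(np.median(r))


@dataclass
class FaceTensors:
    """Per-face second fundamental form in a per-face orthonormal frame."""

    II: np.ndarray        # (m, 2, 2) symmetric
    u: np.ndarray         # (m, 3) first tangent axis
    v: np.ndarray         # (m, 3) second tangent axis
    normal: np.ndarray    # (m, 3)
    valid: np.ndarray     # (m,) least-squares well-posedness


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted average of incident face normals, unit length."""
    v, f = mesh.vertices, mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    out = np.zeros_like(v)
    for c in range(3):
        np.add.at(out, f[:, c], cross)
    norms = np.linalg.norm(out, axis=1)
    norms[norms == 0] = 1.0
    return out / norms[:, None]


def per_face_second_fundamental(
    mesh: TriangleMesh, normals: Optional[np.ndarray] = None
) -> FaceTensors:
    """Least-squares per-face second fundamental form.

    For each face the symmetric tensor ``[[e, f], [f, g]]`` minimizing
    ``|II . t_k - dn_k|`` over the three edges is solved in the face's
    orthonormal tangent frame, where ``t_k`` is the edge tangent and
    ``dn_k`` the difference of vertex normals across the edge.  Faces
    whose normal equations are numerically rank-deficient are marked
    invalid.
    """
    if normals is None:
        normals = vertex_normals(mesh)
    v, f = mesh.vertices, mesh.faces
    p = v[f]                       # (m, 3, 3)
    n = normals[f]                 # (m, 3, 3)

    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    fn /= np.linalg.norm(fn, axis=1, keepdims=True)
    u = p[:, 1] - p[:, 0]
    u -= np.einsum("ij,ij->i", u, fn)[:, None] * fn
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    w = np.cross(fn, u)

    # edges opposite each corner and matching normal differences
    e = np.stack([p[:, 2] - p[:, 1], p[:, 0] - p[:, 2], p[:, 1] - p[:, 0]], axis=1)
    dn = np.stack([n[:, 2] - n[:, 1], n[:, 0] - n[:, 2], n[:, 1] - n[:, 0]], axis=1)

    eu = np.einsum("mkj,mj->mk", e, u)     # (m, 3)
    ev = np.einsum("mkj,mj->mk", e, w)
    du = np.einsum("mkj,mj->mk", dn, u)
    dv = np.einsum("mkj,mj->mk", dn, w)

    m = len(f)
    A = np.zeros((m, 6, 3))
    b = np.empty((m, 6))
    A[:, 0:3, 0] = eu
    A[:, 0:3, 1] = ev
    A[:, 3:6, 1] = eu
    A[:, 3:6, 2] = ev
    b[:, 0:3] = du
    b[:, 3:6] = dv

    ata = np.einsum("mki,mkj->mij", A, A)
    atb = np.einsum("mki,mk->mi", A, b)
    det = np.linalg.det(ata)
    scale = np.einsum("mkk->m", ata) / 3.0
    valid = det > (1e-12 * np.maximum(scale, 1e-300) ** 3)

    sol = np.zeros((m, 3))
    if valid.any():
        sol[valid] = np.linalg.solve(ata[valid], atb[valid][..., None])[..., 0]
    II = np.empty((m, 2, 2))
    II[:, 0, 0] = sol[:, 0]
    II[:, 0, 1] = II[:, 1, 0] = sol[:, 1]
    II[:, 1, 1] = sol[:, 2]
    return FaceTensors(II=II, u=u, v=w, normal=fn, valid=valid)


def _rotate_frame_to_normal(axes: np.ndarray, from_n: np.ndarray, to_n: np.ndarray) -> np.ndarray:
    """Minimal rotation taking ``from_n`` to ``to_n``, applied to ``axes``.

    ``axes`` has shape (m, 3); the rotation is about ``from_n x to_n``.
    Antiparallel normal pairs (c <= -1 + 1e-9) fall back to a flip
    through the plane, which only occurs on pathological meshes.
    """
    c = np.einsum("ij,ij->i", from_n, to_n)
    r = np.cross(from_n, to_n)
    out = np.empty_like(axes)
    ok = c > -1.0 + 1e-9
    cc = np.where(ok, c, 1.0)
    # Rodrigues with angle from cross/dot of unit vectors
    rx = np.cross(r, axes)
    rrx = np.cross(r, rx)
    out[:] = axes + rx + rrx / (1.0 + cc)[:, None]
    if (~ok).any():
        out[~ok] = -axes[~ok]
    return out


def _vertex_frames(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """An arbitrary orthonormal tangent basis per vertex."""
    n = normals
    ref = np.zeros_like(n)
    smallest = np.argmin(np.abs(n), axis=1)
    ref[np.arange(len(n)), smallest] = 1.0
    u = np.cross(n, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(n, u)
    return u, v


def per_vertex_shape_operator(
    mesh: TriangleMesh, face_tensors: Optional[FaceTensors] = None
) -> VertexCurvature:
    """Average adjacent face tensors into per-vertex principal curvatures.

    Each face tensor is transported into the vertex tangent frame by the
    minimal rotation aligning the face normal with the vertex normal, and
    averaged with weight equal to the face's barycentric area
    contribution (one third of the face area).  The 2x2 eigenproblem is
    solved in closed form; eigenvalues are ordered by magnitude with
    positive-first tie-breaking.
    """
    normals = vertex_normals(mesh)
    if face_tensors is None:
        face_tensors = per_face_second_fundamental(mesh, normals)
    fa = face_areas(mesh)
    uv_u, uv_v = _vertex_frames(normals)

    nv = mesh.n_vertices
    acc = np.zeros((nv, 3))       # s11, s12, s22 accumulators
    wsum = np.zeros(nv)

    f = mesh.faces
    ok = face_tensors.valid
    for corner in range(3):
        vid = f[:, corner]
        # rotate the face frame into each corner vertex's tangent plane
        fu = _rotate_frame_to_normal(face_tensors.u, face_tensors.normal, normals[vid])
        fv = _rotate_frame_to_normal(face_tensors.v, face_tensors.normal, normals[vid])
        # coordinates of the vertex axes in the rotated face frame
        a1 = np.stack(
            [np.einsum("ij,ij->i", uv_u[vid], fu), np.einsum("ij,ij->i", uv_u[vid], fv)], axis=1
        )
        a2 = np.stack(
            [np.einsum("ij,ij->i", uv_v[vid], fu), np.einsum("ij,ij->i", uv_v[vid], fv)], axis=1
        )
        II = face_tensors.II
        s11 = np.einsum("mi,mij,mj->m", a1, II, a1)
        s12 = np.einsum("mi,mij,mj->m", a1, II, a2)
        s22 = np.einsum("mi,mij,mj->m", a2, II, a2)
        w = np.where(ok, fa / 3.0, 0.0)
        np.add.at(acc, vid, np.stack([s11 * w, s12 * w, s22 * w], axis=1))
        np.add.at(wsum, vid, w)

    has_data = wsum > 0
    s = np.zeros((nv, 3))
    s[has_data] = acc[has_data] / wsum[has_data, None]

    tr_half = 0.5 * (s[:, 0] + s[:, 2])
    disc = np.sqrt(np.maximum(0.25 * (s[:, 0] - s[:, 2]) ** 2 + s[:, 1] ** 2, 0.0))
    ka = tr_half + disc
    kb = tr_half - disc
    swap = np.abs(ka) > np.abs(kb)
    k1 = np.where(swap, kb, ka)
    k2 = np.where(swap, ka, kb)
    tie = np.isclose(np.abs(k1), np.abs(k2)) & (k1 < k2)
    k1t = np.where(tie, k2, k1)
    k2 = np.where(tie, k1, k2)
    k1 = k1t
    return VertexCurvature.from_principal(k1, k2, has_data)


def curvature_sum_K(mesh: TriangleMesh, curv: VertexCurvature) -> float:
    """Direct estimate sum_i kappa_gi * a_i over valid vertices (steradians)."""
    va = vertex_areas(mesh)
    m = curv.valid
    return float(np.sum(curv.kappa_g[m] * va[m]))


# -- artifact removal ---------------------------------------------------


def _n_ring_mask(mesh: TriangleMesh, seeds: np.ndarray, n_ring: int) -> np.ndarray:
    """Vertices within ``n_ring`` edge hops of any seed vertex."""
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    if len(seeds) == 0 or n_ring < 0:
        return mask
    edges = mesh.edges_unique()
    nbr_from = np.concatenate([edges[:, 0], edges[:, 1]])
    nbr_to = np.concatenate([edges[:, 1], edges[:, 0]])
    mask[seeds] = True
    frontier = mask.copy()
    for _ in range(n_ring):
        hit = frontier[nbr_from]
        new = np.zeros_like(mask)
        new[nbr_to[hit]] = True
        frontier = new & ~mask
        mask |= new
        if not frontier.any():
            break
    return mask


def remove_rim_artifacts(
    mesh: TriangleMesh,
    curv: VertexCurvature,
    n_ring: int = 3,
    kappa_g_threshold: float = 1e-6,
    curvedness_threshold: float = 1e-3,
    max_removed_fraction: float = 0.5,
) -> tuple[VertexCurvature, float]:
    """Flag rim and machine-flat artifact vertices as invalid.

    Vertices within ``n_ring`` topological rings of any boundary loop
    are removed (truncated specimen ends), as are connected patches of
    machine-flat vertices (|kappa_g| below ``kappa_g_threshold`` mm^-2
    AND curvedness below ``curvedness_threshold`` mm^-1 -- segmentation
    cut planes and caps; genuinely cylindrical walls stay well above the
    curvedness threshold).  Returns the updated curvature record and the
    retained valid-vertex area (mm^2).  Raises if more than
    ``max_removed_fraction`` of previously valid vertices would be lost.
    """
    valid = curv.valid.copy()
    n_valid_before = int(valid.sum())

    rim = _n_ring_mask(mesh, mesh.boundary_vertices(), n_ring)

    flat = (np.abs(curv.kappa_g) < kappa_g_threshold) & (
        curv.curvedness < curvedness_threshold
    )
    flat_patch = np.zeros(mesh.n_vertices, dtype=bool)
    if flat.any():
        edges = mesh.edges_unique()
        keep = flat[edges[:, 0]] & flat[edges[:, 1]]
        e = edges[keep]
        graph = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])),
            shape=(mesh.n_vertices, mesh.n_vertices),
        )
        _, labels = connected_components(graph, directed=False)
        flat_ids = np.unique(labels[flat])
        flat_patch = np.isin(labels, flat_ids) & flat

    valid &= ~(rim | flat_patch)
    n_removed = n_valid_before - int(valid.sum())
    if n_valid_before and n_removed / n_valid_before > max_removed_fraction:
        raise ValueError(
            f"artifact removal would discard {n_removed}/{n_valid_before} vertices; "
            "surface dominated by artifact"
        )
    va = vertex_areas(mesh)
    retained_area = float(va[valid].sum())
    return replace(curv, valid=valid), retained_area


# -- comparator metrics -------------------------------------------------


def comparator_curvature_metrics(mesh: TriangleMesh, curv: VertexCurvature) -> dict:
    """Literature comparator metrics from per-vertex curvatures.

    GAA/MAA are area-weighted means of Gaussian and mean curvature; GLN
    and MLN are the square roots of the area-weighted means of their
    squares (L2-norm forms).  Sphericity and flatness come from the
    eigenvalues (l1 >= l2 >= l3) of the area-weighted vertex covariance:
    sphericity = sqrt(l3/l1) and flatness = sqrt(l3/l2), both maximal
    (= 1) on a sphere.
    """
    va = vertex_areas(mesh)
    m = curv.valid
    w = va[m] / va[m].sum()
    kg = curv.kappa_g[m]
    km = 0.5 * (curv.k1[m] + curv.k2[m])
    gaa = float(np.sum(w * kg))
    maa = float(np.sum(w * km))
    gln = float(np.sqrt(np.sum(w * kg**2)))
    mln = float(np.sqrt(np.sum(w * km**2)))

    pts = mesh.vertices[m]
    mu = np.average(pts, axis=0, weights=w)
    d = pts - mu
    cov = np.einsum("i,ij,ik->jk", w, d, d)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam = np.maximum(lam, 0.0)
    sphericity = float(np.sqrt(lam[2] / lam[0])) if lam[0] > 0 else 0.0
    flatness = float(np.sqrt(lam[2] / lam[1])) if lam[1] > 0 else 0.0
    return {
        "GLN": gln,
        "GAA": gaa,
        "MLN": mln,
        "MAA": maa,
        "sphericity_chi": sphericity,
        "flatness_gamma": flatness,
    }
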