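"""Parametric ideal surfaces with analytic curvature oracles.

Spheres, cylinders, tori, catenoids and pseudospheres are the canonical
representatives of the elliptic / parabolic / hyperbolic geometries with
total curvature 4*pi, 0, and -4*pi; they validate the whole pipeline
end-to-end because their principal curvatures are known in closed form
at every vertex.

Open surfaces (cylinder, catenoid, pseudosphere) are generated without
caps; downstream rim-artifact removal excludes a few vertex rings at the
boundaries, mirroring how truncated specimen ends are treated.  The
pseudosphere is the two-horn tractricoid truncated away from its cusp
circle (the meridian is singular there) and away from the thin far ends:
each horn spans t in [t_min, t_max] and carries total curvature
-2*pi*(sech(t_min) - sech(t_max)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

from .mesh import TriangleMesh

__all__ = [
    "IdealSurface",
    "sphere",
    "cylinder",
    "torus",
    "catenoid",
    "pseudosphere",
    "generate",
    "validation_suite",
]


@dataclass
class IdealSurface:
    """A generated ideal shape with per-vertex analytic curvatures."""

    mesh: TriangleMesh
    family: str
    params: dict
    k1: np.ndarray
    k2: np.ndarray
    uv: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def kappa_g(self) -> np.ndarray:
        return self.k1 * self.k2


def _grid_faces(nu: int, nv: int, close_u: bool) -> np.ndarray:
    """Triangulate an nv x nu structured grid (rows indexed by v)."""
    iu = np.arange(nu if close_u else nu - 1)
    iu1 = (iu + 1) % nu
    faces = []
    for j in range(nv - 1):
        a = j * nu + iu
        b = j * nu + iu1
        c = (j + 1) * nu + iu1
        d = (j + 1) * nu + iu
        faces.append(np.stack([a, b, c], axis=1))
        faces.append(np.stack([a, c, d], axis=1))
    return np.concatenate(faces)


def sphere(radius: float = 10.0, edge: float = 1.0, label: str = "") -> IdealSurface:
    """Icosphere of the given radius; k1 = k2 = 1/r everywhere."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    sub = int(np.clip(np.ceil(np.log2(max(1.0514 * radius / edge, 1.0))), 1, 7))
    tm = trimesh.creation.icosphere(subdivisions=sub, radius=radius)
    mesh = TriangleMesh(tm.vertices, tm.faces, label or f"sphere_r{radius:g}")
    n = mesh.n_vertices
    k = np.full(n, 1.0 / radius)
    return IdealSurface(mesh, "sphere", {"radius": radius, "edge": edge}, k.copy(), k)


def cylinder(
    radius: float = 10.0, length: float = 160.0, edge: float = 1.0, label: str = ""
) -> IdealSurface:
    """Open cylinder (no caps): k1 = 0 axially, k2 = 1/r circumferentially."""
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    nu = max(16, int(round(2 * np.pi * radius / edge)))
    nv = max(8, int(round(length / edge)) + 1)
    u = np.linspace(0, 2 * np.pi, nu, endpoint=False)
    v = np.linspace(0, length, nv)
    uu, vv = np.meshgrid(u, v)
    verts = np.stack(
        [radius * np.cos(uu), radius * np.sin(uu), vv], axis=-1
    ).reshape(-1, 3)
    faces = _grid_faces(nu, nv, close_u=True)
    mesh = TriangleMesh(verts, faces, label or f"cylinder_r{radius:g}")
    n = mesh.n_vertices
    return IdealSurface(
        mesh, "cylinder", {"radius": radius, "length": length, "edge": edge},
        np.zeros(n), np.full(n, 1.0 / radius),
        uv=np.stack([uu.ravel(), vv.ravel()], axis=1),
    )


def torus(
    R: float = 30.0, r: float = 10.0, edge: float = 1.0, label: str = ""
) -> IdealSurface:
    """Closed torus; kappa_g = cos(v) / (r * (R + r*cos(v)))."""
    if R <= r or r <= 0:
        raise ValueError("torus requires R > r > 0")
    nu = max(16, int(round(2 * np.pi * (R + r) / edge)))
    nv = max(16, int(round(2 * np.pi * r / edge)))
    u = np.linspace(0, 2 * np.pi, nu, endpoint=False)
    v = np.linspace(0, 2 * np.pi, nv, endpoint=False)
    uu, vv = np.meshgrid(u, v)
    w = R + r * np.cos(vv)
    verts = np.stack([w * np.cos(uu), w * np.sin(uu), r * np.sin(vv)], axis=-1).reshape(-1, 3)
    mesh = TriangleMesh(verts, _torus_faces(nu, nv), label or f"torus_R{R:g}_r{r:g}")
    k_tube = np.full(nu * nv, 1.0 / r)
    k_ring = (np.cos(vv) / w).ravel()
    # order by magnitude for the oracle as well
    k1 = np.where(np.abs(k_ring) <= np.abs(k_tube), k_ring, k_tube)
    k2 = np.where(np.abs(k_ring) <= np.abs(k_tube), k_tube, k_ring)
    return IdealSurface(
        mesh, "torus", {"R": R, "r": r, "edge": edge}, k1, k2,
        uv=np.stack([uu.ravel(), vv.ravel()], axis=1),
    )


def _torus_faces(nu: int, nv: int) -> np.ndarray:
    iu = np.arange(nu)
    iu1 = (iu + 1) % nu
    faces = []
    for j in range(nv):
        j1 = (j + 1) % nv
        a = j * nu + iu
        b = j * nu + iu1
        c = j1 * nu + iu1
        d = j1 * nu + iu
        faces.append(np.stack([a, b, c], axis=1))
        faces.append(np.stack([a, c, d], axis=1))
    return np.concatenate(faces)


def catenoid(
    c: float = 10.0, v_extent: float = 1.5, edge: float = 1.0, label: str = ""
) -> IdealSurface:
    """Catenoid with waist c, truncated at |v| <= v_extent * c.

    Minimal surface: k1 = -k2 = 1/(c*cosh^2(v/c)), total curvature
    -4*pi*tanh(v_extent) in the limit of fine meshing.  Meridian rows are
    spaced uniformly in arc length (s = c*sinh(v/c)).  The default
    truncation keeps the surface tube-like (flare radius 2.35x the
    waist), the regime where the inner-scale partition ansatz holds,
    while retaining 90% of the full -4*pi.
    """
    if c <= 0 or v_extent <= 0:
        raise ValueError("c and v_extent must be positive")
    vmax = v_extent * c
    r_max = c * np.cosh(v_extent)
    nu = max(16, int(round(2 * np.pi * c / edge)))
    s_max = c * np.sinh(v_extent)
    nv = max(16, int(round(2 * s_max / edge)) + 1)
    u = np.linspace(0, 2 * np.pi, nu, endpoint=False)
    v = c * np.arcsinh(np.linspace(-s_max, s_max, nv) / c)
    uu, vv = np.meshgrid(u, v)
    rho = c * np.cosh(vv / c)
    verts = np.stack([rho * np.cos(uu), rho * np.sin(uu), vv], axis=-1).reshape(-1, 3)
    faces = _grid_faces(nu, nv, close_u=True)
    mesh = TriangleMesh(verts, faces, label or f"catenoid_c{c:g}")
    k = (1.0 / (c * np.cosh(vv / c) ** 2)).ravel()
    return IdealSurface(
        mesh, "catenoid", {"c": c, "v_extent": v_extent, "edge": edge, "r_max": r_max},
        k, -k, uv=np.stack([uu.ravel(), vv.ravel()], axis=1),
    )


def pseudosphere(
    rho: float = 10.0,
    t_min: float = 0.15,
    t_max: float = 4.5,
    edge: float = 1.0,
    label: str = "",
) -> IdealSurface:
    """Two-horn tractricoid with kappa_g = -1/rho^2 everywhere.

    Profile r(t) = rho*sech(t), z(t) = rho*(t - tanh(t)); principal
    curvatures sinh(t)/rho (circumferential) and -1/(rho*sinh(t))
    (meridional).  Both horns are emitted as one mesh with two connected
    components and four boundary loops; the retained total curvature is
    -4*pi*(sech(t_min) - sech(t_max)).
    """
    if not (0 < t_min < t_max):
        raise ValueError("require 0 < t_min < t_max")
    # Rows are spaced uniformly in sech(t): each ring then carries the same
    # integrated curvature 2*pi*rho^2*d(sech t), so boundary-ring removal
    # discards only ~6/nv of the total curvature mass per horn.
    s0, s1 = rho * np.log(np.cosh(t_min)), rho * np.log(np.cosh(t_max))
    nv = max(160, int(round((s1 - s0) / edge)) + 1)
    w = np.linspace(1.0 / np.cosh(t_max), 1.0 / np.cosh(t_min), nv)
    t = np.arccosh(1.0 / w)[::-1]  # increasing t
    nu = max(16, int(round(2 * np.pi * rho / edge)))
    u = np.linspace(0, 2 * np.pi, nu, endpoint=False)
    uu, tt = np.meshgrid(u, t)
    r = rho / np.cosh(tt)
    z = rho * (tt - np.tanh(tt))

    all_verts, all_faces, all_k1, all_k2, all_uv = [], [], [], [], []
    offset = 0
    for sign in (+1.0, -1.0):
        verts = np.stack([r * np.cos(uu), r * np.sin(uu), sign * z], axis=-1).reshape(-1, 3)
        faces = _grid_faces(nu, nv, close_u=True) + offset
        k_circ = (np.sinh(tt) / rho).ravel()
        k_mer = (-1.0 / (rho * np.sinh(tt))).ravel()
        k1 = np.where(np.abs(k_mer) <= np.abs(k_circ), k_mer, k_circ)
        k2 = np.where(np.abs(k_mer) <= np.abs(k_circ), k_circ, k_mer)
        all_verts.append(verts)
        all_faces.append(faces)
        all_k1.append(k1)
        all_k2.append(k2)
        all_uv.append(np.stack([uu.ravel(), sign * tt.ravel()], axis=1))
        offset += nu * nv
    mesh = TriangleMesh(
        np.concatenate(all_verts), np.concatenate(all_faces),
        label or f"pseudosphere_rho{rho:g}",
    )
    return IdealSurface(
        mesh, "pseudosphere",
        {"rho": rho, "t_min": t_min, "t_max": t_max, "edge": edge},
        np.concatenate(all_k1), np.concatenate(all_k2),
        uv=np.concatenate(all_uv),
    )


_FAMILIES = {
    "sphere": sphere,
    "cylinder": cylinder,
    "torus": torus,
    "catenoid": catenoid,
    "pseudosphere": pseudosphere,
}


def generate(family: str, **params) -> IdealSurface:
    """Dispatch to a family generator by name."""
    try:
        fn = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(_FAMILIES)}")
    return fn(**params)


def validation_suite(edge: float = 1.0, config=None) -> dict:
    """Run the specimen pipeline over all five families at two sizes each.

    Asserts the analytic total-curvature targets (4*pi spherical, 0
    parabolic, -4*pi hyperbolic) and the curvature-based size identities
    (inverse mean curvedness = r on spheres and r*sqrt(2) on cylinders).
    Returns a machine-readable report with one record per case and a
    global ``passed`` flag.
    """
    from .partition import PipelineConfig, specimen_pipeline

    cfg = config or PipelineConfig.light()
    four_pi = 4 * np.pi
    cases = [
        (sphere(5.0, edge=min(edge, 0.7)), four_pi, 0.1 * four_pi, 5.0),
        (sphere(20.0, edge=edge * 2), four_pi, 0.1 * four_pi, 20.0),
        (cylinder(8.0, 120.0, edge=edge), 0.0, 0.1 * four_pi, 8.0 * np.sqrt(2)),
        (cylinder(12.0, 180.0, edge=edge * 1.5), 0.0, 0.1 * four_pi, 12.0 * np.sqrt(2)),
        (torus(30.0, 10.0, edge=edge), 0.0, 0.1 * four_pi, None),
        (torus(45.0, 15.0, edge=edge * 1.5), 0.0, 0.1 * four_pi, None),
        (pseudosphere(10.0, edge=edge), -four_pi, 0.2 * four_pi, None),
        (pseudosphere(15.0, edge=edge * 1.5), -four_pi, 0.2 * four_pi, None),
        (catenoid(10.0, edge=edge), -four_pi, 0.2 * four_pi, None),
        (catenoid(15.0, edge=edge * 1.5), -four_pi, 0.2 * four_pi, None),
    ]
    records = []
    for surf, target, tol, size_target in cases:
        feats = specimen_pipeline(surf.mesh, cfg)
        ok = abs(feats.sum_K - target) <= tol
        size_ok = True
        if size_target is not None:
            size_ok = abs(feats.inv_mean_curvedness - size_target) <= 0.02 * size_target
        records.append(
            {
                "label": surf.mesh.label,
                "family": surf.family,
                "sum_K": feats.sum_K,
                "target": target,
                "tolerance": tol,
                "inv_mean_curvedness": feats.inv_mean_curvedness,
                "size_target": size_target,
                "passed": bool(ok and size_ok),
            }
        )
    return {"cases": records, "passed": all(r["passed"] for r in records)}
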