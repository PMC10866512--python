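"""Synthetic tubular specimens and feature-table cohorts.

Real specimens are bent cylinders: a toroidal arch followed by a
straight descending segment, with a centerline length-to-radius ratio
c ~ 16.6.  ``generate_tube`` sweeps a circular cross-section along such
a planar centerline and modulates the radius with a seeded band-limited
bump field, emulating aneurysmal surface degeneration at the inner scale
(bump wavelength of order the tube radius).  ``growth_sequence`` is a
kinematic surrogate for growth simulations: size and bump amplitude
increase linearly and the feature time-series is returned.

``simulate_feature_cohort`` draws feature tables directly (no meshes)
with the statistical structure observed across disease states: Gaussian
size marginals, tight baseline shape fluctuation for normals, and
bounded power-law delta_K tails for diseased groups with the failed
group stochastically dominating the successful one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mesh import TriangleMesh

__all__ = [
    "TubeSpec",
    "CohortGroupSpec",
    "CohortSpec",
    "generate_tube",
    "growth_sequence",
    "simulate_feature_cohort",
    "sample_power_law",
]


@dataclass
class TubeSpec:
    """Geometry of one synthetic bent tube.

    ``radius`` is the tube radius ell_0 (mm); the centerline length is
    ``c * radius`` with ``c = 16.6`` by default, of which ``arch_fraction``
    is a planar U-bend (half-torus arch) and the rest a straight
    descending segment.  ``bump_amplitude`` is the peak radial
    perturbation as a fraction of the radius; ``bump_wavelength`` (mm)
    defaults to twice the radius.  The bump pattern lives in scale-free
    coordinates, so scaling ``radius`` with everything else fixed scales
    the whole surface uniformly.
    """

    radius: float = 10.0
    c: float = 16.6
    arch_fraction: float = 0.45
    bump_amplitude: float = 0.0
    bump_wavelength: Optional[float] = None
    n_waves: int = 20
    seed: int = 0
    edge: Optional[float] = None  # target edge length; default radius / 5
    label: str = ""

    @property
    def length(self) -> float:
        return self.c * self.radius


def _bump_field(spec: TubeSpec, sigma: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Band-limited random bump field, unit peak amplitude.

    A sum of ``n_waves`` plane waves on the scale-free cylinder
    coordinates (sigma = arclength / radius, theta), with wavelengths
    log-uniform within a factor 4/3 of the target wavelength and random
    directions and phases.  The circumferential wavenumber is rounded to
    an integer so the field is exactly periodic around the tube.
    """
    rng = np.random.default_rng(spec.seed)
    # default roughness wavelength: twice the tube radius (order of the
    # radius, gentle enough that the median-R2 inner scale stays the tube
    # radius); scale-free when the spec is uniformly resized
    lam = (spec.bump_wavelength or 2.0 * spec.radius) / spec.radius
    n = spec.n_waves
    wavelengths = lam * np.exp(rng.uniform(np.log(0.75), np.log(4 / 3), n))
    angles = rng.uniform(0, 2 * np.pi, n)
    phases = rng.uniform(0, 2 * np.pi, n)
    amps = rng.uniform(0.5, 1.0, n)
    k = 2 * np.pi / wavelengths
    k_s = k * np.cos(angles)
    m = np.round(k * np.sin(angles)).astype(int)  # integer circumferential mode
    fld = np.zeros_like(sigma)
    for i in range(n):
        fld += amps[i] * np.cos(k_s[i] * sigma + m[i] * theta + phases[i])
    peak = np.max(np.abs(fld))
    return fld / peak if peak > 0 else fld


def _centerline(spec: TubeSpec, n_s: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planar U-bend + straight centerline with unit-speed frames.

    Returns points (n_s, 3), in-plane normals and the constant binormal.
    The curve lies in the x-z plane so the rotation-minimizing frame is
    (in-plane normal, +y).
    """
    L = spec.length
    L_arch = spec.arch_fraction * L
    R_arch = L_arch / np.pi  # semicircular arch
    s = np.linspace(0.0, L, n_s)
    pts = np.empty((n_s, 3))
    nrm = np.empty((n_s, 3))
    in_arch = s <= L_arch
    phi = s[in_arch] / R_arch  # 0..pi
    pts[in_arch, 0] = R_arch * np.sin(phi)
    pts[in_arch, 1] = 0.0
    pts[in_arch, 2] = R_arch * np.cos(phi)
    # inward normal of the arc (towards center) -> use outward for the frame
    nrm[in_arch, 0] = np.sin(phi)
    nrm[in_arch, 1] = 0.0
    nrm[in_arch, 2] = np.cos(phi)
    # straight segment continues tangentially from the arch end (0, 0, -R)
    rest = ~in_arch
    pts[rest, 0] = -(s[rest] - L_arch)
    pts[rest, 1] = 0.0
    pts[rest, 2] = -R_arch
    nrm[rest, 0] = 0.0
    nrm[rest, 1] = 0.0
    nrm[rest, 2] = -1.0
    binormal = np.array([0.0, 1.0, 0.0])
    return pts, nrm, binormal


def generate_tube(spec: TubeSpec) -> TriangleMesh:
    """Swept bent tube with a seeded rough surface.

    The surface is ``C(s) + r(s, theta) * (N(s) cos(theta) + B sin(theta))``
    with ``r = radius * (1 + amplitude * bump)``; deterministic for a
    fixed spec and seed (bitwise-identical vertex arrays).
    """
    if spec.radius <= 0 or spec.c <= 0:
        raise ValueError("radius and c must be positive")
    if spec.bump_amplitude > 0.8:
        raise ValueError("bump amplitude > 0.8 risks self-intersection")
    if spec.bump_amplitude < 0:
        raise ValueError("bump amplitude must be nonnegative")
    edge = spec.edge or spec.radius / 5.0
    n_theta = max(24, int(round(2 * np.pi * spec.radius / edge)))
    n_s = max(24, int(round(spec.length / edge)) + 1)
    pts, nrm, binormal = _centerline(spec, n_s)
    s = np.linspace(0.0, spec.length, n_s)
    # Arc-length-uniform sampling around each ring: vertex spacing must not
    # correlate with the bump field, or partition statistics (which pair
    # partition area with an unweighted curvature mean, emulating the
    # uniform-density meshes produced by segmentation remeshers) acquire a
    # covariance bias.  Sample the radius on a fine reference grid, invert
    # the cumulative circumference, and place n_theta equally spaced points.
    fine = np.linspace(0, 2 * np.pi, 8 * n_theta + 1)
    sigma = s / spec.radius
    tt = np.empty((n_s, n_theta))
    for i in range(n_s):
        rf = spec.radius * (
            1.0 + spec.bump_amplitude * _bump_field(spec, np.full_like(fine, sigma[i]), fine)
        )
        seg = 0.5 * (rf[:-1] + rf[1:]) * np.diff(fine)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        targets = np.linspace(0, cum[-1], n_theta, endpoint=False)
        tt[i] = np.interp(targets, cum, fine)
    ss = np.repeat(s[:, None], n_theta, axis=1)
    bump = _bump_field(spec, ss / spec.radius, tt)
    r = spec.radius * (1.0 + spec.bump_amplitude * bump)
    ring = (
        nrm[:, None, :] * np.cos(tt)[:, :, None]
        + binormal[None, None, :] * np.sin(tt)[:, :, None]
    )
    verts = (pts[:, None, :] + r[:, :, None] * ring).reshape(-1, 3)
    from .ideal import _grid_faces

    faces = _grid_faces(n_theta, n_s, close_u=True)
    label = spec.label or (
        f"tube_r{spec.radius:g}_eps{spec.bump_amplitude:g}_seed{spec.seed}"
    )
    return TriangleMesh(verts, faces, label)


def growth_sequence(
    spec: TubeSpec,
    n_steps: int = 4,
    size_growth: float = 0.5,
    bump_growth: float = 1.0,
    config=None,
) -> pd.DataFrame:
    """Feature time-series under simultaneous size and roughness growth.

    Step ``i`` scales the radius by ``1 + size_growth * i/(n-1)`` and the
    bump amplitude by ``1 + bump_growth * i/(n-1)`` (the bump pattern and
    relative wavelength are held fixed).  Returns one feature row per
    step.  Because total curvature is scale-free, ``sum_K`` stays flat
    and ``delta_K`` tracks only the roughness; ``delta_kappa_g`` carries
    an extra 1/length^4 size factor and is confounded when size grows.
    """
    from dataclasses import replace

    from .partition import PipelineConfig, features_to_frame, specimen_pipeline

    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    cfg = config or PipelineConfig.light()
    rows = []
    for i in range(n_steps):
        f = i / (n_steps - 1)
        step = replace(
            spec,
            radius=spec.radius * (1 + size_growth * f),
            bump_amplitude=spec.bump_amplitude * (1 + bump_growth * f),
            label=f"growth_step{i}",
        )
        mesh = generate_tube(step)
        feats = specimen_pipeline(mesh, cfg)
        rows.append(feats)
    out = features_to_frame(rows)
    out.insert(0, "step", np.arange(n_steps))
    return out


# -- feature-table cohorts ----------------------------------------------


def sample_power_law(
    n: int,
    exponent: float,
    x_min: float,
    x_max: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inverse-CDF samples from a bounded power law p(x) ~ x^exponent.

    ``exponent`` is the density exponent (e.g. -2); the support is
    [x_min, x_max].
    """
    if x_min <= 0 or x_max <= x_min:
        raise ValueError("require 0 < x_min < x_max")
    u = rng.uniform(size=n)
    a = exponent + 1.0
    if abs(a) < 1e-12:
        return x_min * (x_max / x_min) ** u
    return (x_min**a + u * (x_max**a - x_min**a)) ** (1.0 / a)


@dataclass
class CohortGroupSpec:
    """Sampling law of one patient-like group in feature space."""

    n: int
    ell_mean: float
    ell_sd: float
    dK_mode: str = "gaussian"      # "gaussian" | "powerlaw"
    dK_loc: float = 1.0            # Gaussian mean, or power-law x_min
    dK_scale: float = 0.1          # Gaussian sd, or x_max / x_min span factor
    tail_exponent: float = -2.0    # power-law density exponent


@dataclass
class CohortSpec:
    """Three-group synthetic cohort in (delta_K, ell) feature space.

    Defaults emulate the observed structure: normal specimens have tight
    Gaussian delta_K near a small baseline and the smallest radii;
    diseased groups have larger radii and bounded power-law delta_K
    tails, the failed group stochastically dominating the successful
    one.
    """

    groups: dict = field(default_factory=lambda: {
        "normal": CohortGroupSpec(
            n=120, ell_mean=12.0, ell_sd=1.5,
            dK_mode="gaussian", dK_loc=0.010, dK_scale=0.0015,
        ),
        "success": CohortGroupSpec(
            n=40, ell_mean=15.0, ell_sd=2.0,
            dK_mode="powerlaw", dK_loc=0.012, dK_scale=50.0, tail_exponent=-2.5,
        ),
        "failed": CohortGroupSpec(
            n=40, ell_mean=18.0, ell_sd=2.5,
            dK_mode="powerlaw", dK_loc=0.04, dK_scale=200.0, tail_exponent=-2.0,
        ),
    })
    seed: int = 0


def simulate_feature_cohort(spec: Optional[CohortSpec] = None) -> pd.DataFrame:
    """Draw a labeled feature table from a :class:`CohortSpec`.

    Deterministic for a fixed seed.  Columns follow the standard feature
    schema (delta_K, ell, mean_curvedness, mean_radius, ...) plus a
    ``group`` label.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for name, g in spec.groups.items():
        if g.n <= 0 or g.ell_sd <= 0:
            raise ValueError(f"group {name!r}: n and ell_sd must be positive")
        ell = rng.normal(g.ell_mean, g.ell_sd, g.n)
        ell = np.clip(ell, 1e-3, None)
        if g.dK_mode == "gaussian":
            dK = np.clip(rng.normal(g.dK_loc, g.dK_scale, g.n), 1e-9, None)
        elif g.dK_mode == "powerlaw":
            dK = sample_power_law(
                g.n, g.tail_exponent, g.dK_loc, g.dK_loc * g.dK_scale, rng
            )
        else:
            raise ValueError(f"unknown dK_mode {g.dK_mode!r}")
        for i in range(g.n):
            rows.append(
                {
                    "scan_id": f"{name}_{i:03d}",
                    "group": name,
                    "delta_K": dK[i],
                    "ell": ell[i],
                    "mean_curvedness": 1.0 / (ell[i] * np.sqrt(2)),
                    "mean_radius": ell[i],
                    "max_radius": ell[i] * float(rng.uniform(1.05, 1.4)),
                    "total_area": 2 * np.pi * 16.6 * ell[i] ** 2,
                    "volume": np.pi * 16.6 * ell[i] ** 3,
                }
            )
    return pd.DataFrame(rows)
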