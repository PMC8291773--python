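"""Position- and direction-dependent diffusivity models.

Diffusion close to a wall is hindered: the 3x3 diffusion tensor D(x) has a
reduced eigenvalue for motion along the nearest-wall normal and a less
reduced one for tangential motion.  Four models are provided:

``bulk_constant``
    D0 * I everywhere (Stokes-Einstein bulk value).
``r_dependent``
    closed-form hindrance factors of a sphere near an infinite plane wall,
    evaluated with the distance to the nearest wall.
``z_dependent``
    the numerically computed (LRNH) tensor at the channel centerline,
    extended radially.
``combined_rz``
    the r-dependent tensor rescaled per z so that its centerline value
    equals the centerline LRNH tensor (the reference model).
``lrnh_numeric``
    direct low-Reynolds-number-hydrodynamics evaluation: three Stokes solves
    with unit velocities on the sphere give the friction tensor gamma(x) and
    D = kT gamma^-1.  Restricted to on-axis positions, where the two
    azimuthal Fourier modes of the axisymmetric solver provide all three
    diagonal components.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constants import CONSTANTS, NM, PhysicalConstants
from .geometry import MeshOptions, PoreSpec, mesh as build_mesh, wall_distance

__all__ = [
    "bulk_diffusivity",
    "plane_wall_factors",
    "lrnh_tensor",
    "build_field",
    "channel_average",
    "DiffusivityField",
]

#: floor applied to hindrance factors in the slip regime where the channel
#: is as narrow as the particle
FACTOR_FLOOR = 1e-3


def bulk_diffusivity(constants: PhysicalConstants = CONSTANTS, radius: float = 0.11) -> float:
    """Stokes-Einstein bulk diffusivity kT / (6 pi eta a) for radius in nm."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return constants.kT / (6 * np.pi * constants.eta * radius * NM)


def plane_wall_factors(a: float, h):
    """Hindrance factors (f_parallel, f_perpendicular) of a sphere of radius
    ``a`` with centre at distance ``h`` from an infinite plane wall (nm).

    Parallel motion uses the Faxen series in s = a/h; perpendicular motion
    uses the Pade approximant in the surface gap g = h - a,
    (6 g^2 + 2 a g) / (6 g^2 + 9 a g + 2 a^2), which has the correct
    lubrication limit at contact.  Both approach 1 as h/a -> infinity.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < a - 1e-12):
        raise ValueError("wall distance h must be >= particle radius a")
    s = a / h
    f_par = 1.0 - (9.0 / 16.0) * s + (1.0 / 8.0) * s**3 \
        - (45.0 / 256.0) * s**4 - (1.0 / 16.0) * s**5
    g = h - a
    f_perp = (6.0 * g**2 + 2.0 * a * g) / (6.0 * g**2 + 9.0 * a * g + 2.0 * a**2)
    f_par = np.clip(f_par, FACTOR_FLOOR, 1.0)
    f_perp = np.clip(f_perp, FACTOR_FLOOR, 1.0)
    if np.isscalar(h) or h.ndim == 0:
        return float(f_par), float(f_perp)
    return f_par, f_perp


# ---------------------------------------------------------------------------
# numerical LRNH
# ---------------------------------------------------------------------------

def _lrnh_mesh_options(spec: PoreSpec, a: float, z: float,
                       coarse: float) -> MeshOptions:
    """Gap-adaptive sizing: the sphere surface is resolved with ~a/10 cells,
    sharpened to ~gap/8 when the nearest wall is close."""
    d, _, _ = wall_distance(spec, (0.0, z))
    gap = max(d - a, 1e-3)
    hp = min(a / 10.0, max(gap / 8.0, a / 48.0))
    return MeshOptions(fine=min(3 * hp, max(a / 4, 0.02)), coarse=coarse,
                       protein=hp, growth=0.3)


def _friction_diagonal(spec: PoreSpec, a: float, z: float,
                       constants: PhysicalConstants,
                       coarse: float, refine: bool) -> tuple[float, float]:
    """(gamma_xx, gamma_zz) for a sphere of radius a on the axis at height z
    (N s/m), from the dissipation of unit-velocity Stokes solves."""
    from .continuum import solve_stokes

    def solve_once(opt: MeshOptions) -> tuple[float, float]:
        m = build_mesh(spec, opt, protein=(z, a))
        res_z = solve_stokes(m, ("protein", (0.0, 0.0, 1.0)), constants)
        res_x = solve_stokes(m, ("protein", (1.0, 0.0, 0.0)), constants)
        return res_x["dissipation"], res_z["dissipation"]

    opt = _lrnh_mesh_options(spec, a, z, coarse)
    gx1, gz1 = solve_once(opt)
    if not refine:
        return gx1, gz1
    opt2 = MeshOptions(fine=opt.fine / 1.5, coarse=coarse,
                       protein=opt.protein / 1.5, growth=opt.growth)
    gx2, gz2 = solve_once(opt2)
    return gx2, gz2


def plane_wall_numeric_factors(a: float, h_ratios,
                               constants: PhysicalConstants = CONSTANTS):
    """Numerical LRNH plane-wall hindrance factors (f_par, f_perp) at
    centre-to-wall distances h = ratio * a, normalized by a far-from-wall
    solve in the same wide domain.  This is the independent oracle used to
    validate :func:`plane_wall_factors`."""
    from .geometry import make_fixture
    R = max(150.0 * a, 30.0)
    spec = make_fixture("plane_wall", radius=R, height=2 * R)
    gx0, gz0 = _friction_diagonal(spec, a, R, constants, coarse=R / 20,
                                  refine=False)
    out = []
    for hr in np.atleast_1d(h_ratios):
        gx, gz = _friction_diagonal(spec, a, float(hr) * a, constants,
                                    coarse=R / 20, refine=False)
        out.append((gx0 / gx, gz0 / gz))
    return np.asarray(out)


def lrnh_tensor(spec: PoreSpec, a: float, position,
                constants: PhysicalConstants = CONSTANTS,
                coarse: float = 2.0, refine: bool = True) -> np.ndarray:
    """Full 3x3 diffusion tensor D = kT gamma^-1 of a sphere of radius ``a``
    centred on the axis at ``position`` = (0, 0, z) or scalar z (nm).

    The friction tensor is assembled from Stokes solves with unit boundary
    velocities: an axial solve (azimuthal mode m=0) and a transverse solve
    (m=1); drag is evaluated via the viscous dissipation.
    """
    z = float(np.atleast_1d(np.asarray(position, dtype=float)).ravel()[-1])
    pos = np.atleast_1d(np.asarray(position, dtype=float))
    if pos.size == 3 and np.hypot(pos[0], pos[1]) > 1e-9:
        raise ValueError("lrnh_tensor supports on-axis positions only")
    d, _, _ = wall_distance(spec, (0.0, z))
    if d < a:
        raise ValueError("sphere intersects the wall")
    gx, gz = _friction_diagonal(spec, a, z, constants, coarse, refine)
    kT = constants.kT
    return np.diag([kT / gx, kT / gx, kT / gz])


# ---------------------------------------------------------------------------
# field models
# ---------------------------------------------------------------------------

_centerline_cache: dict = {}


def _centerline_factors(spec: PoreSpec, a: float,
                        constants: PhysicalConstants,
                        n_stations: int, refine: bool):
    """PCHIP interpolants z -> (f_xx, f_zz) of relative centerline LRNH
    diffusivity, sampled at n_stations inside the channel plus anchor points
    in the reservoirs where the factors approach 1."""
    key = (spec.to_yaml(), a, n_stations, refine)
    if key in _centerline_cache:
        return _centerline_cache[key]
    L = spec.channel_length
    zs = np.linspace(-L + max(0.05 * L, a * 1.5), -max(0.05 * L, a * 1.5),
                     n_stations)
    # trim reservoirs for the local hydrodynamic solves (confinement is local)
    res = spec.reservoir
    trim = min(8.0 + 2 * a, res.height_above)
    trimmed = PoreSpec(
        name=spec.name + "_lrnh", profile=spec.profile,
        channel_length=spec.channel_length, wall_thickness=spec.wall_thickness,
        wall_material=spec.wall_material, wall_regions=(),
        membrane=spec.membrane,
        reservoir=type(res)(res.radius, trim, min(trim, res.height_below)),
        cross_section=spec.cross_section, nominal_width=spec.nominal_width,
    )
    D0 = bulk_diffusivity(constants, a)
    kT = constants.kT
    fx, fz = [], []
    for z in zs:
        d, _, _ = wall_distance(spec, (0.0, z))
        if d < 1.05 * a:
            fx.append(FACTOR_FLOOR)
            fz.append(FACTOR_FLOOR)
            continue
        gx, gz = _friction_diagonal(trimmed, a, float(z), constants,
                                    coarse=2.0, refine=refine)
        fx.append(min(kT / gx / D0, 1.0))
        fz.append(min(kT / gz / D0, 1.0))
    # anchors far in the reservoirs
    z_lo = -L - spec.reservoir.height_below * 0.9
    z_hi = spec.reservoir.height_above * 0.9
    zz = np.concatenate([[z_lo, -L - 4 * a], zs, [4 * a, z_hi]])
    ffx = np.concatenate([[1.0, 1.0], fx, [1.0, 1.0]])
    ffz = np.concatenate([[1.0, 1.0], fz, [1.0, 1.0]])
    order = np.argsort(zz)
    interp = (PchipInterpolator(zz[order], ffx[order]),
              PchipInterpolator(zz[order], ffz[order]))
    _centerline_cache[key] = interp
    return interp


@dataclass
class DiffusivityField:
    """Evaluator of the position-dependent diffusion tensor for a particle
    of radius ``a`` (nm).  Distances include the optional explicit protein
    sphere as a wall (for ion fields around a resting protein)."""

    spec: PoreSpec
    a: float
    model: str
    D0: float
    constants: PhysicalConstants = dc_field(default=CONSTANTS, repr=False)
    protein: tuple[float, float] | None = None
    _centerline: tuple | None = dc_field(default=None, repr=False)

    # -- scalar factor evaluation -------------------------------------------
    def _factors_and_normal(self, r, z):
        """(f_tangent, f_normal, n_r, n_z) at points; factors relative to D0."""
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        if self.model == "bulk_constant":
            one = np.ones_like(r)
            return one, one, np.zeros_like(r), np.ones_like(r)
        d, nr, nz = wall_distance(self.spec, np.stack([r, z], axis=-1).reshape(-1, 2),
                                  protein=self.protein)
        d = np.asarray(d).reshape(r.shape)
        nr = np.asarray(nr).reshape(r.shape)
        nz = np.asarray(nz).reshape(r.shape)
        h = np.maximum(d, self.a * (1.0 + 1e-9))
        f_par, f_perp = plane_wall_factors(self.a, h)
        slip = d < self.a
        f_par = np.where(slip, FACTOR_FLOOR, f_par)
        f_perp = np.where(slip, FACTOR_FLOOR, f_perp)
        if self.model == "r_dependent":
            return f_par, f_perp, nr, nz
        fx_i, fz_i = self._centerline
        if self.model == "z_dependent":
            fxx = np.clip(fx_i(z), FACTOR_FLOOR, 1.0)
            fzz = np.clip(fz_i(z), FACTOR_FLOOR, 1.0)
            # eigenframe: radial normal (channel axis frame)
            return fzz, fxx, np.ones_like(r), np.zeros_like(r)
        if self.model == "combined_rz":
            # centerline value of the r-model (open pore, on the axis)
            d0, _, _ = wall_distance(self.spec, np.stack(
                [np.zeros_like(z).ravel(), z.ravel()], axis=-1))
            d0 = d0.reshape(z.shape)
            h0 = np.maximum(d0, self.a * (1.0 + 1e-9))
            f_par0, f_perp0 = plane_wall_factors(self.a, h0)
            s_par = np.clip(np.clip(fz_i(z), FACTOR_FLOOR, 1.0) / f_par0, None, 1.0)
            s_perp = np.clip(np.clip(fx_i(z), FACTOR_FLOOR, 1.0) / f_perp0, None, 1.0)
            return np.clip(f_par * s_par, FACTOR_FLOOR, 1.0), \
                np.clip(f_perp * s_perp, FACTOR_FLOOR, 1.0), nr, nz
        raise ValueError(f"unknown diffusivity model {self.model!r}")

    # -- interfaces ----------------------------------------------------------
    def tensor_components(self, r, z):
        """(D_rr, D_zz) in m^2/s at (r, z) in nm, for the continuum solver."""
        f_par, f_perp, nr, nz = self._factors_and_normal(r, z)
        nrm = np.maximum(np.hypot(nr, nz), 1e-30)
        nr = nr / nrm
        nz = nz / nrm
        D_rr = self.D0 * (f_perp * nr**2 + f_par * (1 - nr**2))
        D_zz = self.D0 * (f_perp * nz**2 + f_par * (1 - nz**2))
        return D_rr, D_zz

    def tensor(self, points_xyz) -> np.ndarray:
        """Full 3x3 tensors (m^2/s) at Cartesian points (n, 3) in nm."""
        pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        r = np.hypot(x, y)
        f_par, f_perp, nr, nz = self._factors_and_normal(r, z)
        nrm = np.maximum(np.hypot(nr, nz), 1e-30)
        nr, nz = nr / nrm, nz / nrm
        # meridian unit vectors
        with np.errstate(invalid="ignore"):
            cos_t = np.where(r > 1e-12, x / np.maximum(r, 1e-12), 1.0)
            sin_t = np.where(r > 1e-12, y / np.maximum(r, 1e-12), 0.0)
        n = np.stack([nr * cos_t, nr * sin_t, nz], axis=-1)  # (m, 3)
        D = self.D0 * (f_par[..., None, None] * np.eye(3)[None, :, :] +
                       (f_perp - f_par)[..., None, None] *
                       n[..., :, None] * n[..., None, :])
        if np.asarray(points_xyz).ndim == 1:
            return D[0]
        return D

    def relative_zz(self, r, z):
        """D_zz / D0 (dimensionless), e.g. for channel averaging."""
        _, D_zz = self.tensor_components(r, z)
        return D_zz / self.D0


def build_field(spec: PoreSpec, a: float, model: str,
                constants: PhysicalConstants = CONSTANTS,
                protein: tuple[float, float] | None = None,
                n_stations: int = 20, refine: bool = False) -> DiffusivityField:
    """Construct a diffusivity field for particles of radius ``a`` (nm).

    ``protein`` = (z_center, radius) makes the explicit protein sphere count
    as a wall (ion fields during blockade computations).  ``n_stations``
    controls the centerline LRNH sampling for the z-dependent and combined
    models.
    """
    valid = {"bulk_constant", "r_dependent", "z_dependent", "combined_rz",
             "lrnh_numeric"}
    if model not in valid:
        raise ValueError(f"unknown diffusivity model {model!r}")
    if model == "lrnh_numeric":
        raise ValueError(
            "lrnh_numeric is evaluated pointwise via lrnh_tensor(); use the "
            "combined_rz field for global evaluation")
    D0 = bulk_diffusivity(constants, a)
    cl = None
    if model in ("z_dependent", "combined_rz"):
        cl = _centerline_factors(spec, a, constants, n_stations, refine)
    return DiffusivityField(spec=spec, a=a, model=model, D0=D0,
                            constants=constants, protein=protein,
                            _centerline=cl)


def channel_average(field: DiffusivityField, weight, mesh=None) -> float:
    """Average relative diffusivity (D_zz / D0) over the channel, weighted by
    ``weight`` (array over mesh cells, e.g. a simulated cation distribution,
    or a callable weight(r, z)).  Requires ``mesh`` for the quadrature."""
    if mesh is None:
        raise ValueError("a mesh is required for the channel average")
    from .continuum import _Grid
    g = _Grid(mesh)
    R, Z = np.meshgrid(mesh.r_centers, mesh.z_centers, indexing="ij")
    in_channel = g.fluid & (Z <= 0.0) & (Z >= -mesh.spec.channel_length)
    if callable(weight):
        w = weight(R, Z)
    else:
        w = np.asarray(weight, dtype=float)
    w = np.where(in_channel, w, 0.0)
    if w.sum() <= 0:
        raise ValueError("weight must have positive mass in the channel")
    rel = field.relative_zz(R.ravel(), Z.ravel()).reshape(R.shape)
    return float((rel * w * g.vol).sum() / (w * g.vol).sum())
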