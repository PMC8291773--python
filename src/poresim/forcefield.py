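"""Precomputed force and current lookup tables for Brownian dynamics.

The continuum solver is expensive, so forces F_PNPS(x) and currents J(x) are
sampled once on a grid of physically possible protein positions and then
interpolated during trajectory integration (the decoupling that makes
microsecond-to-second trajectories tractable).

Two sampling modes fill the table:

``explicit``
    the protein sphere is meshed into the domain at an on-axis position and
    the full PNPS system is re-solved; force from the stress/volume
    integrals, current from the flux integral.
``point_particle``
    off-axis entries (which break axisymmetry) use the protein-free
    solution: F = Q E(x) + gamma(x) u(x) with the friction tensor gamma
    from the protein's hindered-diffusivity field.  Blockades are taken
    from the explicit on-axis profile at equal z inside the channel,
    relaxing to the open-pore current away from the pore mouth.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator

from .constants import CONSTANTS, NM, PhysicalConstants
from .diffusivity import DiffusivityField, build_field
from .geometry import Mesh, MeshOptions, PoreSpec, mesh as build_mesh, wall_distance

log = logging.getLogger(__name__)

__all__ = ["SampleConfig", "ForceCurrentGrid", "make_grid", "sample", "interpolate"]


@dataclass
class SampleConfig:
    """Solver configuration for force-grid sampling."""

    voltage: float  # volts, phi(trans) - phi(cis)
    bulk_conc: float = 1.0  # mol/L
    protein_charge_q: float = 0.0
    ion_model: str = "combined_rz"
    protein_model: str = "combined_rz"
    n_stations: int = 5
    explicit_dz: float = 2.0  # axial spacing of explicit PNPS solves (nm)
    mesh_options: MeshOptions = field(default_factory=lambda: MeshOptions(
        fine=0.25, coarse=1.5, edl=0.05, protein=0.06))
    solver: "SolverOptions | None" = None
    max_failure_fraction: float = 0.1


@dataclass
class ForceCurrentGrid:
    """Structured (r, z) table of axisymmetric forces and currents.

    Force vectors are stored in cylindrical components (F_r, F_z) at the
    nodes and rotated into Cartesian frame on interpolation; the azimuthal
    component vanishes by symmetry.  Invalid nodes (protein overlaps a wall)
    are filled with the nearest valid value and masked in ``valid``.
    """

    spec: PoreSpec
    protein_radius: float
    protein_charge_q: float
    voltage: float
    bulk_conc: float
    r: np.ndarray            # (nr,) nm
    z: np.ndarray            # (nz,) nm
    F_r: np.ndarray          # (nr, nz) N
    F_z: np.ndarray          # (nr, nz) N
    J: np.ndarray            # (nr, nz) A
    I0: float                # open-pore current (A)
    valid: np.ndarray        # (nr, nz) bool
    mode: np.ndarray         # (nr, nz) int8: 0 invalid, 1 explicit, 2 point-particle
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._fr = RegularGridInterpolator((self.r, self.z), self.F_r,
                                           bounds_error=False, fill_value=None)
        self._fz = RegularGridInterpolator((self.r, self.z), self.F_z,
                                           bounds_error=False, fill_value=None)
        self._j = RegularGridInterpolator((self.r, self.z), self.J,
                                          bounds_error=False, fill_value=None)

    # -- queries -------------------------------------------------------------
    def interpolate(self, points_xyz):
        """(F, J) at Cartesian points (n, 3) in nm: F in newtons (n, 3),
        J in amperes (n,).  Outside the table the nearest-node value is
        used (linear extrapolation is clipped)."""
        pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        r = np.hypot(x, y)
        rq = np.clip(r, self.r[0], self.r[-1])
        zq = np.clip(z, self.z[0], self.z[-1])
        q = np.stack([rq, zq], axis=-1)
        fr = self._fr(q)
        fz = self._fz(q)
        jj = self._j(q)
        with np.errstate(invalid="ignore"):
            cos_t = np.where(r > 1e-12, x / np.maximum(r, 1e-12), 1.0)
            sin_t = np.where(r > 1e-12, y / np.maximum(r, 1e-12), 0.0)
        F = np.stack([fr * cos_t, fr * sin_t, fz], axis=-1)
        if np.asarray(points_xyz).ndim == 1:
            return F[0], float(jj[0])
        return F, jj

    def blockade(self, points_xyz):
        """Relative blockade (I0 - J)/I0 at points."""
        _, J = self.interpolate(points_xyz)
        return (abs(self.I0) - np.abs(J)) / abs(self.I0)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            for name in ("r", "z", "F_r", "F_z", "J", "valid", "mode"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["I0"] = self.I0
            f.attrs["protein_radius"] = self.protein_radius
            f.attrs["protein_charge_q"] = self.protein_charge_q
            f.attrs["voltage"] = self.voltage
            f.attrs["bulk_conc"] = self.bulk_conc
            f.attrs["spec_yaml"] = self.spec.to_yaml()
            for k, v in self.metadata.items():
                f.attrs[f"meta_{k}"] = v

    @classmethod
    def load(cls, path: str) -> "ForceCurrentGrid":
        import h5py
        with h5py.File(path, "r") as f:
            spec = PoreSpec.from_yaml(f.attrs["spec_yaml"])
            meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
            return cls(spec=spec,
                       protein_radius=float(f.attrs["protein_radius"]),
                       protein_charge_q=float(f.attrs["protein_charge_q"]),
                       voltage=float(f.attrs["voltage"]),
                       bulk_conc=float(f.attrs["bulk_conc"]),
                       r=f["r"][:], z=f["z"][:],
                       F_r=f["F_r"][:], F_z=f["F_z"][:], J=f["J"][:],
                       I0=float(f.attrs["I0"]),
                       valid=f["valid"][:].astype(bool),
                       mode=f["mode"][:], metadata=meta)

    def to_csv(self, path: str) -> None:
        import pandas as pd
        R, Z = np.meshgrid(self.r, self.z, indexing="ij")
        pd.DataFrame({
            "r_nm": R.ravel(), "z_nm": Z.ravel(),
            "F_r_N": self.F_r.ravel(), "F_z_N": self.F_z.ravel(),
            "J_A": self.J.ravel(), "valid": self.valid.ravel(),
            "mode": self.mode.ravel(),
        }).to_csv(path, index=False)


def make_grid(spec: PoreSpec, protein_radius: float, spacing: float = 1.0,
              spacing_reservoir: float = 2.0):
    """Structured (r, z) node sets covering the channel and near reservoirs,
    with the admissibility mask (protein does not overlap walls/membrane).

    Returns (r_values, z_values, valid) where valid has shape (nr, nz).
    Raises if no in-channel position is admissible.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    a = protein_radius
    L = spec.channel_length
    margin = min(spec.reservoir.height_above, spec.reservoir.height_below)
    z_in = np.arange(-L - 2 * spacing, 2 * spacing + 1e-9, spacing)
    z_up = np.arange(2 * spacing, spec.z_top - a + 1e-9, spacing_reservoir)
    z_dn = -L - np.arange(2 * spacing, margin - a + 1e-9, spacing_reservoir)
    z = np.unique(np.round(np.concatenate([z_dn, z_in, z_up]), 6))
    r_max = spec.reservoir.radius - a
    r = np.unique(np.concatenate([[0.0], np.arange(spacing / 2, r_max, spacing)]))
    R, Z = np.meshgrid(r, z, indexing="ij")
    pts = np.stack([R.ravel(), Z.ravel()], axis=-1)
    d, _, _ = wall_distance(spec, pts)
    valid = (d.reshape(R.shape) >= a - 1e-9) & (spec.solid_at(R, Z) == 0)
    in_chan = (Z <= 0) & (Z >= -L)
    if not (valid & in_chan).any():
        raise ValueError("channel too narrow: no admissible in-channel position")
    return r, z, valid


def _fill_invalid(arr: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid entries with the nearest valid value along r, then z."""
    out = arr.copy()
    nr, nz = arr.shape
    for j in range(nz):
        col_valid = np.nonzero(valid[:, j])[0]
        if len(col_valid):
            bad = np.nonzero(~valid[:, j])[0]
            nearest = col_valid[np.argmin(np.abs(bad[:, None] - col_valid[None, :]),
                                          axis=1)] if len(bad) else []
            out[bad, j] = out[nearest, j] if len(bad) else out[bad, j]
        else:
            out[:, j] = np.nan
    # columns with no valid entry: copy nearest valid column
    good_cols = np.nonzero(~np.isnan(out).any(axis=0))[0]
    for j in range(nz):
        if np.isnan(out[:, j]).any():
            jn = good_cols[np.argmin(np.abs(good_cols - j))]
            out[:, j] = out[:, jn]
    return out


def sample(spec: PoreSpec, config: SampleConfig, protein_radius: float,
           grid=None, constants: PhysicalConstants = CONSTANTS,
           progress: bool = False) -> ForceCurrentGrid:
    """Fill a :class:`ForceCurrentGrid` by continuum sampling.

    Explicit PNPS solves are run at on-axis stations spaced
    ``config.explicit_dz`` through the channel and pore mouths; all other
    nodes use the point-particle closure on the protein-free solution.
    """
    from .continuum import ConvergenceError, compute_current, compute_force, solve_pnps

    a = protein_radius
    Q = config.protein_charge_q
    if grid is None:
        grid = make_grid(spec, a)
    r_vals, z_vals, valid = grid

    # --- open-pore solution -------------------------------------------------
    ion_field = build_field(spec, 0.11, config.ion_model, constants,
                            n_stations=config.n_stations)
    m0 = build_mesh(spec, config.mesh_options)
    sol0 = solve_pnps(m0, constants, ion_field, config.voltage, config.bulk_conc,
                      options=config.solver)
    I0 = compute_current(sol0)
    rc0, zc0 = m0.r_centers, m0.z_centers
    # cell-centred E and u for the point-particle closure
    phi = sol0.phi
    Er = np.zeros_like(phi)
    Er[1:-1, :] = -(phi[2:, :] - phi[:-2, :]) / ((rc0[2:] - rc0[:-2])[:, None] * NM)
    Ez = np.zeros_like(phi)
    Ez[:, 1:-1] = -(phi[:, 2:] - phi[:, :-2]) / ((zc0[2:] - zc0[:-2])[None, :] * NM)
    ur_c = 0.5 * (sol0.u_r[1:, :] + sol0.u_r[:-1, :])
    uz_c = 0.5 * (sol0.u_z[:, 1:] + sol0.u_z[:, :-1])
    interp = {name: RegularGridInterpolator((rc0, zc0), arr, bounds_error=False,
                                            fill_value=None)
              for name, arr in (("Er", Er), ("Ez", Ez), ("ur", ur_c), ("uz", uz_c))}
    D_prot = build_field(spec, a, config.protein_model, constants,
                         n_stations=config.n_stations)

    # --- explicit on-axis stations -------------------------------------------
    L = spec.channel_length
    z_lo = -L - min(4.0, spec.reservoir.height_below - a - 0.5)
    z_hi = min(4.0, spec.reservoir.height_above - a - 0.5)
    stations = np.arange(z_lo, z_hi + 1e-9, config.explicit_dz)
    ok_st, F_st, J_st = [], [], []
    failures = 0
    for z_s in stations:
        d, _, _ = wall_distance(spec, (0.0, float(z_s)))
        if d < a + 0.02:
            continue
        try:
            ion_p = build_field(spec, 0.11, config.ion_model, constants,
                                n_stations=config.n_stations,
                                protein=(float(z_s), a))
            m_p = build_mesh(spec, config.mesh_options, protein=(float(z_s), a))
            sol_p = solve_pnps(m_p, constants, ion_p, config.voltage,
                               config.bulk_conc, protein_charge_q=Q,
                               options=config.solver)
            F_el, F_drag = compute_force(sol_p, constants)
            # current away from the protein
            z_meas = -L - 2.0 if z_s > -L / 2 else 2.0
            J_s = compute_current(sol_p, z_meas)
            ok_st.append(float(z_s))
            F_st.append(F_el[2] + F_drag[2])
            J_st.append(J_s)
            if progress:
                log.info("explicit station z=%.1f: F_z=%.3e N, J=%.3e A",
                         z_s, F_st[-1], J_s)
        except (ConvergenceError, ValueError) as exc:  # pragma: no cover
            failures += 1
            warnings.warn(f"explicit station z={z_s:.2f} dropped: {exc}")
    if len(ok_st) + failures and failures > config.max_failure_fraction * (len(ok_st) + failures):
        raise RuntimeError(f"{failures} of {len(ok_st) + failures} explicit "
                           "stations failed to converge")
    ok_st = np.asarray(ok_st)
    F_axis = PchipInterpolator(ok_st, np.asarray(F_st), extrapolate=True)
    J_axis = PchipInterpolator(ok_st, np.asarray(J_st), extrapolate=True)

    # --- assemble table -------------------------------------------------------
    nr, nz = len(r_vals), len(z_vals)
    F_r = np.zeros((nr, nz))
    F_z = np.zeros((nr, nz))
    J = np.full((nr, nz), I0)
    mode = np.zeros((nr, nz), dtype=np.int8)
    R, Z = np.meshgrid(r_vals, z_vals, indexing="ij")

    # point-particle closure everywhere valid
    q = np.stack([R.ravel(), Z.ravel()], axis=-1)
    Er_q = interp["Er"](q).reshape(R.shape)
    Ez_q = interp["Ez"](q).reshape(R.shape)
    ur_q = interp["ur"](q).reshape(R.shape)
    uz_q = interp["uz"](q).reshape(R.shape)
    pts3 = np.stack([R.ravel(), np.zeros(R.size), Z.ravel()], axis=-1)
    D3 = D_prot.tensor(pts3)  # (n, 3, 3), meridian plane is x-z at y=0
    kT = constants.kT
    gam = kT * np.linalg.inv(D3)
    F_r_pp = Q * constants.q * Er_q + \
        (gam[:, 0, 0] * ur_q.ravel() + gam[:, 0, 2] * uz_q.ravel()).reshape(R.shape)
    F_z_pp = Q * constants.q * Ez_q + \
        (gam[:, 2, 0] * ur_q.ravel() + gam[:, 2, 2] * uz_q.ravel()).reshape(R.shape)
    F_r[:, :] = F_r_pp
    F_z[:, :] = F_z_pp
    mode[valid] = 2

    # on-axis explicit values override the closure; off-axis blockades decay
    # from the axial profile toward I0 away from the pore mouth
    z_cov = (Z >= ok_st.min()) & (Z <= ok_st.max())
    F_z[0, :] = np.where(z_cov[0, :], F_axis(z_vals), F_z[0, :])
    F_r[0, :] = 0.0
    mode[0, z_cov[0, :] & valid[0, :]] = 1
    Jax = J_axis(z_vals)
    in_chan = (Z <= 0.0) & (Z >= -L)
    R_top = spec.channel_radius(0.0)
    w = np.where(in_chan, 1.0, np.exp(-(R / (2 * R_top)) ** 2))
    w = np.where(z_cov, w, 0.0)
    J = I0 + (np.broadcast_to(Jax[None, :], J.shape) - I0) * w

    F_r = _fill_invalid(np.where(valid, F_r, np.nan), valid)
    F_z = _fill_invalid(np.where(valid, F_z, np.nan), valid)
    J = _fill_invalid(np.where(valid, J, np.nan), valid)
    mode[~valid] = 0

    return ForceCurrentGrid(
        spec=spec, protein_radius=a, protein_charge_q=Q,
        voltage=config.voltage, bulk_conc=config.bulk_conc,
        r=r_vals, z=z_vals, F_r=F_r, F_z=F_z, J=J, I0=I0,
        valid=valid, mode=mode,
        metadata={"explicit_stations": len(ok_st), "failures": failures,
                  "ion_model": config.ion_model},
    )


def interpolate(grid: ForceCurrentGrid, x):
    """Module-level convenience wrapper over :meth:`ForceCurrentGrid.interpolate`."""
    return grid.interpolate(x)
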