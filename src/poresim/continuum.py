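"""Coupled Poisson-Nernst-Planck-Stokes solver on axisymmetric meshes.

The electrokinetic system solved here couples

* Poisson's equation for the electric potential (permanent, surface and
  ionic charge),
* Nernst-Planck drift-diffusion-advection transport of a symmetric
  monovalent electrolyte (Scharfetter-Gummel flux discretization),
* Stokes flow of the solvent driven by the electric body force on the space
  charge (MAC staggered finite volumes).

The domain is the (r, z) half-plane of an axisymmetric pore; see
:mod:`poresim.geometry`.  A damped Gummel fixed-point iteration with a
Boltzmann-consistent linearization of the Poisson step couples the blocks.
The Stokes block additionally supports the azimuthal Fourier mode m = 1
(amplitude fields u_r cos, -u_theta sin, u_z cos, p cos), which yields the
transverse components of the hydrodynamic friction tensor of an on-axis
sphere from a purely two-dimensional solve.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import CONSTANTS, NM, PhysicalConstants
from .geometry import FLUID, MEMBRANE, PROTEIN, WALL, Mesh

__all__ = [
    "SolverOptions",
    "ContinuumSolution",
    "StokesOperator",
    "solve_pnps",
    "solve_stokes",
    "compute_current",
    "compute_force",
]


@dataclass
class SolverOptions:
    """Fixed-point options for the PNPS Gummel iteration."""

    tol: float = 1e-6
    max_iter: int = 80
    relax: float = 0.5
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, history: list[float]):
        super().__init__(msg)
        self.history = history


@dataclass
class ContinuumSolution:
    """PNPS solution fields on a mesh (SI units).

    phi (V), c_plus/c_minus (mol/m^3) and p (Pa) are cell-centred with shape
    (n_r, n_z); u_r / u_z (m/s) live on radial / axial faces.  Fields are
    meaningful on the fluid region only (phi also in solids).
    """

    mesh: Mesh
    phi: np.ndarray
    c_plus: np.ndarray
    c_minus: np.ndarray
    u_r: np.ndarray
    u_z: np.ndarray
    p: np.ndarray
    metadata: dict = field(default_factory=dict)

    def save(self, path: str) -> None:
        """Write the fields and parameter metadata to an HDF5 container."""
        import h5py
        with h5py.File(path, "w") as f:
            for name in ("phi", "c_plus", "c_minus", "u_r", "u_z", "p"):
                f.create_dataset(name, data=getattr(self, name))
            f.create_dataset("r_edges", data=self.mesh.r_edges)
            f.create_dataset("z_edges", data=self.mesh.z_edges)
            f.create_dataset("region", data=self.mesh.region)
            f.attrs["spec_yaml"] = self.mesh.spec.to_yaml()
            for k, v in self.metadata.items():
                if isinstance(v, (int, float, str, np.number)):
                    f.attrs[f"meta_{k}"] = v

    @classmethod
    def load(cls, path: str) -> "ContinuumSolution":
        import h5py
        from .geometry import PoreSpec
        from .geometry import mesh as build_mesh_  # noqa: F401 (spec rebuild)
        with h5py.File(path, "r") as f:
            spec = PoreSpec.from_yaml(f.attrs["spec_yaml"])
            m = Mesh(spec=spec, protein=None, r_edges=f["r_edges"][:],
                     z_edges=f["z_edges"][:], region=f["region"][:],
                     sigma_rface=np.zeros((f["region"].shape[0] + 1,
                                           f["region"].shape[1])),
                     sigma_zface=np.zeros((f["region"].shape[0],
                                           f["region"].shape[1] + 1)))
            meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
            return cls(mesh=m, phi=f["phi"][:], c_plus=f["c_plus"][:],
                       c_minus=f["c_minus"][:], u_r=f["u_r"][:],
                       u_z=f["u_z"][:], p=f["p"][:], metadata=meta)


# ---------------------------------------------------------------------------
# SI grid helper
# ---------------------------------------------------------------------------

class _Grid:
    """Precomputed SI-unit arrays and masks for a mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.re = mesh.r_edges * NM
        self.ze = mesh.z_edges * NM
        self.rc = 0.5 * (self.re[1:] + self.re[:-1])
        self.zc = 0.5 * (self.ze[1:] + self.ze[:-1])
        self.dr = np.diff(self.re)
        self.dz = np.diff(self.ze)
        self.nr = len(self.rc)
        self.nz = len(self.zc)
        self.region = mesh.region
        self.fluid = mesh.region == FLUID
        # ring cross-section areas (z-face area) and lateral r-face areas
        self.ring = np.pi * (self.re[1:] ** 2 + self.re[:-1] ** 2) * 0 + \
            np.pi * (self.re[1:] ** 2 - self.re[:-1] ** 2)  # (nr,)
        self.vol = self.ring[:, None] * self.dz[None, :]  # (nr, nz)

    def rface_area(self, j_slice=slice(None)):
        # area of r-face at edge i for cell column j: 2 pi r_e dz_j
        return 2 * np.pi * self.re[:, None] * self.dz[None, :]


# ---------------------------------------------------------------------------
# Bernoulli function for Scharfetter-Gummel fluxes
# ---------------------------------------------------------------------------

def _bernoulli(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, -200.0, 200.0)
    out = np.where(np.abs(x) > 1e-10, x / np.expm1(np.where(np.abs(x) > 1e-10, x, 1.0)),
                   1.0 - x / 2.0)
    return out


# ---------------------------------------------------------------------------
# Poisson block
# ---------------------------------------------------------------------------

class _PoissonBlock:
    """FV Poisson operator over the whole domain with per-material
    permittivity, Dirichlet plates at the reservoir top/bottom and surface
    charge on tagged fluid-solid faces."""

    def __init__(self, g: _Grid, constants: PhysicalConstants):
        self.g = g
        self.constants = constants
        mesh = g.mesh
        spec = mesh.spec
        eps = np.empty(g.region.shape)
        eps[g.region == FLUID] = constants.permittivity("water")
        eps[g.region == WALL] = constants.permittivity(spec.wall_material)
        if (g.region == MEMBRANE).any():
            eps[g.region == MEMBRANE] = constants.permittivity(spec.membrane.material)
        if (g.region == PROTEIN).any():
            eps[g.region == PROTEIN] = constants.permittivity("protein")
        self.eps = eps
        self._build()

    def _build(self) -> None:
        g = self.g
        nr, nz = g.nr, g.nz
        n = nr * nz
        idx = np.arange(n).reshape(nr, nz)
        rows, cols, vals = [], [], []
        diag = np.zeros(n)

        def add_pairs(iL, iR, coef):
            rows.append(iL); cols.append(iR); vals.append(coef)
            rows.append(iR); cols.append(iL); vals.append(coef)
            np.add.at(diag, iL, -coef)
            np.add.at(diag, iR, -coef)

        # radial faces (between i-1 and i)
        dLR = g.rc[1:] - g.rc[:-1]
        A = 2 * np.pi * g.re[1:-1][:, None] * g.dz[None, :]
        epsf = 2.0 * self.eps[:-1, :] * self.eps[1:, :] / (self.eps[:-1, :] + self.eps[1:, :])
        coef = (A * epsf / dLR[:, None]).ravel()
        add_pairs(idx[:-1, :].ravel(), idx[1:, :].ravel(), coef)
        # axial faces
        dLR = g.zc[1:] - g.zc[:-1]
        A = np.broadcast_to(g.ring[:, None], (nr, nz - 1))
        epsf = 2.0 * self.eps[:, :-1] * self.eps[:, 1:] / (self.eps[:, :-1] + self.eps[:, 1:])
        coef = (A * epsf / dLR[None, :]).ravel()
        add_pairs(idx[:, :-1].ravel(), idx[:, 1:].ravel(), coef)
        # Dirichlet plates (ghost at half cell)
        bot_coef = g.ring * self.eps[:, 0] / (g.dz[0] / 2)
        top_coef = g.ring * self.eps[:, -1] / (g.dz[-1] / 2)
        np.add.at(diag, idx[:, 0], -bot_coef)
        np.add.at(diag, idx[:, -1], -top_coef)
        self._bc_bot = bot_coef
        self._bc_top = top_coef

        rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
        self.L = sp.csc_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows).astype(np.int64),
              np.concatenate(cols).astype(np.int64))),
            shape=(n, n))
        self.idx = idx
        # fixed charge: surface charge on tagged faces + protein volume charge
        mesh = g.mesh
        Qfix = np.zeros((nr, nz))
        A_rf = 2 * np.pi * g.re[:, None] * g.dz[None, :]  # (nr+1, nz)
        sig_r = mesh.sigma_rface
        # assign the face sheet charge to the fluid side cell
        for i, j in zip(*np.nonzero(sig_r)):
            q = sig_r[i, j] * A_rf[i, j]
            if i > 0 and g.fluid[i - 1, j]:
                Qfix[i - 1, j] += q
            elif i < nr and g.fluid[i, j]:
                Qfix[i, j] += q
        A_zf = np.broadcast_to(g.ring[:, None], (nr, nz + 1))
        sig_z = mesh.sigma_zface
        for i, j in zip(*np.nonzero(sig_z)):
            q = sig_z[i, j] * A_zf[i, j]
            if j > 0 and g.fluid[i, j - 1]:
                Qfix[i, j - 1] += q
            elif j < nz and g.fluid[i, j]:
                Qfix[i, j] += q
        self.Qfix = Qfix

    def set_protein_charge(self, charge_q: float) -> None:
        g = self.g
        pmask = g.region == PROTEIN
        if pmask.any() and charge_q != 0.0:
            vol = g.vol[pmask].sum()
            self.Qfix = self.Qfix.copy()
            self.Qfix[pmask] += charge_q * self.constants.q * g.vol[pmask] / vol

    def solve(self, c_plus, c_minus, phi_old, v_top: float, v_bot: float):
        """One damped-Newton (Gummel) Poisson step."""
        g = self.g
        c = self.constants
        n = g.nr * g.nz
        Q = self.Qfix.copy()
        fl = g.fluid
        Q[fl] += c.C_F * (c_plus[fl] - c_minus[fl]) * g.vol[fl]
        # Boltzmann-consistent damping term
        damp = np.zeros((g.nr, g.nz))
        damp[fl] = c.C_F * c.q / c.kT * (c_plus[fl] + c_minus[fl]) * g.vol[fl]
        A = self.L - sp.diags(damp.ravel())
        rhs = -(Q + damp * phi_old).ravel()
        rhs[self.idx[:, 0]] -= self._bc_bot * v_bot
        rhs[self.idx[:, -1]] -= self._bc_top * v_top
        phi = spla.spsolve(A.tocsc(), rhs).reshape(g.nr, g.nz)
        return phi


# ---------------------------------------------------------------------------
# Nernst-Planck block (Scharfetter-Gummel)
# ---------------------------------------------------------------------------

class _TransportBlock:
    def __init__(self, g: _Grid, constants: PhysicalConstants, D_rface, D_zface):
        """D_rface: (nr+1, nz), D_zface: (nr, nz+1) diffusivities (m^2/s) at
        faces (only fluid-fluid faces are used)."""
        self.g = g
        self.constants = constants
        self.D_rf = D_rface
        self.D_zf = D_zface
        g = self.g
        fl = g.fluid
        self.mask_rf = fl[:-1, :] & fl[1:, :]          # interior r-faces (nr-1, nz)
        self.mask_zf = fl[:, :-1] & fl[:, 1:]          # interior z-faces (nr, nz-1)
        self.cell_id = -np.ones(fl.shape, dtype=np.int64)
        self.cell_id[fl] = np.arange(fl.sum())
        self.nc = int(fl.sum())

    def _face_quantities(self, phi, u_r, u_z, sign):
        """Peclet numbers and geometric coefficients for all interior faces."""
        g = self.g
        c = self.constants
        # radial faces
        dLR = (g.rc[1:] - g.rc[:-1])[:, None]
        A_rf = 2 * np.pi * g.re[1:-1][:, None] * g.dz[None, :]
        D_rf = self.D_rf[1:-1, :]
        dphi = phi[1:, :] - phi[:-1, :]
        P_r = -sign * c.q / c.kT * dphi + u_r[1:-1, :] * dLR / np.maximum(D_rf, 1e-30)
        coef_r = A_rf * D_rf / dLR
        # axial faces
        dLR = (g.zc[1:] - g.zc[:-1])[None, :]
        A_zf = np.broadcast_to(g.ring[:, None], (g.nr, g.nz - 1))
        D_zf = self.D_zf[:, 1:-1]
        dphi = phi[:, 1:] - phi[:, :-1]
        P_z = -sign * c.q / c.kT * dphi + u_z[:, 1:-1] * dLR / np.maximum(D_zf, 1e-30)
        coef_z = A_zf * D_zf / dLR
        return (P_r, coef_r), (P_z, coef_z)

    def solve(self, phi, u_r, u_z, sign: float, c_bulk: float,
              v_top: float, v_bot: float):
        g = self.g
        c = self.constants
        (P_r, coef_r), (P_z, coef_z) = self._face_quantities(phi, u_r, u_z, sign)
        rows, cols, vals = [], [], []
        diag = np.zeros(self.nc)
        rhs = np.zeros(self.nc)

        def add_faces(mask, P, coef, idL, idR):
            m = mask
            P = P[m]; coef = coef[m]
            iL = idL[m]; iR = idR[m]
            BL = _bernoulli(-P) * coef   # multiplies c_L in flux L->R
            BR = _bernoulli(P) * coef    # multiplies c_R (negative)
            # cell L: +flux ; cell R: -flux
            np.add.at(diag, iL, BL)
            np.add.at(diag, iR, BR)
            rows.extend(iL); cols.extend(iR); vals.extend(-BR)
            rows.extend(iR); cols.extend(iL); vals.extend(-BL)

        idL = self.cell_id[:-1, :]; idR = self.cell_id[1:, :]
        add_faces(self.mask_rf, P_r, coef_r, idL, idR)
        idL = self.cell_id[:, :-1]; idR = self.cell_id[:, 1:]
        add_faces(self.mask_zf, P_z, coef_z, idL, idR)

        # Dirichlet reservoirs via ghost cells at half spacing
        for j, v_ap, dz, uzb, side in (
            (0, v_bot, g.dz[0], u_z[:, 0], "bot"),
            (g.nz - 1, v_top, g.dz[-1], u_z[:, -1], "top"),
        ):
            m = g.fluid[:, j]
            ids = self.cell_id[m, j]
            D = self.D_zf[m, 0 if side == "bot" else -1]
            delta = dz / 2
            A = g.ring[m]
            dphi = phi[m, j] - v_ap if side == "bot" else v_ap - phi[m, j]
            un = uzb[m]
            # orient the face ghost->cell for "bot", cell->ghost for "top"
            P = -sign * c.q / c.kT * dphi + (un if side == "bot" else un) * delta / np.maximum(D, 1e-30)
            coef = A * D / delta
            if side == "bot":
                # flux ghost->cell: coef*(B(-P)*c_ghost - B(P)*c_cell); cell gains
                np.add.at(diag, ids, coef * _bernoulli(P))
                np.add.at(rhs, ids, coef * _bernoulli(-P) * c_bulk)
            else:
                # flux cell->ghost: coef*(B(-P)*c_cell - B(P)*c_ghost); cell loses
                np.add.at(diag, ids, coef * _bernoulli(-P))
                np.add.at(rhs, ids, coef * _bernoulli(P) * c_bulk)

        n = self.nc
        A = sp.csc_matrix((np.concatenate([np.asarray(vals), diag]),
                           (np.concatenate([np.asarray(rows, dtype=np.int64), np.arange(n)]),
                            np.concatenate([np.asarray(cols, dtype=np.int64), np.arange(n)]))),
                          shape=(n, n))
        sol = spla.spsolve(A, rhs)
        out = np.zeros(self.g.fluid.shape)
        out[self.g.fluid] = np.maximum(sol, 0.0)
        return out

    def face_fluxes_z(self, conc, phi, u_r, u_z, sign):
        """Molar flux (mol/s) through every interior z-face, oriented +z."""
        g = self.g
        (_, _), (P_z, coef_z) = self._face_quantities(phi, u_r, u_z, sign)
        cL = conc[:, :-1]
        cR = conc[:, 1:]
        flux = coef_z * (_bernoulli(-P_z) * cL - _bernoulli(P_z) * cR)
        flux = np.where(self.mask_zf, flux, 0.0)
        return flux


# ---------------------------------------------------------------------------
# Stokes block (MAC staggered, azimuthal modes m = 0 and m = 1)
# ---------------------------------------------------------------------------

class StokesOperator:
    """Staggered finite-volume Stokes operator on the fluid region.

    Unknowns: u_r on interior radial faces, u_z on axial faces (including the
    open reservoir top/bottom when ``open_top_bottom``), for m=1 additionally
    u_theta at cell centres, and p at cell centres.  Dirichlet (no-slip or
    prescribed) velocities on fluid-solid faces enter through the right-hand
    side.  The factorized matrix is reused across solves.
    """

    def __init__(self, mesh: Mesh, constants: PhysicalConstants = CONSTANTS,
                 m: int = 0, open_top_bottom: bool = True):
        if m not in (0, 1):
            raise ValueError("azimuthal mode m must be 0 or 1")
        self.g = _Grid(mesh)
        self.constants = constants
        self.m = m
        self.open_tb = open_top_bottom
        self._build()

    # -- unknown numbering --------------------------------------------------
    def _build(self) -> None:
        g = self.g
        eta = self.constants.eta
        nr, nz = g.nr, g.nz
        fl = g.fluid

        # active u_r faces: interior edges with fluid on both sides
        act_ur = np.zeros((nr + 1, nz), dtype=bool)
        act_ur[1:-1, :] = fl[:-1, :] & fl[1:, :]
        # active u_z faces: interior fluid-fluid, plus open top/bottom
        act_uz = np.zeros((nr, nz + 1), dtype=bool)
        act_uz[:, 1:-1] = fl[:, :-1] & fl[:, 1:]
        if self.open_tb:
            act_uz[:, 0] = fl[:, 0]
            act_uz[:, -1] = fl[:, -1]
        self.act_ur, self.act_uz = act_ur, act_uz
        id_ur = -np.ones(act_ur.shape, dtype=np.int64)
        id_uz = -np.ones(act_uz.shape, dtype=np.int64)
        n_ur = int(act_ur.sum()); n_uz = int(act_uz.sum())
        id_ur[act_ur] = np.arange(n_ur)
        id_uz[act_uz] = n_ur + np.arange(n_uz)
        nc = int(fl.sum())
        cell_id = -np.ones(fl.shape, dtype=np.int64)
        off = n_ur + n_uz
        self.n_ut = nc if self.m == 1 else 0
        cell_id[fl] = np.arange(nc)
        id_ut = np.where(cell_id >= 0, cell_id + off, -1) if self.m == 1 else None
        id_p = np.where(cell_id >= 0, cell_id + off + self.n_ut, -1)
        self.id_ur, self.id_uz, self.id_ut, self.id_p = id_ur, id_uz, id_ut, id_p
        self.n_ur, self.n_uz, self.nc = n_ur, n_uz, nc
        ntot = off + self.n_ut + nc
        self.ntot = ntot

        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        # bc_rows/bc_cols: contributions row -> (boundary face, coefficient)
        # boundary faces are identified by ('ur'|'uz'|'ut', i, j)
        self.bc_terms: list[tuple[np.ndarray, str, np.ndarray, np.ndarray, np.ndarray]] = []

        def add(r, c, v):
            rows.append(np.asarray(r, dtype=np.int64).ravel())
            cols.append(np.asarray(c, dtype=np.int64).ravel())
            vals.append(np.asarray(v, dtype=float).ravel())

        diag = np.zeros(ntot)

        def add_diag(r, v):
            np.add.at(diag, np.asarray(r, dtype=np.int64).ravel(), np.asarray(v, float).ravel())

        bc_rows: list[np.ndarray] = []
        bc_kind: list[str] = []
        bc_i: list[np.ndarray] = []
        bc_j: list[np.ndarray] = []
        bc_coef: list[np.ndarray] = []

        def couple(rid, kind, ii, jj, nid, coef):
            """Viscous coupling between unknown rows `rid` and neighbour
            velocity nodes (`nid` where active, else Dirichlet data)."""
            rid = np.asarray(rid).ravel(); nid = np.asarray(nid).ravel()
            coef = np.asarray(coef, float).ravel()
            ii = np.asarray(ii).ravel(); jj = np.asarray(jj).ravel()
            actv = nid >= 0
            add_diag(rid, -coef)
            if actv.any():
                add(rid[actv], nid[actv], coef[actv])
            rest = ~actv
            if rest.any():
                bc_rows.append(rid[rest]); bc_kind.append(kind)
                bc_i.append(ii[rest]); bc_j.append(jj[rest]); bc_coef.append(coef[rest])

        # ---------------- u_r momentum ----------------
        iu, ju = np.nonzero(act_ur)
        rid = id_ur[iu, ju]
        re_u = g.re[iu]
        dz_u = g.dz[ju]
        # CV radial extent [rc[iu-1], rc[iu]]
        drcv = g.rc[iu] - g.rc[iu - 1]
        Vcv = 2 * np.pi * re_u * drcv * dz_u
        # radial neighbours at edges iu-1 and iu+1 (faces), flux areas at cell centres
        for dirn in (-1, +1):
            inb = iu + dirn
            # flux boundary at cell centre rc between
            r_flux = g.rc[iu] if dirn == +1 else g.rc[iu - 1]
            delta = np.abs(g.re[np.clip(inb, 0, nr)] - re_u)
            # neighbour face may be inactive -> Dirichlet value (e.g. axis, wall)
            nid = np.where((inb >= 0) & (inb <= nr), id_ur[np.clip(inb, 0, nr), ju], -1)
            coef = eta * (2 * np.pi * r_flux * dz_u) / np.maximum(delta, 1e-30)
            if self.m == 1:
                # axis regularity: u_r amplitude is finite at r=0 (transverse
                # flow crosses the axis); use a zero-gradient closure there
                coef = np.where(inb == 0, 0.0, coef)
            couple(rid, "ur", np.clip(inb, 0, nr), ju, nid, coef)
        # axial neighbours
        for dirn in (-1, +1):
            jnb = ju + dirn
            inside = (jnb >= 0) & (jnb < nz)
            nid = np.where(inside, id_ur[iu, np.clip(jnb, 0, nz - 1)], -1)
            # tangential wall handling: neighbour inactive because of solid ->
            # wall at the face between cells; distance centre-to-face
            delta = np.where(inside, np.abs(g.zc[np.clip(jnb, 0, nz - 1)] - g.zc[ju]),
                             g.dz[ju] / 2)
            # where neighbour exists but is a solid-adjacent missing face,
            # use centre-to-edge distance
            solidish = inside & (nid < 0)
            delta = np.where(solidish, g.dz[ju] / 2, delta)
            A = 2 * np.pi * re_u * drcv
            if not self.open_tb:
                pass
            # open top/bottom for u_r: zero tangential stress -> skip flux
            at_open = (~inside) & self.open_tb
            coef = eta * A / np.maximum(delta, 1e-30)
            coef = np.where(at_open, 0.0, coef)
            couple(rid, "ur", iu, np.clip(jnb, 0, nz - 1), nid, coef)
        # curvature sink -eta u_r / r^2 (m=0) or -2 eta (u_r - u_t)/r^2 (m=1)
        fac = 1.0 if self.m == 0 else 2.0
        add_diag(rid, -fac * eta * Vcv / re_u**2)
        if self.m == 1:
            # +2 eta u_theta / r^2, u_theta averaged from the two cells
            for side in (0, 1):
                ic = iu - 1 + side
                nid = id_ut[ic, ju]
                ok = nid >= 0
                add(rid[ok], nid[ok], (eta * Vcv / re_u**2)[ok])
                # inactive u_theta cell (solid): Dirichlet
                rest = ~ok
                if rest.any():
                    bc_rows.append(rid[rest]); bc_kind.append("ut")
                    bc_i.append(ic[rest]); bc_j.append(ju[rest])
                    bc_coef.append((eta * Vcv / re_u**2)[rest])
        # pressure gradient: -(p_i - p_{i-1}) * 2 pi r_e dz
        Ap = 2 * np.pi * re_u * dz_u
        add(rid, id_p[iu, ju], -Ap)
        add(rid, id_p[iu - 1, ju], Ap)
        self._ur_nodes = (iu, ju, rid, Vcv)

        # ---------------- u_z momentum ----------------
        iw, jw = np.nonzero(act_uz)
        rid = id_uz[iw, jw]
        ze_w = g.ze[jw]
        ring_w = g.ring[iw]
        # CV axial extent
        z_lo = np.where(jw > 0, g.zc[np.clip(jw - 1, 0, nz - 1)], g.ze[0])
        z_hi = np.where(jw < nz, g.zc[np.clip(jw, 0, nz - 1)], g.ze[-1])
        dzcv = z_hi - z_lo
        Vcv_w = ring_w * dzcv
        # radial neighbours (faces at edges re[iw], re[iw+1])
        for dirn in (-1, +1):
            inb = iw + dirn
            inside = (inb >= 0) & (inb < nr)
            nid = np.where(inside, id_uz[np.clip(inb, 0, nr - 1), jw], -1)
            r_flux = g.re[iw] if dirn == -1 else g.re[iw + 1]
            delta = np.where(inside, np.abs(g.rc[np.clip(inb, 0, nr - 1)] - g.rc[iw]),
                             g.dr[iw] / 2)
            solidish = inside & (nid < 0)
            delta = np.where(solidish,
                             np.abs(g.re[iw + (1 if dirn == 1 else 0)] - g.rc[iw]),
                             delta)
            A = 2 * np.pi * r_flux * dzcv
            coef = eta * A / np.maximum(delta, 1e-30)
            # axis: area is zero anyway (r_flux = 0); lateral wall: no-slip 0
            couple(rid, "uz", np.clip(inb, 0, nr - 1), jw, nid, coef)
        # axial neighbours
        for dirn in (-1, +1):
            jnb = jw + dirn
            inside = (jnb >= 0) & (jnb <= nz)
            nid = np.where(inside, id_uz[iw, np.clip(jnb, 0, nz)], -1)
            delta = np.where(jnb > jw, g.dz[np.clip(jw, 0, nz - 1)],
                             g.dz[np.clip(jw - 1, 0, nz - 1)])
            solidish = inside & (nid < 0)
            # normal velocity at a solid cell's far face: Dirichlet at distance dz
            A = ring_w
            coef = eta * A / np.maximum(delta, 1e-30)
            at_open = (~inside)
            coef = np.where(at_open, 0.0, coef)  # open boundary handled via p term
            couple(rid, "uz", iw, np.clip(jnb, 0, nz), nid, coef)
        if self.m == 1:
            add_diag(rid, -eta * Vcv_w / np.maximum(g.rc[iw], 1e-30) ** 2)
        # pressure: -(p_j - p_{j-1}) ring ; open boundary: outside pressure = 0
        inside_hi = jw < nz
        tgt = id_p[iw, np.clip(jw, 0, nz - 1)]
        ok = inside_hi & (tgt >= 0)
        add(rid[ok], tgt[ok], -ring_w[ok])
        inside_lo = jw > 0
        tgt = id_p[iw, np.clip(jw - 1, 0, nz - 1)]
        ok = inside_lo & (tgt >= 0)
        add(rid[ok], tgt[ok], ring_w[ok])
        self._uz_nodes = (iw, jw, rid, Vcv_w)

        # ---------------- u_theta momentum (m=1) ----------------
        if self.m == 1:
            ic, jc = np.nonzero(fl)
            rid = id_ut[ic, jc]
            Vc = g.vol[ic, jc]
            rc_c = g.rc[ic]
            # radial diffusion between cell centres
            for dirn in (-1, +1):
                inb = ic + dirn
                inside = (inb >= 0) & (inb < nr)
                nid = np.where(inside, id_ut[np.clip(inb, 0, nr - 1), jc], -1)
                r_flux = g.re[ic] if dirn == -1 else g.re[ic + 1]
                delta = np.where(inside, np.abs(g.rc[np.clip(inb, 0, nr - 1)] - rc_c),
                                 g.dr[ic] / 2)
                solidish = inside & (nid < 0)
                delta = np.where(solidish, g.dr[ic] / 2, delta)
                A = 2 * np.pi * r_flux * g.dz[jc]
                coef = eta * A / np.maximum(delta, 1e-30)
                # axis side: r_flux=0 -> no flux (regularity handled by sink)
                couple(rid, "ut", np.clip(inb, 0, nr - 1), jc, nid, coef)
            for dirn in (-1, +1):
                jnb = jc + dirn
                inside = (jnb >= 0) & (jnb < nz)
                nid = np.where(inside, id_ut[ic, np.clip(jnb, 0, nz - 1)], -1)
                delta = np.where(inside, np.abs(g.zc[np.clip(jnb, 0, nz - 1)] - g.zc[jc]),
                                 g.dz[jc] / 2)
                solidish = inside & (nid < 0)
                delta = np.where(solidish, g.dz[jc] / 2, delta)
                A = g.ring[ic]
                coef = eta * A / np.maximum(delta, 1e-30)
                at_open = (~inside) & self.open_tb
                coef = np.where(at_open, 0.0, coef)
                couple(rid, "ut", ic, np.clip(jnb, 0, nz - 1), nid, coef)
            # coupling -2 eta (u_t - u_r)/r^2
            add_diag(rid, -2 * eta * Vc / rc_c**2)
            for side in (0, 1):
                ie = ic + side
                # at the axis (ie=0) use the first interior face instead:
                # u_r is finite and nearly uniform across the axis
                ie = np.where(ie == 0, 1, ie)
                nid = id_ur[ie, jc]
                ok = nid >= 0
                add(rid[ok], nid[ok], (eta * Vc / rc_c**2)[ok])
                rest = ~ok
                if rest.any():
                    bc_rows.append(rid[rest]); bc_kind.append("ur")
                    bc_i.append(ie[rest]); bc_j.append(jc[rest])
                    bc_coef.append((eta * Vc / rc_c**2)[rest])
            # pressure term -p/r * V
            add(rid, id_p[ic, jc], -Vc / rc_c)
            self._ut_nodes = (ic, jc, rid, Vc)

        # ---------------- continuity ----------------
        ic, jc = np.nonzero(fl)
        rid = id_p[ic, jc]
        # u_r faces at edges ic, ic+1
        for side, sgn in ((0, -1.0), (1, +1.0)):
            ie = ic + side
            A = 2 * np.pi * g.re[ie] * g.dz[jc]
            nid = id_ur[ie, jc]
            ok = nid >= 0
            add(rid[ok], nid[ok], (sgn * A)[ok])
            rest = ~ok & (A > 0)
            if rest.any():
                bc_rows.append(rid[rest]); bc_kind.append("ur")
                bc_i.append(ie[rest]); bc_j.append(jc[rest])
                bc_coef.append((sgn * A)[rest])
        for side, sgn in ((0, -1.0), (1, +1.0)):
            je = jc + side
            A = g.ring[ic]
            nid = id_uz[ic, je]
            ok = nid >= 0
            add(rid[ok], nid[ok], sgn * A[ok])
            rest = ~ok
            if rest.any():
                bc_rows.append(rid[rest]); bc_kind.append("uz")
                bc_i.append(ic[rest]); bc_j.append(je[rest])
                bc_coef.append(sgn * A[rest])
        if self.m == 1:
            add(rid, id_ut[ic, jc], -g.vol[ic, jc] / g.rc[ic])

        rows.append(np.arange(ntot)); cols.append(np.arange(ntot)); vals.append(diag)
        A = sp.csc_matrix((np.concatenate(vals),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(ntot, ntot))
        if not self.open_tb:
            # pin one pressure dof (closed domain nullspace)
            pin = id_p[ic[0], jc[0]]
            A = A.tolil()
            A[pin, :] = 0.0
            A[pin, pin] = 1.0
            A = A.tocsc()
            self._pinned = pin
        else:
            self._pinned = None
        self.A = A
        self.lu = spla.splu(A)
        self._bc = (bc_rows, bc_kind, bc_i, bc_j, bc_coef)

    # -- solve --------------------------------------------------------------
    def solve(self, f_r=None, f_z=None, bc_ur=None, bc_uz=None, bc_ut=None):
        """Solve with body-force densities (N/m^3, arrays at faces) and
        Dirichlet data on inactive faces (arrays over (nr+1,nz)/(nr,nz+1)
        /(nr,nz)).  Returns (u_r, u_z, u_theta|None, p)."""
        g = self.g
        rhs = np.zeros(self.ntot)
        iu, ju, rid_u, Vcv = self._ur_nodes
        if f_r is not None:
            np.add.at(rhs, rid_u, -f_r[iu, ju] * Vcv)
        iw, jw, rid_w, Vcv_w = self._uz_nodes
        if f_z is not None:
            np.add.at(rhs, rid_w, -f_z[iw, jw] * Vcv_w)
        bc_rows, bc_kind, bc_i, bc_j, bc_coef = self._bc
        data = {"ur": bc_ur, "uz": bc_uz, "ut": bc_ut}
        for rr, kind, ii, jj, cc in zip(bc_rows, bc_kind, bc_i, bc_j, bc_coef):
            arr = data.get(kind)
            if arr is None:
                continue
            np.add.at(rhs, rr, -cc * arr[ii, jj])
        if self._pinned is not None:
            rhs[self._pinned] = 0.0
        sol = self.lu.solve(rhs)
        u_r = np.zeros((g.nr + 1, g.nz))
        u_z = np.zeros((g.nr, g.nz + 1))
        p = np.zeros((g.nr, g.nz))
        u_r[self.act_ur] = sol[self.id_ur[self.act_ur]]
        u_z[self.act_uz] = sol[self.id_uz[self.act_uz]]
        if bc_ur is not None:
            u_r[~self.act_ur] = bc_ur[~self.act_ur]
        if bc_uz is not None:
            u_z[~self.act_uz] = bc_uz[~self.act_uz]
        if self.m == 1:
            # axis fill-in: u_r amplitude is continuous across r=0
            fill = self.act_ur[1, :] & ~self.act_ur[0, :]
            u_r[0, fill] = u_r[1, fill]
        fl = g.fluid
        p[fl] = sol[self.id_p[fl]]
        u_t = None
        if self.m == 1:
            u_t = np.zeros((g.nr, g.nz))
            u_t[fl] = sol[self.id_ut[fl]]
            if bc_ut is not None:
                u_t[~fl] = bc_ut[~fl]
        return u_r, u_z, u_t, p

    # -- dissipation (drag via energy) --------------------------------------
    def dissipation(self, u_r, u_z, u_t=None) -> float:
        """Total viscous dissipation (W).  For rigid-body boundary motion with
        quiescent far field this equals F_drag . U."""
        g = self.g
        eta = self.constants.eta
        fl = g.fluid
        # cell-centred strain rates
        rc = g.rc[:, None]
        e_rr = (u_r[1:, :] - u_r[:-1, :]) / g.dr[:, None]
        ur_c = 0.5 * (u_r[1:, :] + u_r[:-1, :])
        e_zz = (u_z[:, 1:] - u_z[:, :-1]) / g.dz[None, :]
        # e_rz at cell centres via interpolation of corner values
        dur_dz = np.zeros_like(e_rr)
        dur_dz[:, 1:-1] = 0.5 * ((u_r[1:, 2:] + u_r[:-1, 2:]) -
                                 (u_r[1:, :-2] + u_r[:-1, :-2])) / \
            (g.zc[2:] - g.zc[:-2])[None, :] * 1.0
        duz_dr = np.zeros_like(e_rr)
        duz_dr[1:-1, :] = 0.5 * ((u_z[2:, 1:] + u_z[2:, :-1]) -
                                 (u_z[:-2, 1:] + u_z[:-2, :-1])) / \
            (g.rc[2:] - g.rc[:-2])[:, None]
        e_rz = 0.5 * (dur_dz + duz_dr)
        if self.m == 0:
            e_tt = ur_c / rc
            phi_d = 2 * eta * (e_rr**2 + e_tt**2 + e_zz**2 + 2 * e_rz**2)
            diss = (phi_d * g.vol)[fl].sum()
            return float(diss)
        # m = 1 amplitudes: azimuthal integrals give a factor pi (vs 2 pi in vol)
        ut = u_t if u_t is not None else np.zeros_like(e_rr)
        e_tt = (ur_c - ut) / rc
        dut_dr = np.zeros_like(ut)
        dut_dr[1:-1, :] = (ut[2:, :] - ut[:-2, :]) / (g.rc[2:] - g.rc[:-2])[:, None]
        e_rt = 0.5 * (dut_dr - ut / rc + ur_c / rc) * 1.0
        # note: e_rt amplitude = 1/2 (r d/dr(ut/r) + ur/r) = 1/2(dut/dr - ut/r + ur/r)
        dut_dz = np.zeros_like(ut)
        dut_dz[:, 1:-1] = (ut[:, 2:] - ut[:, :-2]) / (g.zc[2:] - g.zc[:-2])[None, :]
        uz_c = 0.5 * (u_z[:, 1:] + u_z[:, :-1])
        e_tz = 0.5 * (dut_dz + uz_c / rc)
        phi_d = 2 * eta * (e_rr**2 + e_tt**2 + e_zz**2 +
                           2 * (e_rz**2 + e_rt**2 + e_tz**2))
        diss = 0.5 * (phi_d * g.vol)[fl].sum()  # pi instead of 2 pi
        return float(diss)


# ---------------------------------------------------------------------------
# public drivers
# ---------------------------------------------------------------------------

def _ion_D_faces(mesh: Mesh, ion_diffusivity, g: _Grid):
    """Diffusivity (m^2/s) at r- and z-faces from a model object or float."""
    nr, nz = g.nr, g.nz
    if np.isscalar(ion_diffusivity):
        D = float(ion_diffusivity)
        return np.full((nr + 1, nz), D), np.full((nr, nz + 1), D)
    rf_r = np.broadcast_to(mesh.r_edges[:, None], (nr + 1, nz)).ravel()
    rf_z = np.broadcast_to(mesh.z_centers[None, :], (nr + 1, nz)).ravel()
    Drr, _ = ion_diffusivity.tensor_components(rf_r, rf_z)
    zf_r = np.broadcast_to(mesh.r_centers[:, None], (nr, nz + 1)).ravel()
    zf_z = np.broadcast_to(mesh.z_edges[None, :], (nr, nz + 1)).ravel()
    _, Dzz = ion_diffusivity.tensor_components(zf_r, zf_z)
    return Drr.reshape(nr + 1, nz), Dzz.reshape(nr, nz + 1)


def solve_pnps(mesh: Mesh, constants: PhysicalConstants = CONSTANTS,
               ion_diffusivity=None, voltage: float = 0.0,
               bulk_conc: float = 1.0, options: SolverOptions | None = None,
               protein_charge_q: float = 0.0,
               stokes: bool = True) -> ContinuumSolution:
    """Solve the coupled PNPS system.

    Parameters
    ----------
    voltage : applied transmembrane bias in volts, phi(bottom) - phi(top);
        a negative bias makes the electric field point from the upper (cis)
        reservoir toward the lower (trans) one.
    bulk_conc : reservoir salt concentration in mol/L.
    ion_diffusivity : float (m^2/s) or a diffusivity-field object exposing
        ``tensor_components(r_nm, z_nm) -> (D_rr, D_zz)``; defaults to the
        Stokes-Einstein bulk value for a 0.11 nm ion.
    protein_charge_q : net protein charge in elementary charges, spread
        uniformly over the protein region of the mesh.
    stokes : include the Stokes block (electroosmosis); with False the fluid
        is quiescent (useful for quick estimates and tests).
    """
    options = options or SolverOptions()
    g = _Grid(mesh)
    if ion_diffusivity is None:
        from .diffusivity import bulk_diffusivity
        ion_diffusivity = bulk_diffusivity(constants, 0.11)
    c_bulk = bulk_conc * 1e3  # mol/m^3
    v_top, v_bot = -voltage / 2.0, voltage / 2.0

    poisson = _PoissonBlock(g, constants)
    poisson.set_protein_charge(protein_charge_q)
    D_rf, D_zf = _ion_D_faces(mesh, ion_diffusivity, g)
    transport = _TransportBlock(g, constants, D_rf, D_zf)
    stokes_op = StokesOperator(mesh, constants, m=0, open_top_bottom=True) if stokes else None

    nr, nz = g.nr, g.nz
    phi = np.zeros((nr, nz))
    # linear initial potential between the plates
    phi[:] = (v_bot + (v_top - v_bot) *
              (g.zc - g.ze[0]) / (g.ze[-1] - g.ze[0]))[None, :]
    cp = np.where(g.fluid, c_bulk, 0.0)
    cm = cp.copy()
    u_r = np.zeros((nr + 1, nz))
    u_z = np.zeros((nr, nz + 1))
    p = np.zeros((nr, nz))

    history = []
    t0 = time.time()
    for it in range(options.max_iter):
        phi_new = poisson.solve(cp, cm, phi, v_top, v_bot)
        dphi = np.max(np.abs(phi_new - phi))
        phi = phi + options.relax * (phi_new - phi) if it > 0 else phi_new
        cp_new = transport.solve(phi, u_r, u_z, +1.0, c_bulk, v_top, v_bot)
        cm_new = transport.solve(phi, u_r, u_z, -1.0, c_bulk, v_top, v_bot)
        dc = max(np.max(np.abs(cp_new - cp)), np.max(np.abs(cm_new - cm)))
        w = options.relax if it > 0 else 1.0
        cp = cp + w * (cp_new - cp)
        cm = cm + w * (cm_new - cm)
        if stokes_op is not None:
            rho_rf = constants.C_F * 0.5 * ((cp[:-1, :] + cp[1:, :]) -
                                            (cm[:-1, :] + cm[1:, :]))
            f_r = np.zeros((nr + 1, nz))
            f_r[1:-1, :] = -rho_rf * (phi[1:, :] - phi[:-1, :]) / \
                (g.rc[1:] - g.rc[:-1])[:, None]
            rho_zf = constants.C_F * 0.5 * ((cp[:, :-1] + cp[:, 1:]) -
                                            (cm[:, :-1] + cm[:, 1:]))
            f_z = np.zeros((nr, nz + 1))
            f_z[:, 1:-1] = -rho_zf * (phi[:, 1:] - phi[:, :-1]) / \
                (g.zc[1:] - g.zc[:-1])[None, :]
            # boundary faces: use one-sided potential gradient to the plate
            f_z[:, 0] = -constants.C_F * (cp[:, 0] - cm[:, 0]) * \
                (phi[:, 0] - v_bot) / (g.dz[0] / 2)
            f_z[:, -1] = -constants.C_F * (cp[:, -1] - cm[:, -1]) * \
                (v_top - phi[:, -1]) / (g.dz[-1] / 2)
            u_r_new, u_z_new, _, p_new = stokes_op.solve(f_r=f_r, f_z=f_z)
            du = max(np.max(np.abs(u_r_new - u_r)), np.max(np.abs(u_z_new - u_z)))
            u_r = u_r + w * (u_r_new - u_r)
            u_z = u_z + w * (u_z_new - u_z)
            p = p_new
        else:
            du = 0.0
        thermal = constants.kT / constants.q
        res = dphi / thermal + dc / c_bulk + du / max(np.max(np.abs(u_z)), 1e-12) * 0.1
        history.append(res)
        if options.verbose:
            print(f"  gummel it {it}: dphi={dphi:.3e} dc={dc:.3e} du={du:.3e} "
                  f"({time.time() - t0:.1f}s)")
        if res < options.tol:
            break
    else:
        if history[-1] > 100 * options.tol:
            raise ConvergenceError(
                f"PNPS fixed point did not converge: residual {history[-1]:.3e}",
                history)

    meta = {
        "voltage_V": voltage,
        "bulk_conc_M": bulk_conc,
        "protein_charge_q": protein_charge_q,
        "iterations": len(history),
        "residual": history[-1] if history else 0.0,
        "diffusivity_model": getattr(ion_diffusivity, "model", "bulk_constant"),
    }
    sol = ContinuumSolution(mesh=mesh, phi=phi, c_plus=cp, c_minus=cm,
                            u_r=u_r, u_z=u_z, p=p, metadata=meta)
    sol.metadata["_transport"] = transport
    return sol


def compute_current(solution: ContinuumSolution, z_cross: float | None = None) -> float:
    """Ion current (A) through the full cross-section at height ``z_cross``
    (nm); defaults to the channel midpoint.  Positive current flows in +z."""
    mesh = solution.mesh
    if z_cross is None:
        z_cross = -mesh.spec.channel_length / 2.0
    if not (mesh.z_edges[0] <= z_cross <= mesh.z_edges[-1]):
        raise ValueError(f"z_cross={z_cross} outside domain")
    g = _Grid(mesh)
    transport = solution.metadata.get("_transport")
    if transport is None:
        c = CONSTANTS
        from .diffusivity import bulk_diffusivity
        D = bulk_diffusivity(c, 0.11)
        transport = _TransportBlock(g, c, np.full((g.nr + 1, g.nz), D),
                                    np.full((g.nr, g.nz + 1), D))
    j = int(np.clip(np.searchsorted(mesh.z_edges, z_cross) - 1, 0, g.nz - 2))
    # interior z-face layer index j in fluxes array corresponds to edge j+1
    fl_p = transport.face_fluxes_z(solution.c_plus, solution.phi,
                                   solution.u_r, solution.u_z, +1.0)
    fl_m = transport.face_fluxes_z(solution.c_minus, solution.phi,
                                   solution.u_r, solution.u_z, -1.0)
    C_F = CONSTANTS.C_F
    return float(C_F * (fl_p[:, j] - fl_m[:, j]).sum())


def compute_force(solution: ContinuumSolution,
                  constants: PhysicalConstants = CONSTANTS) -> tuple[np.ndarray, np.ndarray]:
    """Electric and hydrodynamic force on the explicit protein (N, vectors).

    F_el integrates (volume charge density) x E over the protein; F_drag
    integrates the fluid stress over a control surface a few cells outside
    the protein plus the electric body force in the enclosed fluid shell
    (momentum balance of the shell).  On-axis configurations have zero
    transverse force; only the z components are nonzero.
    """
    mesh = solution.mesh
    g = _Grid(mesh)
    pmask = mesh.region == PROTEIN
    if not pmask.any():
        raise ValueError("mesh contains no protein region")
    phi = solution.phi
    # E_z at cell centres (central differences on the nonuniform grid)
    Ez = np.zeros_like(phi)
    Ez[:, 1:-1] = -(phi[:, 2:] - phi[:, :-2]) / (g.zc[2:] - g.zc[:-2])[None, :]
    q_chg = solution.metadata.get("protein_charge_q", 0.0) * constants.q
    vol_p = g.vol[pmask].sum()
    rho_p = q_chg / vol_p if vol_p > 0 else 0.0
    F_el_z = float((rho_p * Ez[pmask] * g.vol[pmask]).sum())

    # control region: protein dilated by 2 cells
    S = pmask.copy()
    for _ in range(2):
        grown = S.copy()
        grown[1:, :] |= S[:-1, :]
        grown[:-1, :] |= S[1:, :]
        grown[:, 1:] |= S[:, :-1]
        grown[:, :-1] |= S[:, 1:]
        S = grown
    Sf = S & g.fluid  # fluid shell
    eta = constants.eta
    u_r, u_z, p = solution.u_r, solution.u_z, solution.p

    # cell-centred velocity gradients for traction evaluation
    duz_dz = (u_z[:, 1:] - u_z[:, :-1]) / g.dz[None, :]

    F_z = 0.0
    nr, nz = g.nr, g.nz
    inS = np.zeros((nr + 2, nz + 2), dtype=bool)
    inS[1:-1, 1:-1] = S
    ii, jj = np.nonzero(Sf)
    for i, j in zip(ii, jj):
        # z-faces (normal +-z): sigma_zz = -p + 2 eta duz/dz
        for dj, sgn in ((+1, +1.0), (-1, -1.0)):
            if inS[i + 1, j + 1 + dj]:
                continue
            jn = j + dj
            A = g.ring[i]
            if 0 <= jn < nz and g.fluid[i, jn]:
                pf = 0.5 * (p[i, j] + p[i, jn])
                dd = 0.5 * (duz_dz[i, j] + duz_dz[i, jn])
            else:
                pf = p[i, j]
                dd = duz_dz[i, j]
            F_z += sgn * A * (-pf + 2 * eta * dd)
            # shear sigma_rz contributes to F_r only; skip (axisymmetric)
        # r-faces (normal +-r): sigma_rz = eta (duz/dr + dur/dz)
        for di, sgn in ((+1, +1.0), (-1, -1.0)):
            if inS[i + 1 + di, j + 1]:
                continue
            ie = i + 1 if di == +1 else i
            A = 2 * np.pi * g.re[ie] * g.dz[j]
            if A == 0.0:
                continue
            inn = i + di
            uz_here = 0.5 * (u_z[i, j] + u_z[i, j + 1])
            if 0 <= inn < nr and g.fluid[inn, j]:
                uz_nb = 0.5 * (u_z[inn, j] + u_z[inn, j + 1])
                duz_dr = (uz_nb - uz_here) / (g.rc[inn] - g.rc[i]) * (1.0 if di == 1 else -1.0) * (1.0 if di == 1 else -1.0)
                duz_dr = (uz_nb - uz_here) / ((g.rc[inn] - g.rc[i]))
            else:
                duz_dr = (0.0 - uz_here) / (g.re[ie] - g.rc[i])
            jl = max(j - 1, 0); jh = min(j + 1, nz - 1)
            dur_dz = (0.5 * (u_r[ie, jh] + u_r[ie, jh]) -
                      0.5 * (u_r[ie, jl] + u_r[ie, jl])) / \
                max(g.zc[jh] - g.zc[jl], 1e-30)
            F_z += sgn * A * eta * (duz_dr + dur_dz)
    # body force inside the shell
    rho_e = constants.C_F * (solution.c_plus - solution.c_minus)
    Ez_f = Ez
    F_z += float((rho_e[Sf] * Ez_f[Sf] * g.vol[Sf]).sum())
    F_el = np.array([0.0, 0.0, F_el_z])
    F_drag = np.array([0.0, 0.0, F_z])
    return F_el, F_drag


def solve_stokes(mesh: Mesh, boundary_velocity: tuple[str, tuple[float, float, float]],
                 constants: PhysicalConstants = CONSTANTS,
                 open_top_bottom: bool = True):
    """Stokes flow with a prescribed rigid velocity on one tagged surface.

    ``boundary_velocity`` is ("protein", (vx, vy, vz)); no-slip elsewhere.
    An axial velocity uses the m=0 mode, a transverse one the m=1 mode.
    Returns a dict with fields, the viscous dissipation, and the drag force
    component along the prescribed unit direction (from dissipation).
    """
    tag, v = boundary_velocity
    if tag != "protein":
        raise ValueError("only the protein surface can move")
    vx, vy, vz = v
    if (vx or vy) and vz:
        raise ValueError("prescribe either an axial or a transverse velocity")
    if not (mesh.region == PROTEIN).any():
        raise ValueError("mesh has no protein region")
    if vz or not (vx or vy):
        op = StokesOperator(mesh, constants, m=0, open_top_bottom=open_top_bottom)
        bc_uz = np.zeros((op.g.nr, op.g.nz + 1))
        pm = mesh.region == PROTEIN
        padded = np.zeros((op.g.nr, op.g.nz + 2), dtype=bool)
        padded[:, 1:-1] = pm
        zfaces = padded[:, 1:] | padded[:, :-1]
        bc_uz[zfaces] = vz
        bc_ur = np.zeros((op.g.nr + 1, op.g.nz))
        u_r, u_z, _, p = op.solve(bc_ur=bc_ur, bc_uz=bc_uz)
        diss = op.dissipation(u_r, u_z)
        speed = abs(vz) if vz else 1.0
        return {"u_r": u_r, "u_z": u_z, "p": p, "dissipation": diss,
                "drag": diss / speed**2 * speed, "mode": 0, "operator": op}
    speed = float(np.hypot(vx, vy))
    op = StokesOperator(mesh, constants, m=1, open_top_bottom=open_top_bottom)
    pm = mesh.region == PROTEIN
    bc_ur = np.zeros((op.g.nr + 1, op.g.nz))
    padded = np.zeros((op.g.nr + 2, op.g.nz), dtype=bool)
    padded[1:-1, :] = pm
    rfaces = padded[1:, :] | padded[:-1, :]
    bc_ur[rfaces] = speed
    bc_ut = np.zeros((op.g.nr, op.g.nz))
    bc_ut[pm] = speed
    bc_uz = np.zeros((op.g.nr, op.g.nz + 1))
    u_r, u_z, u_t, p = op.solve(bc_ur=bc_ur, bc_uz=bc_uz, bc_ut=bc_ut)
    diss = op.dissipation(u_r, u_z, u_t)
    return {"u_r": u_r, "u_z": u_z, "u_t": u_t, "p": p, "dissipation": diss,
            "drag": diss / speed**2 * speed, "mode": 1, "operator": op}
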