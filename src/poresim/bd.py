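"""Brownian-dynamics integration of protein trajectories.

The overdamped Langevin update with a position-dependent diffusion tensor is

    x' = x + dt (div D)(x) + dt/kT D(x) F(x) + sqrt(2 dt) C(x) xi,

with D = C C^T (Cholesky) and xi standard normal.  The spurious-drift term
div D is evaluated by central differences on the diffusivity field so that a
spatially varying D still samples the correct (uniform/Boltzmann) stationary
distribution.  Steps that would penetrate a wall are shortened so the
protein stops a small distance before contact (hard-sphere reflection).

Randomness is drawn from counter-based Philox streams keyed by
(global seed, trajectory index): each trajectory's noise sequence is
reproducible independently of how trajectories are batched.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import CONSTANTS, NM, PhysicalConstants
from .forcefield import ForceCurrentGrid
from .geometry import PoreSpec, wall_distance

__all__ = ["TerminationRule", "Trajectory", "step", "reflect",
           "run_trajectory", "run_trajectories", "current_trace"]

#: reflection offset: the protein stops this far (nm) before wall contact
REFLECT_EPS = 1e-3
#: stencil (nm) for the numerical divergence of the diffusion tensor
DIV_STENCIL = 0.05


@dataclass(frozen=True)
class TerminationRule:
    """Trajectory termination: translocation past an exit plane, or escape
    from a boundary region beyond the entry plane.

    ``direction`` is -1 when translocation proceeds toward smaller z (the
    protein enters at the top) and +1 for the opposite.  The escape region
    is a cylinder of ``escape_radius`` extending ``escape_height`` beyond
    the entry plane (the axisymmetric equivalent of the boundary box).
    """

    exit_z: float
    entry_z: float
    direction: int = -1
    escape_radius: float = 10.0 / np.sqrt(np.pi)
    escape_height: float = 12.0
    max_steps: int = 500_000

    @classmethod
    def for_spec(cls, spec: PoreSpec, max_steps: int = 500_000) -> "TerminationRule":
        if spec.name == "solid_state":
            base = spec.channel_radius(-spec.channel_length)
            return cls(exit_z=0.0, entry_z=-spec.channel_length, direction=+1,
                       escape_radius=base + 6.0, escape_height=12.0,
                       max_steps=max_steps)
        return cls(exit_z=-spec.channel_length, entry_z=0.0, direction=-1,
                   max_steps=max_steps)

    def classify(self, pts: np.ndarray):
        """0 = running, 1 = translocated, 2 = escaped, for (n, 3) points."""
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        r = np.hypot(x, y)
        out = np.zeros(len(pts), dtype=np.int8)
        if self.direction < 0:
            out[z <= self.exit_z] = 1
            beyond = z > self.entry_z
            esc = (z > self.entry_z + self.escape_height) | \
                (beyond & (r > self.escape_radius))
        else:
            out[z >= self.exit_z] = 1
            beyond = z < self.entry_z
            esc = (z < self.entry_z - self.escape_height) | \
                (beyond & (r > self.escape_radius))
        out[esc & (out == 0)] = 2
        return out


@dataclass
class Trajectory:
    """One BD trajectory with binding-zone records and current aggregates."""

    dt: float                      # s
    n_steps: int
    termination: str               # translocated | escaped | max_steps
    seed: int
    index: int
    duration: float                # s
    mean_blockade: float           # time-average of (I0-J)/I0
    zone_records: dict = field(default_factory=dict)
    # zone_records[site_idx] = dict(t=..., x=(n,3), F=(n,), blockade=(n,))
    positions: np.ndarray | None = None  # (n_stored, 3) nm if recorded
    stride: int = 0

    @property
    def translocated(self) -> bool:
        return self.termination == "translocated"


# ---------------------------------------------------------------------------
# field plumbing
# ---------------------------------------------------------------------------

class _ConstantD:
    """Isotropic constant diffusivity (m^2/s) presented as a tensor field."""

    def __init__(self, D0: float):
        self.D0 = D0

    def tensor(self, pts):
        pts = np.atleast_2d(pts)
        return np.broadcast_to(np.eye(3) * self.D0, (len(pts), 3, 3)).copy()


def _tensor_of(D_field):
    if np.isscalar(D_field):
        return _ConstantD(float(D_field)).tensor
    return D_field.tensor


def _div_tensor(tensor_fn, pts: np.ndarray, h: float = DIV_STENCIL) -> np.ndarray:
    """(div D)_i = sum_j dD_ij/dx_j by central differences (input nm, output
    in m^2/s per metre = m/s)."""
    out = np.zeros((len(pts), 3))
    for j in range(3):
        dp = pts.copy(); dp[:, j] += h
        dm = pts.copy(); dm[:, j] -= h
        dD = (tensor_fn(dp) - tensor_fn(dm)) / (2 * h * NM)
        out += dD[:, :, j]
    return out


def _chol(D: np.ndarray) -> np.ndarray:
    """Batch Cholesky with eigenvalue-clipping fallback."""
    try:
        return np.linalg.cholesky(D)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(0.5 * (D + np.transpose(D, (0, 2, 1))))
        w = np.clip(w, 0.0, None)
        return V * np.sqrt(w)[:, None, :]


def step(x, dt: float, D_field, F, rng, constants: PhysicalConstants = CONSTANTS):
    """One Langevin update for positions ``x`` (n, 3) in nm.

    ``F`` is a force array (n, 3) in newtons or a callable of positions;
    ``D_field`` a diffusivity field object, scalar (m^2/s) or callable.
    Returns proposed positions in nm (no wall handling).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    tensor_fn = _tensor_of(D_field)
    D = tensor_fn(x)
    F = F(x) if callable(F) else np.atleast_2d(np.asarray(F, dtype=float))
    divD = _div_tensor(tensor_fn, x)
    xi = rng.standard_normal((len(x), 3))
    C = _chol(D)
    dx_m = dt * divD + dt / constants.kT * np.einsum("nij,nj->ni", D, F) + \
        np.sqrt(2 * dt) * np.einsum("nij,nj->ni", C, xi)
    return x + dx_m / NM


def _admissible(spec, pts, radius, protein_margin=REFLECT_EPS):
    r = np.hypot(pts[:, 0], pts[:, 1])
    z = pts[:, 2]
    d, _, _ = wall_distance(spec, np.stack([r, z], axis=-1),
                            include_boundaries=True)
    ok = d >= radius + protein_margin * 0.5
    ok &= spec.solid_at(r, z) == 0            # surface distance is unsigned
    ok &= (r <= spec.reservoir.radius) & (z >= spec.z_bot) & (z <= spec.z_top)
    return ok


def reflect(spec: PoreSpec, x_prev, x_prop, radius: float,
            eps: float = REFLECT_EPS, strict: bool = True):
    """Hard-sphere reflection: if the segment x_prev -> x_prop would leave
    the admissible region (wall distance >= protein radius), truncate it to
    stop ``eps`` before contact.  Inputs in nm; accepts (3,) or (n, 3).

    With ``strict`` (default) an inadmissible ``x_prev`` raises; otherwise
    such particles simply stay at ``x_prev``.
    """
    single = np.asarray(x_prop).ndim == 1
    xp = np.atleast_2d(np.asarray(x_prev, dtype=float))
    xq = np.atleast_2d(np.asarray(x_prop, dtype=float)).copy()
    ok = _admissible(spec, xq, radius + eps)
    bad = ~ok
    if bad.any():
        prev_ok = _admissible(spec, xp[bad], radius)
        if not prev_ok.all():
            if strict:
                raise ValueError("reflection from an inadmissible previous position")
            stuck = np.nonzero(bad)[0][~prev_ok]
            xq[stuck] = xp[stuck]
            bad[stuck] = False
            if not bad.any():
                return xq[0] if single else xq
        lo = np.zeros(bad.sum())
        hi = np.ones(bad.sum())
        seg_a = xp[bad]
        seg_d = xq[bad] - seg_a
        for _ in range(20):
            mid = 0.5 * (lo + hi)
            pts = seg_a + mid[:, None] * seg_d
            good = _admissible(spec, pts, radius + eps)
            lo = np.where(good, mid, lo)
            hi = np.where(good, hi, mid)
        xq[bad] = seg_a + lo[:, None] * seg_d
    return xq[0] if single else xq


# ---------------------------------------------------------------------------
# trajectory engines
# ---------------------------------------------------------------------------

class _NoiseBank:
    """Per-trajectory Philox noise, delivered in aligned blocks."""

    def __init__(self, seed: int, indices: Sequence[int], block: int = 2048):
        self.block = block
        self.gens = [np.random.Generator(np.random.Philox(key=[seed, int(i)]))
                     for i in indices]
        self.buf = None
        self.base = 0

    def get(self, n_step: int, active: np.ndarray) -> np.ndarray:
        k = n_step - self.base
        if self.buf is None or k >= self.block:
            self.base = n_step
            k = 0
            self.buf = np.empty((len(self.gens), self.block, 3))
            for i, g in enumerate(self.gens):
                if active[i]:
                    self.buf[i] = g.standard_normal((self.block, 3))
                else:  # keep streams aligned
                    g.bit_generator.advance(2 * self.block * 3)
        return self.buf[:, k, :]


def run_trajectories(spec: PoreSpec, grid: ForceCurrentGrid, D_field,
                     rule: TerminationRule, dt: float, n_traj: int,
                     seed: int, sites: Sequence = (),
                     start: Callable | np.ndarray | None = None,
                     constants: PhysicalConstants = CONSTANTS,
                     store_positions: bool = False, stride: int = 10,
                     batch: int = 512) -> list[Trajectory]:
    """Integrate ``n_traj`` trajectories and collect binding-zone
    records for the adsorption stage.

    ``start``: array (3,) in nm, per-trajectory array (n, 3), or a callable
    rng -> (3,); defaults to the preset's documented start position.
    ``sites``: binding sites whose zones are monitored each step.
    """
    a = grid.protein_radius
    trajs: list[Trajectory] = []
    I0 = abs(grid.I0)
    tensor_fn = _tensor_of(D_field)
    kT = constants.kT

    def default_start(rng):
        if spec.name == "solid_state":
            # uniform over the admissible part of the wide-entrance disc
            base = spec.channel_radius(-spec.channel_length)
            z0 = -spec.channel_length + a + 0.2
            for _ in range(100):
                rr = base * np.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                p = np.array([rr * np.cos(th), rr * np.sin(th), z0])
                if _admissible(spec, p[None, :], a + 2 * REFLECT_EPS)[0]:
                    return p
            return np.array([0.0, 0.0, z0])
        return np.array([0.0, 0.0, 0.0])

    for lo in range(0, n_traj, batch):
        hi = min(lo + batch, n_traj)
        idx = np.arange(lo, hi)
        M = len(idx)
        start_rngs = [np.random.Generator(np.random.Philox(key=[seed ^ 0x5EED, int(i)]))
                      for i in idx]
        if start is None:
            x = np.stack([default_start(r) for r in start_rngs])
        elif callable(start):
            x = np.stack([np.asarray(start(r), dtype=float) for r in start_rngs])
        else:
            s = np.asarray(start, dtype=float)
            x = np.tile(s, (M, 1)) if s.ndim == 1 else s[lo:hi].copy()
        noise = _NoiseBank(seed, idx)
        active = np.ones(M, dtype=bool)
        n_steps = np.zeros(M, dtype=np.int64)
        blockade_sum = np.zeros(M)
        term = np.full(M, "max_steps", dtype=object)
        zone_recs = [{} for _ in range(M)]
        pos_store = [[x[i].copy()] for i in range(M)] if store_positions else None

        n = 0
        while active.any() and n < rule.max_steps:
            act = np.nonzero(active)[0]
            xa = x[act]
            D = tensor_fn(xa)
            divD = _div_tensor(tensor_fn, xa)
            F, J = grid.interpolate(xa)
            xi = noise.get(n, active)[act]
            C = _chol(D)
            dx = dt * divD + dt / kT * np.einsum("nij,nj->ni", D, F) + \
                np.sqrt(2 * dt) * np.einsum("nij,nj->ni", C, xi)
            xp = xa + dx / NM
            # termination is checked on the raw proposal so the escape
            # region is not masked by reflection at the domain boundary
            cls0 = rule.classify(xp)
            keep = cls0 == 0
            if keep.any():
                xp[keep] = reflect(spec, xa[keep], xp[keep], a, strict=False)
            x[act] = xp
            n_steps[act] = n + 1
            blk = np.clip((I0 - np.abs(J)) / I0, 0.0, 1.0)
            blockade_sum[act] += blk
            # binding zones (records at the pre-step position/force)
            for s_i, site in enumerate(sites):
                inz = site.in_zone(spec, xp, a)
                if inz.any():
                    Fm = np.linalg.norm(F[inz], axis=1)
                    for k, gi in enumerate(act[inz]):
                        rec = zone_recs[gi].setdefault(
                            s_i, {"t": [], "x": [], "F": [], "blockade": []})
                        rec["t"].append((n + 1) * dt)
                        rec["x"].append(xp[inz][k].copy())
                        rec["F"].append(Fm[k])
                        rec["blockade"].append(blk[inz][k])
            if store_positions and (n + 1) % stride == 0:
                for k, gi in enumerate(act):
                    pos_store[gi].append(xp[k].copy())
            cls = cls0
            done = cls > 0
            if done.any():
                for k, gi in enumerate(act):
                    if done[k]:
                        term[gi] = "translocated" if cls[k] == 1 else "escaped"
                active[act[done]] = False
            n += 1

        for i in range(M):
            recs = {s: {kk: np.asarray(vv) for kk, vv in r.items()}
                    for s, r in zone_recs[i].items()}
            trajs.append(Trajectory(
                dt=dt, n_steps=int(n_steps[i]), termination=str(term[i]),
                seed=seed, index=int(idx[i]),
                duration=float(n_steps[i] * dt),
                mean_blockade=float(blockade_sum[i] / max(n_steps[i], 1)),
                zone_records=recs,
                positions=np.asarray(pos_store[i]) if store_positions else None,
                stride=stride if store_positions else 0,
            ))
    return trajs


def run_trajectory(spec: PoreSpec, grid: ForceCurrentGrid, D_field,
                   rule: TerminationRule, dt: float, seed: int,
                   index: int = 0, **kw) -> Trajectory:
    """Single-trajectory convenience wrapper."""
    return run_trajectories(spec, grid, D_field, rule, dt, 1, seed,
                            **{**kw, "batch": 1})[0]


def current_trace(trajectory: Trajectory, grid: ForceCurrentGrid):
    """Current (A) at every stored trajectory position.

    Requires the trajectory to have been run with ``store_positions=True``;
    returns (times_s, currents_A).
    """
    if trajectory.positions is None:
        raise ValueError("trajectory was run without stored positions")
    _, J = grid.interpolate(trajectory.positions)
    t = np.arange(len(trajectory.positions)) * trajectory.stride * trajectory.dt
    return t, J
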