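"""Stochastic protein adsorption on top of Brownian-dynamics trajectories.

A binding site is either a spherical receptor tethered near the wall or a
region of the pore wall itself.  While the protein centre is inside the
binding zone, adsorption attempts occur as a Poisson process with rate
R_a = k_a c_b, where c_b is the single-receptor concentration of the zone.
Each adsorption lasts an exponentially distributed time with mean

    tau_bar = (1/k_d) exp(-|F| delta / kT),

Bell's law with bond-rupture length delta (delta = 0 recovers the
force-free mean 1/k_d).  Because binding never alters the spatial shape of
a trajectory, bindings can be drawn after the fact, and rare-binding
statistics can be generated by resampling trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import CONSTANTS, NM, PhysicalConstants
from .events import EventRecord
from .geometry import PoreSpec, wall_distance

__all__ = ["BindingSite", "BindingEvent", "adsorption_rate", "draw_bindings",
           "binding_duration", "assemble_event", "resample_events"]


@dataclass(frozen=True)
class BindingSite:
    """A receptor or wall region the protein can adsorb to.

    For ``spherical_receptor`` the binding radius ``r_b`` is the
    centre-to-centre threshold (nm) and ``receptor`` = (r, z) is the
    receptor position in the meridian plane.  For ``wall_region`` the
    receptor radius is zero, ``r_b`` is the protein-surface-to-wall
    threshold, and ``z_range`` restricts the wall section.
    """

    kind: str
    r_b: float
    k_a: float            # 1/(M s)
    k_d: float            # 1/s
    delta: float = 0.0    # nm; 0 disables force dependence
    receptor: tuple[float, float] | None = None
    r_rec: float = 0.0
    z_range: tuple[float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("spherical_receptor", "wall_region"):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if self.r_b <= 0:
            raise ValueError("binding radius must be positive")
        if self.k_a < 0 or self.k_d < 0 or self.delta < 0:
            raise ValueError("rate constants and delta must be nonnegative")

    def in_zone(self, spec: PoreSpec, pts, protein_radius: float) -> np.ndarray:
        """Boolean mask of Cartesian points (n, 3) whose protein centre lies
        in the binding zone."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        if self.kind == "spherical_receptor":
            rr, zr = self.receptor
            # receptor anchored at azimuth 0
            d = np.sqrt((pts[:, 0] - rr) ** 2 + pts[:, 1] ** 2 +
                        (pts[:, 2] - zr) ** 2)
            return d < self.r_b
        r = np.hypot(pts[:, 0], pts[:, 1])
        d, _, _ = wall_distance(spec, np.stack([r, pts[:, 2]], axis=-1))
        m = (d - protein_radius) < self.r_b
        if self.z_range is not None:
            m &= (pts[:, 2] >= self.z_range[0]) & (pts[:, 2] <= self.z_range[1])
        return m


@dataclass(frozen=True)
class BindingEvent:
    """One adsorption episode drawn for a trajectory."""

    step_time: float     # s, trajectory time of the adsorption attempt
    duration: float      # s
    force: float         # N, magnitude used in the Bell factor
    site: int            # site index
    blockade: float      # relative blockade at the binding position


def adsorption_rate(site: BindingSite, protein_radius: float,
                    constants: PhysicalConstants = CONSTANTS) -> float:
    """Adsorption attempt rate R_a = k_a c_b (1/s) inside the binding zone.

    The zone volume is the spherical shell between centre distances
    (r_prot + r_rec) and the centre-to-site threshold; for wall regions
    (r_rec = 0) the threshold is r_prot + r_b with r_b measured from the
    protein surface.
    """
    if site.kind == "spherical_receptor":
        r_in = protein_radius + site.r_rec
        r_out = site.r_b
    else:
        r_in = protein_radius
        r_out = protein_radius + site.r_b
    if r_out <= r_in:
        raise ValueError("degenerate binding zone (outer radius <= inner)")
    V_b = 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3) * NM**3  # m^3
    c_b = 1.0 / (1e3 * constants.N_A * V_b)  # mol/L
    return site.k_a * c_b


def binding_duration(site: BindingSite, F, constants: PhysicalConstants,
                     rng: np.random.Generator):
    """Exponential binding duration(s) with the Bell-law mean (s).

    ``F`` is a force vector (3,), a magnitude, or an array of magnitudes.
    """
    if site.k_d <= 0:
        raise ValueError("k_d must be positive (k_d = 0 would bind forever)")
    Fm = np.asarray(F, dtype=float)
    if Fm.ndim and Fm.shape[-1] == 3 and Fm.ndim <= 2:
        Fm = np.linalg.norm(np.atleast_2d(Fm), axis=-1)
    mean = np.exp(-Fm * site.delta * NM / constants.kT) / site.k_d
    out = rng.exponential(mean)
    return float(out) if np.ndim(out) == 0 else out


def draw_bindings(attempt_records: dict, site: BindingSite, dt: float,
                  rng: np.random.Generator, protein_radius: float,
                  constants: PhysicalConstants = CONSTANTS,
                  site_index: int = 0) -> list[BindingEvent]:
    """Draw adsorption events for one trajectory's in-zone records.

    ``attempt_records`` is the per-site dict stored by the BD engine:
    arrays ``t`` (s), ``F`` (N magnitudes), ``blockade``.  The number of
    adsorptions per in-zone step is Poisson with mean R_a dt; several
    adsorptions in one step are applied sequentially (durations add).
    """
    t = np.asarray(attempt_records.get("t", []), dtype=float)
    if t.size == 0:
        return []
    R_a = adsorption_rate(site, protein_radius, constants)
    counts = rng.poisson(R_a * dt, size=t.size)
    events: list[BindingEvent] = []
    Fm = np.asarray(attempt_records["F"], dtype=float)
    blk = np.asarray(attempt_records["blockade"], dtype=float)
    for i in np.nonzero(counts)[0]:
        for _ in range(counts[i]):
            tau = binding_duration(site, Fm[i], constants, rng)
            events.append(BindingEvent(step_time=t[i], duration=float(tau),
                                       force=float(Fm[i]), site=site_index,
                                       blockade=float(blk[i])))
    return events


def assemble_event(trajectory, bindings: Sequence[BindingEvent],
                   voltage: float = np.nan, seed: int = -1) -> EventRecord:
    """Combine a trajectory and its drawn bindings into one current event
    : total duration tau_off and time-weighted amplitude A/I0."""
    tau_free = trajectory.duration
    tau_bind = float(sum(b.duration for b in bindings))
    tau_off = tau_free + tau_bind
    amp = (trajectory.mean_blockade * tau_free +
           sum(b.duration * b.blockade for b in bindings)) / max(tau_off, 1e-300)
    return EventRecord(
        tau_off=tau_off, amplitude=float(np.clip(amp, 0.0, 1.0)),
        outcome=trajectory.termination, bound=len(bindings) > 0,
        n_bindings=len(bindings),
        site_ids=tuple(sorted({b.site for b in bindings})),
        voltage=voltage, seed=seed,
    )


def resample_events(trajectories: Sequence, sites: Sequence[BindingSite],
                    n_events: int, rng: np.random.Generator,
                    protein_radius: float,
                    constants: PhysicalConstants = CONSTANTS,
                    voltage: float = np.nan) -> list[EventRecord]:
    """Generate events by resampling trajectories with fresh binding draws
    - used when binding is rare and trajectories are expensive.

    Fast path: events whose Poisson draw yields zero bindings for every
    site reuse the trajectory's free-motion aggregates directly.
    """
    if not trajectories:
        raise ValueError("empty trajectory pool")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    n_pool = len(trajectories)
    picks = rng.integers(0, n_pool, size=n_events)
    # expected number of bindings per (trajectory, site)
    lam = np.zeros((n_pool, len(sites)))
    for ti, tr in enumerate(trajectories):
        for s_i, site in enumerate(sites):
            rec = tr.zone_records.get(s_i)
            if rec is not None and len(rec["t"]):
                R_a = adsorption_rate(site, protein_radius, constants)
                lam[ti, s_i] = R_a * tr.dt * len(rec["t"])
    tot = rng.poisson(lam.sum(axis=1)[picks])
    events: list[EventRecord] = []
    nonzero = np.nonzero(tot)[0]
    zero = tot == 0
    for ti, count in zip(picks[zero], tot[zero]):
        tr = trajectories[ti]
        events.append(EventRecord(
            tau_off=tr.duration, amplitude=tr.mean_blockade,
            outcome=tr.termination, bound=False, n_bindings=0,
            site_ids=(), voltage=voltage, seed=-1))
    for ev_i in nonzero:
        ti = picks[ev_i]
        tr = trajectories[ti]
        K = int(tot[ev_i])
        lam_s = lam[ti]
        p = lam_s / lam_s.sum()
        per_site = rng.multinomial(K, p)
        bindings: list[BindingEvent] = []
        for s_i, k_s in enumerate(per_site):
            if k_s == 0:
                continue
            rec = tr.zone_records[s_i]
            steps = rng.integers(0, len(rec["t"]), size=k_s)
            for st in steps:
                tau = binding_duration(sites[s_i], rec["F"][st], constants, rng)
                bindings.append(BindingEvent(
                    step_time=float(rec["t"][st]), duration=float(tau),
                    force=float(rec["F"][st]), site=s_i,
                    blockade=float(rec["blockade"][st])))
        events.append(assemble_event(tr, bindings, voltage=voltage))
    return events
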