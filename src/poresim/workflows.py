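"""High-level study workflows composed from the library modules.

These functions bundle the recurring analyses for the built-in pores:
open-pore currents and protein blockades of the DNA origami pore as a
function of channel width, translocation-event statistics from BD
ensembles, and rare-binding statistics for the receptor-modified
solid-state pore.
"""
from __future__ import annotations

import numpy as np

from .binding import BindingSite, adsorption_rate, resample_events
from .constants import CONSTANTS
from .diffusivity import build_field
from .forcefield import SampleConfig, sample
from .geometry import MeshOptions, build_preset, mesh

__all__ = ["dna_blockade_at_width", "dna_width_for_blockade",
           "dna_open_current", "dna_event_ensemble", "solid_state_binding"]

#: mesh sizing used for the DNA-pore continuum solves (nm): EDL-resolving
#: near charged walls, gap-resolving around the protein
DNA_MESH = MeshOptions(fine=0.2, coarse=1.5, edl=0.035, protein=0.04)
#: centerline LRNH stations per channel for the diffusivity normalization
N_STATIONS = 5


def dna_open_current(width: float = 6.0, voltage: float = -0.1,
                     cross_section: str = "square-equivalent",
                     ion_model: str = "combined_rz") -> float:
    """Open-pore current (A) of the DNA origami pore at the given width
    (nm) and bias (V), with position-dependent ion diffusivity."""
    from .continuum import compute_current, solve_pnps
    spec = build_preset("dna_origami", {"width": width,
                                        "cross_section": cross_section})
    field = build_field(spec, 0.11, ion_model, n_stations=N_STATIONS)
    m = mesh(spec, DNA_MESH)
    sol = solve_pnps(m, CONSTANTS, field, voltage, 1.0)
    return compute_current(sol)


def dna_blockade_at_width(width: float, voltage: float = -0.08,
                          protein_radius: float = 2.078,
                          protein_charge_q: float = 5.0,
                          cross_section: str = "circular") -> float:
    """Relative current blockade (I0 - I)/I0 with the trypsin sphere at the
    pore centre, for a circular channel of the given diameter (nm)."""
    from .continuum import compute_current, solve_pnps
    spec = build_preset("dna_origami", {"width": width,
                                        "cross_section": cross_section})
    zp = -spec.channel_length / 2.0
    z_meas = -spec.channel_length - 2.0
    field0 = build_field(spec, 0.11, "combined_rz", n_stations=N_STATIONS)
    m0 = mesh(spec, DNA_MESH)
    I0 = compute_current(solve_pnps(m0, CONSTANTS, field0, voltage, 1.0), z_meas)
    fieldP = build_field(spec, 0.11, "combined_rz", n_stations=N_STATIONS,
                         protein=(zp, protein_radius))
    mP = mesh(spec, DNA_MESH, protein=(zp, protein_radius))
    I = compute_current(solve_pnps(mP, CONSTANTS, fieldP, voltage, 1.0,
                                   protein_charge_q=protein_charge_q), z_meas)
    return float(1.0 - I / I0)


def dna_width_for_blockade(target: float, widths,
                           voltage: float = -0.08, **kw) -> dict:
    """Sweep circular channel diameters and locate where the simulated
    blockade crosses ``target`` (monotone-decreasing interpolation).

    Returns the sweep table and the interpolated crossing diameter (nm).
    """
    widths = np.asarray(sorted(widths), dtype=float)
    blk = np.array([dna_blockade_at_width(w, voltage=voltage, **kw)
                    for w in widths])
    # blockade decreases with width; interpolate width(target)
    order = np.argsort(blk)
    crossing = float(np.interp(target, blk[order], widths[order]))
    return {"widths": widths, "blockades": blk, "crossing": crossing}


def dna_event_ensemble(n_traj: int = 500, seed: int = 1,
                       voltage: float = -0.08, grid=None) -> dict:
    """BD translocation ensemble for trypsin through the nominal DNA pore
    (no binding): per-outcome dwell-time statistics in seconds."""
    from .bd import TerminationRule, run_trajectories
    spec = build_preset("dna_origami")
    if grid is None:
        cfg = SampleConfig(voltage=voltage, protein_charge_q=5.0,
                           explicit_dz=4.0, n_stations=N_STATIONS)
        grid = sample(spec, cfg, protein_radius=2.078)
    D_field = build_field(spec, 2.078, "combined_rz", n_stations=N_STATIONS)
    rule = TerminationRule.for_spec(spec)
    trajs = run_trajectories(spec, grid, D_field, rule, dt=0.2e-9,
                             n_traj=n_traj, seed=seed)
    dur = np.array([t.duration for t in trajs])
    term = np.array([t.termination for t in trajs])
    out = {"grid": grid, "trajectories": trajs,
           "n_translocated": int((term == "translocated").sum()),
           "n_escaped": int((term == "escaped").sum())}
    for key, name in (("translocated", "success"), ("escaped", "failed")):
        sel = dur[term == key]
        out[f"median_{name}_s"] = float(np.median(sel)) if len(sel) else np.nan
    return out


def solid_state_binding(seed: int = 1, n_traj: int = 150,
                        n_events: int = 2_000_000,
                        k_a: float | None = None) -> dict:
    """Rare-binding statistics for the receptor-modified solid-state pore.

    Runs a scaled-down trajectory ensemble, then generates events by
    trajectory resampling with fresh Poisson binding draws.  Returns the
    Monte-Carlo bound fraction, the analytic expectation
    mean(1 - exp(-R_a T_attempt)) over the ensemble, and the attempt-time
    distribution summary.  ``k_a`` defaults to the solution-measurement
    association constant of the preset.
    """
    from .bd import TerminationRule, run_trajectories
    from .continuum import SolverOptions
    spec = build_preset("solid_state")
    md = spec.metadata
    k_a = md["k_a_solution_per_M_s"] if k_a is None else k_a
    z_rec = -spec.channel_length * (1 - md["receptor_height_fraction"])
    site = BindingSite(
        kind="spherical_receptor", r_b=md["binding_radius_nm"],
        k_a=k_a, k_d=md["k_d_solution_per_s"],
        delta=md["bond_rupture_length_nm"],
        receptor=(spec.channel_radius(z_rec) - md["receptor_wall_distance_nm"],
                  z_rec))
    cfg = SampleConfig(voltage=md["voltage_mV"] * 1e-3,
                       protein_charge_q=md["protein_charge_q"],
                       ion_model="bulk_constant", protein_model="r_dependent",
                       explicit_dz=8.0,
                       mesh_options=MeshOptions(fine=1.2, coarse=6.0,
                                                edl=0.2, protein=0.5),
                       solver=SolverOptions(relax=0.3, max_iter=400))
    grid = sample(spec, cfg, protein_radius=md["protein_radius_nm"])
    D_field = build_field(spec, md["protein_radius_nm"], "r_dependent")
    rule = TerminationRule.for_spec(spec, max_steps=300_000)
    trajs = run_trajectories(spec, grid, D_field, rule,
                             dt=md["dt_ns"] * 1e-9, n_traj=n_traj,
                             seed=seed, sites=[site])
    R_a = adsorption_rate(site, md["protein_radius_nm"])
    T_a = np.array([len(t.zone_records.get(0, {}).get("t", [])) * t.dt
                    for t in trajs])
    p_analytic = float(np.mean(1.0 - np.exp(-R_a * T_a)))
    rng = np.random.Generator(np.random.Philox(key=[seed, 77]))
    events = resample_events(trajs, [site], n_events, rng,
                             md["protein_radius_nm"])
    bound = np.array([e.bound for e in events])
    return {"grid": grid, "trajectories": trajs, "site": site, "R_a": R_a,
            "attempt_times": T_a, "bound_fraction_mc": float(bound.mean()),
            "bound_fraction_analytic": p_analytic, "n_events": n_events,
            "median_duration_s": float(np.median([t.duration for t in trajs]))}
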