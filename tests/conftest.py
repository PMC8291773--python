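"""Shared fixtures.

Heavy continuum artifacts (the toy-cylinder solution, the DNA-pore force
table and its trajectory ensemble) are session-scoped so the validation and
statistics tests reuse a single computation.
"""
from __future__ import annotations

import numpy as np
import pytest

from poresim.constants import CONSTANTS
from poresim.continuum import compute_current, solve_pnps
from poresim.diffusivity import build_field, bulk_diffusivity
from poresim.forcefield import SampleConfig, sample
from poresim.geometry import MeshOptions, build_preset, make_fixture, mesh


@pytest.fixture(scope="session")
def toy_cylinder():
    """Uncharged 5 nm-radius, 20 nm-long cylinder with the analytic
    Ohmic + access-resistance conductance oracle."""
    spec = make_fixture("toy_cylinder", radius=5.0, length=20.0,
                        reservoir_radius=30.0, reservoir_height=25.0)
    m = mesh(spec, MeshOptions(fine=0.4, coarse=1.5))
    D = bulk_diffusivity(CONSTANTS, 0.11)
    c = CONSTANTS
    sigma = 2 * c.q * c.C_F * 1000.0 * D / c.kT  # S/m at 1 M
    R, L = 5e-9, 20e-9
    R_oracle = L / (sigma * np.pi * R**2) + 1.0 / (2 * sigma * R)
    return {"spec": spec, "mesh": m, "D": D, "sigma": sigma,
            "R_oracle": R_oracle}


@pytest.fixture(scope="session")
def toy_solution(toy_cylinder):
    sol = solve_pnps(toy_cylinder["mesh"], voltage=0.1, bulk_conc=1.0,
                     ion_diffusivity=toy_cylinder["D"])
    return sol


@pytest.fixture(scope="session")
def dna_spec():
    return build_preset("dna_origami")


@pytest.fixture(scope="session")
def dna_grid(dna_spec):
    """Force/current table for trypsin in the DNA pore at -80 mV."""
    cfg = SampleConfig(voltage=-0.08, protein_charge_q=5.0, explicit_dz=4.0)
    return sample(dna_spec, cfg, protein_radius=2.078)


@pytest.fixture(scope="session")
def dna_trajectories(dna_spec, dna_grid):
    """>=500 trypsin trajectories through the DNA pore (no binding)."""
    from poresim.bd import TerminationRule, run_trajectories
    D_field = build_field(dna_spec, 2.078, "combined_rz", n_stations=5)
    rule = TerminationRule.for_spec(dna_spec)
    return run_trajectories(dna_spec, dna_grid, D_field, rule,
                            dt=0.2e-9, n_traj=500, seed=11)


@pytest.fixture(scope="session")
def dna_wall_trajectories(dna_spec, dna_grid):
    """Smaller ensemble run with the two wall-binding zones monitored."""
    from poresim.bd import TerminationRule, run_trajectories
    from poresim.binding import BindingSite
    L = dna_spec.channel_length
    sites = [
        BindingSite(kind="wall_region", r_b=0.2, k_a=2e7, k_d=77.0,
                    z_range=(-0.6 * L, -0.4 * L), label="central"),
        BindingSite(kind="wall_region", r_b=0.2, k_a=2e6, k_d=6434.0,
                    z_range=(-L, 0.0), label="whole-wall"),
    ]
    D_field = build_field(dna_spec, 2.078, "combined_rz", n_stations=5)
    rule = TerminationRule.for_spec(dna_spec)
    trajs = run_trajectories(dna_spec, dna_grid, D_field, rule,
                             dt=0.2e-9, n_traj=60, seed=5, sites=sites)
    return trajs, sites
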