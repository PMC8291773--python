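"""Brownian dynamics: Langevin statistics, reflection, trajectories."""
import numpy as np
import pytest

from poresim.bd import (TerminationRule, current_trace, reflect, run_trajectories,
                        step)
from poresim.constants import CONSTANTS, NM
from poresim.geometry import make_fixture, wall_distance


class TestStepStatistics:
    def test_free_diffusion_msd(self):
        D0, dt, n = 1e-10, 1e-9, 150
        rng = np.random.default_rng(0)
        x = np.zeros((6000, 3))
        for _ in range(n):
            x = step(x, dt, D0, np.zeros((6000, 3)), rng)
        msd = ((x * NM) ** 2).sum(axis=1).mean()
        assert msd == pytest.approx(6 * D0 * n * dt, rel=0.05)

    def test_constant_force_drift(self):
        D0, dt, n = 1e-10, 1e-9, 120
        F = np.array([0.0, 0.0, 3e-12])
        rng = np.random.default_rng(1)
        x = np.zeros((6000, 3))
        for _ in range(n):
            x = step(x, dt, D0, np.tile(F, (6000, 1)), rng)
        drift = (x[:, 2] * NM).mean()
        expect = n * dt * D0 * F[2] / CONSTANTS.kT
        se = np.sqrt(2 * D0 * n * dt / 6000)
        assert abs(drift - expect) < 3 * se

    def test_varying_diffusivity_stays_uniform(self):
        # D(z) varying by 4x across a closed box; with the spurious-drift
        # term the stationary density remains uniform
        spec = make_fixture("harmonic_box", radius=6.0, length=12.0)

        class VaryingD:
            def tensor(self, pts):
                pts = np.atleast_2d(pts)
                f = 1.0 + 3.0 * (pts[:, 2] + 12.0) / 12.0  # 1 -> 4
                out = np.zeros((len(pts), 3, 3))
                out[:, 0, 0] = out[:, 1, 1] = out[:, 2, 2] = 1e-10 * f
                return out

        field = VaryingD()
        rng = np.random.default_rng(2)
        M = 1500
        x = np.stack([np.zeros(M), np.zeros(M),
                      rng.uniform(-12, 0, M)], axis=-1)
        dt = 2e-10
        for _ in range(4000):
            xp = step(x, dt, field, np.zeros((M, 3)), rng)
            x = reflect(spec, x, xp, 0.3, strict=False)
        z = x[:, 2]
        counts, _ = np.histogram(z, bins=4, range=(-11.4, -0.6))
        total = counts.sum()
        chi2 = ((counts - total / 4) ** 2 / (total / 4)).sum()
        assert chi2 < 11.34  # chi^2_{3, 0.99}

    def test_boltzmann_distribution_in_harmonic_trap(self):
        spec = make_fixture("harmonic_box", radius=8.0, length=16.0)
        k_spring = 1e-3  # N/m -> sigma ~ 2 nm
        x0 = np.array([0.0, 0.0, -8.0])
        rng = np.random.default_rng(3)
        M = 3000
        x = np.tile(x0, (M, 1)) + rng.normal(0, 1.0, (M, 3))
        dt, D0 = 1e-9, 1e-10
        for _ in range(4000):
            F = -k_spring * (x - x0) * NM
            xp = step(x, dt, D0, F, rng)
            x = reflect(spec, x, xp, 0.3, strict=False)
        # chi-square against the Gaussian marginal in each coordinate
        sigma = np.sqrt(CONSTANTS.kT / k_spring) / NM
        # Euler-Maruyama inflates the OU variance by 1/(1 - theta/2)
        sigma *= 1.0 / np.sqrt(1 - dt * D0 * k_spring / CONSTANTS.kT / 2)
        from scipy.stats import chi2, norm
        for axis in range(3):
            u = (x[:, axis] - x0[axis]) / sigma
            edges = norm.ppf(np.linspace(0.02, 0.98, 9))
            counts, _ = np.histogram(u, bins=edges)
            p = np.diff(norm.cdf(edges))
            exp = p / p.sum() * counts.sum()
            stat = ((counts - exp) ** 2 / exp).sum()
            assert stat < chi2.ppf(0.99, len(counts) - 1)


@pytest.fixture(scope="module")
def box():
    return make_fixture("harmonic_box", radius=5.0, length=10.0)


class TestReflect:

    def test_step_in_fluid_unchanged(self, box):
        x0 = np.array([0.0, 0.0, -5.0])
        x1 = np.array([1.0, 0.5, -4.0])
        np.testing.assert_array_equal(reflect(box, x0, x1, 0.5), x1)

    def test_step_into_wall_truncated_on_segment(self, box):
        a = 0.5
        x0 = np.array([0.0, 0.0, -5.0])
        x1 = np.array([6.0, 0.0, -5.0])  # beyond the r=5 wall
        out = reflect(box, x0, x1, a)
        assert out[1] == 0.0 and out[2] == -5.0  # stays on the segment
        d, _, _ = wall_distance(box, (out[0], out[2]), include_boundaries=True)
        assert a <= d <= a + 0.01

    def test_no_penetrations_in_long_run(self, box):
        rng = np.random.default_rng(4)
        a = 0.4
        M = 500
        x = np.zeros((M, 3)); x[:, 2] = -5.0
        for _ in range(2000):
            xp = x + rng.normal(0, 0.5, (M, 3))
            x = reflect(box, x, xp, a, strict=False)
        d, _, _ = wall_distance(box, np.stack([np.hypot(x[:, 0], x[:, 1]),
                                               x[:, 2]], axis=-1),
                                include_boundaries=True)
        assert (d >= a).all()

    def test_inadmissible_previous_raises(self, box):
        with pytest.raises(ValueError):
            reflect(box, np.array([4.9, 0.0, -5.0]),
                    np.array([4.95, 0.0, -5.0]), 0.5)


class TestTrajectories:
    def test_reproducible_bitwise(self, dna_spec, dna_grid):
        from poresim.diffusivity import build_field
        D = build_field(dna_spec, 2.078, "combined_rz", n_stations=5)
        rule = TerminationRule.for_spec(dna_spec)
        t1 = run_trajectories(dna_spec, dna_grid, D, rule, 0.2e-9, 3, seed=42,
                              store_positions=True)
        t2 = run_trajectories(dna_spec, dna_grid, D, rule, 0.2e-9, 3, seed=42,
                              store_positions=True)
        for a, b in zip(t1, t2):
            assert a.termination == b.termination
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_translocations_slower_than_failures(self, dna_trajectories):
        dur = np.array([t.duration for t in dna_trajectories])
        term = np.array([t.termination for t in dna_trajectories])
        trans = dur[term == "translocated"]
        fail = dur[term == "escaped"]
        assert len(trans) >= 20 and len(fail) >= 5
        assert np.median(trans) > np.median(fail)

    def test_no_position_violates_clearance(self, dna_spec, dna_grid):
        from poresim.diffusivity import build_field
        D = build_field(dna_spec, 2.078, "combined_rz", n_stations=5)
        rule = TerminationRule.for_spec(dna_spec)
        trajs = run_trajectories(dna_spec, dna_grid, D, rule, 0.2e-9, 3,
                                 seed=7, store_positions=True, stride=5)
        for t in trajs:
            pts = t.positions
            # skip the final point, which may be the escape/exit proposal
            pts = pts[:-1]
            d, _, _ = wall_distance(
                dna_spec, np.stack([np.hypot(pts[:, 0], pts[:, 1]),
                                    pts[:, 2]], axis=-1))
            assert (d >= dna_grid.protein_radius - 1e-6).all()

    def test_current_trace_blockade_sign(self, dna_spec, dna_grid):
        from poresim.diffusivity import build_field
        D = build_field(dna_spec, 2.078, "combined_rz", n_stations=5)
        rule = TerminationRule.for_spec(dna_spec)
        trajs = run_trajectories(dna_spec, dna_grid, D, rule, 0.2e-9, 8,
                                 seed=21, store_positions=True, stride=2)
        tr = next(t for t in trajs if t.translocated)
        t, J = current_trace(tr, dna_grid)
        assert np.abs(J).min() < abs(dna_grid.I0)  # blockade during passage
        assert len(t) == len(J)

    def test_trace_requires_positions(self, dna_spec, dna_grid):
        from poresim.diffusivity import build_field
        D = build_field(dna_spec, 2.078, "combined_rz", n_stations=5)
        rule = TerminationRule.for_spec(dna_spec, max_steps=300)
        tr = run_trajectories(dna_spec, dna_grid, D, rule, 0.2e-9, 1, seed=3)[0]
        with pytest.raises(ValueError):
            current_trace(tr, dna_grid)

    def test_max_steps_flagged(self, dna_spec, dna_grid):
        from poresim.diffusivity import build_field
        D = build_field(dna_spec, 2.078, "combined_rz", n_stations=5)
        rule = TerminationRule.for_spec(dna_spec, max_steps=50)
        tr = run_trajectories(dna_spec, dna_grid, D, rule, 0.2e-9, 2, seed=9)
        assert all(t.termination == "max_steps" for t in tr)
        assert all(t.n_steps == 50 for t in tr)
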