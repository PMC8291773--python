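"""Stochastic adsorption: rates, durations, event assembly, resampling."""
import numpy as np
import pytest
from scipy.stats import kstest

from poresim.binding import (BindingEvent, BindingSite, adsorption_rate,
                             assemble_event, binding_duration, draw_bindings,
                             resample_events)
from poresim.constants import CONSTANTS, NM


def wall_site(**kw):
    defaults = dict(kind="wall_region", r_b=0.2, k_a=1e5, k_d=25e-3)
    defaults.update(kw)
    return BindingSite(**defaults)


class TestAdsorptionRate:
    def test_zero_association_rate(self):
        assert adsorption_rate(wall_site(k_a=0.0), 3.0) == 0.0

    def test_hand_evaluated_shell_volume(self):
        # solid-state receptor: shell between centre distances 3 and 5.75 nm
        site = BindingSite(kind="spherical_receptor", r_b=5.75, k_a=1.5e5,
                           k_d=25e-3, receptor=(8.0, -2.5), r_rec=0.0)
        V_b = 4 / 3 * np.pi * (5.75**3 - 3.0**3) * 1e-27  # m^3
        c_b = 1.0 / (1e3 * CONSTANTS.N_A * V_b)           # mol/L
        assert adsorption_rate(site, 3.0) == pytest.approx(1.5e5 * c_b, rel=1e-12)

    def test_doubling_volume_halves_rate(self):
        s1 = BindingSite(kind="spherical_receptor", r_b=5.75, k_a=1e5,
                         k_d=1.0, receptor=(0.0, 0.0))
        R1 = adsorption_rate(s1, 3.0)
        V1 = 5.75**3 - 27.0
        # choose r_b so the shell volume doubles
        r_b2 = (2 * V1 + 27.0) ** (1 / 3)
        s2 = BindingSite(kind="spherical_receptor", r_b=r_b2, k_a=1e5,
                         k_d=1.0, receptor=(0.0, 0.0))
        assert adsorption_rate(s2, 3.0) == pytest.approx(R1 / 2, rel=1e-9)

    def test_degenerate_zone_rejected(self):
        site = BindingSite(kind="spherical_receptor", r_b=2.0, k_a=1e5,
                           k_d=1.0, receptor=(0.0, 0.0), r_rec=0.5)
        with pytest.raises(ValueError):
            adsorption_rate(site, 3.0)


class TestDurations:
    def test_force_free_mean_is_inverse_kd(self):
        rng = np.random.default_rng(0)
        site = wall_site(k_d=25e-3)
        taus = binding_duration(site, np.zeros(100_000), CONSTANTS, rng)
        assert taus.mean() == pytest.approx(40.0, rel=0.01)

    def test_zero_force_identical_with_delta(self):
        site_a = wall_site(k_d=10.0, delta=0.0)
        site_b = wall_site(k_d=10.0, delta=0.55)
        ta = binding_duration(site_a, np.zeros(50_000), CONSTANTS,
                              np.random.default_rng(1))
        tb = binding_duration(site_b, np.zeros(50_000), CONSTANTS,
                              np.random.default_rng(1))
        np.testing.assert_allclose(ta, tb)

    def test_force_shortens_binding_by_bell_factor(self):
        site = wall_site(k_d=77.0, delta=0.55)
        rng = np.random.default_rng(2)
        means = []
        for F in (0.0, 2e-12, 5e-12):
            means.append(binding_duration(site, np.full(60_000, F),
                                          CONSTANTS, rng).mean())
        assert means[0] > means[1] > means[2]
        bell = np.exp(-5e-12 * 0.55 * NM / CONSTANTS.kT)
        assert means[2] / means[0] == pytest.approx(bell, rel=0.03)

    def test_ks_against_exponential(self):
        site = wall_site(k_d=50.0, delta=0.55)
        F = 3e-12
        rng = np.random.default_rng(3)
        taus = binding_duration(site, np.full(10_000, F), CONSTANTS, rng)
        mean = np.exp(-F * 0.55 * NM / CONSTANTS.kT) / 50.0
        assert kstest(taus, "expon", args=(0, mean)).pvalue > 0.01

    def test_permanent_binding_rejected(self):
        site = wall_site(k_d=0.0)
        with pytest.raises(ValueError):
            binding_duration(site, 0.0, CONSTANTS, np.random.default_rng(0))


class TestDrawBindings:
    def test_empty_records_no_events(self):
        site = wall_site()
        assert draw_bindings({"t": []}, site, 1e-9,
                             np.random.default_rng(0), 2.0) == []

    def test_poisson_mean(self):
        site = wall_site(k_a=5e7, k_d=100.0)
        R_a = adsorption_rate(site, 2.078)
        N, dt = 1000, 1e-9
        recs = {"t": np.arange(N) * dt, "F": np.zeros(N), "blockade": np.zeros(N)}
        rng = np.random.default_rng(4)
        reps = 1500
        total = sum(len(draw_bindings(recs, site, dt, rng, 2.078))
                    for _ in range(reps))
        lam = R_a * dt * N
        se = np.sqrt(lam / reps)
        assert abs(total / reps - lam) < 3 * se

    def test_probability_of_at_least_one_binding(self):
        site = wall_site(k_a=2e7, k_d=100.0)
        R_a = adsorption_rate(site, 2.078)
        N, dt = 400, 1e-9
        recs = {"t": np.arange(N) * dt, "F": np.zeros(N), "blockade": np.zeros(N)}
        rng = np.random.default_rng(5)
        reps = 2500
        hits = sum(bool(draw_bindings(recs, site, dt, rng, 2.078))
                   for _ in range(reps))
        p = 1 - np.exp(-R_a * N * dt)
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(hits / reps - p) < 3.5 * se

    def test_poisson_additivity_under_step_splitting(self):
        # the total binding probability is invariant when a step is split
        site = wall_site(k_a=3e7, k_d=100.0)
        R_a = adsorption_rate(site, 2.078)
        rng = np.random.default_rng(6)
        dt = 2e-9
        recs1 = {"t": np.array([0.0]), "F": np.zeros(1), "blockade": np.zeros(1)}
        recs2 = {"t": np.array([0.0, dt / 2]), "F": np.zeros(2),
                 "blockade": np.zeros(2)}
        reps = 3000
        h1 = sum(bool(draw_bindings(recs1, site, dt, rng, 2.078))
                 for _ in range(reps)) / reps
        h2 = sum(bool(draw_bindings(recs2, site, dt / 2, rng, 2.078))
                 for _ in range(reps)) / reps
        p = 1 - np.exp(-R_a * dt)
        se = np.sqrt(p * (1 - p) / reps)
        assert abs(h1 - h2) < 4 * se


class _FakeTraj:
    def __init__(self, duration, mean_blockade, recs, dt=1e-9):
        self.duration = duration
        self.mean_blockade = mean_blockade
        self.zone_records = recs
        self.dt = dt
        self.termination = "translocated"


class TestAssembleEvent:
    def test_no_bindings_duration_unchanged(self):
        tr = _FakeTraj(2e-6, 0.1, {})
        ev = assemble_event(tr, [])
        assert ev.tau_off == 2e-6
        assert ev.amplitude == pytest.approx(0.1)
        assert not ev.bound

    def test_long_binding_dominates_amplitude(self):
        tr = _FakeTraj(1e-6, 0.05, {})
        b = BindingEvent(step_time=0.0, duration=1.0, force=0.0, site=0,
                         blockade=0.3)
        ev = assemble_event(tr, [b])
        assert ev.amplitude == pytest.approx(0.3, rel=1e-4)

    def test_two_interval_weighted_average(self):
        # hand-computed: (2us*0.10 + 3us*0.40) / 5us = 0.28
        tr = _FakeTraj(2e-6, 0.10, {})
        b = BindingEvent(step_time=0.0, duration=3e-6, force=0.0, site=0,
                         blockade=0.40)
        ev = assemble_event(tr, [b])
        assert ev.tau_off == pytest.approx(5e-6)
        assert ev.amplitude == pytest.approx(0.28, rel=1e-12)


class TestResampleEvents:
    def _traj_pool(self, n_inzone=200, dt=1e-9):
        recs = {0: {"t": np.arange(n_inzone) * dt,
                    "x": np.zeros((n_inzone, 3)),
                    "F": np.zeros(n_inzone),
                    "blockade": np.full(n_inzone, 0.25)}}
        return [_FakeTraj(1e-6, 0.05, recs, dt)]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            resample_events([], [], 10, np.random.default_rng(0), 2.0)

    def test_no_binding_site_reproduces_base_records(self):
        pool = self._traj_pool()
        site = wall_site(k_a=0.0)
        evs = resample_events(pool, [site], 50, np.random.default_rng(1), 2.0)
        assert all(e.tau_off == 1e-6 and not e.bound for e in evs)

    def test_binding_fraction_matches_expectation(self):
        pool = self._traj_pool(n_inzone=500)
        site = wall_site(k_a=4e6, k_d=100.0)
        R_a = adsorption_rate(site, 2.0)
        p = 1 - np.exp(-R_a * 1e-9 * 500)
        n = 40_000
        evs = resample_events(pool, [site], n, np.random.default_rng(2), 2.0)
        frac = np.mean([e.bound for e in evs])
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3.5 * se

    def test_trajectory_shape_untouched_by_binding(self, dna_wall_trajectories):
        import hashlib
        trajs, sites = dna_wall_trajectories
        def digest():
            h = hashlib.sha256()
            for t in trajs:
                for s in sorted(t.zone_records):
                    h.update(np.ascontiguousarray(t.zone_records[s]["x"]).tobytes())
                h.update(np.float64(t.duration).tobytes())
            return h.hexdigest()
        before = digest()
        resample_events(trajs, sites, 500, np.random.default_rng(3), 2.078)
        assert digest() == before
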