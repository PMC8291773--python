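"""Hindered-diffusivity models and the numerical LRNH route."""
import numpy as np
import pytest

from poresim.constants import CONSTANTS, NM
from poresim.diffusivity import (build_field, bulk_diffusivity, channel_average,
                                 lrnh_tensor, plane_wall_factors)
from poresim.geometry import MeshOptions, build_preset, make_fixture, mesh


class TestBulk:
    def test_stokes_einstein_value(self):
        # kT/(6 pi eta a) evaluated by hand for the 0.11 nm ion radius
        D = bulk_diffusivity(CONSTANTS, 0.11)
        hand = CONSTANTS.k * 293.0 / (6 * np.pi * 1e-3 * 0.11e-9)
        assert D == pytest.approx(hand, rel=1e-12)
        assert D == pytest.approx(1.95e-9, rel=0.01)

    def test_inverse_radius_scaling(self):
        assert bulk_diffusivity(CONSTANTS, 2.0) == pytest.approx(
            bulk_diffusivity(CONSTANTS, 1.0) / 2.0)

    def test_trypsin_value(self):
        D = bulk_diffusivity(CONSTANTS, 2.078)
        assert D == pytest.approx(CONSTANTS.kT / (6 * np.pi * CONSTANTS.eta
                                                  * 2.078e-9), rel=1e-12)

    def test_nonpositive_radius(self):
        with pytest.raises(ValueError):
            bulk_diffusivity(CONSTANTS, 0.0)


class TestPlaneWallFactors:
    def test_far_field_limit(self):
        fp, fq = plane_wall_factors(1.0, 1e6)
        assert fp == pytest.approx(1.0, abs=1e-5)
        assert fq == pytest.approx(1.0, abs=1e-5)

    def test_perpendicular_below_parallel(self):
        h = np.linspace(1.01, 10.0, 200)
        fp, fq = plane_wall_factors(1.0, h)
        assert (fq < fp).all()

    def test_monotone_in_distance(self):
        h = np.linspace(1.01, 20.0, 300)
        fp, fq = plane_wall_factors(1.0, h)
        assert (np.diff(fp) >= 0).all()
        assert (np.diff(fq) >= 0).all()

    def test_inside_particle_rejected(self):
        with pytest.raises(ValueError):
            plane_wall_factors(1.0, 0.5)


class TestLrnh:
    def test_far_from_walls_recovers_bulk(self):
        a = 1.0
        box = make_fixture("open_box", radius=100.0, height=200.0)
        D = lrnh_tensor(box, a, 100.0, refine=False)
        D0 = bulk_diffusivity(CONSTANTS, a)
        np.testing.assert_allclose(np.diag(D), D0, rtol=0.05)
        # symmetric positive definite, off-diagonal free on the axis
        assert np.allclose(D, D.T)
        assert (np.linalg.eigvalsh(D) > 0).all()

    def test_wall_ordering_perpendicular_hindered_more(self):
        a = 1.0
        wall = make_fixture("plane_wall", radius=80.0, height=160.0)
        D = lrnh_tensor(wall, a, 1.5 * a, refine=False)
        # z is the wall normal here: D_zz (perpendicular) < D_xx (parallel)
        assert D[2, 2] < D[0, 0]

    def test_off_axis_rejected(self):
        box = make_fixture("open_box")
        with pytest.raises(ValueError):
            lrnh_tensor(box, 1.0, (3.0, 0.0, 150.0))

    def test_ion_hindrance_grows_toward_constriction(self):
        # alpha-hemolysin-like profile: relative diffusivity decreases as the
        # local bore narrows
        spec = build_preset("alpha_hemolysin")
        D0 = bulk_diffusivity(CONSTANTS, 0.11)
        wide = lrnh_tensor(spec, 0.11, -2.0, refine=False)    # vestibule
        narrow = lrnh_tensor(spec, 0.11, -8.0, refine=False)  # barrel
        assert narrow[2, 2] < wide[2, 2] < D0


@pytest.fixture(scope="module")
def dna():
    return build_preset("dna_origami")


class TestFields:

    def test_bulk_constant_is_identity(self, dna):
        f = build_field(dna, 0.11, "bulk_constant")
        Drr, Dzz = f.tensor_components(np.array([1.0]), np.array([-23.0]))
        assert Drr[0] == pytest.approx(f.D0)
        assert Dzz[0] == pytest.approx(f.D0)

    def test_reservoir_far_from_walls_is_bulk(self, dna):
        for model in ("r_dependent", "combined_rz", "z_dependent"):
            f = build_field(dna, 0.11, model, n_stations=5)
            D = f.tensor([0.0, 0.0, 11.0])  # ~11 nm above the pore mouth
            np.testing.assert_allclose(np.diag(D), f.D0, rtol=0.06)

    def test_tensor_spd_everywhere(self, dna):
        f = build_field(dna, 0.11, "combined_rz", n_stations=5)
        rng = np.random.default_rng(0)
        pts = np.stack([rng.uniform(-3, 3, 400), rng.uniform(-3, 3, 400),
                        rng.uniform(-50, 10, 400)], axis=-1)
        D = f.tensor(pts)
        assert np.allclose(D, np.transpose(D, (0, 2, 1)))
        ev = np.linalg.eigvalsh(D)
        assert (ev > 0).all()
        assert (ev <= f.D0 * (1 + 1e-9)).all()

    def test_combined_below_r_model_inside_channel(self, dna):
        fr = build_field(dna, 0.11, "r_dependent")
        fc = build_field(dna, 0.11, "combined_rz", n_stations=5)
        rng = np.random.default_rng(1)
        r = rng.uniform(0, 3.0, 200)
        z = rng.uniform(-44, -2, 200)
        _, Dz_r = fr.tensor_components(r, z)
        _, Dz_c = fc.tensor_components(r, z)
        assert (Dz_c <= Dz_r * (1 + 1e-9)).all()

    def test_combined_equals_z_model_on_centerline(self, dna):
        fz = build_field(dna, 0.11, "z_dependent", n_stations=5)
        fc = build_field(dna, 0.11, "combined_rz", n_stations=5)
        z = np.linspace(-40, -6, 9)
        _, Dz_z = fz.tensor_components(np.zeros_like(z), z)
        _, Dz_c = fc.tensor_components(np.zeros_like(z), z)
        np.testing.assert_allclose(Dz_c, Dz_z, rtol=1e-6)

    def test_combined_tracks_lrnh_in_dna_pore(self, dna):
        # wide pore: the normalized wall model stays close to direct LRNH
        # at interior on-axis points between sampling stations
        fc = build_field(dna, 0.11, "combined_rz", n_stations=5)
        D0 = fc.D0
        for z in (-16.5, -29.5):
            D_num = lrnh_tensor(dna, 0.11, z, refine=False)
            _, Dzz = fc.tensor_components(np.array([0.0]), np.array([z]))
            assert Dzz[0] == pytest.approx(D_num[2, 2], rel=0.10)

    def test_unknown_model(self, dna):
        with pytest.raises(ValueError):
            build_field(dna, 0.11, "quantum")


class TestChannelAverage:
    def test_uniform_weight_bulk_model(self):
        spec = make_fixture("toy_cylinder", radius=4.0, length=12.0,
                            reservoir_radius=10.0, reservoir_height=6.0)
        m = mesh(spec, MeshOptions(fine=0.5, coarse=2.0))
        f = build_field(spec, 0.11, "bulk_constant")
        avg = channel_average(f, lambda r, z: np.ones_like(r), m)
        assert avg == pytest.approx(1.0)

    def test_wall_concentrated_weight_reduces_average(self):
        spec = make_fixture("toy_cylinder", radius=4.0, length=12.0,
                            reservoir_radius=10.0, reservoir_height=6.0)
        m = mesh(spec, MeshOptions(fine=0.2, coarse=2.0))
        f = build_field(spec, 0.11, "r_dependent")
        uniform = channel_average(f, lambda r, z: np.ones_like(r), m)
        near_wall = channel_average(f, lambda r, z: np.exp((r - 4.0) / 0.2), m)
        assert near_wall < uniform

    def test_zero_weight_rejected(self):
        spec = make_fixture("toy_cylinder")
        m = mesh(spec, MeshOptions(fine=1.0, coarse=3.0))
        f = build_field(spec, 0.11, "bulk_constant")
        with pytest.raises(ValueError):
            channel_average(f, lambda r, z: np.zeros_like(r), m)
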