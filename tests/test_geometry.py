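"""Geometry: presets, wall distance, meshing."""
import numpy as np
import pytest

from poresim.geometry import (MeshOptions, PoreSpec, build_preset, graded_edges,
                              make_fixture, mesh, wall_distance)


class TestPresets:
    def test_dna_origami_dimensions(self):
        spec = build_preset("dna_origami")
        assert spec.channel_length == 46.0
        assert spec.wall_thickness == 6.0
        assert spec.nominal_width == 6.0
        # square-equivalent circle preserves the 36 nm^2 lumen area
        assert np.pi * spec.channel_radius(-23.0) ** 2 == pytest.approx(36.0)
        assert spec.wall_regions[0].sigma == -0.74

    def test_solid_state_cone(self):
        spec = build_preset("solid_state")
        assert spec.channel_radius(0.0) == pytest.approx(10.0)
        # aperture of 40 degrees -> wall slope of 20 degrees from the axis
        slope = (spec.channel_radius(-50.0) - spec.channel_radius(0.0)) / 50.0
        assert slope == pytest.approx(np.tan(np.deg2rad(20.0)))
        assert spec.wall_sigma(-25.0) == pytest.approx(-0.078)

    def test_alpha_hemolysin_radii_span(self):
        spec = build_preset("alpha_hemolysin")
        z = np.linspace(-10, 0, 200)
        r = spec.channel_radius(z)
        assert r.min() == pytest.approx(0.5, abs=0.1)
        assert r.max() == pytest.approx(2.8, abs=0.05)
        assert spec.membrane.center_z == -7.6
        assert spec.membrane.thickness == 2.2

    def test_override_width_circular(self):
        spec = build_preset("dna_origami", {"width": 4.9, "cross_section": "circular"})
        assert spec.channel_radius(-10.0) == pytest.approx(2.45)

    def test_unknown_preset_and_override(self):
        with pytest.raises(KeyError):
            build_preset("mystery_pore")
        with pytest.raises(KeyError):
            build_preset("dna_origami", {"colour": "blue"})

    def test_yaml_round_trip(self):
        spec = build_preset("dna_origami")
        back = PoreSpec.from_yaml(spec.to_yaml())
        assert back.channel_length == spec.channel_length
        assert back.wall_regions == spec.wall_regions
        np.testing.assert_allclose(back.channel_radius(-12.3),
                                   spec.channel_radius(-12.3))


class TestWallDistance:
    def test_axis_of_cylinder(self):
        spec = make_fixture("toy_cylinder", radius=5.0)
        d, nr, nz = wall_distance(spec, (0.0, -10.0))
        assert d == pytest.approx(5.0)
        assert nr == pytest.approx(-1.0)

    def test_point_on_wall(self):
        spec = make_fixture("toy_cylinder", radius=5.0)
        d, _, _ = wall_distance(spec, (5.0, -10.0))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_conical_pore_matches_brute_force(self):
        spec = build_preset("solid_state")
        rng = np.random.default_rng(0)
        # dense sampling of the inner wall surface as the oracle
        zs = np.linspace(-50, 0, 20001)
        wall_pts = np.stack([spec.channel_radius(zs), zs], axis=-1)
        for _ in range(20):
            z = rng.uniform(-45, -5)
            r = rng.uniform(0, spec.channel_radius(z) - 0.2)
            d, _, _ = wall_distance(spec, (r, z))
            brute = np.min(np.hypot(wall_pts[:, 0] - r, wall_pts[:, 1] - z))
            assert d == pytest.approx(brute, abs=1e-3)

    def test_lipschitz(self):
        spec = build_preset("dna_origami")
        rng = np.random.default_rng(1)
        pts = np.stack([rng.uniform(0, 10, 300), rng.uniform(-55, 10, 300)], axis=-1)
        d, _, _ = wall_distance(spec, pts)
        for _ in range(200):
            i, j = rng.integers(0, 300, 2)
            sep = np.hypot(*(pts[i] - pts[j]))
            assert abs(d[i] - d[j]) <= sep + 1e-9

    def test_protein_counts_as_wall(self):
        spec = build_preset("dna_origami")
        d0, _, _ = wall_distance(spec, (0.0, -23.0))
        dp, _, _ = wall_distance(spec, (0.0, -23.0), protein=(-20.0, 2.0))
        assert dp == pytest.approx(1.0)  # 3 nm to centre minus 2 nm radius
        assert d0 > dp


class TestMesh:
    def test_fluid_volume_toy(self):
        spec = make_fixture("toy_cylinder", radius=5.0, length=20.0,
                            reservoir_radius=30.0, reservoir_height=25.0)
        m = mesh(spec, MeshOptions(fine=0.5, coarse=2.0))
        analytic = np.pi * 25 * 20 + 2 * np.pi * 900 * 25
        assert m.fluid_volume() == pytest.approx(analytic, rel=0.01)

    def test_volume_converges_with_refinement(self):
        spec = make_fixture("toy_cylinder", radius=4.0, length=10.0,
                            reservoir_radius=12.0, reservoir_height=8.0)
        analytic = np.pi * 16 * 10 + 2 * np.pi * 144 * 8
        errs = []
        for fine in (1.0, 0.5, 0.25):
            m = mesh(spec, MeshOptions(fine=fine, coarse=2.0))
            errs.append(abs(m.fluid_volume() - analytic) / analytic)
        assert errs[-1] <= errs[0] + 1e-12
        assert errs[-1] < 0.01

    def test_deterministic(self):
        spec = build_preset("dna_origami")
        m1 = mesh(spec, MeshOptions(fine=0.3, coarse=2.0))
        m2 = mesh(spec, MeshOptions(fine=0.3, coarse=2.0))
        assert m1.shape == m2.shape
        np.testing.assert_array_equal(m1.region, m2.region)
        np.testing.assert_array_equal(m1.r_edges, m2.r_edges)

    def test_protein_cavity_tagged(self):
        spec = build_preset("dna_origami", {"width": 4.9, "cross_section": "circular"})
        m = mesh(spec, MeshOptions(fine=0.4, protein=0.15), protein=(-23.0, 2.078))
        assert (m.region == 3).sum() > 50

    def test_protein_in_wall_rejected(self):
        spec = build_preset("dna_origami")
        with pytest.raises(ValueError):
            mesh(spec, MeshOptions(fine=0.5), protein=(-23.0, 5.0))

    def test_charged_faces_tagged(self):
        spec = build_preset("dna_origami")
        m = mesh(spec, MeshOptions(fine=0.3, coarse=2.0, edl=0.1))
        assert (m.sigma_rface < 0).any()  # DNA wall carries negative charge

    def test_vtk_export(self, tmp_path):
        spec = make_fixture("toy_cylinder")
        m = mesh(spec, MeshOptions(fine=1.0, coarse=3.0))
        path = tmp_path / "mesh.vtk"
        m.export_vtk(str(path))
        head = path.read_text().splitlines()
        assert head[0].startswith("# vtk DataFile")


class TestGradedEdges:
    def test_required_edges_exact(self):
        e = graded_edges([0.0, 1.0, 5.0], [(1.0, 0.05)], coarse=1.0)
        for req in (0.0, 1.0, 5.0):
            assert np.min(np.abs(e - req)) < 1e-12

    def test_monotone_and_bounded(self):
        e = graded_edges([0.0, 10.0], [(3.0, 0.1), (2.0, 7.0, 0.2)], coarse=2.0)
        de = np.diff(e)
        assert (de > 0).all()
        assert de.min() >= 0.05
        # fine spacing realized near the point anchor
        i = np.argmin(np.abs(e - 3.0))
        assert de[max(i - 1, 0)] < 0.2
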