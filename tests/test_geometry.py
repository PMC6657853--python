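"""Cone geometry, structured meshes, and their analytic invariants."""

import math

import numpy as np
import pytest

import conesim as cs
from conesim import geometry as geo


class TestConeGeometry:
    def test_radius_profile(self, geom):
        assert geom.lateral_radius(0.0) == pytest.approx(3.08)   # larger base
        assert geom.lateral_radius(geom.H) == pytest.approx(1.15)  # tip
        assert geom.lateral_radius(0.5 * geom.H) == pytest.approx(
            0.5 * (1.15 + 3.08))

    def test_tip_origin_flips_profile(self, geom):
        import dataclasses
        g = dataclasses.replace(geom, z_origin="tip")
        assert g.lateral_radius(0.0) == pytest.approx(1.15)
        assert g.lateral_radius(g.H) == pytest.approx(3.08)

    def test_radius_domain(self, geom):
        with pytest.raises(ValueError):
            geom.lateral_radius(-0.1)
        with pytest.raises(ValueError):
            geom.lateral_radius(geom.H + 0.1)

    def test_aperture_angle(self, geom):
        assert geom.cos_gamma == pytest.approx(
            geom.H / math.hypot(geom.H, geom.r_base - geom.r_tip))

    def test_sliver_area_closed_form(self, geom):
        expected = 0.5 * geom.omega0 * (geom.r_tip + geom.r_base) * \
            math.hypot(geom.H, geom.r_base - geom.r_tip)
        assert geom.sliver_area() == pytest.approx(expected)

    def test_sliver_area_linear_in_omega(self, geom):
        import dataclasses
        g2 = dataclasses.replace(geom, omega0=geom.omega0 / 2)
        assert g2.sliver_area() == pytest.approx(geom.sliver_area() / 2)

    def test_cylinder_limit_area(self):
        # nearly-cylindrical full-circumference geometry: 2*pi*r*H
        g = cs.ConeGeometry(r_tip=1.9999999, r_base=2.0, H=10.0,
                            omega0=2 * math.pi)
        assert g.sliver_area() == pytest.approx(2 * math.pi * 2.0 * 10.0,
                                                rel=1e-6)
        assert g.volume == pytest.approx(math.pi * 4.0 * 10.0, rel=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError):
            cs.ConeGeometry(r_tip=3.0, r_base=2.0)
        with pytest.raises(ValueError):
            cs.ConeGeometry(omega0=0.0)


class TestVolumeFraction:
    def test_analytic(self, geom):
        assert cs.cytosol_volume_fraction(geom) == 0.5
        import dataclasses
        g = dataclasses.replace(geom, nu=1e9)
        assert cs.cytosol_volume_fraction(g) == pytest.approx(1.0)

    def test_measured_on_layered_mesh(self, geom):
        mesh = cs.build_nhom_mesh(geom, 10)
        frac = cs.cytosol_volume_fraction(mesh.geom, mesh)
        assert frac == pytest.approx(0.5, abs=1e-3)

    def test_second_order_in_eps(self, geom):
        errs = []
        for n in (10, 20, 40):
            mesh = cs.build_nhom_mesh(geom, n)
            errs.append(abs(cs.cytosol_volume_fraction(mesh.geom, mesh) - 0.5))
        # halving eps (doubling n) should shrink the error ~4x
        assert errs[1] < errs[0]
        assert errs[2] < errs[1]
        assert errs[0] / max(errs[2], 1e-16) > 8.0


class TestDiscMesh:
    def test_mirror_symmetry(self):
        disc = geo.build_disc_mesh(6, 16, math.pi)
        mir = disc.mirror
        assert np.all(mir[mir] == np.arange(disc.m))  # involution
        # mirror about the sliver mid-angle pi/2: theta -> pi - theta,
        # i.e. (x, y) -> (-x, y)
        refl = np.c_[-disc.nodes[:, 0], disc.nodes[:, 1]]
        assert np.allclose(refl, disc.nodes[mir], atol=1e-12)

    def test_area_convergence_second_order(self):
        errs = []
        for nr, na in ((4, 16), (8, 32), (16, 64)):
            disc = geo.build_disc_mesh(nr, na, math.pi)
            errs.append(abs(disc.lump.sum() - math.pi))
        assert errs[0] / errs[1] > 3.0
        assert errs[1] / errs[2] > 3.0

    def test_bad_resolution(self):
        with pytest.raises(geo.MeshResolutionError):
            geo.build_disc_mesh(6, 15, math.pi)  # no node at the arc edge


class TestHomMesh:
    def test_sliver_trace_compatibility(self, geom):
        mesh = cs.build_hom_mesh(geom, nr=5, na=12, n_z=8)
        sdof = mesh.sliver_global_dofs()
        assert len(np.unique(sdof)) == len(sdof)  # bijection on the strip
        m = mesh.disc.m
        for k in range(mesh.n_slices):
            lam = mesh.lambdas[k]
            for i, nid in enumerate(mesh.disc.sliver_arc):
                xy = mesh.disc.nodes[nid] * lam
                snode = mesh.sliver.nodes[k * mesh.sliver.ns + i]
                assert np.allclose(snode[:2], xy, atol=1e-12)
                assert snode[2] == pytest.approx(mesh.z_centers[k])

    def test_sliver_area_matches_frustum_strip(self, geom):
        mesh = cs.build_hom_mesh(geom, nr=5, na=24, n_z=40)
        assert mesh.sliver.area() == pytest.approx(geom.sliver_area(),
                                                   rel=0.01)

    def test_activation_level_errors(self, geom):
        with pytest.raises(geo.MeshResolutionError):
            cs.build_hom_mesh(geom, nr=5, na=12, n_z=8,
                              activation_levels=[0.0])


class TestLayeredMesh:
    def test_connectivity_through_sliver_only(self, geom):
        mesh = cs.build_nhom_mesh(geom, 10, nr=4, na=12)
        assert geo.element_graph_components(mesh, include_sliver=True) == 1
        assert geo.element_graph_components(mesh, include_sliver=False) == 10

    def test_minimal_two_chambers(self, geom):
        mesh = cs.build_nhom_mesh(geom, 2, nr=4, na=12)
        assert mesh.n_chambers == 2
        assert geo.element_graph_components(mesh, include_sliver=False) == 2

    def test_chamber_stack_fills_height(self, geom):
        mesh = cs.build_nhom_mesh(geom, 25)
        g = mesh.geom
        assert g.n_discs * (1 + g.nu) * g.eps0 == pytest.approx(g.H)

    def test_face_area_totals_against_quadrature(self, geom):
        # boundary-integral totals: lumped face areas vs closed-form disc areas
        mesh = cs.build_nhom_mesh(geom, 2, nr=8, na=32)
        for lev in range(mesh.n_levels):
            lam = mesh.lambdas[lev]
            measured = mesh.disc.lump.sum() * lam ** 2
            assert measured == pytest.approx(math.pi * lam ** 2, rel=0.01)

    def test_snap_to_face(self, geom):
        mesh = cs.build_nhom_mesh(geom, 10)
        c, lev, z = mesh.snap_to_disc_face(0.5 * geom.H)
        assert 0 <= c < 10
        assert abs(z - 0.5 * geom.H) <= (1 + geom.nu) * mesh.eps


def test_vtk_export_roundtrip_size(tmp_path, geom):
    mesh = cs.build_hom_mesh(geom, nr=4, na=12, n_z=6)
    path = tmp_path / "sliver.vtk"
    geo.write_vtk_surface(path, mesh.sliver.nodes, mesh.sliver.tris,
                          {"cg": np.ones(len(mesh.sliver.nodes))})
    text = path.read_text()
    assert text.startswith("# vtk DataFile")
    assert f"POINTS {len(mesh.sliver.nodes)}" in text
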