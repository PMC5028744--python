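"""Generator correctness: topology, labelling, symmetry, morphotype limits."""
import numpy as np
import pytest
from scipy.spatial import cKDTree

from conchmech import regions as R
from conchmech.geometry import (GeometryError, ShellParams, cap_sphere_radius,
                                generate_planispiral_shell, generate_septum_patch,
                                generate_sphere_midsurface, generate_sphere_shell,
                                preset)

from conftest import small_shell_params


class TestPlanispiralShell:
    def test_deterministic_bytes(self):
        a = generate_planispiral_shell(small_shell_params())
        b = generate_planispiral_shell(small_shell_params())
        assert a.vertices.tobytes() == b.vertices.tobytes()
        assert a.triangles.tobytes() == b.triangles.tobytes()
        assert (a.region_labels == b.region_labels).all()

    def test_zero_expansion_is_torus_like(self):
        p = small_shell_params(whorl_expansion_rate=0.0, whorl_count=0.9,
                               septum_count=3)
        m = generate_planispiral_shell(p)
        # all whorl-section centroids at constant distance from the z axis
        S = m.metadata["ring_segments"]
        n_rings = m.metadata["n_rings"]
        cent = m.vertices[: (n_rings + 1) * S].reshape(n_rings + 1, S, 3).mean(axis=1)
        d = np.linalg.norm(cent[:, :2], axis=1)
        assert np.allclose(d, d[0], rtol=1e-9)

    def test_bilateral_symmetry(self, small_shell_surface):
        v = small_shell_surface.vertices.copy()
        v[:, 2] *= -1
        d, _ = cKDTree(small_shell_surface.vertices).query(v)
        assert d.max() < 1e-9

    def test_orientation_consistent_nonmanifold_only_at_margins(self, small_shell_surface):
        audit = small_shell_surface.orientation_audit()
        assert audit["orientation_conflicts"] == 0
        p = small_shell_params()
        # junction (septum margin) edges are the only non-manifold ones
        assert audit["nonmanifold_edges"] == p.septum_count * p.ring_segments

    def test_labels_partition_and_cover(self, small_shell_surface):
        labs = set(small_shell_surface.region_labels.tolist())
        assert labs <= set(R.SURFACE_REGIONS)
        assert R.FINAL_SEPTUM_ADAPERTURAL in labs
        assert R.SUTURE_BAND in labs

    def test_margin_flute_sign_changes(self):
        p = small_shell_params(septum_type="anticlastic", flute_count=6,
                               flute_amplitude=0.2, ring_segments=40,
                               rings_per_whorl=64, cross_section_aspect=0.9)
        m = generate_planispiral_shell(p)
        S = m.metadata["ring_segments"]
        ring = m.metadata["station_rings"][-1]
        th = m.metadata["septum_angles"][-1]
        margin = m.vertices[ring * S:(ring + 1) * S]
        # radial deviation measured in each vertex's own section frame
        # (removes the spiral-direction suture wiggle from the signal)
        th_k = th + np.angle(np.exp(1j * (np.arctan2(margin[:, 1], margin[:, 0]) - th)))
        Rk = p.initial_radius * np.exp(p.whorl_expansion_rate * th_k)
        centres = np.stack([Rk * np.cos(th_k), Rk * np.sin(th_k),
                            np.zeros_like(Rk)], axis=1)
        r = np.linalg.norm(margin - centres, axis=1)
        dev = r - r.mean()
        changes = int((np.sign(dev) != np.roll(np.sign(dev), 1)).sum())
        assert changes == 12  # 2 sign changes per flute period

    def test_anticlastic_zero_amplitude_mirrors_synclastic(self):
        base = dict(septum_count=3, rings_per_whorl=40, ring_segments=16,
                    septum_rings=5)
        ps = small_shell_params(septum_type="synclastic", **base)
        pa = small_shell_params(septum_type="anticlastic", flute_count=4,
                                flute_amplitude=0.0, **base)
        ms = generate_planispiral_shell(ps)
        ma = generate_planispiral_shell(pa)
        # septum interior vertices are reflections through the station section
        for j, th in enumerate(ms.metadata["septum_angles"]):
            ids_s = ms.vertex_tags[f"septum_{j}"]
            ids_a = ma.vertex_tags[f"septum_{j}"]
            t_hat = np.array([-np.sin(th), np.cos(th), 0.0])
            c = (ms.vertices[ids_s] + ma.vertices[ids_a]) / 2.0
            # reflected points coincide: P_a = P_s - 2((P_s-c0)·t)t; equivalently
            # their midpoints lie in the section plane through the station
            d = (ms.vertices[ids_s] - ma.vertices[ids_a]) @ t_hat
            perp = (ms.vertices[ids_s] - ma.vertices[ids_a]) - np.outer(d, t_hat)
            assert np.abs(perp).max() < 1e-9

    def test_flute_monotone_area(self):
        areas = []
        for amp in (0.0, 0.1, 0.2, 0.3):
            p = small_shell_params(septum_type="anticlastic", flute_count=6,
                                   flute_amplitude=amp, ring_segments=40)
            m = generate_planispiral_shell(p)
            sel = np.isin(m.region_labels,
                          [R.FINAL_SEPTUM_ADAPERTURAL])
            areas.append(m.triangle_areas()[sel].sum())
        assert all(np.diff(areas) > 0)

    def test_septa_overlap_rejected(self):
        p = small_shell_params(septum_count=12, whorl_count=0.8,
                               body_chamber_fraction=0.3)
        with pytest.raises(GeometryError):
            generate_planispiral_shell(p)

    def test_oversized_foramen_rejected(self):
        p = small_shell_params(foramen_radius=5.0)
        with pytest.raises(GeometryError):
            generate_planispiral_shell(p)

    def test_invalid_params_rejected(self):
        with pytest.raises(GeometryError):
            small_shell_params(body_chamber_fraction=1.5).validate()
        with pytest.raises(GeometryError):
            small_shell_params(septum_type="anticlastic", flute_count=1).validate()
        with pytest.raises(GeometryError):
            small_shell_params(wall_thickness=-1).validate()


class TestSphereShell:
    def test_construction_radii_and_area(self):
        s = generate_sphere_shell(9.0, 10.0, 4)
        outer = s.submesh(s.region_labels == R.EXTERNAL_WALL)
        rr = np.linalg.norm(outer.vertices, axis=1)
        assert np.abs(rr - 10.0).max() < 1e-9
        assert abs(outer.area() / (4 * np.pi * 100.0) - 1) < 0.01

    def test_watertight_components(self):
        s = generate_sphere_shell(9.0, 10.0, 2)
        outer = s.submesh(s.region_labels == R.EXTERNAL_WALL)
        inner = s.submesh(s.region_labels == R.VALIDATION)
        assert outer.is_watertight() and inner.is_watertight()

    def test_rejections(self):
        with pytest.raises(GeometryError):
            generate_sphere_shell(10.0, 10.0, 3)
        with pytest.raises(GeometryError):
            generate_sphere_shell(9.0, 10.0, 0)
        with pytest.raises(GeometryError):
            generate_sphere_midsurface(5.0, 0)


class TestSeptumPatch:
    def test_boundary_loops(self):
        annulus = generate_septum_patch((5, 4), "synclastic", foramen_radius=0.8)
        disk = generate_septum_patch((5, 4), "synclastic", foramen_radius=0.0)
        assert annulus.boundary_loop_count() == 2
        assert disk.boundary_loop_count() == 1

    def test_flat_limit(self):
        flat = generate_septum_patch((5, 5), "domed", foramen_radius=0.5,
                                     cap_height=0.0)
        assert np.abs(flat.vertices[:, 2]).max() < 1e-12

    def test_syn_anti_mirror(self):
        ps = generate_septum_patch((5, 4), "synclastic", cap_height=2.0,
                                   foramen_radius=0.5)
        pa = generate_septum_patch((5, 4), "anticlastic", 4, 0.0, cap_height=2.0,
                                   foramen_radius=0.5)
        mirrored = ps.vertices.copy()
        mirrored[:, 2] *= -1
        assert np.abs(pa.vertices - mirrored).max() < 1e-9

    def test_flutes_ignored_for_cap_types(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            p = generate_septum_patch((5, 5), "domed", flute_count=6,
                                      flute_amplitude=0.2, foramen_radius=0.5)
        flat_equiv = generate_septum_patch((5, 5), "domed", foramen_radius=0.5)
        assert np.allclose(p.vertices, flat_equiv.vertices)

    def test_area_monotone_in_amplitude(self):
        areas = [generate_septum_patch((5, 4), "anticlastic", 6, a, 0.5).area()
                 for a in (0.0, 0.1, 0.2, 0.3)]
        assert all(np.diff(areas) > 0)

    def test_oversized_foramen_rejected(self):
        with pytest.raises(GeometryError):
            generate_septum_patch((5, 4), "domed", foramen_radius=2.5)


def test_presets_build():
    for name in ("spirula", "nautilus", "cadoceras5", "cadoceras10"):
        p = preset(name)
        p.validate()
    with pytest.raises(KeyError):
        preset("ammonite")
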