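"""Mesh morphometry: areas, volumes, S/V limits, junctions, fenestrations."""

import numpy as np
import pytest
import trimesh

from cristamorph.morphometry3d import (crista_density_3d, crista_metrics,
                                       detect_fenestrations,
                                       detect_junctions, mesh_area,
                                       mesh_genus, mesh_volume, sv_ratio)
from cristamorph.phantom import PhantomSpec, generate_phantom, phantom_solids
from cristamorph.segmentation import LabelVolume, extract_mesh, seal_mesh

from conftest import voxel_solid, mesh_of


def unit_cube():
    return trimesh.creation.box(extents=(1.0, 1.0, 1.0))


def icosphere(r=100.0):
    return trimesh.creation.icosphere(subdivisions=4, radius=r)


class TestAreaVolume:
    def test_unit_cube_area_and_volume(self):
        cube = unit_cube()
        assert len(cube.faces) == 12
        assert mesh_area(cube) * 1e6 == pytest.approx(6.0)
        assert mesh_volume(cube) * 1e9 == pytest.approx(1.0)

    def test_icosphere_closed_forms(self):
        s = icosphere(100.0)
        assert mesh_area(s) * 1e6 == pytest.approx(4 * np.pi * 100 ** 2,
                                                   rel=0.01)
        assert mesh_area(s) * 1e6 == pytest.approx(1.2566e5, rel=0.01)
        assert mesh_volume(s) * 1e9 == pytest.approx(
            4 / 3 * np.pi * 100 ** 3, rel=0.015)

    def test_translation_invariance(self):
        s = icosphere(50.0)
        a0 = mesh_area(s)
        s.apply_translation([123.0, -77.0, 1000.0])
        assert mesh_area(s) == pytest.approx(a0, rel=1e-12)

    def test_flipped_orientation_abs_volume_with_warning(self, caplog):
        cube = unit_cube()
        cube.invert()
        with caplog.at_level("WARNING"):
            v = mesh_volume(cube)
        assert v * 1e9 == pytest.approx(1.0)
        assert "orientation" in caplog.text

    def test_open_mesh_volume_rejected(self):
        mask = voxel_solid((31, 20, 20),
                           lambda z, y, x: (y - 9.5) ** 2 + (x - 9.5) ** 2
                           <= 36)
        open_mesh = mesh_of(mask)
        with pytest.raises(ValueError, match="seal"):
            mesh_volume(open_mesh)


class TestSVRatio:
    def test_sphere_sv_is_3_over_r(self):
        s = icosphere(150.0)
        assert sv_ratio(s) == pytest.approx(3 / 150.0 * 1000.0, rel=0.02)

    def _sealed_slab_solid(self, mask, voxel=1.0):
        mesh = mesh_of(mask, voxel)
        nz = mask.shape[0]
        return seal_mesh(mesh, (0.0, (nz - 1) * voxel))

    def test_long_cylinder_native_sv_tends_to_4_over_d(self):
        # D = 20 nm tube spanning a 1000 nm slab: native (lateral) S/V
        # approaches 4/D = 200 um^-1
        mask = voxel_solid((1001, 33, 33), lambda z, y, x:
                           (y - 16.2) ** 2 + (x - 16.2) ** 2 <= 10.0 ** 2)
        sealed = self._sealed_slab_solid(mask)
        assert sv_ratio(sealed) == pytest.approx(200.0, rel=0.05)

    def test_plate_native_sv_tends_to_2_over_d(self):
        # plate compartment, 20 nm wall separation, 450 nm faces: S/V ->
        # 2/D = 100 um^-1
        mask = np.zeros((451, 44, 471), dtype=bool)
        mask[:, 12:32, 10:460] = True
        sealed = self._sealed_slab_solid(mask)
        assert sv_ratio(sealed) == pytest.approx(100.0, rel=0.10)

    @pytest.mark.parametrize("d_nm", [20.0, 50.0, 80.0])
    def test_cylinder_always_above_plate_at_equal_d(self, d_nm):
        r = d_nm / 2
        n = int(2 * r + 14)
        mask = voxel_solid((301, n, n), lambda z, y, x:
                           (y - n / 2 + 0.3) ** 2 + (x - n / 2 + 0.3) ** 2
                           <= r ** 2)
        cyl = self._sealed_slab_solid(mask)
        w = int(d_nm)
        plate = np.zeros((301, w + 24, 321), dtype=bool)
        plate[:, 12:12 + w, 10:310] = True
        pl = self._sealed_slab_solid(plate)
        assert sv_ratio(cyl) > sv_ratio(pl)

    def test_isotropic_scaling_property(self):
        s = icosphere(80.0)
        base_a, base_v, base_sv = mesh_area(s), mesh_volume(s), sv_ratio(s)
        s2 = s.copy()
        s2.apply_scale(2.0)
        assert mesh_area(s2) == pytest.approx(4 * base_a, rel=1e-9)
        assert mesh_volume(s2) == pytest.approx(8 * base_v, rel=1e-9)
        assert sv_ratio(s2) == pytest.approx(base_sv / 2, rel=1e-9)


def _ibm_cylinder_mesh(shape, voxel, radius_nm):
    nz, ny, nx = shape
    cy, cx = (ny - 1) / 2 * voxel, (nx - 1) / 2 * voxel
    yy, xx = np.meshgrid(np.arange(ny) * voxel, np.arange(nx) * voxel,
                         indexing="ij")
    inner = np.hypot(yy - cy, xx - cx) <= radius_nm
    mask = np.broadcast_to(inner, shape).astype(np.uint8)
    (_k, mesh), = extract_mesh(LabelVolume(mask, voxel))
    return mesh


def _junction_setup(neck_params, seed=4):
    spec = PhantomSpec(
        morphology_class="lamellar", voxel_size=2.0,
        slab_thickness_nm=150.0, envelope_semi_axes=(240.0, 240.0),
        seed=seed,
        crista_params={"n_plates": 1, "junction_necks": True, **neck_params})
    _, _, truth = generate_phantom(spec, render_volume=False)
    solids = phantom_solids(spec)
    (_k, mesh), = extract_mesh(LabelVolume(solids.crista_labels,
                                           solids.voxel_size))
    ibm = _ibm_cylinder_mesh(solids.crista_labels.shape, 2.0, 225.0)
    return truth, mesh, ibm


class TestJunctions:
    def test_two_round_necks_detected_and_sized(self):
        truth, mesh, ibm = _junction_setup(
            {"junction_neck_diameter_nm": (30.0, 30.0)})
        assert truth.cristae[0]["n_junctions"] == 2
        js = detect_junctions(mesh, ibm, contact_tol=10.0)
        assert len(js) == 2
        for j in js:
            assert j.shape == "round"
            assert j.size_nm == pytest.approx(30.0, abs=5.0)

    def test_slot_opening_classified_slot(self):
        truth, mesh, ibm = _junction_setup({"junction_neck_shape": "slot"})
        js = detect_junctions(mesh, ibm, contact_tol=10.0)
        assert len(js) == 2
        for j in js:
            assert j.shape == "slot"
            assert j.size_nm == pytest.approx(70.0, abs=7.0)

    def test_detached_vesicle_has_no_junctions(self):
        vesicle = icosphere(40.0)
        vesicle.apply_translation([200.0, 250.0, 250.0])
        ibm = _ibm_cylinder_mesh((76, 201, 201), 2.0, 180.0)
        assert detect_junctions(vesicle, ibm, contact_tol=10.0) == []

    def test_missing_ibm_rejected(self):
        with pytest.raises(ValueError, match="IBM"):
            detect_junctions(icosphere(30.0), None)


def _fenestrated_plate(diams, seed=2):
    spec = PhantomSpec(
        morphology_class="lamellar", voxel_size=2.0,
        slab_thickness_nm=250.0, envelope_semi_axes=(300.0, 300.0),
        seed=seed,
        crista_params={"n_plates": 1, "n_fenestrations_per_plate": len(diams),
                       "fenestration_diameter_range_nm":
                           (min(diams, default=20.0),
                            max(diams, default=80.0))})
    solids = phantom_solids(spec)
    (_k, mesh), = extract_mesh(LabelVolume(solids.crista_labels,
                                           solids.voxel_size))
    nz = solids.crista_labels.shape[0]
    _, _, truth = generate_phantom(spec, render_volume=False)
    return truth, seal_mesh(mesh, (0.0, (nz - 1) * 2.0))


class TestFenestrations:
    def test_three_40nm_holes(self):
        truth, sealed = _fenestrated_plate([40.0, 40.0])
        # generator samples within the range; use the truth widths
        gt_widths = sorted(truth.cristae[0]["fen_widths_nm"], reverse=True)
        widths, mean, genus = detect_fenestrations(sealed)
        assert genus == len(gt_widths) == len(widths)
        for w, gw in zip(widths, gt_widths):
            assert w == pytest.approx(gw, rel=0.10)
        assert mean == pytest.approx(np.mean(gt_widths), rel=0.10)

    def test_intact_plate_no_holes_genus_zero(self):
        truth, sealed = _fenestrated_plate([])
        widths, mean, genus = detect_fenestrations(sealed)
        assert widths == [] and genus == 0 and mean == 0.0

    def test_open_mesh_rejected(self):
        mask = voxel_solid((31, 20, 20), lambda z, y, x:
                           (y - 9.5) ** 2 + (x - 9.5) ** 2 <= 36)
        with pytest.raises(ValueError, match="sealed"):
            detect_fenestrations(mesh_of(mask))

    def test_genus_equals_hole_count_euler_oracle(self):
        truth, sealed = _fenestrated_plate([30.0, 60.0], seed=5)
        widths, _mean, genus = detect_fenestrations(sealed)
        # brute-force Euler characteristic: chi = V - E + F = 2 - 2g
        chi = (len(sealed.vertices) - len(sealed.edges_unique)
               + len(sealed.faces))
        assert chi == 2 - 2 * genus
        assert genus == truth.cristae[0]["n_fenestrations"] == len(widths)


class TestDensity3D:
    def test_no_cristae_zero_and_doubling_doubles(self):
        env = icosphere(200.0)
        assert crista_density_3d([], env) == 0.0
        c = icosphere(50.0)
        one = crista_density_3d([c], env)
        two = crista_density_3d([c, c.copy()], env)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_analytic_ratio(self):
        env = icosphere(200.0)
        c = icosphere(60.0)
        expect = (4 * np.pi * 60 ** 2) / (4 / 3 * np.pi * 200 ** 3) * 1000.0
        assert crista_density_3d([c], env) == pytest.approx(expect, rel=0.03)


class TestCristaMetricsRecord:
    def test_record_assembly(self):
        truth, sealed = _fenestrated_plate([40.0, 40.0], seed=7)
        rec = crista_metrics(1, sealed)
        assert rec.S_native_um2 > 0 and rec.V_um3 > 0
        assert rec.sv_um == pytest.approx(rec.S_native_um2 / rec.V_um3)
        assert rec.v_per_cj_um3 is None          # no junction info supplied
        assert rec.genus == truth.cristae[0]["n_fenestrations"]
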