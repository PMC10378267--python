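"""Phantom generator: determinism, closed-form geometry, corruption model."""

import numpy as np
import pytest

from cristamorph.morphometry2d import profile_metrics
from cristamorph.phantom import (PhantomSpec, corrupt, generate_phantom,
                                 phantom_solids)
from cristamorph.segmentation import LabelVolume, extract_mesh, seal_mesh
from cristamorph.morphometry3d import mesh_area
from cristamorph.volume import Volume

from conftest import small_spec


class TestSpecValidation:
    def test_rejects_bad_class_and_nonpositive_geometry(self):
        with pytest.raises(ValueError, match="morphology"):
            PhantomSpec(morphology_class="spiral")
        with pytest.raises(ValueError, match="positive"):
            PhantomSpec(voxel_size=-1.0)

    def test_rejects_out_of_range_dimensions(self):
        with pytest.raises(ValueError, match="50-90"):
            PhantomSpec(morphology_class="tubular",
                        crista_params={"diameter_range_nm": (30.0, 90.0)})
        with pytest.raises(ValueError, match="20-80"):
            PhantomSpec(morphology_class="lamellar",
                        crista_params={
                            "fenestration_diameter_range_nm": (10.0, 80.0)})

    def test_rejects_envelope_too_small_for_plates(self):
        with pytest.raises(ValueError, match="too small"):
            PhantomSpec(morphology_class="lamellar",
                        envelope_semi_axes=(60.0, 60.0),
                        crista_params={"n_plates": 10})

    def test_subvoxel_membrane_warns(self):
        with pytest.warns(UserWarning, match="sub-voxel"):
            PhantomSpec(voxel_size=8.0, membrane_thickness_nm=6.0)


class TestDeterminism:
    def test_same_spec_same_seed_bit_identical(self):
        a = generate_phantom(small_spec("tubular", seed=9))
        b = generate_phantom(small_spec("tubular", seed=9))
        np.testing.assert_array_equal(a[0].data, b[0].data)
        assert a[2].crista_density_2d_um == b[2].crista_density_2d_um

    def test_different_seed_differs(self):
        a = generate_phantom(small_spec("tubular", seed=9),
                             render_volume=False)
        b = generate_phantom(small_spec("tubular", seed=10),
                             render_volume=False)
        assert a[2].crista_density_2d_um != b[2].crista_density_2d_um


class TestGroundTruthGeometry:
    def test_single_plate_area_matches_planar_geometry(self):
        # one unfenestrated plate: native midsurface = 2 faces + 2 end rims
        spec = small_spec("lamellar", seed=0,
                          crista_params={"n_plates": 1})
        _, _, truth = generate_phantom(spec, render_volume=False)
        c = truth.cristae[0]
        h = spec.slab_thickness_nm
        sep = spec.crista_params["separation_nm"]
        # infer the plate length back from the volume and check the area form
        length = c["V_nm3"] / (sep * h)
        expected = 2 * length * h + 2 * sep * h
        assert c["S_native_nm2"] == pytest.approx(expected, rel=1e-9)

    def test_straight_tube_lateral_area_is_pi_d_l(self):
        # capsule ground truth: pi*D*L lateral + sphere caps
        from cristamorph.phantom import _Tube, _tube_truth
        cl = np.array([[100.0, 200.0, 100.0], [100.0, 200.0, 1100.0]])
        rec = _tube_truth(_Tube(cl, 80.0))
        lateral = rec["S_native_nm2"] - np.pi * 80.0 ** 2
        assert lateral == pytest.approx(np.pi * 80.0 * 1000.0, rel=1e-12)
        assert lateral == pytest.approx(2.513e5, rel=1e-3)

    @staticmethod
    def _fenestrated_spec():
        return PhantomSpec(
            morphology_class="lamellar", voxel_size=1.25,
            slab_thickness_nm=150.0, envelope_semi_axes=(220.0, 220.0),
            seed=2, crista_params={"n_plates": 1,
                                   "n_fenestrations_per_plate": 3,
                                   "fenestration_diameter_range_nm":
                                       (40.0, 60.0)})

    def test_fenestrated_plate_area_formula_vs_dense_integration(self):
        # hole accounting (base - 2 disk areas + pi*d*w rims) against a
        # dense numerical surface integration: marching cubes run directly
        # on the *analytic* signed distance field at 1 nm sampling, with the
        # slab-cap faces excluded geometrically
        from skimage import measure as skmeasure
        from cristamorph.phantom import _build_geometry, _plate_sdf
        spec = self._fenestrated_spec()
        _, _, truth = generate_phantom(spec, render_volume=False)
        c = truth.cristae[0]
        assert len(c["fen_widths_nm"]) == 3
        geo = _build_geometry(spec, np.random.default_rng(spec.seed))
        plate = geo.plates[0]
        h = spec.slab_thickness_nm
        res = 1.0
        z = np.arange(-2, h + 3, res)[:, None, None]
        y = np.arange(plate.yc - 25, plate.yc + 25, res)[None, :, None]
        x = np.arange(plate.x0 - 10, plate.x1 + 10, res)[None, None, :]
        field = _plate_sdf(plate, z, y, x, h)
        verts, faces, _n, _v = skmeasure.marching_cubes(field, 0.0,
                                                        spacing=(res,) * 3)
        tri = verts[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        zc = tri[:, :, 0].mean(axis=1) - 2  # grid starts at z = -2
        normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nz_frac = np.abs(normals[:, 0]) / np.maximum(
            np.linalg.norm(normals, axis=1), 1e-12)
        caps = ((np.abs(zc) < res) | (np.abs(zc - h) < res)) & (nz_frac > 0.9)
        native = areas[~caps].sum()
        assert native == pytest.approx(c["S_native_nm2"], rel=0.01)

    def test_rendered_solid_mesh_matches_truth(self):
        # the production route (voxel rendering -> EDT distance field ->
        # marching cubes -> sealing) reproduces the closed-form area within
        # discretization tolerance
        spec = self._fenestrated_spec()
        _, _, truth = generate_phantom(spec, render_volume=False)
        c = truth.cristae[0]
        solids = phantom_solids(spec)
        lv = LabelVolume(solids.crista_labels, solids.voxel_size)
        (_k, mesh), = extract_mesh(lv)
        nz = solids.crista_labels.shape[0]
        sealed = seal_mesh(mesh, (0.0, (nz - 1) * solids.voxel_size))
        assert mesh_area(sealed, caps="exclude") * 1e6 == pytest.approx(
            c["S_native_nm2"], rel=0.02)
        from cristamorph.morphometry3d import mesh_volume
        assert mesh_volume(sealed) * 1e9 == pytest.approx(c["V_nm3"],
                                                          rel=0.03)

    def test_contours_reproduce_truth_densities(self, lamellar_phantom):
        spec, _vol, cset, truth = lamellar_phantom
        m = profile_metrics(cset)
        assert m.crista_density == pytest.approx(
            truth.crista_density_2d_um, rel=0.02)
        assert m.A_MIT * 1e6 == pytest.approx(truth.A_MIT_nm2, rel=0.01)

    @pytest.mark.parametrize("morphology", ["tubular", "transitional",
                                            "mixed"])
    def test_contour_lengths_consistent_across_classes(self, morphology):
        spec = small_spec(morphology, seed=6)
        _, cset, truth = generate_phantom(spec, render_volume=False)
        m = profile_metrics(cset)
        assert m.crista_density == pytest.approx(
            truth.crista_density_2d_um, rel=0.02)


class TestCorrupt:
    def test_zero_sigmas_identity(self, lamellar_phantom):
        _, vol, _, _ = lamellar_phantom
        out = corrupt(vol, 0.0, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_seeded_noise_reproducible(self, lamellar_phantom):
        _, vol, _, _ = lamellar_phantom
        a = corrupt(vol, 0.3, 2.0, seed=7)
        b = corrupt(vol, 0.3, 2.0, seed=7)
        np.testing.assert_array_equal(a.data, b.data)
        c = corrupt(vol, 0.3, 2.0, seed=8)
        assert not np.array_equal(a.data, c.data)

    def test_blur_conserves_mass_of_interior_impulse(self):
        data = np.zeros((41, 41, 41), dtype=np.float32)
        data[20, 20, 20] = 1.0
        out = corrupt(Volume(data, 2.0), 0.0, 4.0, seed=0)
        assert float(out.data.sum()) == pytest.approx(1.0, rel=1e-6)

    def test_negative_sigma_rejected(self, lamellar_phantom):
        _, vol, _, _ = lamellar_phantom
        with pytest.raises(ValueError):
            corrupt(vol, -0.1, 0.0, seed=0)
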