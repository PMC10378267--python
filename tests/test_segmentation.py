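"""Thresholding, components, marching-cubes meshing and slab sealing."""

import numpy as np
import pytest

from cristamorph.morphometry3d import mesh_area, mesh_genus, mesh_volume
from cristamorph.phantom import PhantomSpec, phantom_solids
from cristamorph.segmentation import (LabelVolume, binarize, components,
                                      extract_mesh, partition_mitochondrion,
                                      seal_mesh, cap_face_mask)
from cristamorph.volume import Volume

from conftest import voxel_solid, mesh_of


class TestBinarize:
    def test_otsu_separates_bimodal_mixture(self, rng):
        # two Gaussians: background N(0.2, 0.05), foreground N(0.8, 0.05)
        # with mixture weight 0.3 -> foreground fraction ~0.3
        w = 0.3
        n = 40 * 40 * 40
        is_fg = rng.uniform(size=n) < w
        vals = np.where(is_fg, rng.normal(0.8, 0.05, n),
                        rng.normal(0.2, 0.05, n))
        vol = Volume(vals.reshape(40, 40, 40).astype(np.float32), 2.0)
        out = binarize(vol, "otsu")
        assert 0.2 < out.threshold < 0.8
        assert out.foreground_fraction() == pytest.approx(w, abs=0.02)

    def test_fixed_above_max_errors_with_histogram(self, rng):
        vol = Volume(rng.uniform(size=(8, 8, 8)).astype(np.float32), 2.0)
        with pytest.raises(ValueError, match="quartiles"):
            binarize(vol, "fixed", threshold=5.0)
        with pytest.raises(ValueError, match="requires a threshold"):
            binarize(vol, "fixed")

    def test_phantom_membrane_contained_in_foreground(self):
        spec = PhantomSpec(morphology_class="lamellar", voxel_size=2.5,
                           slab_thickness_nm=100.0,
                           envelope_semi_axes=(150.0, 150.0), seed=1,
                           crista_params={"n_plates": 2})
        solids = phantom_solids(spec)
        vol = Volume(solids.membrane, 2.5)
        out = binarize(vol, "fixed", threshold=0.5)
        mid = solids.membrane > 0.95       # membrane midsurface voxels
        assert np.all(out.data[mid] > 0)


class TestComponents:
    def test_two_disjoint_balls(self):
        mask = voxel_solid((40, 40, 80), lambda z, y, x:
                           ((z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2
                            <= 64)
                           | ((z - 20) ** 2 + (y - 20) ** 2 + (x - 60) ** 2
                              <= 225))
        out = components(LabelVolume(mask.astype(np.uint8), 1.0))
        assert out.n_labels == 2
        # labels ordered by size: label 1 is the bigger ball
        assert (out.data == 1).sum() > (out.data == 2).sum()

    def test_min_size_removes_specks(self):
        mask = np.zeros((10, 10, 10), dtype=np.uint8)
        mask[5, 5, 5] = 1
        out = components(LabelVolume(mask, 1.0), min_size=2)
        assert out.n_labels == 0

    def test_lamellar_phantom_plate_count(self):
        spec = PhantomSpec(morphology_class="lamellar", voxel_size=2.5,
                           slab_thickness_nm=100.0,
                           envelope_semi_axes=(200.0, 200.0), seed=3,
                           crista_params={"n_plates": 5})
        solids = phantom_solids(spec)
        out = components(LabelVolume((solids.crista_labels > 0
                                      ).astype(np.uint8), 2.5), min_size=50)
        assert out.n_labels == 5


class TestExtractMesh:
    def test_ball_watertight_genus0_area(self, ball_mesh):
        assert ball_mesh.is_watertight
        assert mesh_genus(ball_mesh) == 0
        assert mesh_area(ball_mesh) * 1e6 == pytest.approx(
            4 * np.pi * 30 ** 2, rel=0.03)

    def test_torus_has_genus_one(self):
        # Euler characteristic V - E + F = 0 for a torus
        mask = voxel_solid((41, 81, 81), lambda z, y, x: (
            (np.sqrt((y - 40.0) ** 2 + (x - 40.0) ** 2) - 22) ** 2
            + (z - 20.0) ** 2 <= 8 ** 2))
        mesh = mesh_of(mask)
        assert mesh.is_watertight
        assert mesh.euler_number == 0
        assert mesh_genus(mesh) == 1

    def test_empty_labels_error(self):
        with pytest.raises(ValueError, match="no surface"):
            extract_mesh(LabelVolume(np.zeros((5, 5, 5), dtype=np.uint8),
                                     1.0))


class TestSealMesh:
    def _open_cylinder(self, r=15.0, nz=61):
        mask = voxel_solid((nz, 40, 40), lambda z, y, x:
                           (y - 19.5) ** 2 + (x - 19.5) ** 2 <= r ** 2)
        return mesh_of(mask), nz

    def test_open_cylinder_sealed_volume(self):
        mesh, nz = self._open_cylinder()
        assert not mesh.is_watertight
        sealed = seal_mesh(mesh, (0.0, float(nz - 1)))
        assert sealed.is_watertight
        v = mesh_volume(sealed) * 1e9
        assert v == pytest.approx(np.pi * 15 ** 2 * (nz - 1), rel=0.03)

    def test_watertight_mesh_unchanged(self, ball_mesh):
        sealed = seal_mesh(ball_mesh, (0.0, 80.0))
        assert sealed is ball_mesh

    def test_caps_tagged_and_area_split(self):
        mesh, nz = self._open_cylinder()
        native_before = mesh_area(mesh, caps="exclude")
        sealed = seal_mesh(mesh, (0.0, float(nz - 1)))
        cap = cap_face_mask(sealed)
        assert cap.sum() > 0
        # sealing adds area but never changes native triangles
        assert (~cap).sum() == len(mesh.faces)
        assert mesh_area(sealed, caps="exclude") == pytest.approx(
            native_before, rel=1e-9)
        # cap area ~ 2 disk cross-sections
        assert mesh_area(sealed, caps="only") * 1e6 == pytest.approx(
            2 * np.pi * 15 ** 2, rel=0.05)

    def test_loop_not_at_slab_face_left_open(self):
        mesh, nz = self._open_cylinder()
        with pytest.warns(UserWarning, match="left open"):
            sealed = seal_mesh(mesh, (-500.0, -400.0))
        assert not sealed.is_watertight


class TestMeshConvergence:
    def test_area_and_volume_error_shrink_with_voxel_refinement(self):
        # fixed smooth solid (ball radius 24 nm), voxel 3 -> 1.5 nm
        r = 24.0
        errs = []
        for voxel in (6.0, 1.5):
            n = int(2 * (r + 4 * voxel) / voxel)
            c = (n - 1) / 2 * voxel + 0.31 * voxel   # off-lattice centre
            zz, yy, xx = np.meshgrid(*(np.arange(n) * voxel,) * 3,
                                     indexing="ij")
            mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r ** 2
            mesh = mesh_of(mask, voxel)
            a_err = abs(mesh_area(mesh) * 1e6 / (4 * np.pi * r ** 2) - 1)
            v_err = abs(mesh_volume(mesh) * 1e9 / (4 / 3 * np.pi * r ** 3)
                        - 1)
            errs.append((a_err, v_err))
        assert errs[1][0] < errs[0][0]
        assert errs[1][1] < errs[0][1]
        assert errs[1][0] < 0.01 and errs[1][1] < 0.01


class TestPartition:
    def test_phantom_membranes_partition_into_compartments(self):
        spec = PhantomSpec(morphology_class="lamellar", voxel_size=2.5,
                           slab_thickness_nm=100.0,
                           envelope_semi_axes=(200.0, 200.0), seed=3,
                           crista_params={"n_plates": 4})
        solids = phantom_solids(spec)
        lv = LabelVolume((solids.membrane > 0.5).astype(np.uint8), 2.5)
        part = partition_mitochondrion(lv, membrane_thickness_nm=6.0)
        assert int(part.crista_solids.max()) == 4
        # recovered envelope masks overlap the rendered ones
        assert (part.om_mask & solids.om_shell).sum() \
            > 0.9 * solids.om_shell.sum()
        assert (part.ibm_mask & solids.ibm_shell).sum() \
            > 0.9 * solids.ibm_shell.sum()
        # IBM interior volume ~ pi a b h
        v = part.ibm_interior.sum() * 2.5 ** 3
        a, b = spec.ibm_semi_axes
        assert v == pytest.approx(np.pi * a * b * 100.0, rel=0.05)

    def test_unenclosed_mask_rejected(self):
        lv = LabelVolume(np.zeros((10, 10, 10), dtype=np.uint8), 1.0)
        with pytest.raises(ValueError, match="enclose"):
            partition_mitochondrion(lv)
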