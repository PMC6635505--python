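"""Segmentation, alignment, coarsening, BV/TV mapping, meshing, lesions."""

import warnings

import numpy as np
import pytest

from femvox.calib import DensityImage
from femvox.geometry import Landmarks, angle_between_deg
from femvox.mesh import (BoneMask, EmbeddingConfig, LesionSpec, MeshError,
                         SegmentationError, align_one_legged_stance,
                         bmd_to_bvtv, build_hex_mesh, coarsen, insert_lesion,
                         segment_bone, wedge_angle_deg, write_text_mesh,
                         write_vtu)


def bmd_image(values, spacing=(1.0, 1.0, 1.0)):
    return DensityImage(values=np.asarray(values, dtype=float),
                        spacing=spacing, unit="mgHA_cm3")


class TestSegmentBone:
    def test_solid_cube(self):
        v = np.zeros((10, 10, 10))
        v[2:8, 2:8, 2:8] = 500.0
        m = segment_bone(bmd_image(v), 100.0)
        assert np.array_equal(m.mask, v >= 100.0)

    def test_hollow_capped_tube_lumen_included(self):
        # dense-walled capped tube along z: the enclosed marrow cavity is not
        # reachable from the border without crossing bone, so it stays inside
        v = np.zeros((20, 20, 20))
        x, y = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        r = np.hypot(x - 9.5, y - 9.5)
        wall = (r >= 4) & (r <= 7)
        lumen = r < 4
        v[:, :, 2:18][wall] = 800.0
        v[:, :, 2][r <= 7] = 800.0   # caps
        v[:, :, 17][r <= 7] = 800.0
        m = segment_bone(bmd_image(v), 100.0)
        assert m.mask[:, :, 3:17][lumen].all()
        assert not m.mask[r > 7.5].any()

    def test_two_blobs_largest_retained(self):
        v = np.zeros((20, 10, 10))
        v[1:8] = 500.0   # 7 slabs
        v[12:15] = 500.0  # 3 slabs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = segment_bone(bmd_image(v), 100.0)
        assert m.mask[1:8].all() and not m.mask[12:15].any()

    def test_empty_threshold_reports_value(self):
        with pytest.raises(SegmentationError, match="900"):
            segment_bone(bmd_image(np.zeros((4, 4, 4))), 900.0)


def femur_landmarks(shaft_dir=(0, 0, 1.0)):
    from femvox.phantom import default_spec

    return default_spec().landmarks()


class TestAlignment:
    def test_vertical_shaft_rotated_to_20_degrees(self, small_phantom):
        img, gt = small_phantom
        bmd = img.copy_with(values=img.values.copy(), unit="mgHA_cm3")
        out, lm = align_one_legged_stance(bmd, gt.landmarks,
                                          crop_mask=gt.bone_mask)
        assert angle_between_deg(lm.shaft_dir, [0, 0, 1]) == pytest.approx(
            20.0, abs=0.1)

    def test_already_aligned_is_identity(self, small_phantom):
        img, gt = small_phantom
        bmd = img.copy_with(values=img.values.copy(), unit="mgHA_cm3")
        out, lm = align_one_legged_stance(bmd, gt.landmarks,
                                          crop_mask=gt.bone_mask)
        out2, lm2 = align_one_legged_stance(out, lm)
        assert np.array_equal(out2.values, out.values)
        np.testing.assert_allclose(lm2.shaft_dir, lm.shaft_dir, atol=1e-12)

    def test_ccd_angle_preserved_by_rigid_rotation(self, small_phantom):
        img, gt = small_phantom
        ccd0 = gt.landmarks.ccd_angle
        bmd = img.copy_with(values=img.values.copy(), unit="mgHA_cm3")
        _, lm = align_one_legged_stance(bmd, gt.landmarks,
                                        crop_mask=gt.bone_mask)
        assert lm.ccd_angle == pytest.approx(ccd0, abs=1e-9)

    def test_head_moves_toward_stance_position(self, small_phantom):
        img, gt = small_phantom
        bmd = img.copy_with(values=img.values.copy(), unit="mgHA_cm3")
        _, lm = align_one_legged_stance(bmd, gt.landmarks,
                                        crop_mask=gt.bone_mask)
        off0 = np.hypot(*(gt.landmarks.head_center - gt.landmarks.shaft_point)[:2])
        off1 = np.hypot(*(lm.head_center - lm.shaft_point)[:2])
        assert off1 < off0

    def test_collinear_landmarks_rejected(self):
        lm = Landmarks(head_center=[0, 0, 100], neck_base=[0, 0, 50],
                       neck_dir=[0, 0, 1], shaft_point=[0, 0, 0],
                       shaft_dir=[0, 0, 1], head_radius=20, neck_length=50)
        img = bmd_image(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="collinear"):
            align_one_legged_stance(img, lm)


class TestCoarsen:
    def test_uniform_stays_uniform(self):
        img = bmd_image(np.full((9, 9, 9), 321.0))
        cimg, cmask = coarsen(img, np.ones((9, 9, 9), bool), 3.0)
        assert cmask.all()
        np.testing.assert_allclose(cimg.values, 321.0)
        assert cimg.spacing == (3.0, 3.0, 3.0)

    def test_block_mean_of_27_values(self):
        vals = (100.0 * np.arange(1, 28)).reshape(3, 3, 3)
        img = bmd_image(vals)
        cimg, cmask = coarsen(img, np.ones((3, 3, 3), bool), 3.0)
        assert cimg.values.shape == (1, 1, 1)
        assert cimg.values[0, 0, 0] == pytest.approx(1400.0)

    def test_native_anisotropic_to_3mm(self):
        img = bmd_image(np.zeros((18, 18, 6)), spacing=(0.33, 0.33, 1.0))
        cimg, _ = coarsen(img, np.ones((18, 18, 6), bool), 3.0)
        assert cimg.spacing == (3.0, 3.0, 3.0)

    def test_fill_fraction_governs_coarse_mask(self):
        img = bmd_image(np.full((3, 3, 3), 100.0))
        mask = np.zeros((3, 3, 3), bool)
        mask[:, :, 0] = True  # 9/27 = 1/3 filled
        _, cm_half = coarsen(img, mask, 3.0, fill_fraction=0.5)
        _, cm_quarter = coarsen(img, mask, 3.0, fill_fraction=0.25)
        assert not cm_half.any()
        assert cm_quarter.any()

    def test_target_below_native_rejected(self):
        img = bmd_image(np.zeros((4, 4, 4)), spacing=(2, 2, 2))
        with pytest.raises(ValueError, match="native"):
            coarsen(img, np.ones((4, 4, 4), bool), 1.0)

    def test_masked_mean_preserved_through_coarsening(self, small_phantom):
        # compare on the same support: fine voxels under the kept coarse
        # voxels (rim voxels below the fill fraction are a genuine exclusion)
        from femvox.calib import compute_densitometry
        img, gt = small_phantom
        bmd = img.copy_with(values=img.values.copy(), unit="mgHA_cm3")
        cimg, cmask = coarsen(bmd, gt.bone_mask, 3.0)
        sp = np.asarray(bmd.spacing)
        idx = np.argwhere(gt.bone_mask)
        ci = ((idx + 0.5) * sp // 3.0).astype(int)
        kept = cmask[ci[:, 0], ci[:, 1], ci[:, 2]]
        fine_vals = bmd.values[gt.bone_mask][kept]
        # volume-weighted coarse mean reproduces the fine masked mean exactly
        counts = np.zeros(cmask.shape)
        np.add.at(counts, tuple(ci[kept].T), 1.0)
        weighted = (cimg.values * counts)[cmask].sum() / counts[cmask].sum()
        assert weighted == pytest.approx(fine_vals.mean(), rel=1e-9)
        # equal-weight densitometry overweights the sparse cortical rim: the
        # residual partial-volume bias stays below 5% for this geometry
        coarse = compute_densitometry(cimg, cmask)
        assert coarse.vBMD == pytest.approx(fine_vals.mean(), rel=0.05)


class TestBvTv:
    def test_typical_trabecular_value(self):
        assert bmd_to_bvtv(200.0) == pytest.approx(0.19677, abs=1e-10)

    def test_lower_root_clamps_to_rho_min(self):
        assert bmd_to_bvtv(-11.5807) == pytest.approx(0.01)
        assert bmd_to_bvtv(-100.0) == pytest.approx(0.01)

    def test_upper_saturation_at_poreless(self):
        assert bmd_to_bvtv(1063.7) == pytest.approx(1.0)
        assert bmd_to_bvtv(1400.0) == pytest.approx(1.0)

    def test_monotone_total_on_clamped_domain(self):
        b = np.linspace(-100, 1400, 2001)
        r = bmd_to_bvtv(b)
        assert np.all(np.diff(r) >= 0)
        assert r.min() >= 0.01 and r.max() <= 1.0


class TestBuildHexMesh:
    def _coarse(self, mask):
        vals = np.full(mask.shape, 400.0)
        return DensityImage(values=vals, spacing=(3.0, 3.0, 3.0),
                            unit="mgHA_cm3"), mask

    def test_two_adjacent_voxels_share_a_face(self):
        mask = np.zeros((2, 1, 1), bool)
        mask[:, 0, 0] = True
        img, m = self._coarse(mask)
        mesh = build_hex_mesh(img, m, embedding=None)
        assert mesh.n_elements == 2
        assert mesh.n_nodes == 12

    def test_isolated_voxels_have_private_nodes(self):
        mask = np.zeros((5, 1, 1), bool)
        mask[0] = mask[2] = mask[4] = True
        img, m = self._coarse(mask)
        mesh = build_hex_mesh(img, m, embedding=None,
                              connectivity_cleanup=False)
        assert mesh.n_elements == 3
        assert mesh.n_nodes == 24

    def test_element_count_is_exact(self):
        rng = np.random.default_rng(3)
        mask = rng.random((4, 4, 4)) < 0.7
        mask[0, 0, 0] = True
        img, m = self._coarse(mask)
        mesh = build_hex_mesh(img, m, embedding=None,
                              connectivity_cleanup=False)
        assert mesh.n_elements == mask.sum()

    def test_embedding_adds_pu_and_steel_above_cranial_surface(self):
        mask = np.ones((3, 3, 2), bool)
        img, m = self._coarse(mask)
        mesh = build_hex_mesh(img, m, embedding=EmbeddingConfig())
        assert (mesh.material == 1).sum() == 9   # one PU layer
        assert (mesh.material == 2).sum() == 9   # one steel layer
        z_by_mat = [mesh.element_centers()[mesh.material == k][:, 2].mean()
                    for k in (0, 1, 2)]
        assert z_by_mat[0] < z_by_mat[1] < z_by_mat[2]

    def test_void_elements_dropped(self):
        mask = np.ones((2, 1, 1), bool)
        img = DensityImage(values=np.array([[[400.0]], [[-100.0]]]),
                           spacing=(3, 3, 3), unit="mgHA_cm3")
        mesh = build_hex_mesh(img, mask, embedding=None)
        assert mesh.n_elements == 1

    def test_empty_mask_rejected(self):
        img, _ = self._coarse(np.zeros((2, 2, 2), bool))
        with pytest.raises(MeshError):
            build_hex_mesh(img, np.zeros((2, 2, 2), bool), embedding=None)

    def test_vtu_round_trip(self, tmp_path):
        from femvox.mesh import read_vtu

        mask = np.ones((3, 3, 2), bool)
        img, m = self._coarse(mask)
        mesh = build_hex_mesh(img, m, embedding=EmbeddingConfig())
        write_vtu(mesh, tmp_path / "m.vtu")
        back = read_vtu(tmp_path / "m.vtu")
        assert back.n_nodes == mesh.n_nodes
        np.testing.assert_allclose(back.nodes, mesh.nodes)
        assert np.array_equal(back.elements, mesh.elements)
        assert np.array_equal(back.material, mesh.material)
        bone = mesh.material == 0
        np.testing.assert_allclose(back.rho[bone], mesh.rho[bone])
        assert back.spacing == mesh.spacing

    def test_exports_are_text(self, tmp_path):
        mask = np.ones((2, 2, 2), bool)
        img, m = self._coarse(mask)
        mesh = build_hex_mesh(img, m, embedding=None)
        write_vtu(mesh, tmp_path / "m.vtu")
        write_text_mesh(mesh, tmp_path / "m.txt")
        vtu = (tmp_path / "m.vtu").read_text()
        assert "UnstructuredGrid" in vtu and "connectivity" in vtu
        header = (tmp_path / "m.txt").read_text().splitlines()[1]
        assert header == f"{mesh.n_nodes} {mesh.n_elements}"


def cylinder_landmarks(L=30.0):
    return Landmarks(head_center=[L, 0, 0], neck_base=[0, 0, 0],
                     neck_dir=[1, 0, 0], shaft_point=[0, 0, -50],
                     shaft_dir=[0, 0, 1], head_radius=0.0, neck_length=L)


class TestInsertLesion:
    def test_wedge_subtends_120_degrees_by_default(self):
        assert wedge_angle_deg(LesionSpec()) == pytest.approx(120.0)

    def test_negligible_fraction_leaves_image_unchanged(self):
        v = np.full((10, 10, 10), 300.0)
        img = bmd_image(v)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, _ = insert_lesion(
                img, None, cylinder_landmarks(),
                LesionSpec(circumferential_fraction=1e-9))
        assert np.count_nonzero(out.values != 300.0) == 0

    def test_wedge_volume_matches_analytic_sector(self):
        # standalone neck cylinder radius 8, length 30 along +x
        L, R = 30.0, 8.0
        n = 48
        sp = 0.75
        shape = (n, n, n)
        ax = (np.arange(n) - n / 2 + 0.5) * sp
        X = ax[:, None, None] + L / 2  # cylinder spans x in [0, L]
        Y = ax[None, :, None]
        Z = ax[None, None, :]
        inside = (X >= 0) & (X <= L) & (Y ** 2 + Z ** 2 <= R ** 2)
        v = np.where(inside, 600.0, 0.0)
        img = DensityImage(values=v, spacing=(sp, sp, sp),
                           origin=(ax[0] + L / 2, ax[0], ax[0]),
                           unit="mgHA_cm3")
        lm = cylinder_landmarks(L)
        out, mask = insert_lesion(img, inside, lm,
                                  LesionSpec(site="inferomedial",
                                             circumferential_fraction=1 / 3,
                                             axial_range=(0.0, L), depth=1.0))
        removed = (inside & ~mask).sum() * sp ** 3
        analytic = np.pi * R ** 2 * L / 3.0
        assert removed == pytest.approx(analytic, rel=0.05)

    def test_never_increases_values_and_mask_shrinks(self, small_phantom):
        img, gt = small_phantom
        bmd = img.copy_with(values=img.values.copy(), unit="mgHA_cm3")
        out, mask = insert_lesion(bmd, gt.bone_mask, gt.landmarks,
                                  LesionSpec(site="superolateral"))
        assert np.all(out.values <= bmd.values + 1e-12)
        assert not (mask & ~gt.bone_mask).any()
        assert mask.sum() < gt.bone_mask.sum()

    def test_zero_removal_warns(self):
        v = np.zeros((6, 6, 6))
        img = bmd_image(v)
        lm = cylinder_landmarks(5.0)
        with pytest.warns(UserWarning, match="zero voxels"):
            insert_lesion(img, np.zeros((6, 6, 6), bool), lm, LesionSpec())

    @pytest.mark.parametrize("bad", [
        {"site": "anterior"}, {"circumferential_fraction": 0.0},
        {"depth": 1.5},
    ])
    def test_spec_validation(self, bad):
        with pytest.raises(ValueError):
            LesionSpec(**bad)
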