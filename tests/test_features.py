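"""The twelve PET parameters against analytic and brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from petdna import (
    FeatureConfig,
    SuvVolume,
    UndefinedFeatureError,
    extract_all,
    label_lesions,
)
from petdna.features import (
    dispersion_features,
    intensity_features,
    massiveness_features,
    tlg,
    volume_surface_features,
)

from conftest import ball_mask, cube_mask, uniform_suv


def features_of(mask, suv_level=10.0, spacing=(1.0, 1.0, 1.0), config=None):
    suv = SuvVolume(mask.astype(np.float32) * suv_level, spacing)
    return extract_all(suv, mask, config)


class TestIntensity:
    def test_uniform_lesion(self):
        mask = cube_mask(3)
        lesions = label_lesions(mask)
        assert intensity_features(uniform_suv(mask, 10.0), lesions) == (10.0, 10.0)

    def test_two_lesions_weighted_mean(self):
        # lesion A: 8 voxels at SUV 4; lesion B: 8 voxels at SUV 12
        m = np.zeros((10, 4, 4), bool)
        m[0:2, 0:2, 0:2] = True
        m[6:8, 0:2, 0:2] = True
        data = np.zeros((10, 4, 4), np.float32)
        data[0:2, 0:2, 0:2] = 4.0
        data[6:8, 0:2, 0:2] = 12.0
        suv = SuvVolume(data)
        smax, smean = intensity_features(suv, label_lesions(m))
        assert smax == 12.0 and smean == 8.0

    def test_mean_never_exceeds_max(self):
        rng = np.random.default_rng(0)
        data = rng.random((8, 8, 8)).astype(np.float32) * 20
        mask = rng.random((8, 8, 8)) < 0.3
        if mask.any():
            smax, smean = intensity_features(SuvVolume(data), label_lesions(mask))
            assert smean <= smax


class TestVolumeSurface:
    def test_digital_ball_matches_analytic_sphere(self, sphere_features_1mm):
        fv = sphere_features_1mm
        r = 20.0
        assert fv.TMTV == pytest.approx(4 / 3 * np.pi * r**3 / 1000, rel=0.02)
        assert fv.TMTS == pytest.approx(4 * np.pi * r**2 / 100, rel=0.04)
        assert fv.TVSR == pytest.approx(r / 3, rel=0.05)

    def test_cube_volume_exact(self):
        # 8 voxels at 2 mm spacing: 8 * 8 mm3 = 0.064 cm3 exactly
        fv = features_of(cube_mask(2), spacing=(2.0, 2.0, 2.0))
        assert fv.TMTV == pytest.approx(0.064, abs=0)

    def test_additivity_over_disjoint_lesions(self):
        single = ball_mask(8, 1.0)
        n = single.shape[0]
        double = np.zeros((2 * n + 10, n, n), bool)
        double[:n] = single
        double[n + 10 :] = single
        fv1 = features_of(single)
        fv2 = features_of(double)
        assert fv2.TMTV == pytest.approx(2 * fv1.TMTV, rel=1e-12)
        assert fv2.TMTS == pytest.approx(2 * fv1.TMTS, rel=1e-9)
        assert fv2.TLG == pytest.approx(2 * fv1.TLG, rel=1e-9)
        assert fv2.nROI == 2 * fv1.nROI


class TestTlg:
    def test_product_and_zero(self):
        assert tlg(2.0, 3.0) == 6.0
        assert tlg(0.0, 5.0) == 0.0

    def test_matches_voxelwise_integral_for_uniform_uptake(self):
        mask = ball_mask(7, 1.0)
        level = 6.5
        fv = features_of(mask, suv_level=level)
        voxelwise = level * mask.sum() * 1.0 / 1000  # sum SUV x voxel volume, cm3
        assert fv.TLG == pytest.approx(voxelwise, rel=1e-9)


class TestDispersion:
    def test_two_balls_geometry(self):
        # balls r = 10 mm centred 100 mm apart along the first axis
        m = np.zeros((130, 30, 30), bool)
        ax = np.arange(130)[:, None, None] + 0.5
        ay = np.arange(30)[None, :, None] + 0.5
        az = np.arange(30)[None, None, :] + 0.5
        m |= (ax - 15) ** 2 + (ay - 15) ** 2 + (az - 15) ** 2 <= 100
        m |= (ax - 115) ** 2 + (ay - 15) ** 2 + (az - 15) ** 2 <= 100
        lesions = label_lesions(m)
        tumbb, dmax, nroi = dispersion_features(lesions)
        assert nroi == 2
        assert dmax == pytest.approx(100.0, abs=1.0)
        assert tumbb == pytest.approx(48.0, rel=0.03)  # 120 x 20 x 20 mm3
        # brute-force pairwise centroid distance oracle
        cents = [np.argwhere(lesions.grid == k).mean(axis=0) for k in (1, 2)]
        assert dmax == pytest.approx(np.linalg.norm(cents[0] - cents[1]), rel=1e-9)

    def test_single_voxel_degenerate(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        tumbb, dmax, nroi = dispersion_features(label_lesions(m))
        assert (tumbb, dmax, nroi) == (0.001, 0.0, 1)

    def test_solid_box_fills_bounding_box(self):
        m = np.zeros((50, 30, 20), bool)
        m[5:45, 5:25, 5:15] = True  # 40 x 20 x 10 mm at 1 mm spacing
        fv = features_of(m)
        assert fv.TumBB == pytest.approx(8.0, rel=1e-12)
        assert fv.TMTV == pytest.approx(8.0, rel=1e-12)

    def test_single_lesion_dmax_is_intra_lesion_diameter(self):
        mask = ball_mask(10, 1.0)
        fv = features_of(mask)
        # diameter of a digital r = 10 ball is ~2r (voxel-centre to voxel-centre)
        assert fv.Dmax == pytest.approx(20.0, abs=1.5)
        assert features_of(mask, config=FeatureConfig(dmax_single_mode="zero")).Dmax == 0.0


class TestMassiveness:
    def test_cube_erosion_count(self):
        # 5^3 -> 3^3 -> 1 -> empty: 3 erosions (brute-force oracle alongside)
        m = cube_mask(5)
        it, _, _ = massiveness_features(label_lesions(m))
        count, cur = 0, m.copy()
        struct = ndimage.generate_binary_structure(3, 1)
        while cur.any():
            cur = ndimage.binary_erosion(cur, struct)
            count += 1
        assert it == count == 3

    def test_iterosion_fractional_mean_over_lesions(self):
        m = np.zeros((20, 10, 10), bool)
        m[1:6, 1:6, 1:6] = True    # 5-cube: 3 erosions
        m[10:13, 1:4, 1:4] = True  # 3-cube: 2 erosions
        it, _, _ = massiveness_features(label_lesions(m))
        assert it == pytest.approx(2.5)

    def test_ball_medpcd_close_to_radius(self, sphere_features_1mm):
        assert sphere_features_1mm.medPCD == pytest.approx(20.0, rel=0.05)

    def test_cube_edge_runs(self):
        _, _, med = massiveness_features(label_lesions(cube_mask(4)))
        assert med == 4.0
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        _, _, med1 = massiveness_features(label_lesions(m))
        assert med1 == 1.0

    def test_centroid_chord_mode_on_cube(self):
        _, _, med = massiveness_features(
            label_lesions(cube_mask(4)), FeatureConfig(edge_mode="centroid_chords")
        )
        assert med == 4.0

    def test_anisotropic_spacing_warns_for_erosion(self):
        m = cube_mask(3)
        with pytest.warns(UserWarning, match="anisotropic"):
            massiveness_features(label_lesions(m, spacing=(1.0, 1.0, 2.0)))


class TestExtractAll:
    def test_definitional_identities(self, sphere_features_1mm):
        fv = sphere_features_1mm
        assert fv.TLG == pytest.approx(fv.TMTV * fv.SUVmean, rel=1e-9)
        assert fv.TVSR * fv.TMTS * 100 == pytest.approx(fv.TMTV * 1000, rel=1e-9)

    def test_axis_permutation_invariance(self):
        rng = np.random.default_rng(2)
        mask = rng.random((12, 14, 16)) < 0.15
        mask[0, 0, 0] = True
        data = (rng.random((12, 14, 16)) * 10).astype(np.float32)
        fv = extract_all(SuvVolume(data), mask)
        perm = (2, 0, 1)
        fv_p = extract_all(SuvVolume(np.transpose(data, perm)), np.transpose(mask, perm))
        for name, value in fv.as_dict().items():
            assert value == pytest.approx(fv_p.as_dict()[name], rel=1e-6), name

    def test_scale_equivariance(self):
        mask = ball_mask(6, 1.0)
        fv1 = features_of(mask, spacing=(1.0, 1.0, 1.0))
        s = 2.0
        fv2 = features_of(mask, spacing=(s, s, s))
        assert fv2.TMTV == pytest.approx(s**3 * fv1.TMTV, rel=1e-9)
        assert fv2.TumBB == pytest.approx(s**3 * fv1.TumBB, rel=1e-9)
        assert fv2.TMTS == pytest.approx(s**2 * fv1.TMTS, rel=1e-6)
        for name in ("TVSR", "Dmax", "medPCD", "medEdgeD"):
            assert getattr(fv2, name) == pytest.approx(s * getattr(fv1, name), rel=1e-6), name
        for name in ("SUVmax", "SUVmean", "nROI", "itErosion"):
            assert getattr(fv2, name) == pytest.approx(getattr(fv1, name), rel=1e-12), name

    def test_translation_invariance_of_distances(self):
        mask = ball_mask(5, 1.0)
        suv = SuvVolume(mask.astype(np.float32) * 10, (1, 1, 1), origin=(0, 0, 0))
        suv_t = SuvVolume(mask.astype(np.float32) * 10, (1, 1, 1), origin=(50, -20, 7))
        fv, fv_t = extract_all(suv, mask), extract_all(suv_t, mask)
        assert fv.as_dict() == fv_t.as_dict()

    def test_monotone_growth_when_lesion_added(self):
        base = np.zeros((40, 20, 20), bool)
        base[2:10, 2:10, 2:10] = True
        grown = base.copy()
        grown[25:32, 5:12, 5:12] = True
        fv_a, fv_b = features_of(base), features_of(grown)
        assert fv_b.TMTV > fv_a.TMTV and fv_b.TMTS > fv_a.TMTS
        assert fv_b.TumBB >= fv_a.TumBB and fv_b.Dmax >= fv_a.Dmax
        assert fv_b.nROI == fv_a.nROI + 1

    def test_empty_mask_raises(self):
        suv = uniform_suv(np.zeros((4, 4, 4), bool))
        with pytest.raises(UndefinedFeatureError):
            extract_all(suv, np.zeros((4, 4, 4), bool))

    def test_faces_surface_mode_overestimates_sphere(self):
        mask = ball_mask(10, 1.0)
        mesh = features_of(mask).TMTS
        faces = features_of(mask, config=FeatureConfig(surface_mode="faces")).TMTS
        true = 4 * np.pi * 100 / 100
        assert abs(mesh - true) / true < 0.04
        assert faces > 1.3 * true  # staircase bias of face counting
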