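"""Auto-contouring: body/lung/liver VOIs, inferior exclusion, count extrapolation."""

import numpy as np
import pytest

from lungshunt import contour, scanner
from lungshunt import phantom as ph


@pytest.fixture(scope="module")
def torso_ct(torso_phantom):
    return torso_phantom.ct_hu()


@pytest.fixture(scope="module")
def body(torso_ct):
    return contour.whole_body_voi(torso_ct)


@pytest.fixture(scope="module")
def lungs(torso_ct, body, torso_phantom):
    return contour.lung_voi(torso_ct, body, voxel_spacing_mm=torso_phantom.voxel_spacing_mm)


class TestWholeBodyVoi:
    def test_recovers_body_volume(self, torso_phantom, body):
        truth = (torso_phantom.label_grid != ph.Compartment.AIR).sum()
        assert body.sum() == pytest.approx(truth, rel=0.02)

    def test_all_air_raises(self):
        with pytest.raises(ValueError, match="empty body"):
            contour.whole_body_voi(np.full((16, 16, 16), -1000.0))

    def test_idempotent_on_masked_ct(self, torso_ct, body):
        masked = np.where(body, torso_ct, -1000.0)
        again = contour.whole_body_voi(masked)
        np.testing.assert_array_equal(again, body)


class TestLungVoi:
    def test_recovers_solved_lung_volume(self, torso_phantom, lungs, solved_specs):
        left, right = lungs
        vol = (left | right).sum() * torso_phantom.voxel_volume_ml
        assert vol == pytest.approx(solved_specs[3.6].lung_volume_ml, rel=0.05)

    def test_left_right_assignment(self, torso_phantom, lungs):
        left, right = lungs
        assert left.sum() > 0 and right.sum() > 0
        # patient left is +x; left lung centroid must sit at higher x
        xs = np.arange(torso_phantom.label_grid.shape[0])
        assert (left.sum(axis=(1, 2)) * xs).sum() / left.sum() > \
               (right.sum(axis=(1, 2)) * xs).sum() / right.sum()

    def test_no_candidates_raises(self, body):
        ct = np.zeros(body.shape)  # soft tissue everywhere
        with pytest.raises(ValueError, match="candidate"):
            contour.lung_voi(ct, body)

    def test_small_air_pocket_removed(self, torso_phantom, torso_ct, body):
        ct = torso_ct.copy()
        # 10 mL abdominal gas pocket: ~46 voxels at 6 mm -> below the 50 mL filter
        ct[30:33, 28:31, 5:10] = -800.0
        left, right = contour.lung_voi(ct, body, voxel_spacing_mm=torso_phantom.voxel_spacing_mm)
        assert not (left | right)[30:33, 28:31, 5:10].any()

    def test_cohort_lung_volume_recovery(self):
        """CT lung volume recovered within 5 % across 1.5-4.8 L."""
        for vol_ml in (1500.0, 2400.0, 3300.0, 4100.0, 4800.0):
            p = ph.build_phantom(ph.patient_spec(1.5, vol_ml, 1800.0, 200.0), 6.0, (64, 64, 64))
            body = contour.whole_body_voi(p.ct_hu())
            left, right = contour.lung_voi(p.ct_hu(), body, voxel_spacing_mm=p.voxel_spacing_mm)
            got = (left | right).sum() * p.voxel_volume_ml
            assert got == pytest.approx(vol_ml, rel=0.05)


class TestExcludeInferior:
    def _lung_pair(self, z0, z1, shape=(20, 20, 50)):
        m = np.zeros(shape, bool)
        m[4:9, 8:12, z0:z1] = True
        other = np.zeros(shape, bool)
        other[12:17, 8:12, z0:z1] = True
        return m, other

    def test_exact_slice_count(self):
        # 40 slices of 2.5 mm; 2 cm margin -> exactly 8 slices removed per lung
        left, right = self._lung_pair(5, 45)
        excl, margin_mm = contour.exclude_inferior((left, right), 2.0, (2.5, 2.5, 2.5))
        assert margin_mm == 20.0
        removed = (left | right) & ~excl
        assert set(np.flatnonzero(removed.any(axis=(0, 1)))) == set(range(5, 13))

    def test_zero_margin_is_identity(self):
        left, right = self._lung_pair(5, 45)
        excl, margin_mm = contour.exclude_inferior((left, right), 0.0, (2.5, 2.5, 2.5))
        np.testing.assert_array_equal(excl, left | right)
        assert margin_mm == 0.0

    def test_per_lung_reference(self):
        # lungs with different inferior extents are clipped independently
        left = np.zeros((20, 20, 50), bool)
        left[4:9, 8:12, 10:40] = True
        right = np.zeros((20, 20, 50), bool)
        right[12:17, 8:12, 4:40] = True
        excl, _ = contour.exclude_inferior((left, right), 2.0, (5.0, 5.0, 5.0))
        assert not excl[:, :, :8].any()          # right clipped from z=4 -> cut at 8
        assert excl[12:17, 8:12, 8:40].all()
        assert not excl[4:9, 8:12, :14].any()    # left clipped from z=10 -> cut at 14
        assert excl[4:9, 8:12, 14:40].all()

    def test_margin_exceeding_lung_height_raises(self):
        left, right = self._lung_pair(5, 9)
        with pytest.raises(ValueError, match="exceeds"):
            contour.exclude_inferior((left, right), 10.0, (2.5, 2.5, 2.5))

    def test_exclusion_reduces_lsf_under_breathing_blur(self, blurred_recon, solved_specs):
        """Under 15 mm blur the exclusion pulls the volumetric LSF back toward
        the administered 3.6 % (spill-in sits in the inferior lung band)."""
        from lungshunt import quantify

        p = blurred_recon["phantom"]
        rec = blurred_recon["recon"].value_grid
        lungs = blurred_recon["lungs"]
        full = lungs[0] | lungs[1]
        lung_volume_ml = full.sum() * p.voxel_volume_ml
        excl, _ = contour.exclude_inferior(lungs, 2.0, p.voxel_spacing_mm)
        liver_mask, _ = contour.liver_voi(rec, preset_override=2.0,
                                          voxel_spacing_mm=p.voxel_spacing_mm)
        liver_mask = liver_mask & ~full

        def lsf(mask):
            lung_counts = contour.estimate_lung_counts(
                rec, mask, lung_volume_ml, voxel_spacing_mm=p.voxel_spacing_mm)
            return quantify.volumetric_lsf(rec, liver_mask, lung_counts).lsf_percent

        with_excl, without = lsf(excl), lsf(full)
        assert with_excl < without
        assert abs(with_excl - 3.6) < abs(without - 3.6)


class TestLiverVoi:
    def test_preset_list_is_standard(self):
        cfg = contour.SegmentationConfig()
        assert cfg.liver_threshold_presets_percent == (0.5, 1.0, 2.0, 5.0, 10.0)
        assert cfg.default_liver_preset_percent == 2.0

    def test_recovers_liver_volume_on_recon(self, torso_phantom, acsc_recon, solved_specs):
        """Preset auto-selected against the CT liver outline (the clinical
        procedure): recovered liver volume within 10 % of the solved
        whole-liver volume (normal tissue + lesions)."""
        p = torso_phantom
        truth = solved_specs[3.6].liver_volume_ml
        mask, preset = contour.liver_voi(acsc_recon.value_grid,
                                         ct_liver_volume_ml=truth,
                                         voxel_spacing_mm=p.voxel_spacing_mm)
        assert preset in contour.SegmentationConfig().liver_threshold_presets_percent
        assert mask.sum() * p.voxel_volume_ml == pytest.approx(truth, rel=0.10)

    def test_mask_volume_decreases_with_preset(self, torso_phantom, acsc_recon):
        vols = [
            contour.liver_voi(acsc_recon.value_grid, preset_override=pr,
                              voxel_spacing_mm=torso_phantom.voxel_spacing_mm)[0].sum()
            for pr in (0.5, 1.0, 2.0, 5.0, 10.0)
        ]
        assert vols == sorted(vols, reverse=True)

    def test_near_max_preset_keeps_only_peak(self):
        vol = np.zeros((8, 8, 8))
        vol[4, 4, 4] = 10.0
        vol[2, 2, 2] = 5.0
        mask, _ = contour.liver_voi(vol, preset_override=99.9)
        assert mask.sum() == 1

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="zero"):
            contour.liver_voi(np.zeros((8, 8, 8)))

    def test_auto_selection_against_ct_volume(self):
        vol = np.zeros((20, 20, 20))
        vol[5:15, 5:15, 5:15] = 1.0    # 1000 voxels of liver
        vol[9:11, 9:11, 9:11] = 50.0   # hot lesion sets the max
        # at 1 mm voxels the 1000 voxel object is 1 mL
        mask, preset = contour.liver_voi(vol, ct_liver_volume_ml=1.0,
                                         voxel_spacing_mm=(1.0, 1.0, 1.0))
        assert preset in (0.5, 1.0, 2.0)
        assert mask.sum() == 1000


class TestEstimateLungCounts:
    @pytest.fixture()
    def uniform_lung(self):
        emission = np.zeros((30, 30, 30))
        mask = np.zeros_like(emission, bool)
        mask[5:25, 5:25, 10:28] = True
        emission[mask] = 2.0
        return emission, mask

    def test_uniform_full_fov_matches_direct_sum(self, uniform_lung):
        emission, mask = uniform_lung
        vol_ml = mask.sum() * 8.0 / 1000.0  # 2 mm voxels
        est = contour.estimate_lung_counts(emission, mask, vol_ml * 1000.0,
                                           voxel_spacing_mm=(2.0, 2.0, 2.0))
        assert est == pytest.approx(emission[mask].sum() * 1000.0, rel=0.01)

    def test_half_fov_matches_full_fov(self, uniform_lung):
        emission, mask = uniform_lung
        vol_ml = mask.sum() * 8.0 / 1000.0
        fov = np.zeros_like(mask)
        fov[:, :, :19] = True  # axial FOV covering roughly half the lung
        full = contour.estimate_lung_counts(emission, mask, vol_ml * 1000.0,
                                            voxel_spacing_mm=(2.0, 2.0, 2.0))
        half = contour.estimate_lung_counts(emission, mask, vol_ml * 1000.0,
                                            in_fov_mask=fov,
                                            voxel_spacing_mm=(2.0, 2.0, 2.0))
        assert half == pytest.approx(full, rel=0.02)

    def test_zero_activity_gives_zero(self, uniform_lung):
        _, mask = uniform_lung
        est = contour.estimate_lung_counts(np.zeros(mask.shape), mask, 2000.0)
        assert est == 0.0

    def test_empty_intersection_raises(self, uniform_lung):
        emission, mask = uniform_lung
        with pytest.raises(ValueError, match="no lung in FOV"):
            contour.estimate_lung_counts(emission, mask, 2000.0,
                                         in_fov_mask=np.zeros_like(mask))


class TestSegmentOrchestration:
    def test_masks_reproducible_and_consistent(self, torso_phantom):
        emission = torso_phantom.activity_grid  # stand-in emission volume
        a = contour.segment(torso_phantom.ct_hu(), emission,
                            voxel_spacing_mm=torso_phantom.voxel_spacing_mm)
        b = contour.segment(torso_phantom.ct_hu(), emission,
                            voxel_spacing_mm=torso_phantom.voxel_spacing_mm)
        np.testing.assert_array_equal(a.liver_mask, b.liver_mask)
        np.testing.assert_array_equal(a.lung_mask_with_exclusion, b.lung_mask_with_exclusion)
        # invariants: exclusion subset of lungs, masks disjoint, inside body
        assert not (a.lung_mask_with_exclusion & ~a.lung_mask).any()
        assert not (a.liver_mask & a.lung_mask).any()
        assert not (a.lung_mask & ~a.body_mask).any()
        # lung volume for dosimetry comes from the full mask, pre-exclusion
        assert a.lung_volume_l == pytest.approx(
            a.lung_mask.sum() * torso_phantom.voxel_volume_ml / 1000.0)
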