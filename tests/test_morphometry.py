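import numpy as np
import pytest

from tibiamap.core_io import VolumeStack
from tibiamap.morphometry import (
    SAMPLING_PRESETS,
    detect_osteophytes,
    lesion_fractions,
    sample_thickness_points,
    thickness_maps,
)


def uniform_slab(cart_mm=1.0, plate_mm=1.0, dy=0.1):
    nz, ny, nx = 4, 40, 30
    vox = np.zeros((nz, ny, nx), dtype=np.uint8)
    c, p = int(round(cart_mm / dy)), int(round(plate_mm / dy))
    top = 20
    vox[:, top : top + c, :] = 2
    vox[:, top + c : top + c + p, :] = 1
    return VolumeStack(vox, (dy, dy, dy))


class TestThicknessMaps:
    def test_uniform_slab_recovers_both_thicknesses(self):
        tm = thickness_maps(uniform_slab(1.0, 1.0))
        assert np.allclose(tm.cartilage_mm[tm.valid], 1.0)
        assert np.allclose(tm.plate_mm[tm.valid], 1.0)

    def test_phantom_agrees_with_ground_truth_per_column(self, phantom):
        vol, gt = phantom
        tm = thickness_maps(vol)
        dy = vol.dy
        m = np.isfinite(gt.cartilage_mm) & np.isfinite(tm.cartilage_mm)
        assert m.sum() == np.isfinite(gt.cartilage_mm).sum()
        assert np.nanmax(np.abs(tm.cartilage_mm[m] - gt.cartilage_mm[m])) <= dy
        mp = np.isfinite(gt.plate_mm) & np.isfinite(tm.plate_mm)
        assert np.nanmax(np.abs(tm.plate_mm[mp] - gt.plate_mm[mp])) <= dy

    def test_central_thick_peripheral_thin(self, phantom, pipeline):
        """Both tissues exceed 1 mm centrally and stay under 1 mm in the
        submeniscal peripheries, the reported topographic pattern."""
        vol, _ = phantom
        tm = thickness_maps(vol)
        sm = pipeline["submap"]
        central = np.isin(sm.labels, [1, 3, 5, 7, 9, 11])
        peripheral = np.isin(sm.labels, [2, 4, 6, 8, 10, 12])
        for arr in (tm.cartilage_mm, tm.plate_mm):
            assert np.nanmean(arr[central]) > 1.0
            assert np.nanmean(arr[peripheral]) < 1.0

    def test_z_translation_invariance(self):
        vol = uniform_slab()
        padded = VolumeStack(
            np.pad(vol.voxels, ((3, 0), (0, 0), (0, 0))), vol.spacing
        )
        tm0 = thickness_maps(vol)
        tm1 = thickness_maps(padded)
        assert np.allclose(tm1.cartilage_mm[3:], tm0.cartilage_mm, equal_nan=True)

    def test_no_cartilage_warns_and_invalidates(self):
        vol = uniform_slab()
        vox = vol.voxels.copy()
        vox[vox == 2] = 0
        with pytest.warns(UserWarning, match="no cartilage"):
            tm = thickness_maps(VolumeStack(vox, vol.spacing))
        assert np.all(np.isnan(tm.cartilage_mm))


class TestSampling:
    def test_twelve_rows_for_one_point_per_subregion(self, phantom, pipeline):
        vol, _ = phantom
        tm = thickness_maps(vol)
        pts = sample_thickness_points(
            tm, pipeline["submap"], k_slices=1, points={n: 1 for n in SAMPLING_PRESETS["points96"]}
        )
        assert len(pts) == 12

    @pytest.mark.parametrize("preset,total", [("points96", 96), ("points98", 98)])
    def test_preset_totals(self, phantom, pipeline, preset, total):
        vol, _ = phantom
        tm = thickness_maps(vol)
        pts = sample_thickness_points(tm, pipeline["submap"], points=preset)
        assert len(pts) == total
        assert sum(SAMPLING_PRESETS[preset].values()) == total

    def test_sampled_values_equal_map_values(self, phantom, pipeline):
        vol, _ = phantom
        tm = thickness_maps(vol)
        pts = sample_thickness_points(tm, pipeline["submap"])
        for row in pts.itertuples():
            z, c = row.slice_index - 1, row.col
            assert row.plate_mm == tm.plate_mm[z, c]
            if np.isfinite(row.cartilage_mm):
                assert row.cartilage_mm == tm.cartilage_mm[z, c]

    def test_summaries_consistent_with_columns(self, phantom, pipeline):
        vol, _ = phantom
        tm = thickness_maps(vol)
        sm = pipeline["submap"]
        summary = tm.summarize(sm)
        row = summary[(summary.abbrev == "MIC") & (summary.tissue == "cartilage")].iloc[0]
        vals = tm.cartilage_mm[sm.mask("MIC") & tm.valid]
        vals = vals[np.isfinite(vals)]
        assert row["mean_mm"] == pytest.approx(vals.mean())
        assert row["n"] == len(vals)


class TestOsteophytes:
    def test_control_against_itself_is_empty(self, phantom, pipeline):
        vol, _ = phantom
        recs, mask = detect_osteophytes(vol, vol, pipeline["submap"], v_min_mm3=0.01)
        assert recs == [] and not mask.any()

    def test_oa_phantom_osteophytes_confined_to_medial_peripheral(self, phantom, oa_phantom, pipeline):
        vol, _ = phantom
        oa_vol, _ = oa_phantom
        recs, _ = detect_osteophytes(oa_vol, vol, pipeline["submap"])
        assert recs
        allowed = {"medial_intermediate_peripheral", "medial_anterior_peripheral"}
        for r in recs:
            assert set(r.subregions) <= allowed
            assert r.volume_mm3 >= 1.0

    def test_detected_mask_dice_against_ground_truth(self, phantom, oa_phantom, pipeline):
        vol, _ = phantom
        oa_vol, oa_gt = oa_phantom
        _, mask = detect_osteophytes(oa_vol, vol, pipeline["submap"])
        inter = (mask & oa_gt.osteophyte_mask).sum()
        dice = 2 * inter / (mask.sum() + oa_gt.osteophyte_mask.sum())
        assert dice >= 0.9

    def test_min_volume_filter(self, phantom, oa_phantom, pipeline):
        vol, _ = phantom
        oa_vol, _ = oa_phantom
        recs, _ = detect_osteophytes(oa_vol, vol, pipeline["submap"], v_min_mm3=1e9)
        assert recs == []


class TestLesions:
    def test_empty_mask_gives_zero_fractions(self, pipeline):
        sm = pipeline["submap"]
        rep = lesion_fractions(np.zeros_like(sm.labels, bool), sm)
        assert all(f == 0.0 for f in rep.fractions.values())
        assert all(c == "0-25%" for c in rep.categories.values())

    def test_sixty_percent_lesion_categorized_50_75(self, oa_phantom, pipeline):
        _, oa_gt = oa_phantom
        rep = lesion_fractions(oa_gt.lesion_mask, pipeline["submap"])
        assert rep.categories["medial_intermediate_central"] == "50-75%"
        assert 0.5 <= rep.fractions["medial_intermediate_central"] < 0.75

    def test_fraction_equals_independent_tally(self, oa_phantom, pipeline):
        _, oa_gt = oa_phantom
        sm = pipeline["submap"]
        rep = lesion_fractions(oa_gt.lesion_mask, sm)
        for code in sm.present_codes():
            name = sm.legend[code][0]
            region = sm.labels == code
            expected = (oa_gt.lesion_mask & region).sum() / region.sum()
            assert rep.fractions[name] == pytest.approx(expected)

    def test_no_double_counting_across_subregions(self, oa_phantom, pipeline):
        _, oa_gt = oa_phantom
        sm = pipeline["submap"]
        rep = lesion_fractions(oa_gt.lesion_mask, sm)
        total = rep.table["lesion_columns"].sum()
        on_fp = (oa_gt.lesion_mask & (sm.labels != 0)).sum()
        assert total == on_fp

    def test_category_boundary_half_open(self, pipeline):
        from tibiamap.morphometry import _categorize

        assert _categorize(0.50) == "50-75%"
        assert _categorize(0.2499) == "0-25%"
        assert _categorize(1.0) == "75-100%"
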