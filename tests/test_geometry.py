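import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tibiamap.geometry import (
    SUBREGION_CODES,
    assign_point,
    build_reference_lines,
    partition_subregions,
    percent_slice,
    thirds_quarters_grid,
)
from tibiamap.landmarks import ReferencePoints


class TestPercentSlice:
    @pytest.mark.parametrize(
        "n1,n5,p,expected",
        [
            (1, 1843, 0, 1),  # p=0 returns N_RP1
            (0, 200, 50, 100),
            (120, 1520, 33, 582),  # 120 + 1400*0.33 = 582
            (0, 300, 100, 300),
        ],
    )
    def test_examples(self, n1, n5, p, expected):
        assert percent_slice(n1, n5, p) == expected

    def test_out_of_range_percent_raises(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            percent_slice(1, 100, 101)

    def test_degenerate_span_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            percent_slice(100, 100, 50)

    @settings(max_examples=50, derandomize=True)
    @given(
        n1=st.integers(0, 500),
        span=st.integers(1, 2000),
        p=st.integers(0, 99),
    )
    def test_monotone_in_percentage_and_exact_at_bounds(self, n1, span, p):
        n5 = n1 + span
        assert percent_slice(n1, n5, 0) == n1
        assert percent_slice(n1, n5, 100) == n5
        assert percent_slice(n1, n5, p) <= percent_slice(n1, n5, p + 1)


class TestThirdsQuarters:
    def test_thirds_of_300_slice_span(self):
        rps = ReferencePoints([1, 100, 150, 200, 301], (0.15, 0.15, 0.15))
        grid = thirds_quarters_grid(rps, "thirds")
        assert grid == [1, 100, 199, 301]  # bounds RL1/RL5 included

    def test_quarters_are_exact(self):
        rps = ReferencePoints([1, 100, 150, 200, 301], (0.15, 0.15, 0.15))
        assert thirds_quarters_grid(rps, "quarters", include_bounds=False) == [76, 151, 226]

    def test_degenerate_span_propagates(self):
        rps = ReferencePoints([5, 5, 5, 5, 5], (0.15, 0.15, 0.15))
        with pytest.raises(ValueError):
            thirds_quarters_grid(rps, "thirds")


def toy_scene(dx=1.0):
    """A 60-slice scene with rectangular footprints and straight ridgelines.

    Lateral spine at x=10 mm, lateral edge at x=30 mm, so the RL6 halving
    point lies at x=20 mm.
    """
    nz, nx = 60, 40
    med = np.zeros((nz, nx), bool)
    lat = np.zeros((nz, nx), bool)
    med[5:56, 2:9] = True
    lat[5:56, 11:31] = True
    ridg = {
        "medial": np.full(nz, 8.0),
        "lateral": np.full(nz, 10.0),
    }
    rps = ReferencePoints([6, 16, 26, 41, 56], (1.0, 1.0, 1.0))
    return rps, {"medial": med, "lateral": lat}, ridg


class TestReferenceLines:
    def test_rl6_passes_through_halving_point(self):
        rps, fps, ridg = toy_scene()
        rls = build_reference_lines(rps, fps, ridg, (1.0, 1.0, 1.0))
        assert rls.rl6[0][1] == pytest.approx(20.0)  # (10 + 30) / 2

    def test_equal_halving_points_give_line_parallel_to_z(self):
        rps, fps, ridg = toy_scene()
        rls = build_reference_lines(rps, fps, ridg, (1.0, 1.0, 1.0))
        xs = rls.rl6_x_at(np.array([0.0, 25.0, 59.0]))
        assert np.allclose(xs, xs[0])

    def test_phantom_lines_match_ground_truth(self, phantom, pipeline):
        _, gt = phantom
        rls = pipeline["lines"]
        dz, _, dx = gt.spacing
        for got, true in ((rls.rl6, gt.rl6), (rls.rl7, gt.rl7)):
            for (za, xa), (zt, xt) in zip(got, true):
                assert abs(xa - xt) <= 2 * dx + 1e-9

    def test_empty_footprint_at_rl3_raises(self):
        rps, fps, ridg = toy_scene()
        fps["lateral"][25] = False
        with pytest.raises(ValueError, match="empty at RL3"):
            build_reference_lines(rps, fps, ridg, (1.0, 1.0, 1.0))

    def test_mostly_undefined_ridgeline_raises(self):
        rps, fps, ridg = toy_scene()
        ridg["medial"][:] = np.nan
        ridg["medial"][25:27] = 8.0
        with pytest.raises(ValueError, match="ridgeline undefined"):
            build_reference_lines(rps, fps, ridg, (1.0, 1.0, 1.0))


class TestPartition:
    def test_twelve_labels_present_on_phantom(self, pipeline):
        assert pipeline["submap"].present_codes() == list(range(1, 13))

    def test_footprints_partitioned_exactly_once(self, pipeline):
        sm = pipeline["submap"]
        fp = pipeline["footprints"]["medial"] | pipeline["footprints"]["lateral"]
        assert not (fp & (sm.labels == 0)).any()  # no unassigned inside
        assert not (~fp & (sm.labels != 0)).any()  # none outside

    def test_subregion_areas_sum_to_footprint_area(self, pipeline):
        sm = pipeline["submap"]
        fp = pipeline["footprints"]["medial"] | pipeline["footprints"]["lateral"]
        total = sum(sm.mask(c).sum() for c in sm.present_codes())
        assert total == fp.sum()

    def test_agreement_with_ground_truth_map(self, phantom, pipeline):
        _, gt = phantom
        sm = pipeline["submap"]
        both = (sm.labels != 0) & (gt.subregion_map != 0)
        agree = (sm.labels == gt.subregion_map)[both].mean()
        assert agree >= 0.97

    def test_overlapping_footprints_raise(self):
        rps, fps, ridg = toy_scene()
        rls = build_reference_lines(rps, fps, ridg, (1.0, 1.0, 1.0))
        fps["medial"][:, 11:13] = True
        with pytest.raises(ValueError, match="overlap"):
            partition_subregions(rls, fps)


class TestAssignPoint:
    def test_point_anterior_of_rl5_is_none(self, pipeline):
        sm = pipeline["submap"]
        i5 = pipeline["rps"].image_numbers[4] - 1
        assert assign_point(i5 + 10, 80, sm) is None

    def test_boundary_slice_goes_to_anterior_band(self, pipeline):
        """A point exactly on the RL3 plane belongs to the intermediate band
        (half-open convention)."""
        sm = pipeline["submap"]
        i3 = pipeline["rps"].image_numbers[2] - 1
        labels = {assign_point(i3, x, sm) for x in range(sm.labels.shape[1])}
        labels.discard(None)
        assert labels and all("intermediate" in lab for lab in labels)

    def test_osteophyte_centroid_maps_to_medial_peripheral(self, oa_phantom, pipeline):
        _, gt = oa_phantom
        zc, _, xc = np.argwhere(gt.osteophyte_mask).mean(axis=0)
        # the centroid lies outside the footprint; nearest footprint column
        sm = pipeline["submap"]
        z, x = int(round(zc)), int(round(xc))
        cols = np.argwhere(sm.labels != 0)
        nearest = cols[np.argmin(((cols - [z, x]) ** 2).sum(axis=1))]
        label = assign_point(*nearest, sm)
        assert label in ("medial_intermediate_peripheral", "medial_anterior_peripheral")

    def test_out_of_bounds_raises(self, pipeline):
        with pytest.raises(IndexError):
            assign_point(-1, 0, pipeline["submap"])

    def test_code_lookup_by_abbreviation(self):
        assert SUBREGION_CODES["MIC"] == SUBREGION_CODES["medial_intermediate_central"]
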