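"""Per-well and per-spheroid quantification and time-course assembly."""

import numpy as np
import pandas as pd
import pytest

from stainquant import (
    ALCIAN_BLUE_8GX,
    ALIZARIN_RED_S,
    OIL_RED_O,
    QuantResult,
    WellMeta,
    assemble_time_course,
    circle_to_mask,
    composite_from_arrays,
    promote_to_float,
    quantify_spheroid,
    quantify_well,
)
from stainquant.synth import (
    DirtBlob,
    StainSpot,
    SyntheticWellSpec,
    generate_spheroid_section,
    generate_well,
)

from conftest import gray_composite


def make_result(well_id, count, roi=1000, **meta):
    return QuantResult(
        positive_count=count, roi_count=roi, area_fraction=count / roi,
        positive_area_um2=float(count), dye="Alizarin Red S",
        meta=WellMeta(well_id=well_id, **meta),
    )


class TestQuantifyWell:
    def test_exact_ground_truth_recovery(self):
        """Measured positive count equals the generator's exact truth."""
        spec = SyntheticWellSpec(
            image_size_px=(256, 256), well_center=(128.0, 128.0), well_radius_px=110.0,
            stain_spots=(StainSpot(110.0, 110.0, 30.0, ratio=3.0, edge_falloff_px=2.0),),
        )
        comp, truth = generate_well(spec)
        roi = circle_to_mask(truth.well_circle, comp.shape)
        res = quantify_well(comp, roi, ALIZARIN_RED_S)
        n, m = int(truth.positive_mask.sum()), roi.pixel_count
        assert res.positive_count == n
        assert res.roi_count == m
        assert res.area_fraction == n / m
        assert res.positive_area_um2 == n * spec.pixel_size_um**2

    @pytest.mark.parametrize("dye", [ALIZARIN_RED_S, OIL_RED_O, ALCIAN_BLUE_8GX])
    def test_uniform_gray_control_is_zero(self, dye):
        comp = gray_composite(25000, shape=(32, 32))
        res = quantify_well(comp, np.ones((32, 32), dtype=bool), dye)
        assert res.positive_count == 0

    def test_all_signal_zero_complement_excluded(self):
        """Pure-signal pixels have an undefined ratio and never count."""
        r = np.full((8, 8), 40000, dtype=np.uint16)
        z = np.zeros((8, 8), dtype=np.uint16)
        comp = composite_from_arrays(r, z, z.copy())
        res = quantify_well(comp, np.ones((8, 8), dtype=bool), ALIZARIN_RED_S)
        assert res.positive_count == 0

    def test_empty_roi_error(self):
        comp = gray_composite(100, shape=(4, 4))
        with pytest.raises(ValueError, match="empty"):
            quantify_well(comp, np.zeros((4, 4), dtype=bool), ALIZARIN_RED_S)

    def test_physical_area_scales_with_pixel_size(self):
        spec = SyntheticWellSpec(
            image_size_px=(128, 128), well_center=(64.0, 64.0), well_radius_px=60.0,
            stain_spots=(StainSpot(64.0, 64.0, 20.0, ratio=3.0),), pixel_size_um=3.0,
        )
        comp, truth = generate_well(spec)
        res = quantify_well(comp, circle_to_mask(truth.well_circle, comp.shape), ALIZARIN_RED_S)
        assert res.positive_area_um2 == res.positive_count * 9.0

    def test_neutral_dirt_changes_nothing(self):
        """Dark neutral debris keeps channel ratios below threshold and is
        never counted: the count equals the spot-only count."""
        base = dict(
            image_size_px=(256, 256), well_center=(128.0, 128.0), well_radius_px=110.0,
            stain_spots=(StainSpot(100.0, 100.0, 25.0, ratio=3.0, edge_falloff_px=2.0),),
        )
        clean_comp, clean_truth = generate_well(SyntheticWellSpec(**base))
        dirty_comp, dirty_truth = generate_well(
            SyntheticWellSpec(**base, dirt_blobs=(
                DirtBlob(170.0, 150.0, 15.0),
                DirtBlob(90.0, 180.0, 10.0, hue=(0.5, 0.45, 0.5)),
            ))
        )
        roi = circle_to_mask(clean_truth.well_circle, clean_comp.shape)
        a = quantify_well(clean_comp, roi, ALIZARIN_RED_S)
        b = quantify_well(dirty_comp, roi, ALIZARIN_RED_S)
        assert a.positive_count == b.positive_count
        np.testing.assert_array_equal(clean_truth.positive_mask, dirty_truth.positive_mask)


class TestQuantifySpheroid:
    def test_half_stained_section(self):
        comp, body, positive = generate_spheroid_section(
            body_radius_px=60.0, stained_radius_px=60.0 / np.sqrt(2)
        )
        res = quantify_spheroid([comp], ALCIAN_BLUE_8GX)
        assert res.pooled_fraction == pytest.approx(positive.sum() / body.sum(), abs=1e-12)
        assert res.pooled_fraction == pytest.approx(0.5, abs=0.02)

    def test_unstained_sections_are_zero(self):
        sections = [generate_spheroid_section(seed=s)[0] for s in (1, 2)]
        res = quantify_spheroid(sections, ALCIAN_BLUE_8GX)
        assert res.pooled_fraction == 0.0

    def test_pooling_is_pixel_weighted_not_mean_of_fractions(self):
        """Sections with fractions 0.2 (100 px body) and 0.8 (300 px body)
        pool to (20+240)/400 = 0.65, not the unweighted mean 0.5."""
        from conftest import rectangular_section

        s1 = rectangular_section(100, 20)
        s2 = rectangular_section(300, 240)
        res = quantify_spheroid([s1, s2], ALCIAN_BLUE_8GX)
        assert res.per_section == ((20, 100), (240, 300))
        assert res.section_fractions == (0.2, 0.8)
        assert res.pooled_fraction == pytest.approx(0.65, abs=1e-12)
        assert res.pooled_fraction != pytest.approx(np.mean([0.2, 0.8]))

    def test_pooled_fraction_from_rendered_sections(self):
        """End-to-end pooling across two rendered sections matches the sum
        of per-section truths over the sum of body areas."""
        s1 = generate_spheroid_section(body_radius_px=40.0, stained_radius_px=20.0)
        s2 = generate_spheroid_section(body_radius_px=80.0, stained_radius_px=70.0)
        res = quantify_spheroid([s1[0], s2[0]], ALCIAN_BLUE_8GX)
        expected = (s1[2].sum() + s2[2].sum()) / (s1[1].sum() + s2[1].sum())
        assert res.pooled_fraction == pytest.approx(expected, abs=1e-12)

    def test_section_order_irrelevant(self):
        a = generate_spheroid_section(body_radius_px=40.0, stained_radius_px=25.0)[0]
        b = generate_spheroid_section(body_radius_px=70.0, stained_radius_px=30.0)[0]
        assert (
            quantify_spheroid([a, b], ALCIAN_BLUE_8GX).pooled_fraction
            == quantify_spheroid([b, a], ALCIAN_BLUE_8GX).pooled_fraction
        )

    def test_empty_input_and_blank_section_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            quantify_spheroid([], ALCIAN_BLUE_8GX)
        with pytest.raises(ValueError, match="section 0"):
            quantify_spheroid([gray_composite(60000, (32, 32), promoted=False)], ALCIAN_BLUE_8GX)


class TestTimeCourse:
    def test_mean_and_sample_sd(self):
        results = [
            make_result(f"w{i}", c, cell_line="F14", lineage="osteo",
                        condition="differentiated", timepoint_days=14.0)
            for i, c in enumerate([10, 20, 30])
        ]
        replicates, summary = assemble_time_course(results)
        assert len(replicates) == 3
        row = summary.iloc[0]
        assert row["mean"] == 20.0
        assert row["sd"] == pytest.approx(10.0)  # sample SD, ddof=1
        assert row["n"] == 3

    def test_single_replicate_sd_flagged_nan(self):
        results = [make_result("w0", 42, cell_line="F14", lineage="osteo",
                               condition="differentiated", timepoint_days=14.0)]
        _, summary = assemble_time_course(results)
        assert summary.iloc[0]["mean"] == 42.0
        assert pd.isna(summary.iloc[0]["sd"])

    def test_empty_input_gives_empty_tables(self):
        replicates, summary = assemble_time_course([])
        assert replicates.empty and summary.empty

    def test_duplicate_well_timepoint_rejected(self):
        results = [make_result("w0", 1, timepoint_days=14.0),
                   make_result("w0", 2, timepoint_days=14.0)]
        with pytest.raises(ValueError, match="duplicate"):
            assemble_time_course(results)

    def test_permutation_invariance(self):
        results = [
            make_result(f"w{i}", c, cell_line="F27", lineage="adipo",
                        condition="differentiated", timepoint_days=t)
            for i, (c, t) in enumerate([(5, 14.0), (9, 17.0), (7, 14.0), (3, 21.0)])
        ]
        _, s1 = assemble_time_course(results)
        _, s2 = assemble_time_course(list(reversed(results)))
        pd.testing.assert_frame_equal(s1, s2)
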