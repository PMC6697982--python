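import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from skimage import draw as skdraw

from synspread import morphometry as mm
from synspread import synthetic_data as sd

# area cutoffs re-scaled to the synthetic fixtures (the published 2000-px
# value is tied to full-resolution 60x acquisition)
BODY_MIN = 300
PROC_MIN = 30


def disc_mask(r, shape=(256, 256), center=None):
    m = np.zeros(shape, bool)
    rr, cc = skdraw.disk(center or (shape[0] // 2, shape[1] // 2), r, shape=shape)
    m[rr, cc] = True
    return m


class TestDynamicThreshold:
    def test_gaussian_image_yields_analytic_fwhm_band(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 10, (256, 256))
        band = mm.dynamic_threshold(img)
        assert band.low == pytest.approx(100 - 11.774, abs=0.8)
        assert band.high == pytest.approx(100 + 11.774, abs=0.8)

    def test_constant_image_raises_degenerate_error(self):
        with pytest.raises(mm.DegenerateHistogramError):
            mm.dynamic_threshold(np.full((64, 64), 7.0))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(mu=hst.floats(10, 200), sigma=hst.floats(0.5, 40),
           seed=hst.integers(0, 10 ** 6))
    def test_band_endpoints_stay_within_image_range(self, mu, sigma, seed):
        img = np.random.default_rng(seed).normal(mu, sigma, (64, 64))
        band = mm.dynamic_threshold(img)
        assert img.min() <= band.low <= band.high <= img.max()


class TestSegmentCellBodies:
    def test_single_interior_cell_above_cutoff_yields_one_region(self, paint_section):
        sec = paint_section(discs=[(200, 200, 40)])  # ~5000 px
        regions = mm.segment_cell_bodies(sec)  # published 2000-px default
        assert len(regions) == 1

    def test_cell_under_2000_px_is_removed(self, paint_section):
        sec = paint_section(discs=[(200, 200, 21)])  # ~1385 px < 2000
        assert len(mm.segment_cell_bodies(sec)) == 0

    def test_cell_touching_border_is_removed(self, paint_section):
        sec = paint_section(discs=[(10, 200, 40)])  # intersects top border
        assert len(mm.segment_cell_bodies(sec)) == 0

    def test_cell_free_image_yields_empty_result_not_error(self, paint_section):
        sec = paint_section(discs=[])
        assert len(mm.segment_cell_bodies(sec)) == 0


class TestSegmentProcesses:
    def test_uniform_image_gives_empty_process_mask(self):
        sec = mm.RGBSection(np.full((200, 200, 3), 128, np.uint8), 0.25)
        bodies = mm.LabeledRegions.from_mask(np.zeros((200, 200), bool))
        assert mm.segment_processes(sec, bodies, area_min_px=PROC_MIN).sum() == 0

    @pytest.mark.parametrize("seed", [4, 7, 9])
    def test_ramified_cell_final_mask_exceeds_body_mask(self, seed):
        cfg = sd.SectionSimConfig(seed=seed, n_ramified=1, n_amoeboid=0,
                                  noise_sd=0.0)
        sec, _ = sd.make_section_image(cfg)
        bodies = mm.segment_cell_bodies(sec, area_min_px=BODY_MIN)
        full = mm.segment_processes(sec, bodies, area_min_px=PROC_MIN)
        assert full.sum() > (bodies.label_image > 0).sum()

    def test_amoeboid_final_mask_stays_near_body_plus_outline(self):
        from scipy import ndimage

        from skimage import morphology as skmorph
        cfg = sd.SectionSimConfig(seed=5, n_ramified=0, n_amoeboid=1,
                                  noise_sd=0.0)
        sec, _ = sd.make_section_image(cfg)
        bodies = mm.segment_cell_bodies(sec, area_min_px=BODY_MIN)
        body = bodies.label_image > 0
        full = mm.segment_processes(sec, bodies, area_min_px=PROC_MIN)
        assert (full & body).sum() == body.sum()  # final ⊇ body
        hull = ndimage.binary_dilation(body, skmorph.disk(8))
        assert (full & ~hull).sum() == 0  # nothing beyond the dilated outline


class TestHydraulicRadius:
    def test_disc_square_and_strip_match_continuous_ratios(self):
        disc = disc_mask(50, (201, 201))
        assert mm.hydraulic_radius(disc).hydraulic_radius_px == pytest.approx(25.0, rel=0.05)
        sq = np.zeros((201, 201), bool)
        sq[50:150, 50:150] = True
        assert mm.hydraulic_radius(sq).hydraulic_radius_px == pytest.approx(25.0, rel=0.05)
        strip = np.zeros((11, 300), bool)
        strip[5, 50:250] = True
        assert mm.hydraulic_radius(strip).hydraulic_radius_px == pytest.approx(0.5, rel=0.05)

    def test_crofton_estimator_still_available_and_near_exact_on_disc(self):
        rec = mm.hydraulic_radius(disc_mask(50, (201, 201)), estimator="crofton")
        assert rec.hydraulic_radius_px == pytest.approx(25.0, rel=0.05)

    def test_index_scales_linearly_with_resolution(self):
        # upsampling 2x should double the pixel-space index (within 5%)
        r30 = mm.hydraulic_radius(disc_mask(30, (101, 101))).hydraulic_radius_px
        r60 = mm.hydraulic_radius(disc_mask(60, (201, 201))).hydraulic_radius_px
        assert r60 / r30 == pytest.approx(2.0, rel=0.05)

    def test_disc_maximizes_index_at_fixed_area(self):
        area = float(disc_mask(50, (221, 221)).sum())
        disc = mm.hydraulic_radius(disc_mask(50, (221, 221))).hydraulic_radius_px
        side = int(round(np.sqrt(area)))
        sq = np.zeros((221, 221), bool)
        sq[10:10 + side, 10:10 + side] = True
        square = mm.hydraulic_radius(sq).hydraulic_radius_px
        arm = int(round(area / (3 * 20)))  # cross with 20-px-wide arms
        cross = np.zeros((arm + 60, arm + 60), bool)
        c = (arm + 60) // 2
        cross[c - 10:c + 10, 20:20 + arm] = True
        cross[20:20 + arm, c - 10:c + 10] = True
        cross_hr = mm.hydraulic_radius(cross).hydraulic_radius_px
        assert disc > square > cross_hr

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            mm.hydraulic_radius(np.zeros((10, 10), bool))

    def test_physical_units_follow_pixel_size(self):
        rec = mm.hydraulic_radius(disc_mask(30, (101, 101)), pixel_size=0.25)
        assert rec.hydraulic_radius_um == pytest.approx(
            rec.hydraulic_radius_px * 0.25)
        assert rec.area_um2 == pytest.approx(rec.area_px * 0.0625)


class TestSelectCells:
    def test_auto_mode_keeps_clean_interior_regions(self, paint_section):
        sec = paint_section(discs=[(120, 120, 40), (280, 280, 40)])
        regions = mm.segment_cell_bodies(sec)
        assert len(mm.select_cells(regions, area_bounds=(2000, 10 ** 6))) == 2

    def test_border_region_never_selected(self):
        mask = np.zeros((100, 100), bool)
        mask[0:30, 40:70] = True  # touches row 0
        regions = mm.LabeledRegions.from_mask(mask)
        assert len(mm.select_cells(regions, area_bounds=(1, 10 ** 6))) == 0

    def test_replay_mode_reproduces_recorded_choices(self, paint_section):
        sec = paint_section(discs=[(120, 120, 40), (280, 280, 40)])
        regions = mm.segment_cell_bodies(sec)
        choices = {1: True, 2: False}
        sel = mm.select_cells(regions, mode="replay", choices=choices)
        assert list(sel) == [1]
        assert list(mm.select_cells(regions, mode="replay", choices=choices)) == [1]

    def test_unknown_mode_rejected(self):
        regions = mm.LabeledRegions.from_mask(np.zeros((10, 10), bool))
        with pytest.raises(ValueError):
            mm.select_cells(regions, mode="manual")


class TestIba1Density:
    def test_ten_cells_in_quarter_square_millimetre(self):
        # 0.25 mm^2 at 1 um/px is a 500x500 px square
        roi = [(0, 0), (0, 500), (500, 500), (500, 0)]
        pts = np.column_stack([np.linspace(50, 450, 10), np.full(10, 250)])
        rec = mm.iba1_density(pts, roi, pixel_size=1.0)
        assert rec.density_per_mm2 == pytest.approx(40.0)

    def test_empty_roi_region_gives_zero_density(self):
        roi = [(0, 0), (0, 100), (100, 100), (100, 0)]
        rec = mm.iba1_density(np.empty((0, 2)), roi, pixel_size=1.0)
        assert rec.n_cells == 0 and rec.density_per_mm2 == 0.0

    def test_density_invariant_to_joint_translation(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(20, 180, size=(25, 2))
        roi = [(0, 0), (0, 200), (200, 200), (200, 0)]
        d0 = mm.iba1_density(pts, roi, 2.0).density_per_mm2
        shift = np.array([37.0, 51.0])
        roi2 = [(y + shift[0], x + shift[1]) for y, x in roi]
        d1 = mm.iba1_density(pts + shift, roi2, 2.0).density_per_mm2
        assert d0 == pytest.approx(d1)

    def test_zero_area_roi_raises(self):
        with pytest.raises(ValueError):
            mm.iba1_density(np.empty((0, 2)), [(0, 0), (0, 0), (0, 0)], 1.0)


class TestActivationIndexSummary:
    def test_amoeboid_group_scores_above_ramified_group(self):
        rows = []
        for group, (n_ram, n_amo) in {"activated": (0, 4), "resting": (4, 0)}.items():
            for animal in range(2):
                cfg = sd.SectionSimConfig(seed=hash((group, animal)) % 1000,
                                          n_ramified=n_ram, n_amoeboid=n_amo)
                sec, _ = sd.make_section_image(cfg)
                cells = mm.measure_section_cells(sec, body_area_min_px=BODY_MIN,
                                                 process_area_min_px=PROC_MIN)
                for _, r in cells.iterrows():
                    rows.append(dict(group=group, animal_id=f"{group}{animal}",
                                     hydraulic_radius_um=r.hydraulic_radius_um))
        summary = mm.activation_index_summary(pd.DataFrame(rows))
        by = summary.set_index("group")
        assert by.loc["activated", "mean"] > by.loc["resting", "mean"]

    def test_single_animal_group_reports_missing_sem(self):
        df = pd.DataFrame(dict(group=["a"], animal_id=["m1"],
                               hydraulic_radius_um=[5.0]))
        out = mm.activation_index_summary(df)
        assert np.isnan(out.loc[0, "sem"])

    def test_identical_animals_give_zero_sem(self):
        df = pd.DataFrame(dict(group=["a"] * 2, animal_id=["m1", "m2"],
                               hydraulic_radius_um=[5.0, 5.0]))
        assert mm.activation_index_summary(df).loc[0, "sem"] == 0.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mm.activation_index_summary(pd.DataFrame(
                columns=["group", "animal_id", "hydraulic_radius_um"]))
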