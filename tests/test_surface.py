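"""Surface-mask construction and densitometry arithmetic, checked against
brute-force dilation and hand-computed values."""

import numpy as np
import pytest

from oracles import brute_force_ribbon
from sgquant.segmentation import classify_borders
from sgquant.surface import (
    build_surface_mask,
    classify_responders,
    measure_surface_intensity,
    subtract_background,
    summarize_population,
)
from sgquant.types import (
    CellIntensityRecord,
    CellLabelMap,
    MultiChannelScene,
    SurfaceMask,
)


def _record(cid, mean, stage="interphase", area=10, corrected=None):
    return CellIntensityRecord(
        cell_id=cid, stage_class=stage, total_intensity=mean * area,
        mask_area=area, mean_intensity=mean, corrected_mean=corrected,
    )


class TestBuildSurfaceMask:
    def test_straight_border_ribbon_matches_brute_force_dilation(self):
        # a 1-px-wide horizontal bar cell: every pixel is outer border
        labels = np.zeros((15, 30), dtype=np.int32)
        labels[7, 8:20] = 1
        borders = classify_borders(CellLabelMap(labels))
        mask = build_surface_mask(borders, width_each_side=3)
        got = set(map(tuple, mask.pixels[1]))
        oracle = brute_force_ribbon(labels, map(tuple, borders.outer[1]), 1, 3)
        assert got == oracle
        # 7-px ribbon: (L + 6) * 7 pixels for a straight segment of length L
        assert len(got) == (12 + 6) * 7

    def test_width_zero_is_the_outer_border_itself(self, two_square_labels):
        borders = classify_borders(CellLabelMap(two_square_labels))
        mask = build_surface_mask(borders, width_each_side=0)
        for cid in (1, 2):
            assert set(map(tuple, mask.pixels[cid])) == set(
                map(tuple, borders.outer[cid])
            )

    def test_ribbon_never_enters_the_neighbouring_cell(self, two_square_labels):
        borders = classify_borders(CellLabelMap(two_square_labels))
        mask = build_surface_mask(borders, width_each_side=3)
        for cid, other in ((1, 2), (2, 1)):
            ribbon = set(map(tuple, mask.pixels[cid]))
            neighbour = set(map(tuple, np.argwhere(two_square_labels == other)))
            assert ribbon.isdisjoint(neighbour)
            oracle = brute_force_ribbon(
                two_square_labels, map(tuple, borders.outer[cid]), cid, 3
            )
            assert ribbon == oracle

    def test_edge_touching_cell_is_flagged_unquantifiable(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[0:6, 0:6] = 1   # touches the frame
        labels[8:13, 8:13] = 2
        borders = classify_borders(CellLabelMap(labels))
        mask = build_surface_mask(borders, width_each_side=3)
        assert 1 in mask.excluded and "edge" in mask.excluded[1]
        assert 1 not in mask.pixels and 2 in mask.pixels


class TestMeasurement:
    def test_uniform_image_gives_the_constant_mean(self, two_square_labels):
        borders = classify_borders(CellLabelMap(two_square_labels))
        mask = build_surface_mask(borders, width_each_side=2)
        scene = MultiChannelScene(channels={"SgII": np.full((20, 20), 7.5)})
        for r in measure_surface_intensity(scene, mask):
            assert r.mean_intensity == 7.5
            assert r.total_intensity == 7.5 * r.mask_area

    def test_hand_defined_mask_arithmetic(self):
        img = np.arange(25, dtype=float).reshape(5, 5)
        pixels = np.array([(0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (0, 4)])
        mask = SurfaceMask(pixels={1: pixels}, width_each_side=1)
        scene = MultiChannelScene(channels={"SgII": img})
        (rec,) = measure_surface_intensity(scene, mask)
        assert rec.total_intensity == 0 + 6 + 12 + 18 + 24 + 4
        assert rec.mean_intensity == 64 / 6
        assert rec.mask_area == 6

    def test_mean_is_exactly_total_over_area(self, two_square_labels):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 50, size=(20, 20))
        borders = classify_borders(CellLabelMap(two_square_labels))
        mask = build_surface_mask(borders, width_each_side=3)
        for r in measure_surface_intensity(
            MultiChannelScene(channels={"SgII": img}), mask
        ):
            assert r.mean_intensity == r.total_intensity / r.mask_area

    def test_additivity_over_a_mask_split(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 10, size=(9, 9))
        coords = np.argwhere(np.ones((9, 9), dtype=bool))[: 40]
        whole = SurfaceMask(pixels={1: coords}, width_each_side=3)
        part_a = SurfaceMask(pixels={1: coords[:17]}, width_each_side=3)
        part_b = SurfaceMask(pixels={1: coords[17:]}, width_each_side=3)
        scene = MultiChannelScene(channels={"SgII": img})
        (w,) = measure_surface_intensity(scene, whole)
        (a,) = measure_surface_intensity(scene, part_a)
        (b,) = measure_surface_intensity(scene, part_b)
        assert w.total_intensity == pytest.approx(a.total_intensity + b.total_intensity)
        recombined = (
            a.mean_intensity * a.mask_area + b.mean_intensity * b.mask_area
        ) / (a.mask_area + b.mask_area)
        assert w.mean_intensity == pytest.approx(recombined)


class TestBackgroundAndClassification:
    def test_hand_worked_background_subtraction(self):
        stim = [_record(1, 2.0), _record(2, 0.5)]
        ctrl = [_record(11, 0.4), _record(12, 0.6)]
        corrected, background = subtract_background(stim, ctrl)
        assert background == pytest.approx(0.5)
        assert [r.corrected_mean for r in corrected] == pytest.approx([1.5, 0.0])

    def test_self_subtraction_zeroes_identical_records(self):
        recs = [_record(1, 1.25), _record(2, 1.25)]
        corrected, _ = subtract_background(recs, recs)
        assert all(r.corrected_mean == pytest.approx(0.0) for r in corrected)
        # in general self-subtraction centres the population at zero
        recs = [_record(1, 1.0), _record(2, 3.0)]
        corrected, _ = subtract_background(recs, recs)
        assert sum(r.corrected_mean for r in corrected) == pytest.approx(0.0)

    def test_empty_controls_are_an_error(self):
        with pytest.raises(ValueError, match="control"):
            subtract_background([_record(1, 1.0)], [])

    def test_responder_rule_and_fraction(self):
        recs = [
            _record(1, 0.0, corrected=-1.0),
            _record(2, 0.0, corrected=0.2),
            _record(3, 0.0, corrected=3.0),
        ]
        flagged, fractions = classify_responders(recs)
        assert [r.responder for r in flagged] == [False, True, True]
        assert fractions["interphase"] == pytest.approx(100 * 2 / 3)

    def test_zero_corrected_means_are_non_responders(self):
        recs = [_record(i, 0.0, corrected=0.0) for i in range(1, 4)]
        _, fractions = classify_responders(recs)
        assert fractions["interphase"] == 0.0

    def test_summary_relative_intensity_hand_example(self):
        recs = [
            _record(1, 0.0, "interphase", corrected=2.0),
            _record(2, 0.0, "interphase", corrected=4.0),
            _record(3, 0.0, "metaphase", corrected=1.5),
            _record(4, 0.0, "metaphase", corrected=1.5),
        ]
        summary = summarize_population(recs)
        assert summary.relative_intensity_pct == pytest.approx(50.0)
        assert summary.responder_fraction_pct == {"interphase": 100.0, "metaphase": 100.0}

    def test_identical_class_distributions_give_100_percent(self):
        recs = [
            _record(1, 0.0, "interphase", corrected=2.0),
            _record(2, 0.0, "metaphase", corrected=2.0),
        ]
        assert summarize_population(recs).relative_intensity_pct == pytest.approx(100.0)

    def test_missing_class_yields_partial_summary(self):
        recs = [_record(1, 0.0, "interphase", corrected=1.0)]
        summary = summarize_population(recs)
        assert summary.relative_intensity_pct is None
        assert "metaphase" not in summary.n_cells


class TestPipelineInvariants:
    def test_background_shift_equivariance(self):
        """Adding a constant to the SgII channel of both arms leaves every
        corrected mean unchanged."""
        from sgquant.pipeline import run_exocytosis
        from sgquant.synth import presets, generate_fluorescence_scene
        from sgquant.synth.fluor import control_params

        p = presets.get("fluor_stimulated", n_cells=4, seed=21)
        stim, _ = generate_fluorescence_scene(p)
        ctrl, _ = generate_fluorescence_scene(control_params(p))
        base = run_exocytosis(stim, ctrl)

        def shifted(scene, c):
            ch = dict(scene.channels)
            ch["SgII"] = ch["SgII"] + c
            return MultiChannelScene(ch, scene.pixel_size_nm, scene.annotations)

        shifted_res = run_exocytosis(shifted(stim, 11.0), shifted(ctrl, 11.0))
        got = {r.cell_id: r.corrected_mean for r in shifted_res.records}
        for r in base.records:
            assert got[r.cell_id] == pytest.approx(r.corrected_mean, abs=1e-9)

    def test_ribbon_monotonicity_and_locality(self, two_square_labels):
        borders = classify_borders(CellLabelMap(two_square_labels))
        mask = build_surface_mask(borders, width_each_side=2)
        img = np.full((20, 20), 5.0)
        scene = MultiChannelScene(channels={"SgII": img})
        base = {r.cell_id: r.mean_intensity for r in measure_surface_intensity(scene, mask)}
        # bump one pixel that lies only in cell 1's ribbon
        only_1 = set(map(tuple, mask.pixels[1])) - set(map(tuple, mask.pixels[2]))
        r0, c0 = sorted(only_1)[0]
        img2 = img.copy()
        img2[r0, c0] += 100.0
        bumped = {
            r.cell_id: r.mean_intensity
            for r in measure_surface_intensity(
                MultiChannelScene(channels={"SgII": img2}), mask
            )
        }
        assert bumped[1] > base[1]
        assert bumped[2] == base[2]
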