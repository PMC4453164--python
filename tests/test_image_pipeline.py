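"""Per-cell image analysis: segmentation, gating, QC, poles, summaries."""

import numpy as np
import pandas as pd
import pytest

from conftest import disc_mask, gaussian_spot
from spindlescreen import image_pipeline as ip
from spindlescreen.image_pipeline import PipelineParams
from spindlescreen.synthetic_data import (CellSpec, FieldImage, FieldSimConfig,
                                          random_cell_layout, ring_poles,
                                          simulate_field)


class TestSegmentNuclei:
    def test_blank_image_yields_zero_nuclei(self, params):
        labels, recs = ip.segment_nuclei(np.zeros((64, 64)), params)
        assert labels.max() == 0
        assert recs.empty

    def test_two_disjoint_nuclei_recovered_within_2px(self, params):
        img = (gaussian_spot((128, 128), (40, 40), 6, 120)
               + gaussian_spot((128, 128), (90, 90), 6, 120) + 5.0)
        labels, recs = ip.segment_nuclei(img, params)
        assert len(recs) == 2
        found = sorted(zip(recs["centroid_r"], recs["centroid_c"]))
        for (fr, fc), (tr, tc) in zip(found, [(40, 40), (90, 90)]):
            assert abs(fr - tr) < 2 and abs(fc - tc) < 2

    def test_touching_nuclei_split_by_watershed(self, params):
        # two nuclei close enough that their Otsu masks fuse, but with an
        # intensity valley along the inter-centroid line
        img = (gaussian_spot((96, 96), (48, 38), 6, 120)
               + gaussian_spot((96, 96), (48, 58), 6, 120) + 5.0)
        profile = img[48, 38:59]
        assert profile.min() < profile[0] and profile.min() < profile[-1]  # valley exists
        labels, recs = ip.segment_nuclei(img, params)
        assert len(recs) == 2


def make_simple_field(seed=0, n_interphase=45, pole_counts=(2, 2, 2, 2, 2),
                      cell_radius=14.0, field_size=(640, 640), **kwargs):
    rng = np.random.default_rng(seed)
    cells = random_cell_layout(rng, field_size, n_interphase, list(pole_counts),
                               cell_radius=cell_radius, **kwargs)
    cfg = FieldSimConfig(field_size=field_size, cells=cells, seed=seed, eight_bit=True)
    return simulate_field(cfg)


class TestClassifyMitotic:
    def test_constant_phh3_extremes(self, params):
        labels = np.zeros((32, 32), np.int32)
        labels[4:8, 4:8] = 1
        labels[20:24, 20:24] = 2
        recs = pd.DataFrame({"label": [1, 2], "centroid_r": [5.5, 21.5],
                             "centroid_c": [5.5, 21.5], "area": [16, 16],
                             "mean_dna": [50.0, 50.0]})
        p_lo = PipelineParams(phh3_threshold=10.0)
        out = ip.classify_mitotic(recs, labels, np.zeros((32, 32)), p_lo)
        assert not out["is_mitotic"].any()
        out = ip.classify_mitotic(recs, labels, np.full((32, 32), 99.0), p_lo)
        assert out["is_mitotic"].all()

    def test_auto_threshold_recovers_mitotic_index(self):
        image, truth = make_simple_field(seed=4)
        labels, recs = ip.segment_nuclei(image["dna"])
        recs = ip.classify_mitotic(recs, labels, image["phh3"])
        mi = recs["is_mitotic"].mean()
        assert recs.shape[0] == 50  # all nuclei found
        assert mi == pytest.approx(5 / 50, abs=1e-9)

    def test_auto_threshold_needs_ten_nuclei(self):
        with pytest.raises(ValueError, match="10 nuclei"):
            ip.auto_phh3_threshold(np.arange(5, dtype=float))


class TestSegmentMitoticCells:
    def test_mask_area_close_to_truth_and_disjoint(self, params):
        image, truth = make_simple_field(seed=7, n_interphase=6,
                                         pole_counts=(2, 2), cell_radius=22.0,
                                         field_size=(300, 300))
        labels, recs = ip.segment_nuclei(image["dna"], params)
        recs = ip.classify_mitotic(recs, labels, image["phh3"],
                                   PipelineParams(phh3_threshold=20.0))
        cells = ip.segment_mitotic_cells(image["rfp"], recs, labels, params)
        assert len(cells) == 2
        true_area = np.pi * 22.0**2
        masks = [c["mask"] for c in cells.values()]
        for m in masks:
            assert abs(m.sum() - true_area) / true_area < 0.15
        assert not (masks[0] & masks[1]).any()

    def test_border_cell_flagged(self, params):
        cell = CellSpec(center=(10.0, 64.0), kind="mitotic", cell_radius=20.0,
                        n_poles=2, pole_positions=ring_poles((10.0, 64.0), 20.0, 2))
        cfg = FieldSimConfig(field_size=(128, 128), cells=(cell,), seed=1)
        image, _ = simulate_field(cfg)
        labels, recs = ip.segment_nuclei(image["dna"], params)
        recs = ip.classify_mitotic(recs, labels, image["phh3"],
                                   PipelineParams(phh3_threshold=20.0))
        cells = ip.segment_mitotic_cells(image["rfp"], recs, labels, params)
        assert len(cells) == 1
        assert next(iter(cells.values()))["touches_edge"]


class TestQCFilter:
    def test_disc_kept_line_excluded(self, params):
        disc = disc_mask((64, 64), (32, 32), 20)
        line = np.zeros((64, 64), bool)
        line[10, 20:40] = True
        tub = np.full((64, 64), 100.0)
        cells = {1: {"mask": disc, "touches_edge": False},
                 2: {"mask": line, "touches_edge": False}}
        out = ip.qc_filter(cells, tub, params)
        assert out[1]["roundness"] > 0.8 and out[1]["exclusion_reason"] == "none"
        assert out[2]["roundness"] < 0.8 and out[2]["exclusion_reason"] == "roundness"

    def test_line_roundness_matches_isoperimetric_formula(self):
        # 1x20 line: naive boundary-walk perimeter, same 4-connected notion
        line = np.zeros((32, 32), bool)
        line[10, 5:25] = True
        r = ip.roundness(line)
        assert r < 0.8 / 2  # far below any plausible QC cut

    def test_tubulin_boundary_is_strict(self, params):
        disc = disc_mask((64, 64), (32, 32), 20)
        cells = {1: {"mask": disc, "touches_edge": False}}
        out = ip.qc_filter(cells, np.full((64, 64), 29.9), params)
        assert out[1]["exclusion_reason"] == "low_tubulin"
        cells = {1: {"mask": disc.copy(), "touches_edge": False}}
        out = ip.qc_filter(cells, np.full((64, 64), 30.0), params)
        assert out[1]["exclusion_reason"] == "none"  # strict '<' keeps exactly 30

    def test_edge_takes_precedence(self, params):
        line = np.zeros((64, 64), bool)
        line[0, 20:40] = True
        cells = {1: {"mask": line, "touches_edge": True}}
        out = ip.qc_filter(cells, np.zeros((64, 64)), params)
        assert out[1]["exclusion_reason"] == "edge"


class TestDetectSpindlePoles:
    def test_uniform_signal_gives_zero_poles(self, params, spot_patch):
        img, mask = spot_patch([])
        assert ip.detect_spindle_poles(img, mask, params) == []

    def test_two_and_four_foci_counted(self, params, spot_patch):
        img, mask = spot_patch([(32, 20), (32, 44)])
        assert len(ip.detect_spindle_poles(img, mask, params)) == 2
        img, mask = spot_patch([(20, 20), (20, 44), (44, 20), (44, 44)])
        assert len(ip.detect_spindle_poles(img, mask, params)) == 4

    def test_close_foci_merge_to_one(self, params, spot_patch):
        counts = {}
        for sep in (24, 16, 10, 6, 4):
            img, mask = spot_patch([(32, 32 - sep // 2), (32, 32 + sep // 2)])
            counts[sep] = len(ip.detect_spindle_poles(img, mask, params))
        assert counts[24] == 2
        assert counts[4] == 1
        # monotone transition: once merged, closer stays merged
        seps = sorted(counts)
        merged = [counts[s] == 1 for s in seps]
        assert merged == sorted(merged, reverse=True)

    def test_empty_mask_raises_small_mask_warns(self, params):
        with pytest.raises(ValueError, match="empty"):
            ip.detect_spindle_poles(np.zeros((8, 8)), np.zeros((8, 8), bool), params)
        tiny = np.zeros((8, 8), bool)
        tiny[3:5, 3:5] = True
        with pytest.warns(UserWarning, match="smaller than the smoothing kernel"):
            assert ip.detect_spindle_poles(np.ones((8, 8)), tiny, params) == []

    def test_intensity_scale_invariance(self, params, spot_patch):
        img, mask = spot_patch([(32, 20), (32, 44), (20, 32)], noise_sd=1.5)
        ref = ip.detect_spindle_poles(img, mask, params)
        for c in (0.1, 3.0, 117.0):
            scaled = ip.detect_spindle_poles(c * img, mask, params)
            assert [p.position for p in scaled] == [p.position for p in ref]
            np.testing.assert_allclose([p.relative_intensity for p in scaled],
                                       [p.relative_intensity for p in ref])

    def test_translation_moves_poles_exactly(self, params, spot_patch):
        img, mask = spot_patch([(30, 24), (30, 40)], shape=(96, 96), noise_sd=1.0)
        ref = ip.detect_spindle_poles(img, mask, params)
        shifted = np.roll(np.roll(img, 5, axis=0), -3, axis=1)
        smask = np.roll(np.roll(mask, 5, axis=0), -3, axis=1)
        out = ip.detect_spindle_poles(shifted, smask, params)
        assert [(r + 5, c - 3) for r, c in (p.position for p in ref)] == \
               [p.position for p in out]


@pytest.mark.parametrize("n_poles,expected", [(0, False), (2, False), (3, True), (5, True)])
def test_classify_multipolar_threshold(n_poles, expected, params):
    assert ip.classify_multipolar(n_poles, params) is expected


class TestDetectMultinucleate:
    def _field(self, binucleate, n_interphase, seed=11):
        rng = np.random.default_rng(seed)
        cells = []
        layout = random_cell_layout(rng, (640, 640), n_interphase, [],
                                    cell_radius=20.0)
        for i, c in enumerate(layout):
            n_nuc = 2 if i < binucleate else 1
            cells.append(CellSpec(center=c.center, kind="interphase",
                                  cell_radius=20.0, n_nuclei=n_nuc))
        cfg = FieldSimConfig(field_size=(640, 640), cells=tuple(cells), seed=seed,
                             eight_bit=True)
        return simulate_field(cfg)

    def test_all_mononucleate_gives_zero(self, params):
        image, _ = self._field(binucleate=0, n_interphase=12)
        labels, recs = ip.segment_nuclei(image["dna"], params)
        recs = ip.classify_mitotic(recs, labels, image["phh3"],
                                   PipelineParams(phh3_threshold=20.0))
        bodies = ip.detect_multinucleate(image["rfp"], recs, labels, params)
        assert len(bodies) == 12
        assert bodies["is_multinucleate"].sum() == 0

    def test_three_binucleate_of_thirty_is_ten_percent(self, params):
        image, _ = self._field(binucleate=3, n_interphase=30)
        labels, recs = ip.segment_nuclei(image["dna"], params)
        recs = ip.classify_mitotic(recs, labels, image["phh3"],
                                   PipelineParams(phh3_threshold=20.0))
        bodies = ip.detect_multinucleate(image["rfp"], recs, labels, params)
        ok = bodies[~bodies["touches_edge"]]
        assert 100.0 * ok["is_multinucleate"].mean() == pytest.approx(10.0)

    def test_edge_body_excluded_from_denominator(self, params):
        cells = (CellSpec(center=(12.0, 60.0), kind="interphase", cell_radius=18.0,
                          n_nuclei=2),
                 CellSpec(center=(80.0, 60.0), kind="interphase", cell_radius=18.0))
        cfg = FieldSimConfig(field_size=(120, 120), cells=cells, seed=3, eight_bit=True)
        image, _ = simulate_field(cfg)
        labels, recs = ip.segment_nuclei(image["dna"], params)
        recs = ip.classify_mitotic(recs, labels, image["phh3"],
                                   PipelineParams(phh3_threshold=20.0))
        bodies = ip.detect_multinucleate(image["rfp"], recs, labels, params)
        edge = bodies[bodies["touches_edge"]]
        assert len(edge) == 1 and bool(edge["is_multinucleate"].iloc[0])
        kept = bodies[~bodies["touches_edge"]]
        assert kept["is_multinucleate"].sum() == 0


class TestMeasureSpindleIntensity:
    def _scene(self, marker_levels):
        dna = np.full((256, 256), 5.0)
        marker = np.zeros((256, 256))
        centers = [(60, 60), (60, 190), (190, 60), (190, 190)][:len(marker_levels)]
        for (r, c), level in zip(centers, marker_levels):
            dna += gaussian_spot((256, 256), (r, c), 5, 200)
            marker += level * disc_mask((256, 256), (r, c), 15)
        return dna, marker

    def test_constant_marker_recovered_exactly(self):
        dna, marker = self._scene([80.0])
        out = ip.measure_spindle_intensity(marker, dna, dna_mitotic_threshold=50.0,
                                           marker_threshold=10.0)
        assert len(out) == 1
        assert out["mean_intensity"].iloc[0] == pytest.approx(80.0)

    def test_integrated_intensity_is_linear_in_gain(self):
        dna, marker = self._scene([40.0])
        a = ip.measure_spindle_intensity(marker, dna, 50.0, marker_threshold=10.0)
        b = ip.measure_spindle_intensity(2 * marker, dna, 50.0, marker_threshold=10.0)
        assert b["integrated_intensity"].iloc[0] == pytest.approx(
            2 * a["integrated_intensity"].iloc[0])

    def test_two_population_ratio_recovered(self):
        dna, marker = self._scene([100.0, 100.0, 25.0, 25.0])
        out = ip.measure_spindle_intensity(marker, dna, 50.0, marker_threshold=10.0)
        means = sorted(out["mean_intensity"])
        ratio = np.mean(means[2:]) / np.mean(means[:2])
        assert abs(ratio - 4.0) / 4.0 < 0.05

    def test_no_marker_signal_recorded_missing(self):
        dna, _ = self._scene([40.0])
        out = ip.measure_spindle_intensity(np.zeros((256, 256)), dna, 50.0,
                                           marker_threshold=10.0)
        assert out["mean_intensity"].isna().all()


def _mitotic_record(n_poles, reason="none"):
    return {"well": "A01", "field": 0, "cell_id": 1, "kind": "mitotic",
            "centroid_r": 0.0, "centroid_c": 0.0, "touches_edge": reason == "edge",
            "roundness": 0.9, "tubulin_mean": 40.0, "exclusion_reason": reason,
            "n_poles": n_poles, "is_multipolar": reason == "none" and n_poles > 2,
            "n_nuclei": 1, "is_multinucleate": False}


class TestSummarizeWell:
    def test_all_bipolar(self):
        recs = pd.DataFrame([_mitotic_record(2) for _ in range(5)])
        s = ip.summarize_well(recs)
        assert s["pct_multipolar"] == 0.0 and s["mean_poles"] == 2.0

    def test_hand_arithmetic(self):
        recs = pd.DataFrame([_mitotic_record(4)] * 2 + [_mitotic_record(2)] * 8)
        s = ip.summarize_well(recs)
        assert s["pct_multipolar"] == pytest.approx(20.0)
        assert s["mean_poles"] == pytest.approx(2.4)

    def test_excluded_cells_do_not_change_percentages(self):
        kept = [_mitotic_record(4)] * 2 + [_mitotic_record(2)] * 8
        excluded = [_mitotic_record(6, reason="roundness"),
                    _mitotic_record(6, reason="edge")]
        s = ip.summarize_well(pd.DataFrame(kept + excluded))
        assert s["pct_multipolar"] == pytest.approx(20.0)
        assert s["mean_poles"] == pytest.approx(2.4)
        assert s["n_cells"] == 12  # excluded nuclei still count as cells

    def test_zero_kept_mitotic_cells_is_missing(self):
        recs = pd.DataFrame([_mitotic_record(2, reason="edge")])
        s = ip.summarize_well(recs)
        assert np.isnan(s["pct_multipolar"]) and np.isnan(s["mean_poles"])


def test_partition_every_mitotic_cell_has_one_reason():
    image, truth = make_simple_field(seed=21, n_interphase=10,
                                     pole_counts=(2, 3, 2, 4), cell_radius=22.0,
                                     field_size=(448, 448))
    records = ip.process_field(image)
    mit = records[records["kind"] == "mitotic"]
    assert len(mit) == 4
    assert mit["exclusion_reason"].isin(ip.EXCLUSION_REASONS).all()
    kept = (mit["exclusion_reason"] == "none").sum()
    excluded = (mit["exclusion_reason"] != "none").sum()
    assert kept + excluded == len(mit)
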