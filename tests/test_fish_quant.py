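"""Quantification pipeline: segmentation, spot calling, scoring, summaries."""
import math
from dataclasses import replace

import numpy as np
import pytest

from coxpet.fish_quant import (
    QuantConfig,
    SpotCall,
    detect_spots,
    quantify_image,
    remove_autofluorescence,
    run_pipeline,
    score_cells,
    segment_nuclei,
    summarize,
)
from coxpet.fish_synth import SceneParams, generate_scene, scene_truth_summary

PX = 0.31  # um per pixel used throughout these constructed images


def _draw_disk(img, cy, cx, r, value=500.0):
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = value


def _blob(img, cy, cx, amp, sigma=1.2):
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


class TestSegmentNuclei:
    def test_single_nucleus(self):
        img = np.full((120, 120), 100.0)
        _draw_disk(img, 60, 60, 11)
        masks = segment_nuclei(img, PX)
        assert len(masks) == 1
        assert not masks[0].touches_edge
        assert masks[0].area_um2 > 20.0

    def test_blank_image_empty(self):
        assert segment_nuclei(np.full((64, 64), 7.0), PX) == []

    def test_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            segment_nuclei(np.zeros((10, 10)), 0.0)

    def test_overlapping_pair_split_by_watershed(self):
        # several singles set the median area; one touching pair
        img = np.full((300, 300), 100.0)
        singles = [(50, 50), (50, 150), (50, 250), (150, 50), (250, 50)]
        for cy, cx in singles:
            _draw_disk(img, cy, cx, 10)
        pair = [(200, 180), (200, 197)]  # centers 17 px apart, r = 10
        for cy, cx in pair:
            _draw_disk(img, cy, cx, 10)
        masks = segment_nuclei(img, PX)
        assert len(masks) == len(singles) + 2
        centroids = np.array([m.centroid for m in masks])
        for cy, cx in pair:
            d = np.sqrt(((centroids - [cy, cx]) ** 2).sum(axis=1)).min()
            assert d < 2.0

    def test_edge_nucleus_excluded(self):
        img = np.full((120, 120), 100.0)
        _draw_disk(img, 60, 60, 11)
        _draw_disk(img, 2, 60, 11)  # intersects the border
        masks = segment_nuclei(img, PX)
        assert len(masks) == 1
        assert abs(masks[0].centroid[0] - 60) < 2

    def test_search_regions_disjoint(self, small_scene):
        masks = segment_nuclei(small_scene.dapi, small_scene.params.pixel_size)
        seen = set()
        for m in masks:
            px = set(zip(m.search_pixels[0].tolist(), m.search_pixels[1].tolist()))
            assert not (px & seen)
            seen |= px
            core = set(zip(m.pixels[0].tolist(), m.pixels[1].tolist()))
            assert core <= px  # search region contains the core mask

    def test_literal_area_reading_available(self):
        img = np.full((120, 120), 100.0)
        _draw_disk(img, 60, 60, 11)  # ~36 um2
        cfg = QuantConfig(min_area_um2=0.0, max_area_um2=20.0)
        assert segment_nuclei(img, PX, cfg) == []


class TestDetectSpots:
    def _one_nucleus(self):
        img = np.full((120, 120), 100.0)
        _draw_disk(img, 60, 60, 11)
        return segment_nuclei(img, PX)

    def test_uniform_image_degenerate_sd(self):
        masks = self._one_nucleus()
        spots = detect_spots(np.full((120, 120), 50.0), masks)
        assert spots == []

    def test_planted_blob_detected_and_assigned(self):
        masks = self._one_nucleus()
        chan = np.full((120, 120), 100.0)
        rng = np.random.default_rng(0)
        chan += rng.normal(0, 10, chan.shape)
        _blob(chan, 60, 60, 100.0)
        spots = detect_spots(chan, masks, channel="cy3")
        assert len(spots) == 1
        assert spots[0].nucleus_id == masks[0].id
        assert math.hypot(spots[0].centroid[0] - 60, spots[0].centroid[1] - 60) < 1.5

    def test_single_pixel_speck_filtered(self):
        masks = self._one_nucleus()
        chan = np.full((120, 120), 100.0)
        rng = np.random.default_rng(1)
        chan += rng.normal(0, 5, chan.shape)
        chan[60, 60] = 5000.0
        cfg = QuantConfig(spot_min_px=2)
        spots = detect_spots(chan, masks, cfg)
        assert spots == []

    def test_conservation(self, small_scene):
        """candidates = assigned + outside regions + size-filtered."""
        masks = segment_nuclei(small_scene.dapi, small_scene.params.pixel_size)
        _, stats = detect_spots(small_scene.cy3, masks, return_stats=True)
        assert stats["candidates"] == (
            stats["assigned"] + stats["outside"] + stats["size_filtered"]
        )
        assert stats["assigned"] > 0

    def test_min_size_monotonicity(self, small_scene):
        masks = segment_nuclei(small_scene.dapi, small_scene.params.pixel_size)
        counts = []
        for min_px in (1, 3, 5, 9, 15):
            spots = detect_spots(small_scene.cy3, masks,
                                 QuantConfig(spot_min_px=min_px))
            counts.append(len(spots))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRemoveAutofluorescence:
    def _spot(self, ch, y, x, nid=1):
        return SpotCall(channel=ch, centroid=(y, x), size=8, nucleus_id=nid)

    def test_disjoint_sets_untouched(self):
        c3 = [self._spot("cy3", 10, 10), self._spot("cy3", 30, 30)]
        c5 = [self._spot("cy5", 70, 70)]
        k3, k5, removed = remove_autofluorescence(c3, c5, tol=2.0)
        assert len(k3) == 2 and len(k5) == 1 and removed == []

    def test_identical_centroids_both_removed(self):
        c3 = [self._spot("cy3", 10.0, 10.0)]
        c5 = [self._spot("cy5", 10.0, 10.0)]
        k3, k5, removed = remove_autofluorescence(c3, c5, tol=2.0)
        assert k3 == [] and k5 == []
        assert len(removed) == 1
        assert removed[0][0].autofluor and removed[0][1].autofluor

    def test_equidistant_tie_removes_lowest_index(self):
        # two Cy3 spots exactly tol away from one Cy5 spot
        c3 = [self._spot("cy3", 10.0, 8.0), self._spot("cy3", 10.0, 12.0)]
        c5 = [self._spot("cy5", 10.0, 10.0)]
        k3, k5, removed = remove_autofluorescence(c3, c5, tol=2.0)
        assert len(removed) == 1
        assert removed[0][0] is c3[0]  # lowest-index Cy3 wins the tie
        assert k3 == [c3[1]] and k5 == []

    def test_each_spot_removed_at_most_once(self):
        c3 = [self._spot("cy3", 10, 10), self._spot("cy3", 11, 10)]
        c5 = [self._spot("cy5", 10.5, 10)]
        k3, k5, removed = remove_autofluorescence(c3, c5, tol=2.0)
        assert len(removed) == 1
        assert len(k3) == 1 and k5 == []


class TestScoreAndSummarize:
    def _mask_stub(self, mid):
        from coxpet.fish_quant import NucleusMask

        e = (np.array([], int), np.array([], int))
        return NucleusMask(id=mid, pixels=e, search_pixels=e, area_um2=30.0,
                           centroid=(0.0, 0.0), touches_edge=False,
                           image_shape=(10, 10))

    def _spot(self, ch, nid):
        return SpotCall(channel=ch, centroid=(1.0, 1.0), size=8, nucleus_id=nid)

    def test_two_dot_rule(self):
        masks = [self._mask_stub(1), self._mask_stub(2), self._mask_stub(3)]
        c3 = [self._spot("cy3", 1), self._spot("cy3", 1), self._spot("cy3", 2)]
        scores = score_cells(masks, c3, [])
        by_id = {s.nucleus_id: s for s in scores}
        assert by_id[1].expressing_cy3        # two dots
        assert not by_id[2].expressing_cy3    # one dot
        assert not by_id[3].expressing_cy3 and not by_id[3].expressing_cy5

    def test_unknown_nucleus_rejected(self):
        with pytest.raises(ValueError, match="unknown nucleus"):
            score_cells([self._mask_stub(1)], [self._spot("cy3", 9)], [])

    def test_summarize_full_coexpression(self):
        masks = [self._mask_stub(i) for i in (1, 2)]
        c3 = [self._spot("cy3", i) for i in (1, 1, 2, 2)]
        c5 = [self._spot("cy5", i) for i in (1, 1, 2, 2)]
        res = summarize(score_cells(masks, c3, c5), "region")
        assert res.frac_cy3 == 1.0 and res.colocalization == 1.0

    def test_fold_change_against_reference(self):
        masks = [self._mask_stub(i) for i in range(1, 21)]
        ref_scores = score_cells(masks, [self._spot("cy3", 1)] * 2, [])
        ref = summarize(ref_scores, "control")      # 1/20 = 0.05
        c3 = [self._spot("cy3", i) for i in range(1, 7) for _ in range(2)]
        res = summarize(score_cells(masks, c3, []), "treated", reference=ref)
        assert res.frac_cy3 == pytest.approx(0.30)
        assert res.fold_change_cy3 == pytest.approx(6.0)

    def test_no_positive_cells_degenerate(self):
        masks = [self._mask_stub(1)]
        res = summarize(score_cells(masks, [], []), "r")
        assert res.frac_cy3 == 0.0 and res.colocalization is None

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            summarize([], "r")


class TestQuantifyImage:
    def test_background_only_scene_empty_result(self):
        scene = generate_scene(SceneParams(shape=(128, 128), n_nuclei=0,
                                           n_autofluor=0, seed=1))
        res = quantify_image(scene.images, scene.params.pixel_size)
        assert res.n_cells == 0 and res.frac_cy3 is None

    def test_default_scene_recovery(self):
        """Recovered expressing fractions within 0.05 of planted truth."""
        scene = generate_scene(SceneParams(seed=7))
        truth = scene_truth_summary(scene)
        res = quantify_image(scene.images, scene.params.pixel_size)
        assert res.frac_cy3 == pytest.approx(truth["frac_cy3"], abs=0.05)
        assert res.frac_cy5 == pytest.approx(truth["frac_cy5"], abs=0.05)

    def test_autofluorescence_only_scene_scores_nothing(self):
        """Planted dual-channel artifacts must not count as expression."""
        p = SceneParams(shape=(256, 256), n_nuclei=30, lambda_cy3=0.0,
                        lambda_cy5=0.0, eno2_background_lambda=0.0,
                        n_autofluor=25, seed=9)
        scene = generate_scene(p)
        res = quantify_image(scene.images, p.pixel_size)
        assert res.n_cells > 0
        assert res.frac_cy3 == 0.0 and res.frac_cy5 == 0.0
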