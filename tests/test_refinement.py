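import numpy as np
import pytest

import zdiskseg as z
from zdiskseg.refinement import BandRegion, EdgeTrace, GeometryError, TraceError


class TestMembraneResponses:
    def test_horizontal_step_fires_lme_positive(self):
        img = np.zeros((10, 10))
        img[5:, :] = 255.0  # dark top -> bright bottom
        lme, ume = z.detect_membrane_responses(img)
        assert np.all(lme[4, :] == 1020.0) and np.all(lme[5, :] == 1020.0)
        assert np.all(ume[4, :] == -1020.0)
        assert np.array_equal(ume, -lme)

    def test_vertical_step_gives_zero_response(self):
        img = np.zeros((10, 10))
        img[:, 5:] = 255.0
        lme, ume = z.detect_membrane_responses(img)
        assert np.all(lme == 0) and np.all(ume == 0)

    def test_constant_image_gives_zero_responses(self):
        lme, ume = z.detect_membrane_responses(np.full((8, 8), 42.0))
        assert np.all(lme == 0) and np.all(ume == 0)


class TestSuppressWeakEdges:
    def test_isolated_pixel_removed(self):
        m = np.zeros((6, 6), bool)
        m[3, 3] = True
        assert not z.suppress_weak_edges(m).any()

    def test_solid_3x3_block_leaves_2x2(self):
        m = np.zeros((7, 7), bool)
        m[2:5, 2:5] = True
        out = z.suppress_weak_edges(m)
        expected = np.zeros((7, 7), bool)
        expected[2:4, 2:4] = True  # SE origin at its top-left corner
        assert np.array_equal(out, expected)

    def test_empty_mask_and_anti_extensive(self, rng):
        assert not z.suppress_weak_edges(np.zeros((5, 5), bool)).any()
        m = rng.random((20, 20)) > 0.5
        assert not (z.suppress_weak_edges(m) & ~m).any()


class TestRemoveFixedPatterns:
    def test_background_interface_edges_cleared(self):
        # black left margin abutting a grey region; edge mask on the boundary
        raw = np.full((20, 30), 40.0)
        raw[:, :8] = 3.0
        mask = np.zeros((20, 30), bool)
        mask[:, 7:9] = True   # interface edge pixels
        mask[:, 20] = True    # a genuine edge far from the interface
        out = z.remove_fixed_patterns(mask, raw, background_threshold=10.0)
        assert not out[:, 7:9].any()
        assert out[:, 20].all()

    def test_no_background_leaves_mask_unchanged(self, rng):
        raw = np.full((10, 10), 100.0)
        mask = rng.random((10, 10)) > 0.5
        assert np.array_equal(z.remove_fixed_patterns(mask, raw, 10.0), mask)

    def test_all_dark_slice_unchanged(self, rng):
        raw = np.zeros((10, 10))
        mask = rng.random((10, 10)) > 0.5
        assert np.array_equal(z.remove_fixed_patterns(mask, raw, 10.0), mask)

    def test_interior_dark_blob_not_background(self):
        # dark region not touching the border is an organelle, not background
        raw = np.full((20, 20), 100.0)
        raw[8:12, 8:12] = 2.0
        mask = np.ones((20, 20), bool)
        assert np.array_equal(z.remove_fixed_patterns(mask, raw, 10.0), mask)


class TestRemoveDenseClusters:
    def test_solid_blob_fully_removed(self):
        m = np.zeros((20, 20), bool)
        m[4:14, 4:14] = True
        assert not z.remove_dense_clusters(m).any()

    def test_thin_line_survives(self):
        m = np.zeros((30, 10), bool)
        m[5:25, 4] = True
        assert np.array_equal(z.remove_dense_clusters(m), m)

    def test_empty_mask_and_anti_extensive(self, rng):
        assert not z.remove_dense_clusters(np.zeros((8, 8), bool)).any()
        m = rng.random((30, 30)) > 0.4
        assert not (z.remove_dense_clusters(m) & ~m).any()


class TestTraceEdge:
    def test_continuous_line_reproduced_exactly(self, config):
        m = np.zeros((80, 100), bool)
        m[40, :] = True
        trace = z.trace_edge(m, "upper", config)
        assert np.array_equal(trace.rows, np.full(100, 40))
        assert trace.points[0] == (40, 0) and trace.points[-1] == (40, 99)

    def test_short_gap_bridged_horizontally(self, config):
        m = np.zeros((80, 100), bool)
        m[40, 0:50] = True
        m[40, 55:100] = True  # gap of 5 < threshold 10
        trace = z.trace_edge(m, "upper", config)
        assert np.array_equal(trace.rows, np.full(100, 40))

    def test_long_gap_closed_by_linear_interpolation(self, config):
        m = np.zeros((100, 100), bool)
        m[40, 0:50] = True    # ends at column 49
        m[60, 70:100] = True  # resumes at column 70: gap 21 >= 10
        trace = z.trace_edge(m, "upper", config)
        gap_cols = np.arange(50, 70)
        expected = np.floor(40 + 20 * (gap_cols - 49) / 21).astype(int)
        assert np.array_equal(trace.rows[50:70], expected)
        assert np.all(trace.rows[:50] == 40) and np.all(trace.rows[70:] == 60)

    def test_lower_role_follows_bottommost_pixels(self, config):
        m = np.zeros((50, 30), bool)
        m[10, :] = True
        m[30, :] = True
        upper = z.trace_edge(m, "upper", config)
        lower = z.trace_edge(m, "lower", config)
        assert np.all(upper.rows == 10) and np.all(lower.rows == 30)

    def test_trailing_gap_continues_horizontally(self, config):
        m = np.zeros((50, 60), bool)
        m[20, 0:30] = True
        trace = z.trace_edge(m, "upper", config)
        assert np.all(trace.rows[30:] == 20)

    def test_full_coverage_and_no_teleporting(self, config, rng):
        m = rng.random((60, 120)) > 0.97
        m[30, ::3] = True
        trace = z.trace_edge(m, "upper", config)
        assert len(trace.rows) == 120
        slope_bound = max(config.track_half_window, config.track_search_radius)
        assert np.all(np.abs(np.diff(trace.rows)) <= slope_bound)

    def test_empty_mask_raises_trace_error(self, config):
        with pytest.raises(TraceError):
            z.trace_edge(np.zeros((10, 10), bool), "upper", config)

    def test_seed_at_border_window_clamped(self, config):
        m = np.zeros((30, 40), bool)
        m[0, :] = True
        trace = z.trace_edge(m, "upper", config)
        assert np.all(trace.rows == 0)

    def test_paint_round_trip(self, config):
        m = np.zeros((20, 30), bool)
        m[7, :] = True
        canvas = z.trace_edge(m, "upper", config).paint((20, 30))
        assert np.array_equal(canvas == 255, m)


class TestBuildBandMask:
    def test_constant_band_pixel_count(self):
        upper = EdgeTrace(rows=np.full(5, 10), role="upper")
        lower = EdgeTrace(rows=np.full(5, 20), role="lower")
        mask = z.build_band_mask([BandRegion(upper, lower)], (30, 5))
        assert mask.sum() == 11 * 5
        assert mask[10:21, :].all()

    def test_degenerate_band_one_pixel_tall(self):
        t = EdgeTrace(rows=np.full(4, 7), role="upper")
        b = EdgeTrace(rows=np.full(4, 7), role="lower")
        mask = z.build_band_mask([BandRegion(t, b)], (10, 4))
        assert mask.sum() == 4 and mask[7, :].all()

    def test_empty_band_list_gives_empty_mask(self):
        assert not z.build_band_mask([], (8, 8)).any()

    def test_crossed_traces_raise_geometry_error(self):
        upper = EdgeTrace(rows=np.full(4, 12), role="upper")
        lower = EdgeTrace(rows=np.full(4, 5), role="lower")
        with pytest.raises(GeometryError):
            z.build_band_mask([BandRegion(upper, lower)], (20, 4))

    def test_multiple_bands_unioned(self):
        bands = [BandRegion(EdgeTrace(rows=np.full(3, 2), role="upper"),
                            EdgeTrace(rows=np.full(3, 4), role="lower")),
                 BandRegion(EdgeTrace(rows=np.full(3, 10), role="upper"),
                            EdgeTrace(rows=np.full(3, 12), role="lower"))]
        mask = z.build_band_mask(bands, (20, 3))
        assert mask.sum() == 2 * 3 * 3


class TestDilateZdisks:
    def test_single_pixel_becomes_plus_shape(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        out = z.dilate_zdisks(m, "disk:1")
        assert out.sum() == 5
        assert out[2, 1] and out[2, 3] and out[1, 2] and out[3, 2] and out[2, 2]

    def test_empty_mask_stays_empty(self):
        assert not z.dilate_zdisks(np.zeros((6, 6), bool), "disk:1").any()

    def test_line_grows_and_is_superset(self):
        m = np.zeros((20, 9), bool)
        m[3:17, 4] = True
        out = z.dilate_zdisks(m, "disk:1")
        assert out.sum() > m.sum()
        assert not (m & ~out).any()


class TestRefineSlice:
    def test_synthetic_slice_outside_band_removed_inside_kept(self, config):
        fx = z.generate_slice(z.sbfsem_like(3))
        pre = z.preprocess_slice(fx.image, config)
        cand = z.segment_slice(pre, config)
        refined, band, traces = z.refine_slice(cand, pre, fx.image, config,
                                               return_detail=True)
        assert traces[0] is not None  # membranes were traceable
        assert not (refined & ~band).any()
        # pixels inside the band that are no dense cluster are preserved
        kept = z.remove_dense_clusters(cand) & band
        assert np.array_equal(refined, kept)

    def test_empty_candidate_gives_empty_output(self, config):
        fx = z.generate_slice(z.sbfsem_like(4))
        pre = z.preprocess_slice(fx.image, config)
        refined = z.refine_slice(np.zeros_like(fx.zdisk_truth), pre,
                                 fx.image, config)
        assert not refined.any()

    def test_dense_blob_inside_band_removed_thin_lines_survive(self, config):
        fx = z.generate_slice(z.sbfsem_like(5))
        pre = z.preprocess_slice(fx.image, config)
        cand = z.segment_slice(pre, config)
        blob = np.zeros_like(cand)
        r0 = fx.membranes[0].rows.max() + 10
        blob[r0:r0 + 12, 100:112] = True
        refined = z.refine_slice(cand | blob, pre, fx.image, config)
        assert not refined[r0 + 2:r0 + 10, 102:110].any()  # blob core gone
        thin = z.remove_dense_clusters(cand)
        assert (refined & thin).sum() > 0

    def test_untraceable_membranes_fall_back_to_full_slice(self, config):
        flat = np.full((30, 40), 128.0)
        cand = np.zeros((30, 40), bool)
        cand[10, 10] = True
        refined, band, traces = z.refine_slice(cand, flat, flat, config,
                                               return_detail=True)
        assert band.all() and traces[0] is None
        assert refined[10, 10]

    def test_refinement_improves_specificity_and_accuracy(self, config):
        """Cutting artifacts outside the membrane band must pay off in
        specificity/accuracy while refinement (anti-extensive) can only
        keep or reduce sensitivity."""
        preds_raw, preds_ref, truths = [], [], []
        for seed in range(6):
            fx = z.generate_slice(z.sbfsem_like(seed))
            pre = z.preprocess_slice(fx.image, config)
            cand = z.segment_slice(pre, config)
            preds_raw.append(cand)
            preds_ref.append(z.refine_slice(cand, pre, fx.image, config))
            truths.append(fx.zdisk_truth)
        before = z.evaluate_masks(preds_raw, truths)
        after = z.evaluate_masks(preds_ref, truths)
        assert after.specificity > before.specificity
        assert after.accuracy > before.accuracy
        assert after.sensitivity >= before.sensitivity - 0.02


class TestFuseOrthogonal:
    @staticmethod
    def _planes(vol):
        return (vol,
                np.moveaxis(vol, 1, 0).copy(),
                np.moveaxis(vol, 2, 0).copy())

    def test_identical_volumes_idempotent(self, rng):
        vol = rng.random((4, 5, 6)) > 0.5
        xy, xz, yz = self._planes(vol)
        assert np.array_equal(z.fuse_orthogonal(xy, xz, yz, "union"), vol)
        assert np.array_equal(z.fuse_orthogonal(xy, xz, yz, "intersection"), vol)

    def test_single_plane_voxel_union_vs_intersection(self):
        vol = np.zeros((3, 3, 3), bool)
        xy, xz, yz = self._planes(vol)
        xz[1, 2, 0] = True  # voxel (z=2, y=1, x=0) present only in xz
        assert z.fuse_orthogonal(xy, xz, yz, "union")[2, 1, 0]
        assert not z.fuse_orthogonal(xy, xz, yz, "intersection").any()

    def test_matches_voxel_loop_oracle(self, rng):
        vol_a = rng.random((3, 4, 5)) > 0.5
        vol_b = rng.random((3, 4, 5)) > 0.5
        vol_c = rng.random((3, 4, 5)) > 0.5
        xy = vol_a
        xz = np.moveaxis(vol_b, 1, 0).copy()
        yz = np.moveaxis(vol_c, 2, 0).copy()
        fused = z.fuse_orthogonal(xy, xz, yz, "union")
        for idx in np.ndindex(vol_a.shape):
            assert fused[idx] == (vol_a[idx] or vol_b[idx] or vol_c[idx])

    def test_shape_mismatch_raises(self):
        with pytest.raises(GeometryError):
            z.fuse_orthogonal(np.zeros((2, 3, 4), bool),
                              np.zeros((2, 3, 4), bool),
                              np.zeros((4, 2, 3), bool))
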