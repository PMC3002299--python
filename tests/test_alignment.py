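"""Alignment tests: anchor detection, warp correction, grid invariants."""

from __future__ import annotations

import numpy as np
import pytest

from gelbands.alignment import (
    GRID_SIZE,
    AlignedLane,
    align_experiment,
    between_gel_align,
    detect_ss_anchors,
    truncate_and_scale,
    within_gel_correct,
)
from gelbands.bands import pick_bands
from gelbands.lane_io import LaneTrace
from gelbands.presets import BACTEROIDES_DESIGN, BACTEROIDES_PRESETS
from gelbands.simulate import make_synthetic_standard, simulate_experiment

from conftest import flat_profile, make_layout, render_small_gel

SS = make_synthetic_standard()  # 24 bands, 0.05-0.95


def _gaussian_trace(rfs, n_pixels=1101, sigma=0.0025, heights=None, **meta):
    x = np.linspace(0, 1, n_pixels)
    heights = heights if heights is not None else np.ones(len(rfs))
    v = 100.0 + sum(
        h * 30000.0 * np.exp(-0.5 * ((x - rf) / sigma) ** 2)
        for rf, h in zip(rfs, heights)
    )
    kw = dict(gel_id="g", lane_index=0, sample_id="s", replicate_id="r1", group="g")
    kw.update(meta)
    return LaneTrace(intensities=v, **kw)


class TestAnchorDetection:
    def test_undistorted_anchors_at_planted_positions(self):
        layout = make_layout("g1", ["a"], noise_sd=0.0)
        traces = render_small_gel(layout, {"a": flat_profile("a", [0.5])})
        anchors = detect_ss_anchors([t for t in traces if t.is_ss], 24)
        half_px = 0.5 / (layout.n_pixels - 1)
        assert anchors.positions.shape == (4, 24)
        assert np.all(np.abs(anchors.positions - SS.rfs[None, :]) <= half_px)

    def test_translation_moves_every_anchor(self):
        base = make_layout("g1", ["a"], noise_sd=0.0)
        shifted = make_layout("g1", ["a"], shift=0.01, noise_sd=0.0)
        prof = {"a": flat_profile("a", [0.5])}
        a0 = detect_ss_anchors([t for t in render_small_gel(base, prof) if t.is_ss], 24)
        a1 = detect_ss_anchors([t for t in render_small_gel(shifted, prof) if t.is_ss], 24)
        assert np.allclose(a1.positions - a0.positions, 0.01, atol=1e-3)

    def test_smile_displacement_tracks_generator_warp(self):
        layout = make_layout("g1", ["a"] * 8, smile=0.008, noise_sd=0.0)
        traces = render_small_gel(layout, {"a": flat_profile("a", [0.5])})
        anchors = detect_ss_anchors([t for t in traces if t.is_ss], 24)
        half_px = 0.5 / (layout.n_pixels - 1)
        for i, lane in enumerate(anchors.lane_indices):
            expected = np.asarray(layout.warp(SS.rfs, lane))
            assert np.max(np.abs(anchors.positions[i] - expected)) <= half_px + 1e-9

    def test_too_few_usable_ss_lanes_is_fatal(self):
        flat = LaneTrace(np.ones(1100), "g1", 0, "SS", "ss0", "SS", is_ss=True)
        good = _gaussian_trace(SS.rfs, sample_id="SS", is_ss=True)
        with pytest.raises(ValueError, match="unalignable"):
            detect_ss_anchors([flat, good], 24)


class TestWithinGelCorrection:
    def test_zero_smile_is_identity(self):
        layout = make_layout("g1", ["a", "b"], noise_sd=0.0)
        profs = {"a": flat_profile("a", [0.3]), "b": flat_profile("b", [0.6])}
        traces = render_small_gel(layout, profs)
        anchors = detect_ss_anchors([t for t in traces if t.is_ss], 24)
        corrected = within_gel_correct(traces, anchors, degree=2)
        for t, c in zip(traces, corrected):
            rel = np.max(np.abs(t.intensities - c.intensities)) / t.intensities.max()
            assert rel < 0.01

    def test_quadratic_smile_shrinks_anchor_scatter(self):
        """Between-lane SD of each SS band position drops >=5x after the
        polynomial lane-index correction."""
        layout = make_layout("g1", ["a"] * 8, smile=0.01, noise_sd=0.0)
        traces = render_small_gel(layout, {"a": flat_profile("a", [0.5])})
        ss = [t for t in traces if t.is_ss]
        pre = detect_ss_anchors(ss, 24)
        corrected = within_gel_correct(traces, pre, degree=2)
        post = detect_ss_anchors([t for t in corrected if t.is_ss], 24)
        sd_pre = pre.positions.std(axis=0)
        sd_post = post.positions.std(axis=0)
        assert np.median(sd_pre / np.maximum(sd_post, 1e-9)) >= 5.0

    def test_band_between_anchors_moves_by_interpolated_displacement(self):
        """A lane whose SS anchors are displaced by d0 at rf=0.2 and d1 at
        rf=0.8 moves a band at 0.5 by the linear interpolation (d0+d1)/2."""
        rf_band = 0.5
        d0, d1 = 0.006, 0.002
        n = 1101
        x = np.linspace(0, 1, n)
        anchors_ref = np.array([0.2, 0.8])

        # two SS lanes displaced symmetrically so the gel mean is the truth
        def ss_trace(lane_index, sign):
            return LaneTrace(
                _gaussian_trace(anchors_ref + sign * np.array([d0, d1])).intensities,
                "g", lane_index, "SS", f"ss{lane_index}", "SS", is_ss=True,
            )

        # plant the sample band displaced like lane 0: at rf 0.5 the linear
        # interpolation of the anchor displacements is (d0 + d1) / 2
        sample = LaneTrace(
            _gaussian_trace([rf_band + (d0 + d1) / 2]).intensities,
            "g", 0, "s", "r1", "grp",
        )
        traces = [ss_trace(0, +1), ss_trace(2, -1), sample]
        anchors = detect_ss_anchors([traces[0], traces[1]], 2)
        corrected = within_gel_correct(traces, anchors, degree=1)
        peak = x[np.argmax(corrected[2].intensities)]
        assert abs(peak - rf_band) <= 1.5 / (n - 1)


class TestBetweenGelAlignment:
    def test_identity_when_anchors_equal_global_means(self):
        trace = _gaussian_trace([0.3, 0.5, 0.7])
        grid = np.linspace(0, 1, GRID_SIZE)
        x = np.linspace(0, 1, trace.n_pixels)
        out = between_gel_align(trace, SS.rfs, SS.rfs)
        expected = np.interp(grid, x, trace.intensities)
        rel_rms = np.sqrt(np.mean((out.values - expected) ** 2)) / np.sqrt(
            np.mean(expected**2)
        )
        assert rel_rms < 1e-6

    def test_piecewise_map_matches_closed_form(self):
        """Anchors {0.2, 0.8} -> means {0.25, 0.75}: a band at 0.5 stays at
        0.5 and a band at 0.3 maps to 0.25 + 0.1/0.6*0.5 = 1/3."""
        trace = _gaussian_trace([0.3, 0.5])
        out = between_gel_align(trace, np.array([0.2, 0.8]), np.array([0.25, 0.75]))
        grid = out.rf_axis
        w = np.abs(grid - 1 / 3) < 0.02
        assert abs(grid[w][np.argmax(out.values[w])] - 1 / 3) <= 0.001
        w = np.abs(grid - 0.5) < 0.02
        assert abs(grid[w][np.argmax(out.values[w])] - 0.5) <= 0.0005

    def test_crossing_anchors_rejected(self):
        trace = _gaussian_trace([0.5])
        with pytest.raises(ValueError, match="non-monotone"):
            between_gel_align(trace, np.array([0.2, 0.8]), np.array([0.75, 0.25]))

    def test_duplicate_lanes_on_shifted_gels_coincide(self):
        """Two gels differing by a pure shift: the same sample's band maxima
        agree within one grid step after full alignment."""
        prof = {"a": flat_profile("a", [0.25, 0.45, 0.65])}
        traces = []
        for gel_id, shift in (("g1", +0.012), ("g2", -0.008)):
            layout = make_layout(gel_id, ["a"], shift=shift, noise_sd=0.0)
            for t in render_small_gel(layout, prof, seed=3):
                traces.append(t)
        aligned, _ = align_experiment(traces, expected_ss_bands=24)
        lanes = [l for l in aligned if l.sample_id == "a"]
        assert len(lanes) == 2
        b0 = pick_bands(lanes[0]).rfs
        b1 = pick_bands(lanes[1]).rfs
        assert b0.size == b1.size == 3
        assert np.max(np.abs(b0 - b1)) <= 0.001 + 1e-12


class TestTruncateAndScale:
    def test_window_length_and_scaling(self):
        lane = AlignedLane(np.linspace(0, 2, GRID_SIZE), "g", 0, "s", "r", "grp")
        out = truncate_and_scale(lane)
        assert out.values.size == 731
        assert out.values.min() == 0.0 and out.values.max() == 1.0
        assert np.all(np.diff(out.values) >= 0)  # ramp stays monotone
        assert out.rf_axis[0] == pytest.approx(0.09)
        assert out.rf_axis[-1] == pytest.approx(0.82)

    def test_values_spanning_unit_range_unchanged(self):
        v = np.zeros(GRID_SIZE)
        v[90:821] = np.linspace(0, 1, 731)
        out = truncate_and_scale(AlignedLane(v, "g", 0, "s", "r", "grp"))
        assert np.allclose(out.values, np.linspace(0, 1, 731))

    def test_constant_lane_rejected(self):
        lane = AlignedLane(np.ones(GRID_SIZE), "g", 0, "s", "r", "grp")
        with pytest.raises(ValueError, match="constant"):
            truncate_and_scale(lane)

    def test_wrong_input_length_rejected(self):
        with pytest.raises(ValueError):
            truncate_and_scale(AlignedLane(np.ones(731), "g", 0, "s", "r", "grp"))


class TestExperimentInvariants:
    def test_ss_positions_converge_across_gels(self):
        """After full alignment the SD of each SS band position across all
        SS lanes of all gels is at most one grid step (0.001 Rf)."""
        _, _, _, gels = simulate_experiment(
            BACTEROIDES_PRESETS, seed=5, design=BACTEROIDES_DESIGN, n_replicates=2
        )
        traces = [t for _, _, _, ts in gels for t in ts]
        aligned, diag = align_experiment(traces, expected_ss_bands=24)
        global_means = diag["global_anchor_means"]
        inside = global_means[(global_means > 0.10) & (global_means < 0.81)]
        positions = []
        for lane in aligned:
            if not lane.is_ss:
                continue
            rf = lane.rf_axis
            pos = []
            for m in inside:
                w = np.abs(rf - m) <= 0.004
                seg = lane.values[w]
                k = int(np.argmax(seg))
                if 0 < k < seg.size - 1:  # parabolic refinement
                    denom = seg[k - 1] - 2 * seg[k] + seg[k + 1]
                    k = k + 0.5 * (seg[k - 1] - seg[k + 1]) / denom
                pos.append(rf[w][0] + k * 0.001)
            positions.append(pos)
        sd = np.asarray(positions).std(axis=0)
        assert np.max(sd) <= 0.001

    def test_alignment_preserves_planted_band_count(self):
        """Noise-free distorted gels: peak counts inside the truncation
        window equal the planted counts after alignment."""
        profs = {
            "a": flat_profile("a", [0.15, 0.30, 0.45, 0.60, 0.75]),
            "b": flat_profile("b", [0.20, 0.40, 0.60, 0.80]),
        }
        traces = []
        for gel_id, shift, smile in (("g1", 0.01, 0.006), ("g2", -0.015, -0.009)):
            layout = make_layout(gel_id, ["a", "b"], shift=shift, smile=smile,
                                 stretch=0.01, noise_sd=0.0)
            traces.extend(render_small_gel(layout, profs, seed=1))
        aligned, _ = align_experiment(traces, expected_ss_bands=24)
        for lane in aligned:
            if lane.is_ss:
                continue
            planted = profs[lane.sample_id].rfs
            inside = ((planted >= 0.09) & (planted <= 0.82)).sum()
            assert len(pick_bands(lane)) == inside
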