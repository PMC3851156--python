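"""Region classification, Hough peak, removal and the detection loop."""

import numpy as np
import pytest

from conftest import angle_diff, brute_hough
from sonofiber.detect import (
    DetectedLine,
    DetectorConfig,
    classify_region,
    detect_lines,
    ellipse_angle_to_mfo,
    hough_line,
    line_angle_from_theta,
    remove_line_pixels,
    run_pipeline,
)
from sonofiber.synthfix import BarSpec, SceneSpec, render_crossing, render_scene


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "Ar,omega,expected",
        [
            (6.0, 20.0, "ellipse"),  # long and thin: single fiber
            (5.0, 20.0, "hough"),  # Ar boundary is strict
            (6.0, 30.0, "hough"),  # omega boundary is strict
            (12.0, 35.0, "hough"),  # too wide: merged fibers
            (1.2, 4.0, "hough"),  # blob
        ],
    )
    def test_routing_with_default_thresholds(self, Ar, omega, expected):
        assert classify_region(Ar, omega, DetectorConfig()) == expected


class TestHoughLine:
    def test_horizontal_pixel_row(self):
        pixels = [(10, c) for c in range(50)]
        theta, rho, votes = hough_line(np.array(pixels), image_diag=100.0)
        assert theta == 90.0
        assert abs(rho - 10.0) <= 0.5
        assert votes == 50

    def test_vertical_pixel_column(self):
        pixels = [(r, 5) for r in range(30)]
        theta, rho, votes = hough_line(np.array(pixels), image_diag=60.0)
        assert theta == 0.0
        assert abs(rho - 5.0) <= 0.5
        assert votes == 30

    def test_single_pixel_tie_breaks_to_smallest_theta(self):
        theta, rho, votes = hough_line(np.array([(7, 3)]), image_diag=20.0)
        assert theta == 0.0
        assert votes == 1

    def test_empty_pixel_set_rejected(self):
        with pytest.raises(ValueError):
            hough_line(np.empty((0, 2)), image_diag=10.0)

    def test_matches_brute_force_accumulator(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = rng.integers(5, 40)
            pixels = rng.integers(0, 30, size=(n, 2))
            diag = float(np.hypot(30, 30))
            assert hough_line(pixels, diag) == brute_hough(pixels, diag)


class TestAngleConventions:
    @pytest.mark.parametrize("theta,expected", [(90.0, 90.0), (0.0, 0.0), (45.0, 45.0)])
    def test_hough_normal_to_nih_angle(self, theta, expected):
        assert line_angle_from_theta(theta) == pytest.approx(expected)

    def test_out_of_range_theta_rejected(self):
        with pytest.raises(ValueError):
            line_angle_from_theta(180.0)

    @pytest.mark.parametrize("phi", [0.0, 90.0, 137.2])
    def test_ellipse_phi_passes_through(self, phi):
        assert ellipse_angle_to_mfo(phi) == phi


def _line(angle, anchor):
    return DetectedLine(
        order=1, angle_deg=angle, method="ellipse", anchor=anchor,
        L=10.0, omega=1.0, Ar=10.0, region_label=1,
    )


class TestRemoveLinePixels:
    def test_strip_half_width(self):
        mask = np.ones((30, 30), dtype=bool)
        out = remove_line_pixels(mask, _line(90.0, (15.0, 15.0)), 17)
        removed_rows = np.nonzero(~out.any(axis=1))[0]
        assert removed_rows.tolist() == list(range(7, 24))  # 17 rows: +/- 8 around 15

    def test_no_overlap_leaves_map_unchanged(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0, :] = True
        out = remove_line_pixels(mask, _line(90.0, (15.0, 10.0)), 3)
        assert np.array_equal(out, mask)

    def test_collinear_pixels_all_removed(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, :] = True
        out = remove_line_pixels(mask, _line(90.0, (5.0, 10.0)), 1)
        assert not out.any()

    def test_never_increases_and_idempotent(self):
        rng = np.random.default_rng(2)
        mask = rng.random((40, 40)) < 0.4
        line = _line(30.0, (20.0, 20.0))
        once = remove_line_pixels(mask, line, 9)
        assert once.sum() <= mask.sum()
        assert np.array_equal(remove_line_pixels(once, line, 9), once)

    def test_input_not_mutated(self):
        mask = np.ones((10, 10), dtype=bool)
        before = mask.copy()
        remove_line_pixels(mask, _line(0.0, (5.0, 5.0)), 5)
        assert np.array_equal(mask, before)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            remove_line_pixels(np.ones((5, 5), dtype=bool), _line(0.0, (2, 2)), 4)


class TestDetectLines:
    def test_empty_map_gives_no_lines(self):
        assert detect_lines(np.zeros((50, 50), dtype=bool)) == []

    def test_nine_bars_capped_at_n(self, nine_bar_scene):
        frame, _ = render_scene(nine_bar_scene)
        res = run_pipeline(frame)
        assert len(res.lines) == 7

    def test_single_thin_bar_uses_ellipse_path(self, single_bar_frame):
        frame, truth = single_bar_frame
        res = run_pipeline(frame)
        assert res.lines[0].method == "ellipse"
        assert angle_diff(res.lines[0].angle_deg, truth.angle_deg[0]) <= 1.0

    def test_crossing_bars_route_first_line_to_hough(self):
        spec = SceneSpec(
            shape=(200, 200),
            bars=(
                BarSpec(angle_deg=45.0, center=(100, 100), length=120, width=7),
                BarSpec(angle_deg=135.0, center=(100, 100), length=120, width=7),
            ),
            seed=5,
        )
        frame, truth = render_crossing(spec)
        res = run_pipeline(frame)
        assert res.lines[0].method == "hough"
        assert res.lines[0].votes is not None
        detected = [ln.angle_deg for ln in res.lines[:2]]
        for true_angle in truth.angle_deg:
            assert min(angle_diff(d, true_angle) for d in detected) <= 3.0

    def test_first_line_has_maximal_length_and_order_consecutive(self, nine_bar_scene):
        frame, _ = render_scene(nine_bar_scene)
        res = run_pipeline(frame)
        assert [ln.order for ln in res.lines] == list(range(1, len(res.lines) + 1))
        assert res.lines[0].L == max(ln.L for ln in res.lines)

    def test_nonterminal_lines_respect_length_ratio(self, nine_bar_scene):
        frame, _ = render_scene(nine_bar_scene)
        lines = run_pipeline(frame).lines
        L1 = lines[0].L
        for ln in lines[:-1]:
            assert ln.L >= L1 * DetectorConfig().T3

    def test_terminal_short_line_kept_by_default_dropped_on_request(self):
        # one long bar plus one much shorter one below the 10% cutoff
        mask = np.zeros((120, 220), dtype=bool)
        mask[10:13, 10:210] = True  # L ~ 200
        mask[60:62, 100:110] = True  # L ~ 10 < 0.1 * 200
        kept = detect_lines(mask, DetectorConfig())
        assert len(kept) == 2
        dropped = detect_lines(mask, DetectorConfig(drop_terminal_short_line=True))
        assert len(dropped) == 1

    def test_ellipse_lines_satisfy_shape_gate(self, nine_bar_scene):
        frame, _ = render_scene(nine_bar_scene)
        cfg = DetectorConfig()
        for ln in run_pipeline(frame, cfg).lines:
            if ln.method == "ellipse":
                assert ln.Ar > cfg.T1 and ln.omega < cfg.T2


class TestRunPipeline:
    def test_blank_frame_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sonofiber.detect"):
            res = run_pipeline(np.zeros((64, 64)))
        assert res.lines == []
        assert not res.binary_map.any()
        assert any("constant" in rec.message for rec in caplog.records)

    def test_multi_bar_frame_counts_lines(self):
        bars = tuple(
            BarSpec(angle_deg=a, center=(r, 100), length=130, width=w)
            for a, r, w in [(105.0, 30, 4), (100.0, 70, 4), (95.0, 110, 4), (90.0, 155, 7)]
        )
        frame, _ = render_scene(SceneSpec(shape=(200, 200), bars=bars, seed=21))
        res = run_pipeline(frame)
        assert len(res.lines) == 4

    def test_determinism_bitwise(self, single_bar_frame):
        frame, _ = single_bar_frame
        r1 = run_pipeline(frame)
        r2 = run_pipeline(frame)
        assert [
            (l.order, l.angle_deg, l.method, l.anchor, l.L, l.omega, l.Ar)
            for l in r1.lines
        ] == [
            (l.order, l.angle_deg, l.method, l.anchor, l.L, l.omega, l.Ar)
            for l in r2.lines
        ]


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"T1": 0.0},
            {"T3": 0.0},
            {"T3": 1.5},
            {"N": 0},
            {"removal_width": 16},
            {"theta_step": 0.0},
            {"connectivity": 6},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectorConfig(**kwargs)
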