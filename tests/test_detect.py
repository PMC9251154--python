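"""Hough accumulators and peaks against brute-force and analytic oracles."""

import math

import numpy as np
import pytest
from skimage.draw import circle_perimeter, line

from stereoloc import (CircleFeature, CircleParams, PhantomSpec,
                       denoise_wavelet, detect_edges, find_circles,
                       hough_circle_accumulate, hough_circle_peaks,
                       hough_line_accumulate, hough_line_peaks,
                       make_phantom_slice, refine_center)
from stereoloc.detect import circle_perimeter_offsets

from conftest import disc_phantom


def brute_line_accumulator(edge_mask, n_theta, rho_res):
    """Literal per-pixel, per-theta voting loop (independent of the
    vectorized implementation)."""
    h, w = edge_mask.shape
    rho_max = math.hypot(h - 1, w - 1)
    offset = int(math.ceil(rho_max / rho_res))
    votes = np.zeros((n_theta, 2 * offset + 1), dtype=np.int64)
    for y, x in np.argwhere(edge_mask):
        for t in range(n_theta):
            theta = t * math.pi / n_theta
            rho = x * math.cos(theta) + y * math.sin(theta)
            votes[t, int(math.floor(rho / rho_res + 0.5)) + offset] += 1
    return votes


def brute_circle_accumulator(edge_mask, r_min, r_max, r_step=1):
    """Per-pixel loop voting via skimage's Bresenham circle (an
    independent rasterizer that realizes the same midpoint geometry)."""
    h, w = edge_mask.shape
    radii = list(range(r_min, r_max + 1, r_step))
    votes = np.zeros((h, w, len(radii)), dtype=np.int64)
    for y, x in np.argwhere(edge_mask):
        for ri, r in enumerate(radii):
            rr, cc = circle_perimeter(int(y), int(x), r)
            # one vote per accumulator bin (skimage may list octant-
            # boundary pixels twice)
            for a, b in set(zip(rr.tolist(), cc.tolist())):
                if 0 <= a < h and 0 <= b < w:
                    votes[a, b, ri] += 1
    return votes


class TestLineAccumulator:
    def test_single_pixel_traces_one_sinusoid(self):
        mask = np.zeros((32, 32), bool)
        mask[10, 20] = True
        acc = hough_line_accumulate(mask, n_theta=90)
        assert acc.votes.sum() == 90
        assert np.all(acc.votes.max(axis=1) == 1)  # one vote per theta bin

    def test_collinear_pixels_peak_at_line_params(self):
        # horizontal line y = 12: theta = pi/2, rho = 12
        mask = np.zeros((64, 64), bool)
        mask[12, 5:55] = True
        acc = hough_line_accumulate(mask, n_theta=180)
        t, r = np.unravel_index(np.argmax(acc.votes), acc.votes.shape)
        assert acc.votes[t, r] == 50
        assert acc.thetas[t] == pytest.approx(math.pi / 2)
        assert acc.rhos[r] == pytest.approx(12.0)

    def test_parallel_lines_share_theta(self):
        mask = np.zeros((64, 64), bool)
        mask[10, 5:60] = True
        mask[40, 5:60] = True
        acc = hough_line_accumulate(mask, n_theta=180)
        peaks = hough_line_peaks(acc, k=2, min_votes=30, nms_radius=3)
        assert len(peaks) == 2
        assert peaks[0].theta == peaks[1].theta == pytest.approx(math.pi / 2)
        assert sorted(p.rho for p in peaks) == [10.0, 40.0]

    def test_empty_edge_map_gives_empty_accumulator(self):
        acc = hough_line_accumulate(np.zeros((16, 16), bool))
        assert acc.votes.sum() == 0
        assert hough_line_peaks(acc, k=3) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) < 0.03
        acc = hough_line_accumulate(mask, n_theta=45, rho_resolution=2.0)
        np.testing.assert_array_equal(
            acc.votes, brute_line_accumulator(mask, 45, 2.0))


class TestLinePeaks:
    def test_clean_line_recovered_within_one_bin(self):
        # oblique line via skimage.draw (independent rasterization)
        mask = np.zeros((64, 64), bool)
        rr, cc = line(5, 5, 50, 35)
        mask[rr, cc] = True
        acc = hough_line_accumulate(mask, n_theta=180)
        p = hough_line_peaks(acc, k=1)[0]
        # the recovered normal form must describe the drawn segment:
        # nearly every rasterized pixel within one bin of the line
        pts = np.argwhere(mask)
        dist = np.abs(pts[:, 1] * math.cos(p.theta)
                      + pts[:, 0] * math.sin(p.theta) - p.rho)
        assert np.mean(dist <= 1.0) >= 0.9
        assert p.votes >= 0.8 * len(pts)

    def test_min_votes_above_max_gives_empty(self):
        mask = np.zeros((32, 32), bool)
        mask[8, 2:20] = True
        acc = hough_line_accumulate(mask)
        assert hough_line_peaks(acc, k=5, min_votes=100) == []

    def test_tied_peaks_ordered_deterministically(self):
        mask = np.zeros((40, 40), bool)
        mask[10, 5:15] = True   # 10 votes at (pi/2, 10)
        mask[30, 5:15] = True   # 10 votes at (pi/2, 30)
        acc = hough_line_accumulate(mask, n_theta=180)
        p1 = hough_line_peaks(acc, k=2, min_votes=10, nms_radius=2)
        p2 = hough_line_peaks(acc, k=2, min_votes=10, nms_radius=2)
        assert p1 == p2
        assert p1[0].rho < p1[1].rho  # tie broken by ascending rho


class TestCircleAccumulator:
    def test_single_pixel_votes_form_circle(self):
        mask = np.zeros((41, 41), bool)
        mask[20, 20] = True
        acc = hough_circle_accumulate(mask, 8, 8)
        voted = np.argwhere(acc.votes[:, :, 0] > 0)
        d = np.hypot(voted[:, 0] - 20, voted[:, 1] - 20)
        assert np.all(np.abs(d - 8) < 1.0)
        assert len(voted) == acc.perimeter_counts[0]

    def test_vote_total_equals_per_pixel_enumeration(self):
        rng = np.random.default_rng(0)
        mask = rng.random((32, 32)) < 0.05
        acc = hough_circle_accumulate(mask, 3, 6)
        # direct enumeration of in-bounds bins cast per pixel
        expected = 0
        for y, x in np.argwhere(mask):
            for r in range(3, 7):
                offs = circle_perimeter_offsets(r)
                aa, bb = y + offs[:, 0], x + offs[:, 1]
                expected += int(np.sum((aa >= 0) & (aa < 32) & (bb >= 0) & (bb < 32)))
        assert acc.votes.sum() == expected

    def test_clean_circle_argmax_at_truth(self):
        spec = PhantomSpec(width=96, height=96,
                           circles=[CircleFeature(30, 40, 10)], noise_sigma=0.0)
        img, _ = make_phantom_slice(spec)
        # use the midline between the annulus edge rings via a filled disc
        spec_f = PhantomSpec(width=96, height=96,
                             circles=[CircleFeature(30, 40, 10, filled=True)],
                             noise_sigma=0.0)
        img_f, _ = make_phantom_slice(spec_f)
        acc = hough_circle_accumulate(detect_edges(img_f), 5, 15)
        a, b, ri = np.unravel_index(np.argmax(acc.votes), acc.votes.shape)
        assert abs(a - 30) <= 1 and abs(b - 40) <= 1
        assert abs(acc.radii[ri] - 10) <= 1

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = rng.random((40, 40)) < 0.04
        acc = hough_circle_accumulate(mask, 4, 9, 2)
        np.testing.assert_array_equal(
            acc.votes, brute_circle_accumulator(mask, 4, 9, 2))

    def test_infeasible_radius_range_warns(self):
        mask = np.zeros((16, 16), bool)
        mask[8, 8] = True
        with pytest.warns(UserWarning):
            hough_circle_accumulate(mask, 100, 120)

    def test_rasterizer_matches_skimage_bresenham(self):
        for r in (1, 2, 5, 11, 20):
            rr, cc = circle_perimeter(0, 0, r)
            assert set(zip(rr.tolist(), cc.tolist())) == set(
                map(tuple, circle_perimeter_offsets(r)))


class TestCirclePeaks:
    def test_two_disjoint_circles_recovered(self):
        spec = PhantomSpec(width=128, height=128, noise_sigma=0.0,
                           circles=[CircleFeature(35, 35, 9, filled=True),
                                    CircleFeature(90, 85, 14, filled=True)])
        img, _ = make_phantom_slice(spec)
        acc = hough_circle_accumulate(detect_edges(img), 6, 18)
        peaks = hough_circle_peaks(acc, k=2, nms_radius=4)
        got = sorted([(p.a, p.b, p.r) for p in peaks])
        for (a, b, r), (ta, tb, tr) in zip(got, [(35, 35, 9), (90, 85, 14)]):
            assert math.hypot(a - ta, b - tb) <= 1.0
            assert abs(r - tr) <= 1.0

    def test_normalization_prevents_large_circle_bias(self):
        # complete small circle vs half of a large circle: the complete
        # one must rank first even though the arc casts more raw votes
        mask = np.zeros((128, 128), bool)
        rr, cc = circle_perimeter(40, 40, 8)
        mask[rr, cc] = True
        rr, cc = circle_perimeter(80, 80, 30)
        keep = cc >= 80  # half arc
        mask[rr[keep], cc[keep]] = True
        acc = hough_circle_accumulate(mask, 6, 34)
        top = hough_circle_peaks(acc, k=1, nms_radius=3)[0]
        assert (top.a, top.b) == (40.0, 40.0)

    def test_empty_accumulator_gives_empty_list(self):
        acc = hough_circle_accumulate(np.zeros((16, 16), bool), 3, 5)
        assert hough_circle_peaks(acc, k=3) == []

    def test_peaks_deterministic(self):
        img, _ = disc_phantom(3)
        acc = hough_circle_accumulate(detect_edges(img), 5, 22)
        assert hough_circle_peaks(acc, k=4) == hough_circle_peaks(acc, k=4)


class TestRefineCenter:
    def test_subpixel_center_on_noiseless_annulus(self):
        spec = PhantomSpec(circles=[CircleFeature(30.4, 40.7, 10)],
                           noise_sigma=0.0)
        img, _ = make_phantom_slice(spec)
        ref = refine_center(img, CircleParams(30, 41, 10))
        assert math.hypot(ref.refined_center[0] - 30.4,
                          ref.refined_center[1] - 40.7) <= 0.1

    def test_exact_center_is_fixed_point(self):
        spec = PhantomSpec(circles=[CircleFeature(30, 40, 10)], noise_sigma=0.0)
        img, _ = make_phantom_slice(spec)
        ref = refine_center(img, CircleParams(30, 40, 10))
        assert math.hypot(ref.refined_center[0] - 30,
                          ref.refined_center[1] - 40) <= 0.1

    def test_refinement_beats_coarse_under_noise(self):
        coarse_err, refined_err = [], []
        for seed in range(20):
            spec = PhantomSpec(circles=[CircleFeature(60.3, 60.6, 12)],
                               noise_sigma=10.0, seed=seed)
            img, _ = make_phantom_slice(spec)
            c = find_circles(denoise_wavelet(img), 8, 16, k=1)[0]
            coarse_err.append(math.hypot(c.a - 60.3, c.b - 60.6))
            refined_err.append(math.hypot(c.refined_center[0] - 60.3,
                                          c.refined_center[1] - 60.6))
        assert np.mean(refined_err) < np.mean(coarse_err)

    def test_window_clipped_at_border_is_flagged(self):
        spec = PhantomSpec(circles=[CircleFeature(10, 10, 8)], noise_sigma=0.0)
        img, _ = make_phantom_slice(spec)
        ref = refine_center(img, CircleParams(10, 10, 8))
        assert ref.refinement_clipped

    def test_refined_never_moves_beyond_cap(self):
        for seed in range(10):
            img, (a, b, r) = disc_phantom(seed)
            c = find_circles(img, 5, 22, k=1)[0]
            assert math.hypot(c.refined_center[0] - c.a,
                              c.refined_center[1] - c.b) <= 1.5 + 1e-9
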