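"""Operator-level tests against independent oracles.

Each named operator of the mask recipes is checked against a brute-force
re-implementation of its definition (and, where one exists, against the
scipy/skimage equivalent), so the pipeline modules can rely on them.
"""

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings, strategies as st

from strainquant.imageops import (
    DegenerateHistogramError,
    Histogram256,
    LabeledRegions,
    _structuring_element,
    binarize,
    erode,
    gaussian_blur,
    label_and_filter,
    renyi_entropy_candidates,
    rolling_background,
    subtract_background,
    threshold_renyi_entropy,
    threshold_triangle,
)

# ---------------------------------------------------------------------------
# oracles


def opening_oracle(img, radius, paraboloid):
    """Direct grayscale opening: per-pixel min/max over the structuring
    element, out-of-image samples ignored (erosion +inf / dilation -inf)."""
    dys, dxs, hts, _ = _structuring_element(radius, paraboloid)
    h, w = img.shape

    def erode_at(y, x):
        vals = []
        for dy, dx, ht in zip(dys, dxs, hts):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                vals.append(img[yy, xx] - ht)
        return min(vals)

    ero = np.array([[erode_at(y, x) for x in range(w)] for y in range(h)])

    def dilate_at(y, x):
        vals = []
        for dy, dx, ht in zip(dys, dxs, hts):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                vals.append(ero[yy, xx] + ht)
        return max(vals)

    return np.array([[dilate_at(y, x) for x in range(w)] for y in range(h)])


def triangle_oracle(counts):
    """Exhaustive Triangle construction: perpendicular distance of every bin
    to the peak->far-tail chord, longest-tail side on the right."""
    counts = np.asarray(counts, dtype=np.float64)
    nz = np.flatnonzero(counts)
    peak = int(np.argmax(counts))
    if (peak - nz[0]) > (nz[-1] - peak):
        return 255 - triangle_oracle(counts[::-1])
    end = int(nz[-1])
    if end <= peak:
        return peak
    x1, y1, x2, y2 = peak, counts[peak], end, counts[end]
    norm = np.hypot(x2 - x1, y2 - y1)
    best, best_d = peak, -np.inf
    for i in range(peak, end + 1):
        cross = (x2 - x1) * (counts[i] - y1) - (i - x1) * (y2 - y1)
        d = -cross / norm  # positive below the chord
        if d > best_d:
            best, best_d = i, d
    return best


def renyi_candidate_oracle(counts, alpha):
    """Exhaustive search of the Rényi entropy-sum criterion at one order.

    Returns ``(argmax_bin, criterion_values)`` so callers can recognise
    exactly tied maxima.
    """
    p = np.asarray(counts, dtype=np.float64)
    p = p / p.sum()
    crit = np.full(256, -np.inf)
    for t in range(256):
        p1 = p[: t + 1].sum()
        p2 = p[t + 1 :].sum()
        if p1 <= np.finfo(float).eps or p2 <= np.finfo(float).eps:
            continue
        back = [q / p1 for q in p[: t + 1] if q > 0]
        fore = [q / p2 for q in p[t + 1 :] if q > 0]
        if alpha == 1.0:
            v = -sum(q * np.log(q) for q in back) - sum(q * np.log(q) for q in fore)
        else:
            v = np.log(sum(q**alpha for q in back)) / (1 - alpha) + np.log(
                sum(q**alpha for q in fore)
            ) / (1 - alpha)
        if np.isfinite(v):
            crit[t] = v
    return int(np.argmax(crit)), crit


def random_histogram(rng):
    """Random 256-bin histogram from a mixture of intensity populations."""
    n_modes = rng.integers(1, 4)
    samples = []
    for _ in range(n_modes):
        mu = rng.uniform(10, 245)
        sigma = rng.uniform(2, 40)
        samples.append(rng.normal(mu, sigma, size=rng.integers(200, 3000)))
    values = np.clip(np.concatenate(samples), 0, 255).astype(np.int64)
    return np.bincount(values, minlength=256)


def hist256(counts):
    return Histogram256(np.asarray(counts, dtype=np.int64), 0.0, 1.0)


# ---------------------------------------------------------------------------
# background subtraction


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        img = np.full((20, 20), 37.0)
        assert np.allclose(subtract_background(img, 3, True), 0.0)
        assert np.allclose(subtract_background(img, 3, False), 0.0)

    @pytest.mark.parametrize("paraboloid", [True, False])
    def test_single_bright_pixel_is_preserved(self, paraboloid):
        img = np.zeros((21, 21))
        img[10, 10] = 80.0
        out = subtract_background(img, 3, paraboloid)
        # structure smaller than the element survives almost untouched
        assert out[10, 10] == pytest.approx(80.0, abs=1.0)

    @pytest.mark.parametrize(
        "paraboloid,shape", [(True, (48, 48)), (False, (32, 32))]
    )
    def test_matches_direct_opening_oracle(self, rng, paraboloid, shape):
        ramp = np.linspace(0, 30, shape[1])[None, :] * np.ones((shape[0], 1))
        noise = rng.normal(0, 3, shape)
        spikes = np.zeros(shape)
        spikes[tuple(rng.integers(0, shape[0], (2, 12)))] = rng.uniform(20, 80, 12)
        img = ramp + noise + spikes
        bg = rolling_background(img, 3, paraboloid)
        oracle = opening_oracle(img, 3, paraboloid)
        np.testing.assert_allclose(bg, oracle, atol=1e-10)
        out = subtract_background(img, 3, paraboloid)
        assert np.all(out <= img - bg + 1e-9)

    def test_output_never_exceeds_input(self, rng):
        img = rng.uniform(0, 100, (40, 40))
        out = subtract_background(img, 3, True)
        assert np.all(out <= img + 1e-9)
        assert np.all(out >= 0)

    def test_ball_envelope_is_idempotent(self, rng):
        img = rng.uniform(0, 50, (32, 32))
        bg = rolling_background(img, 3, False)
        bg2 = rolling_background(bg, 3, False)
        np.testing.assert_allclose(bg, bg2, atol=1e-9)

    def test_rejects_small_radius(self):
        with pytest.raises(ValueError, match="radius"):
            subtract_background(np.zeros((5, 5)), 0.5, True)


# ---------------------------------------------------------------------------
# gaussian blur


class TestGaussianBlur:
    def test_constant_image_unchanged(self):
        img = np.full((15, 15), 4.2)
        np.testing.assert_allclose(gaussian_blur(img, 1.0), img, rtol=1e-12)

    def test_impulse_matches_explicit_kernel(self):
        img = np.zeros((17, 17))
        img[8, 8] = 1.0
        out = gaussian_blur(img, 1.0)
        r = 4
        x = np.arange(-r, r + 1, dtype=float)
        k1 = np.exp(-(x**2) / 2.0)
        k1 /= k1.sum()
        kernel2d = np.outer(k1, k1)
        assert out[8, 8] == pytest.approx(kernel2d[r, r], rel=1e-12)
        np.testing.assert_allclose(out[4:13, 4:13], kernel2d, atol=1e-12)

    def test_total_intensity_preserved(self, rng):
        img = rng.uniform(0, 10, (30, 30))
        out = gaussian_blur(img, 1.3)
        assert abs(out.sum() - img.sum()) / img.sum() < 1e-6

    def test_matches_scipy_symmetric_boundary(self, rng):
        img = rng.uniform(0, 100, (25, 33))
        mine = gaussian_blur(img, 1.0)
        # scipy's "reflect" is the half-sample symmetric boundary
        ref = ndi.gaussian_filter(img, 1.0, mode="reflect", truncate=4.0)
        np.testing.assert_allclose(mine, ref, atol=1e-9)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_blur(np.zeros((5, 5)), 0.0)


# ---------------------------------------------------------------------------
# thresholds


class TestThresholdTriangle:
    def test_two_delta_peaks(self):
        counts = np.zeros(256, dtype=int)
        counts[10], counts[200] = 1000, 100
        t = threshold_triangle(hist256(counts))
        assert 10 < t < 200
        assert t == triangle_oracle(counts)

    def test_exponential_tail(self):
        counts = (1e5 * np.exp(-np.arange(256) / 20.0)).astype(int)
        t = threshold_triangle(hist256(counts))
        assert t == triangle_oracle(counts)

    def test_random_histograms_match_oracle(self, rng):
        for _ in range(100):
            counts = random_histogram(rng)
            if np.count_nonzero(counts) < 2:
                continue
            assert threshold_triangle(hist256(counts)) == triangle_oracle(counts)

    def test_mirror_symmetry(self):
        counts = np.zeros(256, dtype=int)
        counts[30] = 500
        counts[31:120] = np.linspace(400, 1, 89).astype(int)
        t = threshold_triangle(hist256(counts))
        t_mirror = threshold_triangle(hist256(counts[::-1]))
        assert t_mirror == 255 - t

    def test_separates_bimodal_like_skimage(self, rng):
        pytest.importorskip("skimage")
        from skimage.filters import threshold_triangle as sk_triangle

        values = np.concatenate(
            [rng.normal(40, 6, 5000), rng.normal(180, 10, 500)]
        )
        img = np.clip(values, 0, 255).astype(np.uint8).reshape(50, 110)
        t = threshold_triangle(Histogram256.from_image(img))
        t_sk = sk_triangle(img)
        # conventions differ by at most a couple of bins; both must cut
        # above the dominant background mode and below the bright mode
        assert 40 < t < 180
        assert abs(int(t) - int(t_sk)) <= 3

    def test_degenerate_histogram_rejected(self):
        counts = np.zeros(256, dtype=int)
        counts[7] = 100
        with pytest.raises(DegenerateHistogramError):
            threshold_triangle(hist256(counts))


class TestThresholdRenyiEntropy:
    def test_kapur_candidate_on_two_deltas(self):
        counts = np.zeros(256, dtype=int)
        counts[10], counts[200] = 1000, 100
        cands = renyi_entropy_candidates(hist256(counts))
        assert cands[1] == renyi_candidate_oracle(counts, 1.0)[0]

    def test_all_candidates_match_exhaustive_oracle(self, rng):
        for _ in range(30):
            counts = random_histogram(rng)
            if np.count_nonzero(counts) < 2:
                continue
            cands = renyi_entropy_candidates(hist256(counts))
            for alpha, cand in zip((0.5, 1.0, 2.0), cands):
                oracle_bin, crit = renyi_candidate_oracle(counts, alpha)
                # a bin achieving the exhaustive maximum; exactly tied maxima
                # may resolve to either bin
                assert crit[cand] >= crit[oracle_bin] - 1e-9, alpha
                assert cand == oracle_bin or abs(crit[cand] - crit[oracle_bin]) < 1e-9

    def test_combined_threshold_within_candidate_range(self, rng):
        for _ in range(100):
            counts = random_histogram(rng)
            if np.count_nonzero(counts) < 2:
                continue
            cands = renyi_entropy_candidates(hist256(counts))
            t = threshold_renyi_entropy(hist256(counts))
            assert min(cands) <= t <= max(cands)

    def test_agreeing_candidates_collapse(self):
        # narrow bimodal histogram: all three candidates coincide
        counts = np.zeros(256, dtype=int)
        counts[5:15] = 1000
        counts[240:250] = 1000
        cands = renyi_entropy_candidates(hist256(counts))
        if len(set(cands)) == 1:
            assert threshold_renyi_entropy(hist256(counts)) == cands[0]
        t = threshold_renyi_entropy(hist256(counts))
        assert min(cands) <= t <= max(cands)

    def test_degenerate_histogram_rejected(self):
        counts = np.zeros(256, dtype=int)
        counts[0] = 42
        with pytest.raises(DegenerateHistogramError):
            threshold_renyi_entropy(hist256(counts))


class TestHistogramAndBinarize:
    def test_histogram_sums_to_pixel_count(self, rng):
        img = rng.integers(0, 65535, (40, 40)).astype(np.uint16)
        h = Histogram256.from_image(img)
        assert h.counts.sum() == img.size

    def test_uint8_uses_native_bins(self):
        img = np.array([[0, 5], [255, 5]], dtype=np.uint8)
        h = Histogram256.from_image(img)
        assert h.counts[5] == 2 and h.counts[0] == 1 and h.counts[255] == 1
        assert h.bin_width == 1.0

    def test_binarize_strictly_above(self):
        img = np.array([[0, 10], [11, 255]], dtype=np.uint8)
        assert binarize(img, 10).tolist() == [[False, False], [True, True]]
        assert not binarize(img, 255).any()
        assert binarize(img, -1).all()

    def test_foreground_count_equals_histogram_mass_above(self, rng):
        img = rng.integers(0, 256, (30, 30)).astype(np.uint8)
        h = Histogram256.from_image(img)
        for t in (0, 50, 128, 254):
            assert binarize(img, t).sum() == h.counts[t + 1 :].sum()

    def test_digitize_roundtrip_for_float_images(self, rng):
        img = rng.uniform(-5, 300, (20, 20))
        h = Histogram256.from_image(img)
        bins = h.digitize(img)
        assert bins.min() >= 0 and bins.max() <= 255
        assert np.bincount(bins.ravel(), minlength=256).tolist() == h.counts.tolist()


# ---------------------------------------------------------------------------
# erosion


class TestErode:
    def test_isolated_pixel_vanishes(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert not erode(m, 1).any()

    def test_solid_square_shrinks_by_one(self):
        m = np.zeros((9, 9), bool)
        m[2:7, 2:7] = True
        out = erode(m, 1)
        expected = np.zeros((9, 9), bool)
        expected[3:6, 3:6] = True
        assert (out == expected).all()

    def test_iteration_composition(self, rng):
        m = rng.random((30, 30)) > 0.3
        assert (erode(erode(m, 1), 1) == erode(m, 2)).all()

    def test_matches_scipy_binary_erosion(self, rng):
        m = rng.random((40, 40)) > 0.4
        ref = ndi.binary_erosion(m, structure=np.ones((3, 3), bool), border_value=0)
        assert (erode(m, 1) == ref).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 3))
    def test_anti_extensive_and_decreasing(self, seed, iterations):
        m = np.random.default_rng(seed).random((20, 20)) > 0.35
        out = erode(m, iterations)
        assert not (out & ~m).any()
        assert out.sum() <= erode(m, 1).sum() or iterations == 1


# ---------------------------------------------------------------------------
# labeling / particle filter


def scipy_regions(mask, connectivity):
    structure = np.ones((3, 3)) if connectivity == 8 else ndi.generate_binary_structure(2, 1)
    labels, n = ndi.label(mask, structure=structure)
    areas = np.bincount(labels.ravel())[1:]
    return n, sorted(areas.tolist())


class TestLabelAndFilter:
    def test_diagonal_pixels_depend_on_connectivity(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = m[2, 2] = True
        assert label_and_filter(m, 2, connectivity=8).n_regions == 1
        assert label_and_filter(m, 2, connectivity=4).n_regions == 0

    def test_blank_mask(self):
        lr = label_and_filter(np.zeros((8, 8), bool), 0, 8)
        assert lr.n_regions == 0 and not lr.foreground.any()

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_floodfill_oracle_on_random_masks(self, rng, connectivity):
        for density in np.linspace(0.2, 0.7, 50):
            m = rng.random((64, 64)) < density
            lr = label_and_filter(m, 0, connectivity)
            n_ref, areas_ref = scipy_regions(m, connectivity)
            assert lr.n_regions == n_ref
            assert sorted(lr.areas.tolist()) == areas_ref
            assert (lr.foreground == m).all()

    def test_size_filter_boundary_is_strict_less_than(self):
        m = np.zeros((10, 10), bool)
        m[1:3, 1:6] = True  # area exactly 10
        assert label_and_filter(m, 10, 8).n_regions == 1
        assert label_and_filter(m, 11, 8).n_regions == 0

    def test_filtered_counts_match_oracle(self, rng):
        for _ in range(20):
            m = rng.random((48, 48)) < 0.45
            for min_area in (0, 5, 20):
                lr = label_and_filter(m, min_area, 8)
                _, areas_ref = scipy_regions(m, 8)
                assert lr.n_regions == sum(a >= min_area for a in areas_ref)
                assert sorted(lr.areas.tolist()) == [a for a in areas_ref if a >= min_area]

    def test_labels_are_contiguous_and_areas_consistent(self, rng):
        m = rng.random((32, 32)) < 0.5
        lr = label_and_filter(m, 3, 8)
        labels_present = np.unique(lr.labels)
        assert labels_present[0] == 0 or lr.n_regions == labels_present.size
        assert set(labels_present) - {0} == set(range(1, lr.n_regions + 1))
        for k in range(1, lr.n_regions + 1):
            assert (lr.labels == k).sum() == lr.areas[k - 1]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_component_count_non_increasing_in_min_area(self, seed):
        m = np.random.default_rng(seed).random((24, 24)) < 0.5
        counts = [label_and_filter(m, a, 8).n_regions for a in (0, 2, 4, 8, 16)]
        assert counts == sorted(counts, reverse=True)
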