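"""Spot location, 6x6 integration, normalization and count estimation."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacquant.spots import (
    SpotQuantifier,
    SpotStack,
    estimate_unattached_count,
    locate_spot,
    measure_spot,
    normalize_intensities,
    summarize_counts,
)
from sacquant.synthetic import SpotTruth, generate_kinetochore_pair, generate_spot_stack


def brute_force_measure(image, center, box=6):
    """Independent re-implementation: plain Python sum over the box and
    median over the one-pixel ring around it."""
    r, c = center
    anchor = box // 2 - 1 if box % 2 == 0 else box // 2
    r0, c0 = r - anchor, c - anchor
    raw = sum(image[i][j] for i in range(r0, r0 + box) for j in range(c0, c0 + box))
    ring = []
    for i in range(r0 - 1, r0 + box + 1):
        for j in range(c0 - 1, c0 + box + 1):
            if i < r0 or i >= r0 + box or j < c0 or j >= c0 + box:
                ring.append(image[i][j])
    return raw, statistics.median(ring), raw - box * box * statistics.median(ring)


class TestLocateSpot:
    def test_delta_spike(self):
        img = np.zeros((1, 32, 32))
        img[0, 10, 12] = 5.0
        assert locate_spot(SpotStack(img)) == (10, 12)

    def test_uniform_image_tie_breaks_to_origin(self):
        with pytest.warns(UserWarning):
            assert locate_spot(SpotStack(np.ones((2, 16, 16)))) == (0, 0)

    def test_subpixel_spot_located_within_one_pixel(self):
        truth = SpotTruth(spots=[((4.5, 20.3, 41.7), 10000.0)], background_level=0.0, psf_sigma=1.0)
        stack = generate_spot_stack(truth, noise="none", image_size=64)
        r, c = locate_spot(stack)
        assert abs(r - 20) <= 1 and abs(c - 42) <= 1

    def test_roi_restricts_search(self):
        img = np.zeros((1, 40, 40))
        img[0, 5, 5] = 10.0
        img[0, 30, 30] = 7.0
        assert locate_spot(SpotStack(img), roi=(20, 20, 40, 40)) == (30, 30)
        with pytest.raises(ValueError):
            locate_spot(SpotStack(img), roi=(20, 20, 80, 80))


class TestMeasureSpot:
    def test_zero_stack(self):
        m = measure_spot(SpotStack(np.zeros((2, 20, 20))), (10, 10))
        assert m.raw_integral == 0 and m.corrected_intensity == 0

    def test_flat_field_null(self):
        m = measure_spot(SpotStack(np.full((3, 20, 20), 7.0)), (10, 10))
        assert m.raw_integral == pytest.approx(36 * 21.0)
        assert m.corrected_intensity == 0.0

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            img = rng.uniform(0, 1000, size=(20, 20))
            m = measure_spot(SpotStack(img[None]), (10, 10))
            raw, bg, corr = brute_force_measure(img.tolist(), (10, 10))
            assert m.raw_integral == pytest.approx(raw, rel=1e-12)
            assert m.background_per_pixel == bg
            assert m.corrected_intensity == pytest.approx(corr, rel=1e-12, abs=1e-9)

    def test_psf_mass_recovered_within_three_percent(self):
        truth = SpotTruth(spots=[((4.5, 32.0, 32.0), 10000.0)], background_level=50.0, psf_sigma=1.0)
        stack = generate_spot_stack(truth, noise="none", image_size=64)
        m = measure_spot(stack, locate_spot(stack))
        # expected box mass of a sigma=1 Gaussian centered on a pixel
        from scipy.special import erf

        def axis_mass(lo, hi, mu, sigma=1.0):
            f = lambda x: 0.5 * (1 + erf((x - mu) / (sigma * math.sqrt(2))))
            return f(hi) - f(lo)

        mass = axis_mass(29.5, 35.5, 32.0) ** 2  # 6x6 box anchored at (2, 2)
        assert m.corrected_intensity == pytest.approx(10000.0 * mass, rel=0.03)

    def test_linearity_in_spot_intensity(self):
        intensities = [2000.0, 8000.0, 20000.0]
        measured = []
        for total in intensities:
            truth = SpotTruth(spots=[((4.5, 32.0, 32.0), total)], background_level=20.0, psf_sigma=1.0)
            stack = generate_spot_stack(truth, noise="none", image_size=64)
            measured.append(measure_spot(stack, locate_spot(stack)).corrected_intensity)
        slope = np.polyfit(intensities, measured, 1)[0]
        assert 0.9 < slope < 1.0  # box mass factor, constant across intensities
        ratios = np.array(measured) / np.array(intensities)
        assert np.ptp(ratios) / ratios.mean() < 0.03

    def test_boundary_error_and_nearby_area_fallback(self):
        img = np.full((1, 20, 20), 5.0)
        with pytest.raises(ValueError):
            measure_spot(SpotStack(img), (1, 10))
        m = measure_spot(SpotStack(img), (10, 10), background_area=(0, 0))
        assert m.corrected_intensity == 0.0

    def test_zmode_sum_preserves_signal_vs_max(self):
        truth = SpotTruth(spots=[((4.5, 32.0, 32.0), 9000.0)], background_level=0.0, psf_sigma=1.0)
        stack = generate_spot_stack(truth, noise="none", image_size=64)
        m_sum = measure_spot(stack, locate_spot(stack), zmode="sum")
        m_max = measure_spot(stack, locate_spot(stack, zmode="max"), zmode="max")
        assert m_sum.corrected_intensity > m_max.corrected_intensity > 0


class TestNormalization:
    def test_simple_ratios(self):
        assert np.allclose(normalize_intensities([2, 4], [2, 2]), [1.0, 2.0])

    def test_self_normalization_mean_one(self):
        vals = [3.0, 5.0, 9.5]
        assert normalize_intensities(vals, vals).mean() == pytest.approx(1.0)

    def test_half_intensity_strain_reads_half(self):
        rng = np.random.default_rng(23)
        strain_a, strain_b = [], []
        for i in range(40):
            for strain, per_kt, out in (("a", 2000.0, strain_a), ("b", 1000.0, strain_b)):
                truth = SpotTruth(
                    spots=[((4.5, 32.0, 32.0), 16 * per_kt)],
                    background_level=100.0,
                    psf_sigma=1.2,
                )
                stack = generate_spot_stack(
                    truth, noise="poisson", image_size=64, seed=int(rng.integers(2**31))
                )
                out.append(measure_spot(stack, locate_spot(stack)).corrected_intensity)
        normalized_b = normalize_intensities(strain_b, strain_a)
        assert normalized_b.mean() == pytest.approx(0.5, abs=0.05)

    def test_reference_errors(self):
        with pytest.raises(ValueError):
            normalize_intensities([1.0], [])
        with pytest.raises(ValueError):
            normalize_intensities([1.0], [-2.0, 2.0])


class TestUnattachedCount:
    def test_zero_unattached(self):
        assert estimate_unattached_count(0.0, 100.0).estimate == 0

    def test_symmetric_split(self):
        assert estimate_unattached_count(50.0, 50.0).estimate == 16

    def test_bankers_rounding(self):
        # 32 * 0.5/ (0.5 + 7.5) = 2.0 exactly; 3/32 boundary rounds to even
        est = estimate_unattached_count(3.0, 61.0)  # 32*3/64 = 1.5 -> 2
        assert est.estimate == 2
        est = estimate_unattached_count(5.0, 59.0)  # 32*5/64 = 2.5 -> 2
        assert est.estimate == 2

    def test_both_zero_raises(self):
        with pytest.raises(ValueError):
            estimate_unattached_count(0.0, 0.0)

    def test_negative_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            est = estimate_unattached_count(-5.0, 100.0)
        assert est.estimate == 0

    @given(
        st.floats(0, 1e6),
        st.floats(0.001, 1e6),
        st.integers(1, 64),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_and_monotonicity(self, f_u, f_s, total):
        est = estimate_unattached_count(f_u, f_s, total)
        assert 0 <= est.estimate <= total
        bigger = estimate_unattached_count(f_u + 1.0, f_s, total)
        assert bigger.estimate >= est.estimate

    def test_noiseless_cell_recovers_truth(self):
        stack, meta = generate_kinetochore_pair(5, noise="none", seed=2)
        q = SpotQuantifier()
        m_u = q.measure(stack, roi=meta["roi_unattached"])
        m_s = q.measure(stack, roi=meta["roi_spindle"])
        assert q.unattached_count(m_u, m_s).estimate == 5


class TestSummarizeCounts:
    def test_constant(self):
        s = summarize_counts([5, 5, 5])
        assert s["mean"] == 5 and s["sd"] == 0

    def test_two_point_sd(self):
        s = summarize_counts([0, 10])
        assert s["mean"] == 5 and s["sd"] == pytest.approx(7.07, abs=0.005)

    def test_histogram_matches_sampling_distribution(self):
        rng = np.random.default_rng(6)
        probs = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        draws = rng.choice(5, size=2000, p=probs)
        s = summarize_counts(draws)
        assert s["frequency"].sum() == pytest.approx(1.0)
        # multinomial standard error ~ sqrt(p(1-p)/n) <= 0.011
        assert np.abs(s["frequency"] - probs).max() < 0.05
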