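"""Background estimation, bin profiles, map assembly, pooled intactness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from axotrace import colliculus as scq
from axotrace.colliculus import SCSection
from axotrace.errors import (
    InvalidParameterError,
    MissingReferenceError,
    NoDataError,
)
from conftest import random_section


def _section_with_bg(bg_values, shape=(10, 10)):
    pixels = np.zeros(shape)
    bg = np.zeros(shape, bool)
    for i, v in enumerate(bg_values):
        pixels[0, i] = v
        bg[0, i] = True
    roi = np.zeros(shape, bool)
    roi[5:8, :] = True
    return SCSection(pixels=pixels, roi_mask=roi, background_roi=bg)


def brute_force_profile(section, threshold, n_bins):
    """Per-pixel tally oracle: explicit loops, no vectorized shortcuts."""
    rows, cols = np.nonzero(section.roi_mask)
    if section.flip:
        cols = section.pixels.shape[1] - 1 - cols
    cmin, cmax = cols.min(), cols.max()
    extent = cmax - cmin + 1
    totals = [0] * n_bins
    hits = [0] * n_bins
    for r, c in zip(rows, cols):
        b = min(((c - cmin) * n_bins) // extent, n_bins - 1)
        totals[b] += 1
        if section.flip:
            value = section.pixels[r, section.pixels.shape[1] - 1 - c]
        else:
            value = section.pixels[r, c]
        if value > threshold:
            hits[b] += 1
    return np.array([h / t if t else np.nan for h, t in zip(hits, totals)])


def brute_force_pooled(sections, k):
    total = above = 0
    for sec in sections:
        if not sec.roi_mask.any():
            continue
        thr = scq.estimate_background(sec, k)
        for r, c in zip(*np.nonzero(sec.roi_mask)):
            total += 1
            if sec.pixels[r, c] > thr:
                above += 1
    return 100.0 * above / total


class TestBackground:
    def test_constant_reference_any_k(self):
        sec = _section_with_bg([50.0] * 5)
        assert scq.estimate_background(sec, k=7.3) == 50.0

    def test_mean_plus_sample_sd(self):
        sec = _section_with_bg([10.0, 20.0, 30.0])
        assert scq.estimate_background(sec, k=1.0) == pytest.approx(30.0)

    def test_matches_definition_on_random_reference(self, rng):
        vals = rng.uniform(0, 255, 40)
        sec = _section_with_bg(vals, shape=(10, 50))
        expected = vals.mean() + 2.0 * vals.std(ddof=1)
        assert scq.estimate_background(sec, k=2.0) == pytest.approx(
            expected, abs=1e-12)

    def test_empty_reference_raises(self):
        pixels = np.zeros((10, 10))
        roi = np.ones((10, 10), bool)
        sec = SCSection(pixels=pixels, roi_mask=roi,
                        background_roi=np.zeros((10, 10), bool))
        with pytest.raises(MissingReferenceError):
            scq.estimate_background(sec, 2.0)


class TestBinProfile:
    def test_all_above_threshold(self, rng):
        sec = random_section(rng)
        prof = scq.bin_density_profile(sec, threshold=-1.0, n_bins=5)
        assert np.all(prof.bin_fractions[np.isfinite(prof.bin_fractions)] == 1.0)

    def test_none_above_threshold(self, rng):
        sec = random_section(rng)
        prof = scq.bin_density_profile(sec, threshold=1e9, n_bins=5)
        assert np.all(prof.bin_fractions[np.isfinite(prof.bin_fractions)] == 0.0)

    @pytest.mark.parametrize("n_bins", [1, 3, 4, 7])
    def test_matches_brute_force_oracle(self, rng, n_bins):
        for _ in range(20):
            sec = random_section(rng)
            thr = float(rng.uniform(20, 80))
            prof = scq.bin_density_profile(sec, thr, n_bins)
            oracle = brute_force_profile(sec, thr, n_bins)
            np.testing.assert_array_equal(prof.bin_fractions, oracle)

    def test_flip_reverses_mediolateral_order(self):
        pixels = np.zeros((4, 10))
        pixels[:, :5] = 100.0  # bright on the left
        roi = np.ones((4, 10), bool)
        bg = np.zeros((4, 10), bool)
        plain = SCSection(pixels=pixels, roi_mask=roi, background_roi=bg)
        flipped = SCSection(pixels=pixels, roi_mask=roi, background_roi=bg,
                            flip=True)
        a = scq.bin_density_profile(plain, 50.0, 2).bin_fractions
        b = scq.bin_density_profile(flipped, 50.0, 2).bin_fractions
        np.testing.assert_array_equal(a, b[::-1])

    def test_empty_span_flagged_nan(self):
        pixels = np.zeros((4, 30))
        roi = np.zeros((4, 30), bool)
        roi[:, :3] = True
        roi[:, 27:] = True  # gap in the middle -> empty central bins
        sec = SCSection(pixels=pixels, roi_mask=roi,
                        background_roi=np.zeros((4, 30), bool))
        prof = scq.bin_density_profile(sec, -1.0, n_bins=10)
        assert np.isnan(prof.bin_fractions[4])
        assert prof.bin_fractions[0] == 1.0

    def test_invalid_bins_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            scq.bin_density_profile(random_section(rng), 0.0, n_bins=0)

    def test_threshold_monotonicity(self, rng):
        # raising the background margin can never raise any bin fraction
        for _ in range(10):
            sec = random_section(rng)
            lo = scq.bin_density_profile(sec, 30.0, 6).bin_fractions
            hi = scq.bin_density_profile(sec, 60.0, 6).bin_fractions
            good = np.isfinite(lo) & np.isfinite(hi)
            assert np.all(hi[good] <= lo[good])


class TestDensityMap:
    def test_single_constant_profile(self):
        prof = scq.DensityProfile(np.full(7, 0.5), threshold_used=1.0)
        dmap = scq.build_density_map([prof], n_bins_out=12)
        assert dmap.values_pct.shape == (1, 12)
        np.testing.assert_allclose(dmap.values_pct, 50.0)

    def test_resampling_identity_when_lengths_match(self, rng):
        vals = rng.uniform(0, 1, 9)
        prof = scq.DensityProfile(vals, threshold_used=0.0)
        dmap = scq.build_density_map([prof], n_bins_out=9)
        np.testing.assert_array_equal(dmap.values_pct[0], vals * 100.0)

    def test_rows_ordered_rostrocaudally(self):
        p2 = scq.DensityProfile(np.full(4, 0.2), 0.0, rostrocaudal_index=2)
        p1 = scq.DensityProfile(np.full(4, 0.1), 0.0, rostrocaudal_index=1)
        dmap = scq.build_density_map([p2, p1], n_bins_out=4)
        np.testing.assert_allclose(dmap.values_pct[:, 0], [10.0, 20.0])
        assert dmap.section_indices == [1, 2]

    @settings(max_examples=50, derandomize=True)
    @given(vals=hst.lists(hst.floats(0.0, 1.0), min_size=3, max_size=40),
           n_down=hst.integers(2, 10))
    def test_down_up_resampling_stays_bounded_preserves_endpoints(
            self, vals, n_down):
        vals = np.asarray(vals)
        prof = scq.DensityProfile(vals, 0.0)
        down = scq.build_density_map([prof], n_bins_out=n_down)
        up = scq.build_density_map(
            [scq.DensityProfile(down.values_pct[0] / 100.0, 0.0)],
            n_bins_out=vals.size)
        out = up.values_pct[0]
        assert np.all(out >= 0.0) and np.all(out <= 100.0)
        # the mediolateral endpoints survive a down/up round trip exactly
        assert out[0] == pytest.approx(100.0 * vals[0], abs=1e-9)
        assert out[-1] == pytest.approx(100.0 * vals[-1], abs=1e-9)

    def test_empty_list_rejected(self):
        with pytest.raises(NoDataError):
            scq.build_density_map([], 10)


class TestIntactFraction:
    def _uniform_stack(self, value, n=3):
        sections = []
        for i in range(n):
            pixels = np.full((20, 20), value)
            roi = np.zeros((20, 20), bool)
            roi[2:8] = True
            bg = np.zeros((20, 20), bool)
            bg[12:18] = True
            pixels[bg] = 10.0
            sections.append(SCSection(pixels=pixels, roi_mask=roi,
                                      background_roi=bg,
                                      rostrocaudal_index=i))
        return sections

    def test_fully_labeled_stack_is_100(self):
        assert scq.sc_intact_fraction(self._uniform_stack(200.0), k=2.0) == 100.0

    def test_unlabeled_stack_is_0(self):
        assert scq.sc_intact_fraction(self._uniform_stack(10.0), k=2.0) == 0.0

    def test_half_labeled_fixture_is_50(self):
        pixels = np.full((10, 10), 0.0)
        roi = np.zeros((10, 10), bool)
        roi[0:4] = True  # 40 roi pixels
        pixels[0:2] = 100.0  # exactly half of them bright
        bg = np.zeros((10, 10), bool)
        bg[8:] = True
        pixels[8:] = 10.0
        sec = SCSection(pixels=pixels, roi_mask=roi, background_roi=bg)
        assert scq.sc_intact_fraction([sec], k=2.0) == pytest.approx(50.0)

    def test_matches_brute_force_pooled_count(self, rng):
        sections = [random_section(rng) for _ in range(4)]
        ours = scq.sc_intact_fraction(sections, k=1.0)
        assert ours == pytest.approx(brute_force_pooled(sections, 1.0), abs=0)

    def test_aggregation_identity(self, rng):
        # roi-weighted mean of bin fractions == pooled fraction to 1e-12
        for _ in range(10):
            sec = random_section(rng, shape=(16, 16))
            thr = scq.estimate_background(sec, k=0.5)
            n_bins = 4
            prof = scq.bin_density_profile(sec, thr, n_bins)
            cols = np.nonzero(sec.roi_mask)[1]
            cmin, cmax = cols.min(), cols.max()
            extent = cmax - cmin + 1
            b = np.minimum(((cols - cmin) * n_bins) // extent, n_bins - 1)
            weights = np.bincount(b, minlength=n_bins)
            good = weights > 0
            weighted = np.sum(prof.bin_fractions[good] * weights[good]) / weights.sum()
            pooled = scq.sc_intact_fraction([sec], k=0.5) / 100.0
            assert weighted == pytest.approx(pooled, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(NoDataError):
            scq.sc_intact_fraction([], k=2.0)
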