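"""Fluorescence quantification: peaks, CTWF/RID, puncta."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nemaphen.config import PeakParams
from nemaphen.fluorescence import (
    background_mean,
    ctwf,
    find_peaks,
    measure_fluorescence,
    puncta_morphometry,
    rid,
)

from conftest import bar_mask


def _gaussian_blob(shape, center, amp, sigma=2.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return amp * np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)))


class TestFindPeaks:
    def test_single_blob_found_at_center(self, peak_params):
        mask = bar_mask(30, 60, canvas=(40, 70))
        fl = _gaussian_blob(mask.shape, (20, 35), 0.8) * mask
        peaks = find_peaks(fl, mask, peak_params)
        assert peaks.count == 1
        assert np.hypot(*(peaks.coordinates[0] - (20, 35))) <= 1

    def test_all_zero_crop_yields_empty_set(self, peak_params):
        mask = bar_mask(10, 20)
        peaks = find_peaks(np.zeros(mask.shape), mask, peak_params)
        assert peaks.count == 0
        assert math.isnan(peaks.mean_intensity)

    def test_planted_separated_peaks_all_found(self, peak_params):
        mask = np.ones((100, 140), dtype=bool)
        mask[0] = mask[-1] = mask[:, 0] = mask[:, -1] = False
        centers = [(15, 15), (15, 70), (15, 125), (50, 40), (50, 100), (85, 15), (85, 125)]
        fl = np.zeros(mask.shape)
        for k, c in enumerate(centers):
            fl += _gaussian_blob(mask.shape, c, 0.6 + 0.05 * k)
        peaks = find_peaks(fl, mask, peak_params)
        assert peaks.count == 7

    def test_close_pair_suppressed_to_brighter(self):
        params = PeakParams(neighborhood=11, threshold_frac=0.3)
        mask = np.ones((40, 40), dtype=bool)
        fl = np.zeros((40, 40))
        fl[20, 20] = 1.0
        fl[20, 23] = 0.8  # 3 px away, inside the 11x11 square
        peaks = find_peaks(fl, mask, params)
        assert peaks.count == 1
        assert tuple(peaks.coordinates[0]) == (20, 20)

    def test_peaks_outside_mask_discarded(self, peak_params):
        mask = bar_mask(20, 20, canvas=(60, 60))
        fl = _gaussian_blob((60, 60), (5, 5), 1.0)  # bright corner, off-worm
        fl += _gaussian_blob((60, 60), (30, 30), 0.9)  # on-worm
        peaks = find_peaks(fl, mask, peak_params)
        assert peaks.count == 1
        assert mask[tuple(peaks.coordinates[0])]

    @given(st.integers(0, 500))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_brute_force_suppression_oracle(self, seed):
        """O(n^2) all-pairs oracle on small random crops."""
        rng = np.random.default_rng(seed)
        fl = rng.random((48, 48))
        mask = np.zeros((48, 48), dtype=bool)
        mask[8:40, 8:40] = True
        params = PeakParams(neighborhood=9, threshold_frac=0.6)
        peaks = find_peaks(fl, mask, params)
        # oracle: full scan for strict local maxima, then greedy suppression
        half = 4
        floor = 0.6 * fl.max()
        cands = []
        for r in range(48):
            for c in range(48):
                if not mask[r, c] or fl[r, c] < floor:
                    continue
                window = fl[max(0, r - half) : r + half + 1, max(0, c - half) : c + half + 1]
                if fl[r, c] == window.max():
                    cands.append((r, c))
        cands.sort(key=lambda rc: (-fl[rc], rc[0], rc[1]))
        accepted = []
        for r, c in cands:
            if all(abs(r - ar) > half or abs(c - ac) > half for ar, ac in accepted):
                accepted.append((r, c))
        assert sorted(map(tuple, peaks.coordinates)) == sorted(accepted)


class TestBackgroundAndIntegrals:
    def test_uniform_background(self):
        mask = bar_mask(10, 20, canvas=(40, 40))
        fl = np.where(mask, 0.7, 0.1)
        assert background_mean(fl, mask) == pytest.approx(0.1)

    def test_bimodal_background_averages(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4:6, 4:6] = True
        fl = np.zeros((10, 10))
        fl[:5][~mask[:5]] = 0.0
        fl[5:][~mask[5:]] = 0.2
        assert background_mean(fl, mask) == pytest.approx(
            fl[~mask].mean()
        )

    def test_full_mask_rejected(self):
        mask = np.ones((5, 5), dtype=bool)
        with pytest.raises(ValueError, match="background"):
            background_mean(np.zeros((5, 5)), mask)

    def test_ctwf_zero_when_worm_matches_background(self):
        mask = bar_mask(10, 20, canvas=(40, 40))
        fl = np.full((40, 40), 0.3)
        bg = background_mean(fl, mask)
        assert ctwf(fl, mask, bg) == pytest.approx(0.0)

    def test_ctwf_arithmetic(self):
        mask = bar_mask(10, 20, canvas=(40, 40))  # 200 px worm
        fl = np.where(mask, 0.5, 0.1)
        bg = background_mean(fl, mask)
        assert ctwf(fl, mask, bg) == pytest.approx((0.5 - 0.1) * 200)
        assert rid(fl, mask, bg) == pytest.approx(80.0)

    @given(st.integers(0, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ctwf_rid_algebraic_identity(self, seed):
        rng = np.random.default_rng(seed)
        fl = rng.random((30, 30))
        mask = rng.random((30, 30)) < 0.4
        mask[0, 0] = False  # keep one background pixel
        if not mask.any():
            mask[15, 15] = True
        bg = background_mean(fl, mask)
        c, r = ctwf(fl, mask, bg), rid(fl, mask, bg)
        assert abs(c - r) <= 1e-9 * max(abs(r), 1e-12)

    def test_additivity_constant_offset_cancels(self):
        rng = np.random.default_rng(4)
        fl = rng.random((30, 30))
        mask = bar_mask(8, 16, canvas=(30, 30))
        bg = background_mean(fl, mask)
        shifted_bg = background_mean(fl + 0.25, mask)
        assert ctwf(fl + 0.25, mask, shifted_bg) == pytest.approx(ctwf(fl, mask, bg))
        assert rid(fl + 0.25, mask, shifted_bg) == pytest.approx(rid(fl, mask, bg))

    def test_scale_equivariance(self, peak_params):
        rng = np.random.default_rng(5)
        mask = bar_mask(20, 40, canvas=(50, 60))
        fl = _gaussian_blob(mask.shape, (25, 30), 0.5) + rng.random(mask.shape) * 0.05
        rec1 = measure_fluorescence(fl, mask, peak_params)
        rec2 = measure_fluorescence(3.0 * fl, mask, peak_params)
        assert rec2.peak_count == rec1.peak_count
        assert rec2.ctwf == pytest.approx(3.0 * rec1.ctwf)
        assert rec2.rid == pytest.approx(3.0 * rec1.rid)
        assert rec2.peak_mean == pytest.approx(3.0 * rec1.peak_mean)


class TestPuncta:
    def test_single_punctum_relative_size(self, peak_params):
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:45, 5:30] = True  # 1000-px worm
        fl = np.full((60, 60), 0.01)
        fl[20:25, 15:20] = 1.0  # 25-px bright punctum
        peaks = find_peaks(fl, mask, peak_params)
        sizes, mean_rel = puncta_morphometry(fl, mask, peaks, peak_params)
        assert sizes == [25]
        assert mean_rel == pytest.approx(2.5)

    def test_no_peaks_gives_empty_sizes(self, peak_params):
        mask = bar_mask(10, 20)
        peaks = find_peaks(np.zeros(mask.shape), mask, peak_params)
        sizes, mean_rel = puncta_morphometry(np.zeros(mask.shape), mask, peaks, peak_params)
        assert sizes == []
        assert math.isnan(mean_rel)

    def test_aging_series_ordering(self):
        """More, smaller puncta (aged worms) move count up and mean size down."""
        from nemaphen.synthetic import FluorSpec, SyntheticSpec, generate_plate
        from nemaphen.pipeline import process_plate, build_feature_table

        counts, relsizes = [], []
        for n_puncta, sigma in ((3, 3.0), (8, 1.6)):
            spec = SyntheticSpec(
                n_worms=6,
                image_size=(800, 800),
                seed=21,
                fluor={"YFP": FluorSpec(puncta_count=n_puncta, puncta_sigma=sigma,
                                        puncta_min_separation=20.0, worm_base=0.05,
                                        puncta_amplitude=0.8)},
            )
            plate, _ = generate_plate(spec)
            crops = process_plate(plate)
            table, _ = build_feature_table(crops, 1.14, 1.14)
            counts.append(table["peak_count_YFP"].mean())
            relsizes.append(table["puncta_mean_relsize_pct_YFP"].mean())
        assert counts[1] > counts[0]
        assert relsizes[1] < relsizes[0]
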