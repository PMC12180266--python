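"""Optical metrics (peaks, FWHM, MAD, SNR/SBR) and stitch deduplication."""

import math

import numpy as np
import pytest
from scipy.signal import peak_widths

import stqc
from stqc.imaging import GAUSSIAN_FWHM_FACTOR
from stqc.simulate import LineProfile


class TestDetectLocalMaxima:
    def test_single_bright_pixel(self):
        img = np.zeros((9, 9))
        img[4, 6] = 10.0
        peaks = stqc.detect_local_maxima(img, threshold=5.0)
        assert peaks.tolist() == [[4, 6]]

    def test_two_separated_gaussians(self):
        yy, xx = np.mgrid[0:40, 0:40]
        img = 100 * np.exp(-((yy - 10) ** 2 + (xx - 10) ** 2) / 8) + 80 * np.exp(
            -((yy - 30) ** 2 + (xx - 30) ** 2) / 8
        )
        peaks = stqc.detect_local_maxima(img, threshold=10.0, min_distance=5)
        assert sorted(peaks.tolist()) == [[10, 10], [30, 30]]

    def test_all_below_threshold(self):
        img = np.random.default_rng(0).uniform(0, 1, (10, 10))
        assert len(stqc.detect_local_maxima(img, threshold=5.0)) == 0

    def test_suppression_keeps_brighter(self):
        img = np.zeros((9, 9))
        img[4, 4] = 10.0
        img[4, 6] = 8.0
        peaks = stqc.detect_local_maxima(img, threshold=1.0, min_distance=4)
        assert peaks.tolist() == [[4, 4]]


class TestFwhm:
    def test_sampled_gaussian_closed_form(self):
        sigma = 2.0
        x = np.arange(-10, 11, dtype=float)
        profile = np.exp(-(x**2) / (2 * sigma**2))
        expected = GAUSSIAN_FWHM_FACTOR * sigma  # 4.7096 for sigma = 2
        assert stqc.fwhm(profile, spacing=1.0) == pytest.approx(expected, rel=0.01)
        assert expected == pytest.approx(4.7096, abs=1e-3)

    def test_triangle_exact(self):
        assert stqc.fwhm([0, 1, 2, 1, 0], spacing=1.0) == pytest.approx(2.0)

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError):
            stqc.fwhm([1.0, 1.0, 1.0, 1.0])

    def test_monotone_profile_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            stqc.fwhm([0.0, 1.0, 2.0, 3.0])

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (1.0, 5.0), (3.5, -1.0)])
    def test_affine_intensity_invariance(self, a, b):
        x = np.arange(-8, 9, dtype=float)
        p = np.exp(-(x**2) / 6.0)
        assert stqc.fwhm(a * p + b) == pytest.approx(stqc.fwhm(p), rel=1e-9)

    def test_matches_scipy_peak_widths(self):
        # independent cross-check on a zero-baseline Gaussian
        sigma = 3.0
        x = np.arange(-15, 16, dtype=float)
        p = np.exp(-(x**2) / (2 * sigma**2))
        ours = stqc.fwhm(p)
        scipy_w = peak_widths(p, [15], rel_height=0.5)[0][0]
        assert ours == pytest.approx(scipy_w, rel=0.02)


class TestMad:
    def test_constant(self):
        assert stqc.mad([1, 1, 1]) == 0.0

    def test_hand_example(self):
        assert stqc.mad([1, 2, 3, 4, 5]) == 1.0

    def test_single_value(self):
        assert stqc.mad([7.0]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stqc.mad([])


class TestBeadResolution:
    VOXEL = (0.108, 0.108, 0.3)  # (x, y, z) µm

    def test_recovery_within_5_percent(self):
        stack, _ = stqc.simulate_bead_stack(
            (0.47, 0.47, 0.8), self.VOXEL, 6, noise_sd=10.0, seed=2
        )
        res = stqc.bead_resolution_summary(stack, threshold=300, min_distance=5)
        assert res.fwhm_inplane_nm == pytest.approx(470.0, rel=0.05)
        assert res.fwhm_nm["z"] == pytest.approx(800.0, rel=0.05)
        assert res.n_beads == 6

    def test_single_noiseless_bead_mad_zero(self):
        stack, _ = stqc.simulate_bead_stack(
            (0.47, 0.47, 0.8), self.VOXEL, 1, noise_sd=0.0, seed=0
        )
        res = stqc.bead_resolution_summary(stack, threshold=300)
        assert res.mad_nm["z"] == 0.0
        assert res.n_beads == 1

    def test_intensity_scaling_leaves_fwhm_unchanged(self):
        stack, _ = stqc.simulate_bead_stack(
            (0.47, 0.47, 0.8), self.VOXEL, 3, noise_sd=0.0, seed=4
        )
        res1 = stqc.bead_resolution_summary(stack, threshold=300)
        doubled = stqc.BeadStack(stack.data * 2.0, stack.voxel_size)
        res2 = stqc.bead_resolution_summary(doubled, threshold=600)
        assert res1.fwhm_inplane_nm == pytest.approx(res2.fwhm_inplane_nm, rel=1e-9)

    def test_mad_grows_with_fwhm_jitter(self):
        mads = []
        for jitter in (0.0, 0.05, 0.15):
            stack, _ = stqc.simulate_bead_stack(
                (0.47, 0.47, 0.8), self.VOXEL, 8, noise_sd=0.0, seed=6,
                fwhm_jitter=jitter,
            )
            res = stqc.bead_resolution_summary(stack, threshold=300)
            mads.append(res.mad_inplane_nm)
        assert mads[0] < mads[1] < mads[2]

    def test_no_beads_detected(self):
        stack, _ = stqc.simulate_bead_stack(
            (0.47, 0.47, 0.8), self.VOXEL, 0, noise_sd=1.0, seed=0,
            shape=(20, 30, 30),
        )
        with pytest.raises(ValueError, match="no beads"):
            stqc.bead_resolution_summary(stack, threshold=500)


def _profile(center, bg_values, i_dark=0.0):
    samples = np.zeros(21)
    bg_idx = np.abs(np.arange(-10, 11)) > 5
    samples[bg_idx] = bg_values
    samples[~bg_idx] = center  # shoulders irrelevant to the estimators
    samples[10] = center
    return LineProfile(samples, i_dark=i_dark)


class TestSnrSbr:
    def test_snr_direct_evaluation(self):
        # raw center 105, dark 5, background raw mean 15 sd 2 -> (100-10)/2 = 45
        bg = np.array([13.0, 17.0] * 5)  # mean 15, sd ~2.108; rescale to sd 2
        bg = 15.0 + (bg - 15.0) * (2.0 / bg.std(ddof=1))
        p = _profile(105.0, bg, i_dark=5.0)
        assert stqc.snr(p) == pytest.approx(45.0)

    def test_flat_signal_zero_snr(self):
        bg = np.array([9.0, 11.0] * 5)
        p = _profile(10.0, bg, i_dark=0.0)
        assert stqc.snr(p) == pytest.approx(0.0)

    def test_constant_background_rejected(self):
        p = _profile(50.0, np.full(10, 10.0), i_dark=0.0)
        with pytest.raises(ValueError, match="sigma"):
            stqc.snr(p)

    def test_sbr_direct(self):
        bg = np.array([9.0, 11.0] * 5)
        p = _profile(100.0, bg, i_dark=0.0)
        assert stqc.sbr(p) == pytest.approx(10.0)

    def test_sbr_identity(self):
        bg = np.array([99.0, 101.0] * 5)
        p = _profile(100.0, bg, i_dark=0.0)
        assert stqc.sbr(p) == pytest.approx(1.0)

    def test_sbr_zero_background_rejected(self):
        # background equal to the dark level -> mu_bg = 0 after subtraction
        p = _profile(100.0, np.full(10, 5.0), i_dark=5.0)
        with pytest.raises(ValueError, match="background"):
            stqc.sbr(p)

    def test_estimators_unbiased_on_simulated_profiles(self):
        profiles, truth = stqc.simulate_spot_profiles(20.0, 3.0, 200, seed=8)
        snrs = np.array([stqc.snr(p) for p in profiles])
        sbrs = np.array([stqc.sbr(p) for p in profiles])
        se_snr = max(snrs.std(ddof=1) / np.sqrt(200), 1e-9)
        se_sbr = max(sbrs.std(ddof=1) / np.sqrt(200), 1e-9)
        assert abs(snrs.mean() - truth.snr) <= max(3 * se_snr, 1e-6)
        assert abs(sbrs.mean() - truth.sbr) <= max(3 * se_sbr, 1e-6)


def _dedup_fixture(seed=7, n=24_000):
    """Two 2144-px tiles side by side; mixed gene abundances; z in [0, 10).

    A subset of genes is abundant enough (>= 10 calls in any 60-px border
    window) to vote on the consensus shift, mirroring real panels where a
    few high expressors dominate the border population.
    """
    rng = np.random.default_rng(seed)
    n_anchor = 16
    probs = np.array([0.75 / n_anchor] * n_anchor + [0.25 / 80] * 80)
    genes = np.array([f"G{i:02d}" for i in range(96)], dtype=object)
    return stqc.TranscriptTable.from_arrays(
        gene=rng.choice(genes, size=n, p=probs),
        x=rng.uniform(0, 4288.0, n),
        y=rng.uniform(0, 2144.0, n),
        z=rng.uniform(0, 10.0, n),
    )


class TestDedupStitch:
    def test_no_points_near_lines_unchanged(self):
        rng = np.random.default_rng(1)
        n = 500
        tt = stqc.TranscriptTable.from_arrays(
            ["A"] * n,
            rng.uniform(100, 2000, n),  # all far from the x = 2144 line
            rng.uniform(0, 2000, n),
        )
        out, rate = stqc.dedup_stitch(tt, tile_size=2144.0, window=30.0)
        assert len(out) == n
        assert rate == 0.0

    def test_recovers_planted_duplicates_exactly(self):
        tt = _dedup_fixture()
        planted, truth = stqc.plant_stitch_duplicates(
            tt, 0.0015, (15.0, 6.0), 2144.0
        )
        clean, rate = stqc.dedup_stitch(planted, tile_size=2144.0, window=30.0)
        removed = set(planted.df["record_id"]) - set(clean.df["record_id"])
        pairs = truth.duplicate_pairs
        pair_ids = set(pairs["original_id"]) | set(pairs["duplicate_id"])
        # exactly one member of every planted pair removed, nothing else
        for row in pairs.itertuples(index=False):
            assert (row.original_id in removed) != (row.duplicate_id in removed)
        assert removed <= pair_ids
        assert rate == pytest.approx(len(pairs) / len(planted))

    def test_duplicate_rate_definition(self):
        tt = _dedup_fixture()
        planted, _ = stqc.plant_stitch_duplicates(tt, 0.005, (15.0, 6.0), 2144.0)
        clean, rate = stqc.dedup_stitch(planted, tile_size=2144.0, window=30.0)
        assert rate == (len(planted) - len(clean)) / len(planted)

    def test_idempotent_after_cleaning(self):
        tt = _dedup_fixture()
        planted, _ = stqc.plant_stitch_duplicates(tt, 0.0015, (15.0, 6.0), 2144.0)
        once, _ = stqc.dedup_stitch(planted, tile_size=2144.0, window=30.0)
        twice, rate2 = stqc.dedup_stitch(once, tile_size=2144.0, window=30.0)
        assert len(twice) == len(once)
        assert rate2 == 0.0

    def test_window_must_be_smaller_than_half_tile(self):
        tt = _dedup_fixture(n=100)
        with pytest.raises(ValueError, match="window"):
            stqc.dedup_stitch(tt, tile_size=100.0, window=60.0)

    def test_no_grid_lines_returns_input(self):
        tt = stqc.TranscriptTable.from_arrays(["A"], [10.0], [10.0])
        out, rate = stqc.dedup_stitch(tt, tile_size=2144.0, window=30.0)
        assert len(out) == 1 and rate == 0.0
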