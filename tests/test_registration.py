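"""Drift-correction unit and property tests.

The greedy single-pixel climb is checked against an exhaustive
translation-search oracle, and the overlap-restricted Pearson correlation
against the direct covariance formula.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import blob_image
from helpers import exhaustive_best_shift
from intravital.registration import (
    DegenerateOverlapError,
    ShiftSeries,
    apply_shifts,
    greedy_align,
    pearson_overlap,
    register_movie,
    shift_image,
    validate_correction,
)
from intravital.synthetic import SimConfig, generate_movie


# ---------------------------------------------------------------- pearson


class TestPearsonOverlap:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 4000, size=(32, 32))
        assert pearson_overlap(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 2000, size=(32, 32))
        assert pearson_overlap(a, 2 * a) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_covariance_formula(self):
        a = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=float)
        b = np.array([[2, 1, 4], [3, 6, 5], [8, 7, 9]], dtype=float)
        # independent oracle: direct covariance / (sigma_a sigma_b)
        av, bv = a.ravel(), b.ravel()
        cov = np.mean((av - av.mean()) * (bv - bv.mean()))
        expected = cov / (av.std() * bv.std())
        assert pearson_overlap(a, b, min_overlap=9) == pytest.approx(
            expected, abs=1e-12
        )

    def test_only_jointly_positive_pixels_enter(self):
        # zeroing a corner in one image must drop it from the mask
        rng = np.random.default_rng(2)
        a = rng.integers(1, 1000, size=(16, 16)).astype(float)
        b = a.copy()
        a2 = a.copy()
        a2[0, 0] = 0.0
        b[0, 0] = 999999.0  # huge value, but excluded by the a2 zero
        assert pearson_overlap(a2, b, min_overlap=32) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_dimension_mismatch_is_distinct_error(self):
        a = np.ones((16, 16))
        with pytest.raises(ValueError, match="dimension mismatch"):
            pearson_overlap(a, np.ones((16, 17)))

    def test_small_overlap_and_zero_variance_are_degenerate(self):
        a = np.zeros((16, 16))
        a[0, 0] = 5
        with pytest.raises(DegenerateOverlapError):
            pearson_overlap(a, a)
        flat = np.full((16, 16), 7.0)
        with pytest.raises(DegenerateOverlapError):
            pearson_overlap(flat, flat, min_overlap=16)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        alpha=st.floats(0.1, 50.0),
        beta=st.floats(0.0, 500.0),
        seed=st.integers(0, 100),
    )
    def test_affine_invariance_property(self, alpha, beta, seed):
        """pearson(a, alpha*a + beta) = 1 for alpha > 0, beta >= 0."""
        rng = np.random.default_rng(seed)
        a = rng.uniform(1.0, 1000.0, size=(16, 16))
        assert pearson_overlap(a, alpha * a + beta) == pytest.approx(
            1.0, abs=1e-9
        )


# ------------------------------------------------------------ shift_image


class TestShiftImage:
    def test_zero_shift_is_identity(self):
        img = np.arange(16).reshape(4, 4)
        assert np.array_equal(shift_image(img, 0, 0), img)

    def test_inverse_composition_restores_interior(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 4096, size=(12, 12))
        back = shift_image(shift_image(img, 3, -2), -3, 2)
        # rows vacated by the round trip: first 2; cols: last 3
        assert np.array_equal(back[2:, :-3], img[2:, :-3])

    def test_ramp_column_shift(self):
        img = np.arange(16).reshape(4, 4)
        out = shift_image(img, 1, 0)
        assert np.all(out[:, 0] == 0)
        assert np.array_equal(out[:, 1:], img[:, :-1])

    def test_shift_as_large_as_image_rejected(self):
        with pytest.raises(ValueError):
            shift_image(np.ones((8, 8)), 8, 0)

    def test_input_not_modified(self):
        img = np.ones((8, 8), dtype=np.uint16)
        ref = img.copy()
        shift_image(img, 2, 2)
        assert np.array_equal(img, ref)


# ------------------------------------------------------------ greedy_align


class TestGreedyAlign:
    def test_already_aligned_returns_zero_shift(self):
        ref = blob_image()
        shift, r, converged = greedy_align(ref, ref)
        assert shift == (0, 0)
        assert converged
        assert r == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("disp", [(3, -2), (5, 0), (-7, 4), (0, 9)])
    def test_recovers_blob_translation_matches_exhaustive(self, disp):
        ref = blob_image()
        moving = shift_image(ref, *disp)
        shift, r, converged = greedy_align(ref, moving)
        assert converged
        assert shift == (-disp[0], -disp[1])
        oracle_shift, oracle_r = exhaustive_best_shift(ref, moving, window=10)
        assert shift == oracle_shift
        assert r == pytest.approx(oracle_r, abs=1e-12)

    def test_random_texture_translation(self):
        # spatially correlated positive texture: correlation falls off
        # smoothly with shift, as in real tissue images, so the greedy
        # climb has a monotone path to the optimum
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(4)
        ref = 500 + 400 * gaussian_filter(
            rng.standard_normal((48, 48)), sigma=2.0
        )
        ref = np.clip(np.rint(ref), 1, 4095).astype(np.uint16)
        moving = shift_image(ref, 5, 0)
        shift, _, converged = greedy_align(ref, moving)
        assert converged
        assert shift == (-5, 0)
        assert shift == exhaustive_best_shift(ref, moving, window=8)[0]

    def test_accepted_correlations_strictly_increase(self):
        ref = blob_image()
        moving = shift_image(ref, 6, -5)
        trace: list[float] = []
        greedy_align(ref, moving, trace=trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) > 0)

    def test_degenerate_start_raises(self):
        flat = np.full((32, 32), 9.0)
        with pytest.raises(DegenerateOverlapError):
            greedy_align(flat, flat)

    def test_tiny_frames_rejected(self):
        img = blob_image(shape=(8, 8), center=(4, 4), sigma=2)
        with pytest.raises(ValueError, match="smaller"):
            greedy_align(img, img)


# ----------------------------------------------------------- movie level


class TestRegisterMovie:
    def test_zero_drift_noiseless_yields_zero_shifts(self):
        cfg = SimConfig(
            seed=5, n_static_cells=6, n_migratory_cells=0, n_cluster_events=0,
            noise_sd=0.0, static_jitter_frac=0.0,
            drift_shifts=[(0, 0)] * 5,
        )
        stack, _ = generate_movie(cfg)
        _, series = register_movie(stack)
        assert np.all(series.shifts == 0)
        assert series.converged.all()

    def test_recovers_random_walk_drift(self, noiseless_static_movie):
        cfg, stack, truth = noiseless_static_movie
        corrected, series = register_movie(stack)
        assert np.array_equal(series.shifts, -truth.true_shifts)
        # cross-check against the exhaustive oracle, frame by frame
        ref = stack.frame(0, "rfp")
        for t in range(1, stack.n_frames):
            window = int(np.abs(truth.true_shifts[t]).max()) + 2
            oracle, _ = exhaustive_best_shift(
                ref, stack.frame(t, "rfp"), window=window
            )
            assert tuple(series.shifts[t]) == oracle

    def test_registration_is_idempotent(self, noiseless_static_movie):
        _, stack, _ = noiseless_static_movie
        corrected, _ = register_movie(stack)
        _, series2 = register_movie(corrected)
        assert np.all(series2.shifts == 0)

    def test_round_trip_reapplying_shifts_is_bit_exact(
        self, noiseless_static_movie
    ):
        _, stack, _ = noiseless_static_movie
        corrected, series = register_movie(stack)
        again = apply_shifts(stack, series)
        assert np.array_equal(again.data, corrected.data)

    def test_shift_series_frame0_invariant(self):
        with pytest.raises(ValueError):
            ShiftSeries(
                shifts=np.array([[1, 0], [0, 0]]),
                r_final=np.ones(2),
                converged=np.ones(2, bool),
            )


# ------------------------------------------------------------- validation


class TestValidateCorrection:
    def test_static_landmarks_pass(self):
        tracks = np.zeros((3, 5, 2))
        success, max_res, res = validate_correction(tracks, 20.0, 1.0)
        assert success
        assert max_res == 0.0

    def test_landmark_beyond_half_diameter_fails(self):
        tracks = np.zeros((2, 5, 2))
        tracks[1, 4, 0] = 12.0  # 0.6 x 20 um diameter
        success, max_res, _ = validate_correction(tracks, 20.0, 1.0)
        assert not success
        assert max_res == pytest.approx(12.0)

    def test_boundary_is_strict_less_than(self):
        tracks = np.zeros((1, 5, 2))
        tracks[0, 4, 0] = 10.0  # exactly half of 20 um
        success, _, _ = validate_correction(tracks, 20.0, 1.0)
        assert not success

    def test_errors_on_no_landmarks_and_short_window(self):
        with pytest.raises(ValueError, match="no landmarks"):
            validate_correction(np.zeros((0, 5, 2)), 20.0, 1.0)
        with pytest.raises(ValueError, match="window"):
            validate_correction(np.zeros((1, 3, 2)), 20.0, 1.0)
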