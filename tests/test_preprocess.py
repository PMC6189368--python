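"""Temporal preprocessing contracts: volume discard, motion screening, FD,
scrubbing, nuisance regression, band-pass and spatial smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgbc import (
    BoldRun,
    MotionTrace,
    ScalarMap,
    bandpass,
    compute_fd,
    discard_initial_volumes,
    exceeds_motion_limits,
    preprocess_for_fc,
    preprocess_for_wgbc,
    regress_nuisance,
    scrub,
    smooth_volume,
)
from wgbc.preprocess import FC_VARIANT, WGBC_VARIANT, FdSeries, NuisanceSet, build_nuisance
from wgbc.synthetic import generate_motion_trace


def _run(n_t=64, shape=(3, 3, 2), tr=2.0, seed=0):
    rng = np.random.default_rng(seed)
    return BoldRun(rng.standard_normal((*shape, n_t)), np.eye(4), tr)


class TestDiscard:
    def test_acquisition_length_discard(self):
        run = _run(240)
        assert discard_initial_volumes(run, 10).n_volumes == 230

    def test_zero_is_identity(self):
        run = _run(40)
        out = discard_initial_volumes(run, 0)
        assert np.array_equal(out.data, run.data)

    def test_discarding_whole_run_is_an_error(self):
        run = _run(40)
        with pytest.raises(ValueError):
            discard_initial_volumes(run, 40)
        # leaving a single volume is allowed but any temporal op then fails
        with pytest.raises(ValueError):
            BoldRun(run.data[..., :1], np.eye(4), 2.0)


class TestMotionLimits:
    def test_still_trace_passes(self):
        assert not exceeds_motion_limits(MotionTrace(np.zeros((20, 6))))

    def test_translation_over_limit_trips(self):
        p = np.zeros((20, 6))
        p[7, 2] = 1.6
        assert exceeds_motion_limits(MotionTrace(p))

    def test_rotation_exactly_at_limit_is_kept(self):
        p = np.zeros((20, 6))
        p[3, 4] = np.deg2rad(1.5)
        assert not exceeds_motion_limits(MotionTrace(p))
        p[3, 4] = np.deg2rad(1.5001)
        assert exceeds_motion_limits(MotionTrace(p))


class TestFd:
    def test_static_trace_is_zero(self):
        fd = compute_fd(MotionTrace(np.zeros((10, 6)))).fd
        assert np.all(fd == 0)

    def test_translation_jump_sums_absolute_deltas(self):
        p = np.zeros((5, 6))
        p[2, :3] = 0.1
        fd = compute_fd(MotionTrace(p)).fd
        assert fd[2] == pytest.approx(0.3)
        assert fd[3] == pytest.approx(0.3)  # moving back counts too

    def test_rotation_lever_arm_is_50mm(self):
        p = np.zeros((5, 6))
        p[3, 4] = 0.002
        fd = compute_fd(MotionTrace(p)).fd
        assert fd[3] == pytest.approx(0.1)

    def test_first_frame_is_zero_by_convention(self):
        p = np.random.default_rng(0).standard_normal((8, 6))
        assert compute_fd(MotionTrace(p)).fd[0] == 0.0

    def test_nonfinite_params_rejected(self):
        p = np.zeros((5, 6))
        p[1, 0] = np.nan
        with pytest.raises(ValueError):
            compute_fd(MotionTrace(p))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_fd_nonnegative_and_translation_bounded(self, seed):
        """FD is non-negative and at least the largest single-axis
        translation step, for arbitrary random-walk traces."""
        trace = generate_motion_trace(30, 0.3, seed)
        fd = compute_fd(trace).fd
        assert (fd >= 0).all()
        steps = np.abs(np.diff(trace.translations, axis=0)).max(axis=1)
        assert np.all(fd[1:] >= steps - 1e-12)


class TestScrub:
    def test_clean_trace_is_identity(self):
        run = _run(60)
        trace = generate_motion_trace(60, 0.05, 4)
        fd = compute_fd(trace)
        assert fd.fd.max() < 0.3
        out, keep = scrub(run, fd)
        assert keep.all()
        assert np.array_equal(out.data, run.data)

    def test_planted_spikes_are_deleted_exactly(self):
        spikes = [12, 30, 44]
        run = _run(60)
        trace = generate_motion_trace(60, 0.05, 4, spike_indices=spikes)
        out, keep = scrub(run, compute_fd(trace))
        assert sorted(np.flatnonzero(~keep).tolist()) == spikes
        assert out.n_volumes == 57
        np.testing.assert_array_equal(out.data, run.data[..., keep])

    def test_infinite_threshold_is_identity(self):
        run = _run(60)
        trace = generate_motion_trace(60, 0.4, 4, spike_indices=[5])
        out, keep = scrub(run, compute_fd(trace), threshold=np.inf)
        assert keep.all() and out.n_volumes == 60

    def test_over_scrubbed_run_signals_exclusion(self):
        run = _run(60)
        trace = generate_motion_trace(60, 0.05, 4, spike_indices=list(range(1, 21)))
        with pytest.raises(ValueError, match="exclude"):
            scrub(run, compute_fd(trace), min_volumes=50)


class TestRegressNuisance:
    def test_series_equal_to_regressor_vanishes(self, rng):
        reg = rng.standard_normal(40)
        data = np.tile(reg, (2, 2, 1, 1))
        run = BoldRun(data, np.eye(4), 2.0)
        out = regress_nuisance(run, NuisanceSet(reg[:, None]))
        assert np.abs(out.data).max() < 1e-10

    def test_zero_regressors_reduce_to_demeaning(self, rng):
        run = _run(40)
        out = regress_nuisance(run, NuisanceSet(np.zeros((40, 3))))
        np.testing.assert_allclose(
            out.data, run.data - run.data.mean(-1, keepdims=True), atol=1e-12
        )

    def test_residuals_orthogonal_to_all_regressors(self, rng):
        run = _run(50, seed=3)
        R = rng.standard_normal((50, 8))
        out = regress_nuisance(run, NuisanceSet(R))
        resid = out.data.reshape(-1, 50)
        inner = np.abs(resid @ R)
        scale = np.linalg.norm(resid, axis=1)[:, None] * np.linalg.norm(R, axis=0)
        assert (inner / scale).max() < 1e-8

    def test_idempotent(self, rng):
        run = _run(50, seed=5)
        nuis = NuisanceSet(rng.standard_normal((50, 4)))
        once = regress_nuisance(run, nuis)
        twice = regress_nuisance(once, nuis)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-8)


class TestBandpass:
    @pytest.mark.parametrize(
        "freq, lo, hi",
        [(0.05, 0.95, 1.05), (0.2, 0.0, 0.05)],
        ids=["passband-0.05Hz", "stopband-0.2Hz"],
    )
    def test_frequency_response(self, freq, lo, hi):
        t = np.arange(512) * 2.0
        sig = np.sin(2 * np.pi * freq * t)
        run = BoldRun(np.tile(sig, (1, 1, 2, 1)), np.eye(4), 2.0)
        out = bandpass(run).data[0, 0, 0]
        ratio = out[100:-100].std() / sig[100:-100].std()
        assert lo <= ratio <= hi

    def test_constant_series_removed(self):
        run = BoldRun(np.full((2, 2, 1, 64), 7.0), np.eye(4), 2.0)
        assert np.abs(bandpass(run).data).max() < 1e-6

    def test_invalid_band_rejected(self):
        run = _run(64)
        with pytest.raises(ValueError):
            bandpass(run, 0.1, 0.01)
        with pytest.raises(ValueError):
            bandpass(run, 0.01, 0.3)  # above Nyquist at TR=2
        with pytest.raises(ValueError):
            bandpass(_run(20))


class TestSmoothVolume:
    def test_impulse_response_fwhm_matches_request(self):
        img = np.zeros((15, 15, 15))
        img[7, 7, 7] = 1.0
        aff = np.diag([3.0, 3.0, 3.0, 1.0])
        sm = smooth_volume(ScalarMap(img, aff), 6.0).data
        prof = sm[:, 7, 7]
        half = prof.max() / 2
        x = np.arange(15.0)
        left = np.interp(half, prof[:8], x[:8])
        right = np.interp(half, prof[7:][::-1], x[7:][::-1])
        assert (right - left) * 3.0 == pytest.approx(6.0, abs=1.5)  # half a voxel
        assert sm.sum() == pytest.approx(1.0, rel=1e-6)

    def test_zero_fwhm_is_identity(self, rng):
        m = ScalarMap(rng.standard_normal((6, 6, 6)), np.eye(4))
        out = smooth_volume(m, 0.0)
        assert np.array_equal(out.data, m.data)

    def test_uniform_interior_unchanged(self):
        img = np.ones((20, 20, 20))
        sm = smooth_volume(ScalarMap(img, np.diag([3.0, 3, 3, 1])), 6.0).data
        np.testing.assert_allclose(sm[8:12, 8:12, 8:12], 1.0, atol=1e-6)

    def test_affine_preserved_bit_exactly(self, rng):
        aff = np.diag([3.0, 3, 3, 1.0])
        aff[:3, 3] = [-10, 4, 2]
        m = ScalarMap(rng.standard_normal((6, 6, 6)), aff)
        assert np.array_equal(smooth_volume(m, 6.0).affine, aff)


class TestPipelineVariants:
    def test_variant_configs_differ_only_in_global_and_smoothing(self):
        keys = set(WGBC_VARIANT) | set(FC_VARIANT)
        diffs = {k for k in keys if WGBC_VARIANT.get(k) != FC_VARIANT.get(k)}
        assert diffs == {
            "order", "global_signal_regression",
            "timeseries_smoothing_fwhm_mm", "map_smoothing_fwhm_mm",
        }
        assert WGBC_VARIANT["global_signal_regression"] is True
        assert FC_VARIANT["global_signal_regression"] is False
        assert FC_VARIANT["order"].index("smooth") < FC_VARIANT["order"].index("scrub")

    def test_both_variants_run_and_preserve_geometry(self, tiny_cohort):
        run, trace = tiny_cohort.runs[0], tiny_cohort.motion[0]
        for fn in (preprocess_for_wgbc, preprocess_for_fc):
            clean, keep = fn(run, trace, tiny_cohort.wm_mask, tiny_cohort.csf_mask,
                             min_volumes=30)
            assert clean.grid_shape == run.grid_shape
            assert np.array_equal(clean.affine, run.affine)
            assert clean.n_volumes == keep.sum() == run.n_volumes - 10

    def test_nuisance_column_count_follows_variant(self, tiny_cohort):
        run, trace = tiny_cohort.runs[0], tiny_cohort.motion[0]
        for include_global, n_cols in ((True, 9), (False, 8)):
            nuis = build_nuisance(
                run, trace, tiny_cohort.wm_mask, tiny_cohort.csf_mask,
                include_global=include_global,
            )
            assert nuis.regressors.shape[1] == n_cols


def test_scrub_after_fd_identity_on_clean_data():
    """scrub(compute_fd(trace)) leaves the data untouched when no frame
    exceeds the threshold (the no-deletion regime)."""
    run = _run(80)
    trace = generate_motion_trace(80, 0.1, 2)
    out, keep = scrub(run, compute_fd(trace))
    assert keep.all()
    assert out.data is run.data or np.array_equal(out.data, run.data)


def test_fd_series_first_element_invariant():
    fd = FdSeries(np.array([0.0, 0.2, 0.1]))
    assert fd.fd[0] == 0.0
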