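"""Postprocessing chain: FD, censoring, confounds, filters, regression, QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from funcontrol import preprocess as prep
from funcontrol import synth
from funcontrol.preprocess import (
    MotionRecord,
    alias_band,
    bandpass,
    build_confound_matrix,
    censor_mask,
    clean_run,
    extract_roi_timeseries,
    finalize_task_timeseries,
    framewise_displacement,
    notch_filter_motion,
    nuisance_regress,
    qc_run,
    qc_task,
    spectral_interpolate,
)


def _fit_amplitude(x, freq, tr, margin=50):
    """Least-squares amplitude of a sinusoid in x, away from filter edges."""
    t = np.arange(len(x)) * tr
    sl = slice(margin, len(x) - margin)
    D = np.column_stack([np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)])[sl]
    beta, *_ = np.linalg.lstsq(D, x[sl], rcond=None)
    return float(np.hypot(*beta))


class TestFramewiseDisplacement:
    def test_constant_parameters_zero_fd(self):
        params = np.ones((6, 20)) * 0.3
        assert np.all(framewise_displacement(params) == 0)

    def test_single_translation_step(self):
        params = np.zeros((6, 10))
        params[0, 4:] = 0.1  # 0.1 mm x-step between frames 3 and 4
        fd = framewise_displacement(params)
        assert np.isclose(fd[4], 0.1)
        assert np.all(fd[np.arange(10) != 4] == 0)

    def test_rotation_arc_length(self):
        params = np.zeros((6, 10))
        params[3, 5:] = 0.002  # rad; arc at 50 mm radius = 0.1 mm
        fd = framewise_displacement(params, rotation_radius=50.0)
        assert np.isclose(fd[5], 0.1)

    def test_first_frame_zero_and_nonnegative(self, rng):
        params = rng.standard_normal((6, 50)) * 0.05
        fd = framewise_displacement(params)
        assert fd[0] == 0
        assert np.all(fd >= 0)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="6 x T"):
            framewise_displacement(np.zeros((5, 10)))


class TestNotchFilter:
    def test_alias_maps_respiration_band_below_nyquist(self):
        # 0.31-0.41 Hz sampled at 0.5 Hz folds to 0.09-0.19 Hz
        assert alias_band((0.31, 0.41), tr_seconds=2.0) == pytest.approx((0.09, 0.19))

    def test_alias_identity_below_nyquist(self):
        assert alias_band((0.05, 0.1), tr_seconds=2.0) == pytest.approx((0.05, 0.1))

    def test_constant_input_preserved(self):
        params = np.ones((6, 200)) * 0.7
        out = notch_filter_motion(params, tr_seconds=2.0)
        assert np.allclose(out, params, atol=1e-8)

    def test_stopband_center_attenuated(self):
        tr = 2.0
        t = np.arange(400) * tr
        center = 0.14  # aliased image of the respiration band center
        params = np.zeros((6, 400))
        params[1] = np.sin(2 * np.pi * center * t)
        out = notch_filter_motion(params, tr_seconds=tr)
        assert _fit_amplitude(out[1], center, tr) < 0.1

    def test_passband_preserved(self):
        tr = 2.0
        t = np.arange(400) * tr
        params = np.zeros((6, 400))
        params[2] = np.sin(2 * np.pi * 0.05 * t)
        out = notch_filter_motion(params, tr_seconds=tr)
        assert _fit_amplitude(out[2], 0.05, tr) > 0.9


class TestCensorMask:
    def test_all_below_threshold_retained(self):
        fd = np.full(20, 0.05)
        assert np.all(censor_mask(fd, 0.2, 5))

    def test_short_leading_segment_dropped(self):
        fd = np.array([0.1, 0.1, 0.3, 0.1, 0.1, 0.1, 0.1, 0.1])
        mask = censor_mask(fd, 0.2, 5)
        assert mask.tolist() == [False, False, False, True, True, True, True, True]

    def test_alternating_spikes_censor_everything(self):
        fd = np.tile([0.1, 0.3], 10)
        assert not censor_mask(fd, 0.2, 5).any()

    def test_idempotent(self, rng):
        fd = rng.exponential(0.15, size=200)
        mask1 = censor_mask(fd, 0.2, 5)
        fd2 = np.where(mask1, 0.0, 1.0)  # re-encode the mask as FD
        mask2 = censor_mask(fd2, 0.2, 5)
        assert np.array_equal(mask1, mask2)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 0.5, allow_nan=False), min_size=6, max_size=60))
    def test_segments_meet_minimum_length(self, fds):
        fd = np.array(fds)
        mask = censor_mask(fd, 0.2, 5)
        assert not mask[fd > 0.2].any()
        # every maximal retained segment has length >= 5
        runs, count = [], 0
        for m in list(mask) + [False]:
            count = count + 1 if m else (runs.append(count) or 0) if count else 0
        assert all(r >= 5 for r in runs)


class TestConfoundMatrix:
    def test_exactly_36_labeled_columns(self, rng):
        cm = build_confound_matrix(
            rng.standard_normal((6, 30)),
            rng.standard_normal(30),
            rng.standard_normal(30),
            rng.standard_normal(30),
        )
        assert cm.n_columns == 36
        assert len(set(cm.labels)) == 36

    def test_constant_signal_has_zero_derivatives(self):
        motion = np.zeros((6, 25))
        g = np.full(25, 3.0)
        cm = build_confound_matrix(motion, g, np.zeros(25), np.zeros(25))
        idx_d = cm.labels.index("global_derivative")
        idx_dp = cm.labels.index("global_derivative_power2")
        assert np.all(cm.values[idx_d] == 0)
        assert np.all(cm.values[idx_dp] == 0)

    def test_square_is_elementwise(self, rng):
        g = rng.standard_normal(40)
        cm = build_confound_matrix(np.zeros((6, 40)), g, np.zeros(40), np.zeros(40))
        assert np.allclose(cm.values[cm.labels.index("global_power2")], g**2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_confound_matrix(np.zeros((6, 10)), np.zeros(9), np.zeros(10), np.zeros(10))


class TestSpectralInterpolation:
    def test_full_mask_identity(self, rng):
        X = rng.standard_normal((3, 50))
        out = spectral_interpolate(X, np.ones(50, bool), 2.0)
        assert np.array_equal(out, X)

    def test_sinusoid_reconstruction(self, rng):
        tr = 2.0
        t = np.arange(200) * tr
        X = np.sin(2 * np.pi * 0.03 * t)[None, :]
        mask = rng.random(200) > 0.2
        out = spectral_interpolate(X, mask, tr)
        err = np.sqrt(np.mean((out[0, ~mask] - X[0, ~mask]) ** 2))
        assert err < 0.1  # < 10% of unit amplitude

    def test_constant_signal_interpolates_to_constant(self):
        X = np.full((2, 60), 5.0)
        mask = np.ones(60, bool)
        mask[20:25] = False
        out = spectral_interpolate(X, mask, 2.0)
        assert np.allclose(out, 5.0, atol=1e-8)

    def test_retained_frames_untouched(self, rng):
        X = rng.standard_normal((4, 80))
        mask = rng.random(80) > 0.3
        out = spectral_interpolate(X, mask, 2.0)
        assert np.array_equal(out[:, mask], X[:, mask])

    def test_too_few_retained_frames(self, rng):
        X = rng.standard_normal((2, 30))
        mask = np.zeros(30, bool)
        mask[3] = True
        with pytest.raises(ValueError, match="2 retained"):
            spectral_interpolate(X, mask, 2.0)


class TestBandpass:
    def test_constant_removed(self):
        out = bandpass(np.full((2, 300), 4.0), tr_seconds=2.0)
        assert np.max(np.abs(out)) < 0.05

    def test_inband_preserved(self):
        tr = 2.0
        t = np.arange(500) * tr
        x = np.sin(2 * np.pi * 0.04 * t)
        out = bandpass(x[None, :], tr_seconds=tr)
        assert _fit_amplitude(out[0], 0.04, tr) > 0.9

    def test_out_of_band_attenuated(self):
        tr = 2.0
        t = np.arange(500) * tr
        x = np.sin(2 * np.pi * 0.2 * t)
        out = bandpass(x[None, :], tr_seconds=tr)
        assert _fit_amplitude(out[0], 0.2, tr) < 0.1

    def test_band_order_enforced(self):
        with pytest.raises(ValueError, match="band"):
            bandpass(np.zeros((1, 100)), band_hz=(0.08, 0.009), tr_seconds=2.0)


class TestNuisanceRegression:
    def _confounds(self, rng, T):
        return build_confound_matrix(
            rng.standard_normal((6, T)),
            rng.standard_normal(T),
            rng.standard_normal(T),
            rng.standard_normal(T),
        )

    def test_data_equal_to_confound_fits_perfectly(self, rng):
        T = 100
        cm = self._confounds(rng, T)
        data = cm.values[[7]].copy()  # the global-signal column
        mask = np.ones(T, bool)
        resid, dropped = nuisance_regress(data, cm, mask)
        assert np.allclose(resid[:, mask], 0.0, atol=1e-8)

    def test_zero_confounds_pass_through(self, rng):
        T = 60
        cm = build_confound_matrix(
            np.zeros((6, T)), np.zeros(T), np.zeros(T), np.zeros(T)
        )
        data = rng.standard_normal((3, T))
        resid, dropped = nuisance_regress(data, cm, np.ones(T, bool))
        assert np.array_equal(resid, data)
        assert len(dropped) == 36

    def test_residuals_orthogonal_to_confounds(self, rng):
        T = 150
        cm = self._confounds(rng, T)
        data = rng.standard_normal((5, T)) * 3.0
        mask = rng.random(T) > 0.2
        resid, dropped = nuisance_regress(data, cm, mask)
        kept = [i for i, lbl in enumerate(cm.labels) if lbl not in dropped]
        dots = cm.values[kept][:, mask] @ resid[:, mask].T
        scale = np.abs(data).max() * np.abs(cm.values).max()
        assert np.max(np.abs(dots)) < 1e-8 * scale

    def test_collinear_columns_dropped_and_reported(self, rng):
        T = 80
        motion = rng.standard_normal((6, T))
        g = motion[0].copy()  # duplicate of trans_x
        cm = build_confound_matrix(motion, g, rng.standard_normal(T), rng.standard_normal(T))
        resid, dropped = nuisance_regress(rng.standard_normal((2, T)), cm, np.ones(T, bool))
        assert dropped  # at least the duplicated raw column
        assert np.all(np.isfinite(resid))


class TestQC:
    def test_high_mean_fd_excluded(self):
        qc = qc_run(np.full(100, 0.6), np.ones(100, bool))
        assert not qc.included and qc.reason == "mean FD"

    def test_too_few_good_timepoints_excluded(self):
        mask = np.zeros(100, bool)
        mask[:49] = True
        qc = qc_run(np.full(100, 0.1), mask)
        assert not qc.included and qc.reason == "good timepoints"

    def test_clean_run_included(self):
        qc = qc_run(np.full(150, 0.1), np.ones(150, bool))
        assert qc.included and qc.n_good == 150

    def test_task_level_minimum(self):
        def run_with(n_good, T=100):
            mask = np.zeros(T, bool)
            mask[:n_good] = True
            return prep.RunTimeseries(
                data=np.zeros((3, T)),
                censor_mask=mask,
                tr_seconds=2.0,
                qc=qc_run(np.full(T, 0.1), mask),
            )

        ok, reason, included = qc_task([run_with(80), run_with(80)])
        assert ok and len(included) == 2
        ok, reason, _ = qc_task([run_with(80), run_with(60)])
        assert not ok and "timepoints" in reason


class TestFinalize:
    def test_standardized_output_moments(self, rng):
        data = rng.standard_normal((4, 120)) * 7 + 3
        run = prep.RunTimeseries(
            data=data, censor_mask=np.ones(120, bool), tr_seconds=2.0
        )
        out, mask = finalize_task_timeseries([run])
        assert np.allclose(out[:, mask].mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(out[:, mask].std(axis=1), 1.0, atol=1e-10)

    def test_two_identical_runs_concatenate(self, rng):
        data = rng.standard_normal((3, 50))
        runs = [
            prep.RunTimeseries(data=data.copy(), censor_mask=np.ones(50, bool), tr_seconds=2.0)
            for _ in range(2)
        ]
        out, mask = finalize_task_timeseries(runs)
        assert out.shape == (3, 100)
        assert np.allclose(out[:, :50], out[:, 50:])

    def test_linear_ramp_detrended_to_zero(self):
        ramp = np.outer(np.ones(2), np.arange(80, dtype=float))
        run = prep.RunTimeseries(data=ramp, censor_mask=np.ones(80, bool), tr_seconds=2.0)
        out, _ = finalize_task_timeseries([run])
        assert np.allclose(out, 0.0, atol=1e-8)

    def test_roi_mismatch_rejected(self, rng):
        r1 = prep.RunTimeseries(
            data=rng.standard_normal((3, 40)), censor_mask=np.ones(40, bool), tr_seconds=2.0
        )
        r2 = prep.RunTimeseries(
            data=rng.standard_normal((4, 40)), censor_mask=np.ones(40, bool), tr_seconds=2.0
        )
        with pytest.raises(ValueError, match="ROI"):
            finalize_task_timeseries([r1, r2])


class TestCleaningRemovesMotionArtifact:
    def test_fd_signal_coupling_reduced(self):
        # rank-one motion contamination with positive loadings: the mean
        # ROI signal tracks FD before cleaning; censoring + regression
        # must break that coupling in the frames that enter analysis
        cfg = synth.CohortConfig(
            n_per_group=1,
            contexts=(("rest", 1, 150),),
            seed=7,
            motion_spike_rate=0.1,
            motion_subject_sigma=0.0,
        )
        cohort = synth.make_cohort(cfg)
        ses = cohort.subjects[0].sessions[0]
        sc = synth.simulate_session(ses.ground_truth, ("rest", 1, 150), ses.seed, cfg)
        run = sc.runs[0]
        motion = MotionRecord.from_params(run.motion_params, 2.0)
        before = abs(np.corrcoef(motion.fd_raw, run.data.mean(axis=0))[0, 1])
        cleaned = clean_run(
            run.data,
            motion,
            run.nuisance["global"].to_numpy(),
            run.nuisance["wm"].to_numpy(),
            run.nuisance["csf"].to_numpy(),
        )
        mask = cleaned.censor_mask
        after = abs(
            np.corrcoef(motion.fd_raw[mask], cleaned.data[:, mask].mean(axis=0))[0, 1]
        )
        assert after < before


class TestROIExtraction:
    def test_uniform_volume(self):
        atlas = synth.make_atlas(8, ("a", "b"))
        ts = np.full((8, 3), 2.5)
        img = synth.make_nifti_fixture(ts, atlas)
        import numpy as np_

        vol = np.asarray(img.dataobj) * 0 + 2.5  # make every voxel 2.5
        import nibabel as nib

        img_u = nib.Nifti1Image(vol, img.affine)
        out, missing = extract_roi_timeseries(img_u, atlas, radius_mm=4.0)
        assert missing == []
        assert np.allclose(out, 2.5)

    def test_small_radius_single_voxel(self, rng):
        atlas = synth.make_atlas(6, ("a", "b"), spacing_mm=12.0)
        ts = rng.standard_normal((6, 5))
        img = synth.make_nifti_fixture(ts, atlas, voxel_size_mm=3.0)
        out, missing = extract_roi_timeseries(img, atlas, radius_mm=2.0)
        assert missing == []
        assert np.allclose(out, ts)

    def test_out_of_bounds_rois_flagged(self, rng):
        # a 300-region parcellation whose field of view truncates 16
        # regions leaves 284 usable
        atlas = synth.make_atlas(300, ("a", "b", "c", "d"), spacing_mm=6.0)
        atlas = atlas.copy()
        atlas.loc[atlas.index[-16:], ["x", "y", "z"]] = 10_000.0
        ts = rng.standard_normal((300, 2))
        img = synth.make_nifti_fixture(
            ts[: len(atlas) - 16], atlas.iloc[:-16], voxel_size_mm=6.0
        )
        out, missing = extract_roi_timeseries(img, atlas, radius_mm=4.0)
        assert len(missing) == 16
        assert len(atlas) - len(missing) == 284
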