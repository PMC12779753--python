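"""Generator correctness: design arithmetic, trial construction, motion."""

import numpy as np
import pandas as pd
import pytest

from graspkin import motionqc, synth
from graspkin.segment import compute_speed

from conftest import make_trial


class TestBuildSession:
    def test_reference_design_arithmetic(self):
        ledger = synth.build_session(synth.SessionSpec(), seed=0)
        assert len(ledger) == 1260
        per_cell = ledger.groupby(["participant", "trial_type"]).size()
        assert (per_cell == 60).all()

    def test_small_spec_counts(self, small_spec):
        ledger = synth.build_session(small_spec, seed=1)
        assert len(ledger) == 9
        assert (ledger["trial_type"].value_counts() == 3).all()

    def test_conditions_balanced_within_each_run(self):
        spec = synth.SessionSpec(participants=2, runs_per_participant=2)
        ledger = synth.build_session(spec, seed=3)
        per_run = ledger.groupby(["participant", "run", "trial_type"]).size()
        assert (per_run == 15).all()

    def test_onsets_strictly_increasing_within_run(self, small_spec):
        ledger = synth.build_session(small_spec, seed=2)
        for _, run in ledger.groupby(["participant", "run"]):
            assert (np.diff(run["onset"]) > 0).all()

    def test_grip_types_counterbalanced(self):
        ledger = synth.build_session(synth.SessionSpec(participants=2), seed=0)
        counts = ledger.groupby(["participant", "trial_type"])["grip_type"].value_counts()
        assert (counts == 30).all()

    def test_unbalanced_spec_rejected(self):
        spec = synth.SessionSpec(blocks_per_run=14)
        with pytest.raises(synth.ConfigurationError):
            synth.build_session(spec, seed=0)

    def test_same_seed_bit_identical(self):
        a = synth.build_session(synth.SessionSpec(participants=2), seed=9)
        b = synth.build_session(synth.SessionSpec(participants=2), seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestJitter:
    def test_jitter_bounds_and_mean(self):
        spec = synth.SessionSpec()
        draws = synth._sample_jitter(np.random.default_rng(0), spec, 5000)
        assert draws.min() >= spec.iti_min_s
        assert draws.max() <= spec.iti_max_s
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - spec.iti_mean_s) < 3 * se

    def test_onset_to_onset_preset(self):
        spec = synth.SessionSpec(
            iti_min_s=5.0, iti_max_s=13.0, iti_mean_s=7.0, iti_onset_to_onset=True
        )
        ledger = synth.build_session(spec, seed=0)
        gaps = ledger.groupby(["participant", "run", "block"])["onset"].diff().dropna()
        assert gaps.between(5.0, 13.0).all()


class TestSimulateTrial:
    def test_reaction_latency_sets_first_moving_frame(self):
        gt = synth.TrialGroundTruth(reaction_latency_s=0.5)
        trial = synth.simulate_trial(gt, frame_rate_hz=60.0, seed=0)
        assert gt.phase_boundary_frames[0] == 30
        speed = compute_speed(trial.positions("wrist"), 60.0).values
        assert speed[29] == 0.0
        assert speed[30] > 0.0

    def test_power_grip_minimum_apertures_exact(self):
        gt = synth.TrialGroundTruth(
            grip_type="power", min_grip_aperture_mm=45.0, min_hand_aperture_mm=122.0
        )
        trial = synth.simulate_trial(gt, seed=0)
        grip = np.linalg.norm(
            trial.positions("index_tip") - trial.positions("thumb_tip"), axis=1
        )
        hand = np.linalg.norm(
            trial.positions("index_tip") - trial.positions("wrist"), axis=1
        )
        assert grip.min() == pytest.approx(45.0, abs=1e-9)
        assert hand.min() == pytest.approx(122.0, abs=1e-9)

    def test_zero_distance_trial_never_moves(self):
        gt = synth.TrialGroundTruth(reach_distance_mm=0.0)
        trial = synth.simulate_trial(gt, seed=0)
        speed = compute_speed(trial.positions("wrist"), 60.0).values
        assert np.all(speed == 0.0)
        assert gt.peak_wrist_speed_mm_s == 0.0

    def test_boundaries_recoverable_by_half_peak_threshold(self):
        """Construction oracle: thresholding the noiseless wrist speed at
        half the slower movement's peak recovers the stored boundaries."""
        for seed in range(10):
            trial, gt = make_trial(seed=seed)
            b0, b1, b2, b3 = gt.phase_boundary_frames
            speed = compute_speed(trial.positions("wrist"), 60.0).values
            peak_reach = speed[b0:b1].max()
            peak_back = speed[b2:b3].max()
            moving = speed > 0.5 * min(peak_reach, peak_back)
            idx = np.flatnonzero(moving)
            assert idx[0] == b0
            runs = np.flatnonzero(np.diff(idx) > 1)
            assert len(runs) == 1
            assert idx[runs[0]] == b1 - 1
            assert idx[runs[0] + 1] == b2
            assert idx[-1] == b3 - 1

    def test_peak_speed_matches_stored_ground_truth(self, noiseless_trial):
        trial, gt = noiseless_trial
        speed = compute_speed(trial.positions("wrist"), 60.0).values
        assert speed.max() == pytest.approx(gt.peak_wrist_speed_mm_s, rel=1e-12)

    def test_phases_exceeding_window_raise(self):
        gt = synth.TrialGroundTruth()
        with pytest.raises(synth.GenerationError):
            synth.simulate_trial(gt, window_s=1.0, seed=0)

    def test_dropout_marks_missing_frames(self):
        trial, _ = make_trial(seed=3, dropout_prob=0.05)
        missing = np.isnan(trial.positions("wrist")).any(axis=1)
        assert 0 < missing.sum() < trial.n_frames

    def test_same_seed_bit_identical(self):
        a, _ = make_trial(noise_sd_mm=1.5, seed=11, dropout_prob=0.01)
        b, _ = make_trial(noise_sd_mm=1.5, seed=11, dropout_prob=0.01)
        for m in synth.MARKERS:
            np.testing.assert_array_equal(a.positions(m), b.positions(m))

    def test_precision_apertures_exceed_power_by_construction(self, rng):
        for seed in range(25):
            local = np.random.default_rng(seed)
            prec = synth.sample_ground_truth(local, "precision")
            pw = synth.sample_ground_truth(local, "power")
            assert prec.min_grip_aperture_mm > pw.min_grip_aperture_mm
            assert prec.min_hand_aperture_mm > pw.min_hand_aperture_mm


@pytest.fixture(scope="module")
def run_events():
    spec = synth.SessionSpec(participants=1, runs_per_participant=1)
    return synth.build_session(spec, seed=0)


@pytest.fixture(scope="module")
def bold_setup(run_events):
    n_tr = int(np.ceil((run_events["onset"].max() + 8.0) / 0.8))
    move = run_events[run_events["trial_type"].isin(synth.MOVEMENT_CONDITIONS)]
    scores = pd.DataFrame(
        np.random.default_rng(1).normal(size=(len(move), 2)),
        index=move.index,
        columns=["PC1", "PC2"],
    )
    return run_events, scores, n_tr


class TestMotionSeries:
    def test_zero_amplitude_means_zero_head_fd(self, run_events):
        params = synth.MotionGenParams(head_amplitude_mm=0.0)
        motion = synth.simulate_motion_series(run_events, params, seed=0)
        deltas = motionqc.params_to_deltas(
            motion[list(motionqc.MOTION_PARAM_COLUMNS)]
        )
        fd = motionqc.framewise_displacement(deltas, 50.0)
        assert np.all(fd.values == 0.0)

    def test_parameter_decomposition_reproduces_target_fd(self, run_events):
        motion = synth.simulate_motion_series(
            run_events, synth.MotionGenParams(), seed=4
        )
        deltas = motionqc.params_to_deltas(
            motion[list(motionqc.MOTION_PARAM_COLUMNS)]
        )
        fd = motionqc.framewise_displacement(deltas, 50.0)
        # head FD is generated first and decomposed exactly
        assert fd.values.mean() == pytest.approx(0.1, abs=0.02)

    def test_zero_coupling_long_series(self):
        spec = synth.SessionSpec(
            participants=1, runs_per_participant=1, blocks_per_run=600
        )
        events = synth.build_session(spec, seed=0)
        params = synth.MotionGenParams(arm_head_coupling=0.0)
        motion = synth.simulate_motion_series(events, params, seed=0)
        mask = motion["is_movement"].to_numpy()
        assert mask.sum() >= 9000
        deltas = motionqc.params_to_deltas(
            motion[list(motionqc.MOTION_PARAM_COLUMNS)]
        )
        fd = motionqc.framewise_displacement(deltas, 50.0)
        r = motionqc.fd_correlation(fd.values, motion["arm_fd"].to_numpy(), mask)
        assert abs(r) < 0.05


class TestSimulateBold:
    def test_all_betas_zero_no_noise_constant_baseline(self, bold_setup):
        events, scores, n_tr = bold_setup
        params = synth.BoldGenParams(
            baseline=50.0,
            condition_betas={c: 0.0 for c in synth.CONDITIONS},
            noise_sd=0.0,
        )
        y = synth.simulate_bold(events, scores, params, n_tr, seed=0)
        np.testing.assert_allclose(y, 50.0)

    def test_ar1_noise_marginal_sd(self, bold_setup):
        events, scores, n_tr = bold_setup
        params = synth.BoldGenParams(
            condition_betas={}, noise_sd=2.0, ar1_coefficient=0.5
        )
        ys = [
            synth.simulate_bold(events, None, params, n_tr, seed=s)
            for s in range(30)
        ]
        sds = [y.std() for y in ys]
        assert np.mean(sds) == pytest.approx(2.0, rel=0.1)


class TestFactorTable:
    def test_planted_structure_and_unit_variance(self):
        table, lam, scores = synth.simulate_factor_table(2000, 7, seed=0)
        assert table.shape == (2000, 28)
        assert np.allclose(table.var(ddof=1), 1.0, atol=0.15)
        # measures in the same group correlate near loading^2
        corr = np.corrcoef(table.iloc[:, 0], table.iloc[:, 1])[0, 1]
        assert corr == pytest.approx(0.64, abs=0.08)

    def test_uneven_split_rejected(self):
        with pytest.raises(synth.ConfigurationError):
            synth.simulate_factor_table(100, 5, n_measures=28)
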