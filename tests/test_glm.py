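"""HRF, design construction, least-squares fits, and inference."""

import numpy as np
import pandas as pd
import pytest

from graspkin import glm, synth


@pytest.fixture(scope="module")
def run_setup():
    spec = synth.SessionSpec(participants=1, runs_per_participant=1)
    events = synth.build_session(spec, seed=0)
    n_tr = int(np.ceil((events["onset"].max() + 8.0) / 0.8))
    move = events[events["trial_type"].isin(synth.MOVEMENT_CONDITIONS)]
    scores = pd.DataFrame(
        np.random.default_rng(1).normal(size=(len(move), 2)),
        index=move.index,
        columns=["PC1", "PC2"],
    )
    return events, scores, n_tr


class TestHrf:
    def test_zero_at_origin_and_peak_position(self):
        kernel = glm.hrf_canonical(0.1)
        assert kernel[0] == 0.0
        t_peak = kernel.argmax() * 0.1
        assert 4.5 <= t_peak <= 6.5
        assert kernel.max() == pytest.approx(1.0)

    def test_halving_tr_doubles_samples(self):
        assert len(glm.hrf_canonical(0.4)) == pytest.approx(
            2 * len(glm.hrf_canonical(0.8)), abs=2
        )

    def test_matches_reference_double_gamma_shape(self):
        # independent reference implementation of the canonical HRF
        from nilearn.glm.first_level import spm_hrf

        tr = 0.8
        ours = glm.hrf_canonical(tr)
        ref = spm_hrf(tr, oversampling=16, time_length=32.0 + tr)[::16]
        n = min(len(ours), len(ref))
        r = np.corrcoef(ours[:n], ref[:n])[0, 1]
        assert r > 0.999


class TestRegressors:
    def test_no_onsets_zero_column(self):
        col = glm.build_condition_regressor([], 0.8, 100)
        assert np.all(col == 0.0)

    def test_single_onset_is_shifted_kernel(self):
        kernel = glm.hrf_canonical(0.8)
        col = glm.build_condition_regressor([8.0], 0.8, 100, kernel)
        np.testing.assert_allclose(col[10 : 10 + len(kernel)],
                                   kernel[: 100 - 10])

    def test_two_distant_onsets_superpose(self):
        a = glm.build_condition_regressor([8.0], 0.8, 200)
        b = glm.build_condition_regressor([88.0], 0.8, 200)
        ab = glm.build_condition_regressor([8.0, 88.0], 0.8, 200)
        np.testing.assert_allclose(ab, a + b, atol=1e-12)

    def test_equal_scores_center_to_zero(self):
        main = glm.build_condition_regressor([8.0, 24.0], 0.8, 100)
        col = glm.build_modulator([8.0, 24.0], [3.0, 3.0], 0.8, 100, main)
        np.testing.assert_allclose(col, 0.0, atol=1e-12)

    def test_modulator_orthogonal_to_main(self):
        main = glm.build_condition_regressor([8.0, 24.0, 40.0], 0.8, 120)
        col = glm.build_modulator(
            [8.0, 24.0, 40.0], [1.0, -2.0, 0.5], 0.8, 120, main
        )
        assert abs(col @ main) < 1e-10


class TestOrthogonalize:
    def test_orthogonal_pair_unchanged(self):
        a = np.array([1.0, 0, 0, 0])
        b = np.array([0.0, 1, 0, 0])
        np.testing.assert_array_equal(glm.orthogonalize(a, b), a)

    def test_parallel_gives_zero(self):
        a = np.array([2.0, 4.0, 6.0])
        np.testing.assert_allclose(glm.orthogonalize(a, a / 2), 0.0, atol=1e-12)

    def test_random_pair_residual_orthogonal(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 500))
        assert abs(glm.orthogonalize(a, b) @ b) < 1e-10


class TestDesignMatrix:
    def test_structure(self, run_setup):
        events, scores, n_tr = run_setup
        design = glm.build_design_matrix(events, scores, 0.8, n_tr)
        assert design.columns.is_unique
        assert design.columns[-1] == "constant"
        assert len(design) == n_tr
        for cond in ("MoveVisible", "MoveInvisible"):
            for comp in ("PC1", "PC2"):
                assert f"{cond}_x_{comp}" in design.columns
                dot = design[cond] @ design[f"{cond}_x_{comp}"]
                assert abs(dot) < 1e-10

    def test_fd_orthogonalization_chain(self, run_setup):
        events, scores, n_tr = run_setup
        rng = np.random.default_rng(3)
        head, arm, hand = np.abs(rng.normal(size=(3, n_tr)))
        design = glm.build_design_matrix(
            events, scores, 0.8, n_tr, fd_head=head, fd_arm=arm, fd_hand=hand
        )
        assert abs(design["fd_arm"] @ design["fd_head"]) < 1e-8
        assert abs(design["fd_hand"] @ design["fd_arm"]) < 1e-8

    def test_error_trials_split_by_movement(self, run_setup):
        events, scores, n_tr = run_setup
        ev = events.copy()
        ev["error"] = False
        ev.iloc[0, ev.columns.get_loc("error")] = True
        ev["error_moved"] = ev["error"]
        design = glm.build_design_matrix(ev, scores, 0.8, n_tr)
        assert "error_move" in design.columns
        assert "error_still" not in design.columns


class TestFit:
    def test_noiseless_recovery_exact(self, run_setup):
        events, scores, n_tr = run_setup
        params = synth.BoldGenParams(
            modulator_betas={"PC1": 0.7, "PC2": -0.3}, noise_sd=0.0
        )
        y = synth.simulate_bold(events, scores, params, n_tr, seed=0)
        design = glm.build_design_matrix(events, scores, 0.8, n_tr)
        fit = glm.fit(design, y, ar_model="none")
        assert fit.betas["MoveVisible"] == pytest.approx(2.0, abs=1e-8)
        assert fit.betas["NoMovement"] == pytest.approx(0.5, abs=1e-8)
        assert fit.betas["MoveVisible_x_PC1"] == pytest.approx(0.7, abs=1e-8)
        assert fit.betas["constant"] == pytest.approx(100.0, abs=1e-8)

    def test_constant_y_only_constant_beta(self, run_setup):
        events, scores, n_tr = run_setup
        design = glm.build_design_matrix(events, scores, 0.8, n_tr)
        fit = glm.fit(design, np.full(n_tr, 5.0), ar_model="none")
        assert fit.betas["constant"] == pytest.approx(5.0, abs=1e-8)
        others = fit.betas.drop("constant")
        assert np.abs(others).max() < 1e-8

    def test_duplicate_column_reports_rank_deficiency(self, run_setup):
        events, scores, n_tr = run_setup
        design = glm.build_design_matrix(events, scores, 0.8, n_tr)
        design = design.copy()
        design["dup"] = design["MoveVisible"]
        fit = glm.fit(design, np.random.default_rng(0).normal(size=n_tr),
                      ar_model="none")
        assert fit.rank_deficient

    def test_ar1_estimate_recovers_generating_coefficient(self, run_setup):
        events, scores, n_tr = run_setup
        params = synth.BoldGenParams(noise_sd=1.0, ar1_coefficient=0.4)
        design = glm.build_design_matrix(events, scores, 0.8, n_tr)
        rhos = [
            glm.fit(design,
                    synth.simulate_bold(events, scores, params, n_tr, seed=s),
                    ar_model="ar1").ar_rho
            for s in range(20)
        ]
        assert np.mean(rhos) == pytest.approx(0.4, abs=0.04)

    def test_ols_betas_unbiased_under_ar1_noise(self, run_setup):
        events, scores, n_tr = run_setup
        params = synth.BoldGenParams(
            modulator_betas={"PC1": 0.5}, noise_sd=1.0, ar1_coefficient=0.35
        )
        design = glm.build_design_matrix(events, scores, 0.8, n_tr)
        errs = []
        for s in range(60):
            y = synth.simulate_bold(events, scores, params, n_tr, seed=s)
            fit = glm.fit(design, y, ar_model="none")
            errs.append(fit.betas["MoveVisible_x_PC1"] - 0.5)
        mc_bound = 4 * np.std(errs) / np.sqrt(len(errs))
        assert abs(np.mean(errs)) < mc_bound


class TestInference:
    def test_zero_contrast_zero_t(self, run_setup):
        events, scores, n_tr = run_setup
        design = glm.build_design_matrix(events, scores, 0.8, n_tr)
        fit = glm.fit(design, np.random.default_rng(0).normal(size=n_tr))
        out = glm.contrast_t(fit, np.zeros(design.shape[1]))
        assert out["t"] == 0.0

    def test_condition_contrast_detects_planted_difference(self, run_setup):
        events, scores, n_tr = run_setup
        params = synth.BoldGenParams(noise_sd=0.5)
        y = synth.simulate_bold(events, scores, params, n_tr, seed=1)
        design = glm.build_design_matrix(events, scores, 0.8, n_tr)
        fit = glm.fit(design, y)
        out = glm.contrast_t(fit, {"MoveVisible": 1.0, "NoMovement": -1.0})
        assert out["t"] > 3.0 and out["p"] < 0.01

    def test_modulation_f_detects_planted_effect(self, run_setup):
        events, scores, n_tr = run_setup
        params = synth.BoldGenParams(modulator_betas={"PC1": 1.0}, noise_sd=0.5)
        y = synth.simulate_bold(events, scores, params, n_tr, seed=2)
        design = glm.build_design_matrix(events, scores, 0.8, n_tr)
        fit = glm.fit(design, y)
        cols = [c for c in design.columns if "_x_" in c]
        assert glm.modulation_F(fit, cols)["p"] < 0.001

    def test_motion_share_of_pure_motion_signal(self, run_setup):
        events, scores, n_tr = run_setup
        rng = np.random.default_rng(4)
        head, arm = np.abs(rng.normal(size=(2, n_tr)))
        design = glm.build_design_matrix(
            events, scores, 0.8, n_tr, fd_head=head, fd_arm=arm
        )
        y = 3.0 * design["fd_arm"].to_numpy()
        fit = glm.fit(design, y, ar_model="none")
        share = glm.motion_variance_share(fit, ["fd_arm"])
        assert share == pytest.approx(100.0, abs=1e-6)

    def test_motion_share_null_is_small_and_bounded(self, run_setup):
        events, scores, n_tr = run_setup
        rng = np.random.default_rng(5)
        head, arm, hand = np.abs(rng.normal(size=(3, n_tr)))
        design = glm.build_design_matrix(
            events, scores, 0.8, n_tr, fd_head=head, fd_arm=arm, fd_hand=hand
        )
        y = rng.normal(size=n_tr)
        fit = glm.fit(design, y, ar_model="none")
        share = glm.motion_variance_share(fit)
        assert 0.0 <= share < 5.0

    def test_bh_correction_monotone(self):
        p = np.array([0.001, 0.01, 0.04, 0.2, 0.8])
        out = glm.bh_correct(p)
        assert (np.diff(out["p_fdr"]) >= 0).all()
        assert out["significant"].iloc[0]
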