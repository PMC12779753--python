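"""Frame-wise displacement, RMSD, DVARS, censoring, FD coupling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graspkin import motionqc as mq


def independent_fd(deltas, r):
    """Straight transcription of the printed FD formula, kept separate
    from the implementation on purpose."""
    out = []
    for dx, dy, dz, da, db, dg in deltas:
        out.append(abs(dx) + abs(dy) + abs(dz) + r * (abs(da) + abs(db) + abs(dg)))
    return np.array(out)


class TestFramewiseDisplacement:
    def test_zero_frame_zero_fd(self):
        fd = mq.framewise_displacement(np.zeros((5, 6)), 50.0)
        assert np.all(fd.values == 0.0)

    def test_translations_sum_of_absolutes(self):
        deltas = np.zeros((1, 6))
        deltas[0, :3] = [0.1, -0.2, 0.3]
        fd = mq.framewise_displacement(deltas, 50.0)
        assert fd.values[0] == pytest.approx(0.6)

    def test_rotation_converted_by_radius(self):
        deltas = np.zeros((1, 6))
        deltas[0, 3] = 0.001
        fd = mq.framewise_displacement(deltas, 300.0)
        assert fd.values[0] == pytest.approx(0.3)

    def test_oracle_equivalence_on_random_frames(self):
        rng = np.random.default_rng(42)
        deltas = rng.normal(scale=[0.2, 0.2, 0.2, 0.01, 0.01, 0.01], size=(1000, 6))
        for effector, r in mq.EFFECTOR_RADII_MM.items():
            fd = mq.framewise_displacement(deltas, r, effector)
            np.testing.assert_allclose(fd.values, independent_fd(deltas, r),
                                       atol=1e-12)

    def test_sign_invariance(self):
        rng = np.random.default_rng(0)
        deltas = rng.normal(size=(50, 6))
        a = mq.framewise_displacement(deltas, 50.0).values
        b = mq.framewise_displacement(-deltas, 50.0).values
        np.testing.assert_allclose(a, b)

    def test_default_radii(self):
        assert mq.EFFECTOR_RADII_MM == {"head": 50.0, "arm": 300.0, "hand": 180.0}

    @settings(derandomize=True, max_examples=50)
    @given(
        delta=st.lists(
            st.floats(-2.0, 2.0, allow_nan=False), min_size=6, max_size=6
        ),
        split=st.floats(0.0, 1.0),
    )
    def test_same_sign_split_across_two_trs_conserves_total_fd(self, delta, split):
        """Splitting a displacement into two same-sign steps leaves the
        summed FD unchanged (|a| + |b| = |a + b| when signs agree)."""
        whole = np.array([delta])
        parts = np.vstack([split * whole, (1.0 - split) * whole])
        fd_whole = mq.framewise_displacement(whole, 50.0).values.sum()
        fd_parts = mq.framewise_displacement(parts, 50.0).values.sum()
        assert fd_parts == pytest.approx(fd_whole, abs=1e-9)


class TestKinematicsToTr:
    def test_static_limb_zero_deltas(self):
        pos = np.tile([10.0, 20.0, 30.0], (480, 1))
        ref = np.tile([0.0, 0.0, 0.0], (480, 1))
        deltas = mq.kinematics_to_tr(pos, ref, None, 60.0, 0.8)
        assert np.all(deltas == 0.0)

    def test_constant_translation_per_tr(self):
        n = 480
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n)  # 1 mm per frame -> 48 mm per TR
        ref = np.zeros((n, 3))
        deltas = mq.kinematics_to_tr(pos, ref, None, 60.0, 0.8)
        np.testing.assert_allclose(deltas[1:, 0], 48.0)

    def test_sampling_stride(self):
        n = 480
        pos = np.zeros((n, 3))
        deltas = mq.kinematics_to_tr(pos, pos, None, 60.0, 0.8)
        assert len(deltas) == 10  # 480 frames / 48 per TR

    def test_orientation_deltas_included(self):
        n = 96
        pos = np.zeros((n, 3))
        ori = np.zeros((n, 3))
        ori[:, 2] = 0.001 * np.arange(n)  # 0.048 rad per 48-frame TR
        deltas = mq.kinematics_to_tr(pos, pos, ori, 60.0, 0.8)
        assert deltas[1, 5] == pytest.approx(0.048, rel=1e-6)
        none = mq.kinematics_to_tr(pos, pos, ori, 60.0, 0.8,
                                   rotation_strategy="none")
        assert np.all(none[:, 3:] == 0.0)

    def test_missing_samples_nearest_filled(self):
        n = 480
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n, dtype=float)
        pos[48] = np.nan  # the second sample point is missing
        deltas = mq.kinematics_to_tr(pos, np.zeros((n, 3)), None, 60.0, 0.8)
        assert np.isfinite(deltas).all()


class TestRmsd:
    def test_zero_motion(self):
        assert mq.rmsd(np.zeros((10, 6))) == 0.0

    def test_pure_translation_closed_form(self):
        params = np.zeros((10, 6))
        params[:, 0] = 0.3 * np.arange(10)  # constant 0.3 mm per TR
        assert mq.rmsd(params) == pytest.approx(0.3)

    def test_small_angle_oracle(self):
        # pure rotation by theta about one axis between successive frames:
        # ||R - I||_F^2 = 4 (1 - cos theta) ~ 2 theta^2, so the sphere-
        # averaged displacement is r * theta * sqrt(2/5)
        params = np.zeros((5, 6))
        theta = 1e-4
        params[:, 3] = theta * np.arange(5)
        r = 80.0
        expected = r * theta * np.sqrt(2.0 / 5.0)
        assert mq.rmsd(params, r) == pytest.approx(expected, rel=1e-4)


class TestStdDvars:
    def test_constant_series_zero(self):
        ts = np.tile([1.0, 2.0, 3.0], (20, 1))
        assert np.all(mq.std_dvars(ts) == 0.0)

    def test_iid_gaussian_mean_near_one(self):
        rng = np.random.default_rng(0)
        ts = rng.normal(size=(5000, 50))
        dvars = mq.std_dvars(ts)
        assert dvars[1:].mean() == pytest.approx(1.0, abs=0.02)

    def test_single_spike_localized(self):
        ts = np.zeros((50, 10))
        ts += np.random.default_rng(1).normal(0, 0.1, ts.shape)
        ts[25] += 10.0
        dvars = mq.std_dvars(ts)
        assert dvars.argmax() in (25, 26)


class TestCensoring:
    def test_all_below_both_thresholds(self):
        fd = mq.FDSeries("head", 50.0, np.full(100, 0.1), 0.8)
        stats = mq.censoring_stats(fd, np.repeat("Movement", 100))
        assert (stats["fraction_retained"] == 1.0).all()

    def test_constructed_retention_fraction(self):
        values = np.full(100, 0.1)
        values[[3, 50, 97]] = 0.9
        fd = mq.FDSeries("head", 50.0, values, 0.8)
        stats = mq.censoring_stats(fd, np.repeat("Movement", 100),
                                   thresholds=(0.5,))
        assert stats["fraction_retained"].iloc[0] == pytest.approx(0.97)
        assert stats["retained_minutes"].iloc[0] == pytest.approx(97 * 0.8 / 60)

    def test_retention_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        fd = mq.FDSeries("head", 50.0, np.abs(rng.normal(0.2, 0.1, 500)), 0.8)
        curve = mq.retention_curve(fd, np.linspace(0.05, 1.0, 20))
        assert (np.diff(curve) >= 0).all()


class TestFdCorrelation:
    def test_identical_series(self):
        v = np.abs(np.random.default_rng(0).normal(size=200))
        assert mq.fd_correlation(v, v) == pytest.approx(1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(1)
        a, b = np.abs(rng.normal(size=(2, 20000)))
        assert abs(mq.fd_correlation(a, b)) < 0.03

    def test_group_test_on_positive_correlations(self):
        out = mq.fd_correlation_group([0.2, 0.25, 0.3, 0.22, 0.18, 0.28, 0.21])
        assert out["p"] < 0.001
        assert out["t"] > 0
        assert out["dof"] == 6

    def test_mask_restricts_the_window(self):
        a = np.concatenate([np.zeros(50), np.arange(50.0)])
        b = np.concatenate([np.zeros(50), np.arange(50.0)])
        mask = np.arange(100) >= 50
        assert mq.fd_correlation(a, b, mask) == pytest.approx(1.0)
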