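"""Schedule construction, design assembly, the truncated-SVD fit against
independent oracles, calibration-quality RMSE, and backward selection."""

import numpy as np
import pytest

import myoreg as mr
from myoreg.calibration import DesignData, EmgForceModel

from conftest import held_segment_frames


class TestSchedule:
    def test_dircon_sequence_and_timing(self, dircon_schedule):
        assert dircon_schedule.labels == [
            "Rest", "Cls", "Opn", "Sup", "Pro",
            "Cls+Sup", "Cls+Pro", "Opn+Sup", "Opn+Pro",
        ]
        assert all(d == 10.0 for _, _, d in dircon_schedule.segments)
        assert dircon_schedule.total_s == 90.0

    def test_mapcon_sequence(self, mapcon_schedule):
        assert mapcon_schedule.labels == [
            "Rest", "Flx", "Ext", "Uln", "Rad",
            "Flx+Uln", "Flx+Rad", "Ext+Uln", "Ext+Rad",
        ]
        assert mapcon_schedule.total_s == 90.0

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            mr.build_schedule("classify")

    @pytest.mark.parametrize(
        "label, expected",
        [
            ("Rest", (0.0, 0.0)),
            ("Cls", (-30.0, 0.0)),
            ("Opn", (30.0, 0.0)),
            ("Pro", (0.0, 30.0)),
            ("Opn+Sup", (30.0, -30.0)),
            ("Flx+Rad", (-30.0, 30.0)),
        ],
    )
    def test_signed_targets_with_zero_for_unused_dof(self, label, expected):
        np.testing.assert_array_equal(mr.targets_for(label, 30.0), expected)


def _sigma(frames, channels, seed=0):
    rng = np.random.default_rng(seed)
    return mr.SigmaSeries(
        rng.random((frames, channels)), 100.0, [f"ch{c:02d}" for c in range(channels)]
    )


class TestAssembleDesign:
    def test_default_trim_and_rest_replication_row_counts(self, dircon_schedule):
        d = mr.assemble_design(_sigma(9000, 4), dircon_schedule, mr.FitSpec())
        assert (d.row_labels == "Cls").sum() == 800
        assert (d.row_labels == "Rest").sum() == 8 * 800
        assert d.X.shape == (8 * 800 + 8 * 800, 4 + 1)
        assert d.Y.shape[0] == d.X.shape[0]
        assert set(np.unique(d.Y)) <= {0.0, 30.0, -30.0}

    def test_no_trim_keeps_full_segments(self, dircon_schedule):
        d = mr.assemble_design(
            _sigma(9000, 4), dircon_schedule, mr.FitSpec(trim_s=0.0, rest_weight=1)
        )
        assert (d.row_labels == "Cls").sum() == 1000
        assert d.X.shape[0] == 9 * 1000

    def test_bias_column_optional(self, dircon_schedule):
        d = mr.assemble_design(_sigma(9000, 16), dircon_schedule, mr.FitSpec(bias=False))
        assert d.X.shape[1] == 16

    def test_short_sigma_reports_missing_duration(self, dircon_schedule):
        with pytest.raises(ValueError, match="missing"):
            mr.assemble_design(_sigma(8000, 4), dircon_schedule, mr.FitSpec())


def _design(X, Y, bias=False):
    labels = np.full(X.shape[0], "Opn", dtype=object)
    names = [f"ch{c:02d}" for c in range(X.shape[1] - (1 if bias else 0))]
    return DesignData(X=X, Y=Y, row_labels=labels, channel_names=names, bias=bias)


class TestPseudoInverseFit:
    def test_identity_design_returns_targets(self):
        Y = np.arange(8.0).reshape(4, 2)
        res = mr.fit_pseudo_inverse(_design(np.eye(4), Y), tol=0.01)
        np.testing.assert_allclose(res.coef, Y, atol=1e-12)
        assert res.n_singular_retained == 4

    def test_well_conditioned_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 4))
        Y = rng.standard_normal((100, 2))
        oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        res = mr.fit_pseudo_inverse(_design(X, Y), tol=0.01)
        np.testing.assert_allclose(res.coef, oracle, rtol=1e-8)

    def test_duplicated_column_matches_truncated_svd_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 4))
        X[:, 3] = X[:, 0]  # exact duplicate -> zero singular value
        Y = rng.standard_normal((60, 2))
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        keep = s / s[0] >= 0.01
        oracle = (Vt[keep].T / s[keep]) @ (U[:, keep].T @ Y)
        res = mr.fit_pseudo_inverse(_design(X, Y), tol=0.01)
        assert res.n_singular_retained == int(keep.sum())
        np.testing.assert_allclose(res.coef, oracle, rtol=1e-10, atol=1e-12)

    def test_all_zero_design_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            mr.fit_pseudo_inverse(_design(np.zeros((10, 3)), np.zeros((10, 2))))


class TestPredict:
    def test_zero_sigma_zero_force_without_bias(self):
        rng = np.random.default_rng(4)
        X, Y = rng.random((50, 3)), rng.random((50, 2))
        res = mr.fit_pseudo_inverse(_design(X, Y))
        out = res.predict(_sigma(5, 3) .sigma * 0.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_channel_subset_selected_by_name(self, jittered_session):
        _, _, _, sigma = jittered_session
        sch = mr.build_schedule(mr.DIRCON)
        res = EmgForceModel.from_session(sigma, sch).select_channels(2)
        full = res.predict(sigma)
        idx = [sigma.channel_names.index(c) for c in res.channel_names]
        narrow = mr.SigmaSeries(sigma.sigma[:, idx], 100.0, res.channel_names)
        np.testing.assert_array_equal(full, res.predict(narrow))

    def test_missing_channel_named_in_error(self, jittered_session):
        _, _, _, sigma = jittered_session
        sch = mr.build_schedule(mr.DIRCON)
        res = EmgForceModel.from_session(sigma, sch).fit()
        bad = mr.SigmaSeries(sigma.sigma[:, :3], 100.0, ["x", "y", "z"])
        with pytest.raises(ValueError, match="ch00"):
            res.predict(bad)

    def test_self_consistency_with_reported_overall_rmse(self, jittered_session):
        """Predicting the calibration data reproduces quality.rmse_overall."""
        _, _, _, sigma = jittered_session
        sch = mr.build_schedule(mr.DIRCON)
        spec = mr.FitSpec()
        res = EmgForceModel.from_session(sigma, sch, spec).fit(spec.tol)
        d = mr.assemble_design(sigma, sch, spec)
        pred = res.predict(
            mr.SigmaSeries(d.X[:, : d.n_channels], 100.0, d.channel_names)
        )
        rmse = float(np.sqrt(((pred - d.Y) ** 2).mean()))
        assert rmse == pytest.approx(res.quality.rmse_overall, rel=1e-12)


class TestQuality:
    def test_noise_free_linear_system_fits_exactly(self):
        rng = np.random.default_rng(5)
        W = rng.standard_normal((3, 2))
        X = rng.random((500, 3))
        res = mr.fit_pseudo_inverse(_design(X, X @ W))
        assert res.quality.rmse_overall < 1e-10
        assert all(v < 1e-10 for v in res.quality.rmse_by_type.values())

    def test_additive_output_noise_recovered_as_rmse(self):
        """With Y = XW + eps, eps ~ N(0, s^2), training RMSE -> s."""
        rng = np.random.default_rng(6)
        s = 2.5
        X = rng.random((6400, 4))
        W = rng.standard_normal((4, 2))
        Y = X @ W + rng.normal(0.0, s, (6400, 2))
        res = mr.fit_pseudo_inverse(_design(X, Y))
        assert res.quality.rmse_overall == pytest.approx(s, rel=0.10)

    def test_overall_recomputable_from_per_row_residuals(self, noisefree_session):
        _, _, _, sigma = noisefree_session
        sch = mr.build_schedule(mr.DIRCON)
        res = EmgForceModel.from_session(sigma, sch).fit()
        d = res.model.design
        cols = list(res.channels) + [d.n_channels]
        resid = d.X[:, cols] @ res.coef - d.Y
        assert res.quality.rmse_overall == pytest.approx(
            float(np.sqrt((resid**2).mean())), rel=1e-12
        )


class TestBackwardSelection:
    def test_k_equal_channel_count_is_identity(self, noisefree_session):
        _, _, _, sigma = noisefree_session
        sch = mr.build_schedule(mr.DIRCON)
        model = EmgForceModel.from_session(sigma, sch)
        res = model.select_channels(16)
        assert res.channels == list(range(16))

    def test_last_step_matches_exhaustive_single_removal_oracle(self, jittered_session):
        _, _, _, sigma = jittered_session
        sch = mr.build_schedule(mr.DIRCON)
        model = EmgForceModel.from_session(sigma, sch)
        got = model.select_channels(15).channels
        # oracle: try all single removals, same tie rule (lowest index wins)
        best_rmse, best_set = np.inf, None
        for ch in range(16):
            trial = [c for c in range(16) if c != ch]
            r = model.fit(channels=trial).quality.rmse_overall
            if r < best_rmse:
                best_rmse, best_set = r, trial
        assert got == best_set

    def test_informative_channels_retained_in_constructed_mixing(self):
        """Four channels carry distinct direction gains, two are pure noise;
        at high SNR selection to k = 4 keeps exactly the informative four."""
        rng = np.random.default_rng(8)
        n = 4000
        efforts = np.abs(rng.standard_normal((n, 4))) * 10.0
        G = np.zeros((6, 4))
        G[0, 0] = G[1, 1] = G[2, 2] = G[3, 3] = 1.0
        X = efforts @ G.T  # channels 4, 5 stay zero-gain
        X += 0.01 * rng.standard_normal(X.shape)  # sensor noise on all
        Y = np.column_stack(
            [efforts[:, 0] - efforts[:, 1], efforts[:, 2] - efforts[:, 3]]
        )
        res = mr.backward_select(_design(X, Y), k=4)
        assert sorted(res.channels) == [0, 1, 2, 3]

    def test_training_rmse_nondecreasing_as_k_shrinks(self, jittered_session):
        _, _, _, sigma = jittered_session
        sch = mr.build_schedule(mr.DIRCON)
        model = EmgForceModel.from_session(sigma, sch)
        rmses = [model.select_channels(k).quality.rmse_overall for k in (16, 12, 8, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_k_larger_than_channel_count_rejected(self, noisefree_session):
        _, _, _, sigma = noisefree_session
        model = EmgForceModel.from_session(sigma, mr.build_schedule(mr.DIRCON))
        with pytest.raises(ValueError, match="k="):
            model.select_channels(17)


class TestParameterRecovery:
    def test_noise_free_session_recovers_signed_effort(self, noisefree_session, dircon_schedule):
        _, traj, _, sigma = noisefree_session
        res = EmgForceModel.from_session(sigma, dircon_schedule).fit()
        idx = held_segment_frames(dircon_schedule)
        err = res.predict(sigma)[idx] - mr.ground_truth_force(traj)[idx]
        assert float(np.sqrt((err**2).mean())) < 1.0

    def test_jittered_session_recovery_within_five_percent_mvc(self, jittered_session, dircon_schedule):
        _, traj, _, sigma = jittered_session
        res = EmgForceModel.from_session(sigma, dircon_schedule).fit()
        idx = held_segment_frames(dircon_schedule)
        err = res.predict(sigma)[idx] - mr.ground_truth_force(traj)[idx]
        assert float(np.sqrt((err**2).mean())) < 5.0

    def test_rest_attains_lowest_per_type_rmse(self, jittered_session, dircon_schedule):
        _, _, _, sigma = jittered_session
        res = EmgForceModel.from_session(sigma, dircon_schedule).fit()
        by_type = res.quality.rmse_by_type
        assert min(by_type, key=by_type.get) == "Rest"

    def test_serialized_model_is_deterministic(self, noisefree_session, dircon_schedule, tmp_path):
        import json

        _, _, _, sigma = noisefree_session
        res = EmgForceModel.from_session(sigma, dircon_schedule).fit()
        a = json.dumps(res.to_dict())
        res2 = EmgForceModel.from_session(sigma, dircon_schedule).fit()
        assert a == json.dumps(res2.to_dict())
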