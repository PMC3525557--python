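"""Synthetic generators: covariance construction, ensembles, trials, studies."""

import json

import numpy as np
import pytest

from gaitcov.covariation import block_mask, covariation_indices, sample_covariance
from gaitcov.model import TASK_VARIABLES
from gaitcov.pipeline import process_trial
from gaitcov.synthetic import (
    GroupSpec,
    StudySpec,
    SyntheticSpec,
    build_covariance,
    generate_ensemble,
    generate_gait_trial,
    generate_study,
    mean_step_posture,
    participant_spec,
    stable_seed,
)


class TestBuildCovariance:
    def test_zero_gains_block_diagonal_cov_one(self, model, step_theta):
        spec = SyntheticSpec(model)
        _, J, build = spec.design("left", 1.0)
        mask = block_mask(model.joint_blocks, model.d)
        assert np.all(build.C[~mask] == 0.0)
        for name, cov in build.cov_true.items():
            assert cov == 1.0

    def test_null_gain_preserves_all_task_variances(self, model):
        base = SyntheticSpec(model).design("left", 1.0)[2]
        gained = SyntheticSpec(model, null_space_gain={"stepX": 1.0}).design(
            "left", 1.0
        )[2]
        J = SyntheticSpec(model).design("left", 1.0)[1]
        for i, name in enumerate(TASK_VARIABLES):
            tv_b = J[i] @ base.C @ J[i]
            tv_g = J[i] @ gained.C @ J[i]
            assert tv_g == pytest.approx(tv_b, abs=1e-10)
        assert gained.cov_true["stepX"] > 1.5

    def test_gain_monotonicity(self, model):
        covs = [
            SyntheticSpec(model, null_space_gain={"stepX": g})
            .design("left", 1.0)[2]
            .cov_true["stepX"]
            for g in (0.0, 0.5, 1.0)
        ]
        assert covs[0] < covs[1] < covs[2]

    def test_range_gain_inflates_tv_lowers_cov(self, model):
        spec0 = SyntheticSpec(model, null_space_gain={"stepX": 1.0})
        spec1 = SyntheticSpec(
            model, null_space_gain={"stepX": 1.0}, range_space_gain={"stepX": 1.0}
        )
        _, J, b0 = spec0.design("left", 1.0)
        _, _, b1 = spec1.design("left", 1.0)
        j = J[0]
        assert j @ b1.C @ j > j @ b0.C @ j * 1.5
        assert b1.cov_true["stepX"] < b0.cov_true["stepX"]

    def test_result_is_psd(self, model):
        spec = SyntheticSpec(
            model,
            null_space_gain={v: 1.0 for v in TASK_VARIABLES},
            step_com_corr={"X": -0.4, "Y": 0.6},
        )
        _, _, build = spec.design("right", 1.2)
        evals = np.linalg.eigvalsh(build.C)
        assert evals.min() >= -1e-10

    def test_step_com_corr_targeting(self, model):
        spec = SyntheticSpec(
            model,
            null_space_gain={"stepX": 0.5},
            step_com_corr={"X": -0.4, "Y": 0.6},
        )
        _, J, build = spec.design("left", 1.0)
        for direction, target in (("X", -0.4), ("Y", 0.6)):
            jb = J[TASK_VARIABLES.index("bCoM" + direction)]
            jf = J[TASK_VARIABLES.index("fCoM" + direction)]
            r = jb @ build.C @ jf / np.sqrt(
                (jb @ build.C @ jb) * (jf @ build.C @ jf)
            )
            assert r == pytest.approx(target, abs=0.05)

    def test_negative_gain_rejected(self, model):
        with pytest.raises(ValueError, match=">= 0"):
            SyntheticSpec(model, null_space_gain={"stepX": -1.0})


class TestGenerateEnsemble:
    def test_deterministic_per_entity(self, model):
        spec = SyntheticSpec(model, null_space_gain={"stepX": 1.0}, seed=9)
        a, _ = generate_ensemble(spec, "p01", 1.0, 1, "left")
        b, _ = generate_ensemble(spec, "p01", 1.0, 1, "left")
        c, _ = generate_ensemble(spec, "p01", 1.0, 2, "left")
        assert np.array_equal(a.angles, b.angles)
        assert not np.array_equal(a.angles, c.angles)

    def test_large_sample_recovers_generating_covariance(self, model):
        spec = SyntheticSpec(model, null_space_gain={"stepX": 1.0}, n_steps=2000)
        ens, truth = generate_ensemble(spec, "lln")
        C_hat = sample_covariance(ens.angles)
        C_gen = truth["C_gen"]
        rel = np.linalg.norm(C_hat - C_gen) / np.linalg.norm(C_gen)
        assert rel < 0.10

    def test_study_scale_ensemble_is_pipeline_ready(self, model):
        ens, _ = generate_ensemble(SyntheticSpec(model), "p01")
        assert ens.n == 20 and ens.d == model.d
        res = covariation_indices(ens, model)
        assert set(res) == set(TASK_VARIABLES)

    def test_injected_covariation_recovered(self, model):
        """COV(stepX) > 1 in >= 95% of seeds at n = 20, gain = 1."""
        spec = SyntheticSpec(model, null_space_gain={"stepX": 1.0}, seed=21)
        hits = [
            covariation_indices(
                generate_ensemble(spec, f"p{i:03d}")[0], model
            )["stepX"].cov > 1.0
            for i in range(60)
        ]
        assert np.mean(hits) >= 0.95

    def test_null_distribution_centred(self, model):
        """All gains zero: logCOV estimates centred near 0 (small-sample bias
        below 2 Monte-Carlo SE over 200 replicate ensembles)."""
        spec = SyntheticSpec(model, seed=4)
        vals = np.array(
            [
                covariation_indices(
                    generate_ensemble(spec, f"p{i:03d}")[0], model
                )["stepX"].log_cov
                for i in range(200)
            ]
        )
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 2 * se


class TestGenerateGaitTrial:
    def test_cadence_arithmetic(self, model):
        trial = generate_gait_trial(model, cadence_hz=0.9, duration_s=60.0, seed=2)
        for side in ("left", "right"):
            n = len(trial.events_true.frames(side))
            assert 52 <= n <= 56  # ~54 strides at 0.9 strides/s
        assert trial.traj.n_frames == 12000

    def test_deterministic(self, model):
        a = generate_gait_trial(model, duration_s=10.0, seed=7)
        b = generate_gait_trial(model, duration_s=10.0, seed=7)
        assert np.array_equal(a.angles, b.angles)
        assert np.array_equal(a.traj.data["LHEE"], b.traj.data["LHEE"])

    def test_no_dropout_all_postures_complete(self, model):
        trial = generate_gait_trial(
            model, duration_s=20.0, marker_noise_sd_m=0.0, dropout_rate=0.0, seed=3
        )
        res = process_trial(trial.traj, model, filter_cutoff_hz=None)
        assert res.n_complete == res.n_events

    def test_dropouts_exercise_completeness_rule(self, model):
        trial = generate_gait_trial(
            model, duration_s=30.0, dropout_rate=0.03, seed=3
        )
        res = process_trial(trial.traj, model)
        assert res.n_complete < res.n_events

    def test_rejects_bad_parameters(self, model):
        with pytest.raises(ValueError, match="> 0"):
            generate_gait_trial(model, cadence_hz=0.0)


class TestGenerateStudy:
    def test_roster_counts(self, model):
        study = StudySpec(model=model)
        assert study.n_trial_recordings == 192
        assert len(study.roster()) == 192

    def test_small_study_ensembles_and_manifest(self, model, tmp_path):
        study = StudySpec(model=model, n_participants=2, speeds=(1.0,), n_trials=1)
        out = tmp_path / "study"
        result = generate_study(study, seed=5, out_dir=out)
        assert len(result.ensembles) == 2 * 2 * 1 * 1 * 2
        manifest = json.loads((out / "manifest.json").read_text())
        assert len(manifest["ensembles"]) == len(result.ensembles)
        assert (out / "ground_truth.json").exists()

    def test_refuses_nonempty_dir(self, model, tmp_path):
        study = StudySpec(model=model, n_participants=1, speeds=(1.0,), n_trials=1)
        out = tmp_path / "study"
        generate_study(study, seed=5, out_dir=out)
        with pytest.raises(FileExistsError):
            generate_study(study, seed=5, out_dir=out)
        generate_study(study, seed=5, out_dir=out, overwrite=True)

    def test_group_delta_direction_recovered(self, model):
        """Older group's reduced stepX null-space gain shows up as lower
        recovered mean logCOV(stepX)."""
        study = StudySpec(model=model, n_participants=4, speeds=(1.0,), n_trials=1)
        result = generate_study(study, seed=13)
        by_group = {"younger": [], "older": []}
        for ens in result.ensembles:
            r = covariation_indices(ens, model)["stepX"]
            by_group[ens.meta["group"]].append(r.log_cov)
        assert np.mean(by_group["younger"]) > np.mean(by_group["older"])

    def test_participant_spec_applies_group_deltas(self, model):
        study = StudySpec(model=model, participant_gain_jitter=0.0)
        young = participant_spec(study, "younger", "y01")
        old = participant_spec(study, "older", "o01")
        assert young.null_space_gain["stepX"] == 1.0
        assert old.null_space_gain["stepX"] == 0.2
        assert old.baseline_sd_deg > young.baseline_sd_deg

    def test_stable_seed_below_2_31(self):
        s = stable_seed(123, "ensemble", "p01", 1.0, 1, "left")
        assert 0 <= s < 2**31
        assert s == stable_seed(123, "ensemble", "p01", 1.0, 1, "left")


def test_mean_step_posture_scales_with_speed(model):
    slow = mean_step_posture(model, "left", 0.8)
    fast = mean_step_posture(model, "left", 1.2)
    hip = model.dof_slices["hip_l"].start
    assert abs(fast[hip]) > abs(slow[hip])
    # non-sagittal joints (wrists) do not scale
    wrist = model.dof_slices["wrist_l"]
    assert np.array_equal(fast[wrist], slow[wrist])
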