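import numpy as np
import pytest

from gaitcov.model import JointSpec, KinematicModel, SegmentSpec


@pytest.fixture(scope="session")
def model() -> KinematicModel:
    return KinematicModel.default()


@pytest.fixture(scope="session")
def step_theta(model):
    from gaitcov.synthetic import mean_step_posture

    return mean_step_posture(model, "left")


def build_planar_model() -> KinematicModel:
    """Planar two-legged test chain with closed-form endpoint kinematics.

    Left leg: two 0.4 m links (hip + knee, both sagittal '-y' so positive
    angles swing the links forward); right leg: one rigid 0.8 m link.  The
    left "heel/toe" marker sits at the distal end of the second link, so
    stepX(front=left) = 0.4 sin(a) + 0.4 sin(a + b) - const.
    """
    segs = [
        SegmentSpec("base", 0.1, [0, 0, 1], 0.4, 0.5,
                    {"B1": [0.1, 0.1, 0], "B2": [0.1, -0.1, 0], "B3": [-0.1, 0, 0.05]}),
        SegmentSpec("thigh_l", 0.4, [0, 0, -1], 0.2, 0.5,
                    {"TH1": [0.05, 0.05, -0.1], "TH2": [-0.05, 0.05, -0.2],
                     "TH3": [0, -0.05, -0.3]}),
        SegmentSpec("shank_l", 0.4, [0, 0, -1], 0.2, 0.5,
                    {"LTIP": [0, 0, -0.4], "LTOE": [0.05, 0, -0.4],
                     "SH1": [0.05, 0.05, -0.1], "SH2": [-0.05, 0.05, -0.2]}),
        SegmentSpec("leg_r", 0.8, [0, 0, -1], 0.2, 0.5,
                    {"RTIP": [0, 0, -0.8], "RTOE": [0.05, 0, -0.8],
                     "RL1": [0.05, 0.05, -0.2], "RL2": [-0.05, 0.05, -0.4]}),
    ]
    joints = [
        JointSpec("hip_l", "base", "thigh_l", [0, 0.1, 0], ("-y",)),
        JointSpec("knee_l", "thigh_l", "shank_l", [0, 0, -0.4], ("-y",)),
        JointSpec("hip_r", "base", "leg_r", [0, -0.1, 0], ("-y",)),
    ]
    task = {
        "left": {"heel": "LTIP", "toe": "LTOE"},
        "right": {"heel": "RTIP", "toe": "RTOE"},
    }
    return KinematicModel(segs, joints, "base", task, name="planar")


@pytest.fixture(scope="session")
def planar_model() -> KinematicModel:
    return build_planar_model()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
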