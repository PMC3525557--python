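"""Synthetic stand-ins for treadmill mocap recordings.

Three levels of generation, all seeded and reproducible per entity:

* ``build_covariance`` — joint-angle covariance matrices with controlled
  structure: a block-diagonal baseline (within-joint correlations only),
  compensatory components supported on the null space of the task Jacobian
  (raising the covariation index of a targeted variable without changing its
  task variance), range-space components (raising task variance), and an
  optional rank-2 update steering the bCoM-fCoM correlation.
* ``generate_ensemble`` — step-posture ensembles: multivariate-normal angle
  fluctuations around a speed-dependent mean step posture.
* ``generate_gait_trial`` — marker-level 60 s treadmill trials: smooth
  periodic gait primitives plus per-step perturbations, markers by forward
  kinematics with isotropic noise and optional dropouts; ground-truth heel
  strikes and angles are logged.
* ``generate_study`` — a full two-group design (2 groups x 16 participants
  x 3 speeds x 2 trials), with group deltas emulating reduced step-length
  covariation and inflated fore-aft variability in the older group.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .covariation import covariation_from_cov, decorrelate
from .model import (
    SIDES,
    TASK_VARIABLES,
    KinematicModel,
    compute_task_variables,
    forward_kinematics,
    task_jacobian,
)
from .preprocessing import GaitEvents, StepPostureEnsemble, TrajectorySet

DEG = np.pi / 180.0


def stable_seed(*parts) -> int:
    """Deterministic sub-seed (< 2^31) from a master seed and entity ids."""
    key = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# -- mean step postures ------------------------------------------------------

# nominal heel-strike posture of the default chain, degrees per joint DOF;
# sagittal entries scale with walking speed
_STEP_POSTURE_DEG = {
    # front leg extended forward, back leg trailing
    "hip_front": [22.0, 2.0, 0.0],
    "hip_back": [-12.0, 2.0, 0.0],
    "knee_front": [4.0, 0.0],
    "knee_back": [18.0, 0.0],
    "ankle_front": [6.0, 0.0],
    "ankle_back": [-10.0, 0.0],
    "spine": [4.0, 0.0, 3.0],
    "thorax": [2.0, 0.0, -3.0],
    "neck": [-2.0, 0.0, 0.0],
    "shoulder_front": [-14.0, 2.0, 0.0],  # arm swings opposite to leg
    "shoulder_back": [14.0, 2.0, 0.0],
    "elbow_front": [18.0],
    "elbow_back": [12.0],
    "wrist_front": [0.0, 0.0],
    "wrist_back": [0.0, 0.0],
}
_SAGITTAL_SCALED = {"hip", "knee", "ankle", "shoulder", "elbow"}


def mean_step_posture(
    model: KinematicModel, front_side: str, speed_factor: float = 1.0
) -> np.ndarray:
    """Speed-scaled heel-strike mean posture (rad) for the default chain.

    Joints absent from the nominal table (custom test models) stay at zero.
    """
    if front_side not in SIDES:
        raise ValueError(f"invalid side {front_side!r}")
    back_side = "right" if front_side == "left" else "left"
    suffix = {"_" + front_side[0]: "_front", "_" + back_side[0]: "_back"}
    theta = np.zeros(model.d)
    for jid, sl in model.dof_slices.items():
        key = jid
        for sfx, role in suffix.items():
            if jid.endswith(sfx):
                key = jid[: -len(sfx)] + role
                break
        vals = _STEP_POSTURE_DEG.get(key)
        if vals is None:
            continue
        vals = np.asarray(vals[: sl.stop - sl.start], dtype=float)
        base = jid.rsplit("_", 1)[0]
        if base in _SAGITTAL_SCALED:
            vals = vals * speed_factor
        theta[sl] = vals * DEG
    return theta


# -- covariance construction -------------------------------------------------


@dataclass
class CovarianceBuild:
    C: np.ndarray
    baseline: np.ndarray
    clip_magnitude: float
    cov_true: dict[str, float]  # linearized COV implied by C per task variable


def _null_space_component(
    j_row: np.ndarray,
    J_all: np.ndarray,
    joint_blocks: Sequence[np.ndarray],
    n_pairs: int = 2,
) -> np.ndarray:
    """PSD matrix supported on ker(J_all) whose block-diagonal part loads the
    targeted variable's quadratic form.

    Built from pairwise compensation vectors: for two joint blocks, opposite
    gradient-aligned components cancel in the task variable while each block
    retains variance — then projected onto the null space of the *full*
    Jacobian so no task variable's empirical variance is affected.
    """
    d = j_row.size
    norms = [(float(np.linalg.norm(j_row[b])), b) for b in joint_blocks]
    usable = [nb for nb in norms if nb[0] > 1e-12]
    usable.sort(key=lambda nb: -nb[0])
    pinv = np.linalg.pinv(J_all)
    N = np.zeros((d, d))
    added = 0
    for k in range(0, len(usable) - 1, 2):
        if added >= n_pairs:
            break
        (_, b1), (_, b2) = usable[k], usable[k + 1]
        w = np.zeros(d)
        w[b1] = j_row[b1] / (j_row[b1] @ j_row[b1])
        w[b2] = -j_row[b2] / (j_row[b2] @ j_row[b2])
        w = w - pinv @ (J_all @ w)  # exact null-space projection
        q = sum(float(j_row[b] @ w[b]) ** 2 for b in joint_blocks)
        if q < 1e-14:
            continue
        N += np.outer(w, w)
        added += 1
    return N


def _tune_step_com(
    C: np.ndarray, jb: np.ndarray, jf: np.ndarray, target_r: float
) -> np.ndarray:
    """Rank-2 update steering corr(bCoM, fCoM) toward ``target_r``.

    Bisects the update magnitude along the symmetrized outer product of the
    two gradient directions; the result may be marginally indefinite and is
    PSD-clipped by the caller.
    """
    u = jb / (jb @ jb)
    v = jf / (jf @ jf)
    K = np.outer(u, v) + np.outer(v, u)
    # quadratic forms of C(lam) = C + lam K reduce to scalars:
    vb0, vf0, cbf0 = float(jb @ C @ jb), float(jf @ C @ jf), float(jb @ C @ jf)
    bu, bv, fu, fv = float(jb @ u), float(jb @ v), float(jf @ u), float(jf @ v)

    def corr(lam):
        lam = np.asarray(lam, dtype=float)
        vb = vb0 + 2.0 * lam * bu * bv
        vf = vf0 + 2.0 * lam * fu * fv
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(
                (vb > 0) & (vf > 0),
                (cbf0 + lam * (bu * fv + bv * fu)) / np.sqrt(np.abs(vb * vf)),
                np.nan,
            )
        return out if out.ndim else float(out)

    r0 = corr(0.0)
    if not np.isfinite(r0) or abs(r0 - target_r) < 1e-3:
        return C
    # bracket by scanning outward in both directions, then bisect
    scale = float(np.sqrt(vb0 * vf0))
    best = None
    for sign_dir in (1.0, -1.0):
        grid = sign_dir * np.linspace(0.0, 3.0 * scale, 400)
        vals = corr(grid)
        ok = np.isfinite(vals)
        hit = np.flatnonzero(ok & ((vals - target_r) * (r0 - target_r) <= 0))
        if hit.size:
            lo, hi = 0.0, grid[hit[0]]
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                cm = corr(mid)
                if not np.isfinite(cm):
                    hi = mid
                elif (cm - target_r) * (r0 - target_r) > 0:
                    lo = mid
                else:
                    hi = mid
            best = 0.5 * (lo + hi)
            break
    if best is None:
        return C  # target unreachable without breaking positivity; keep C
    return C + best * K


def psd_clip(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Project onto the PSD cone by eigenvalue clipping; returns the clipped
    magnitude (most negative eigenvalue before clipping, 0 if none)."""
    C = 0.5 * (C + C.T)
    evals, evecs = np.linalg.eigh(C)
    clip = float(max(0.0, -evals.min()))
    evals = np.clip(evals, 0.0, None)
    return (evecs * evals) @ evecs.T, clip


def build_covariance(
    J: np.ndarray,
    baseline_sd: np.ndarray,
    joint_blocks: Sequence[np.ndarray],
    within_joint_corr: float = 0.2,
    null_space_gain: Mapping[str, float] | None = None,
    range_space_gain: Mapping[str, float] | None = None,
    step_com_corr: Mapping[str, float | None] | None = None,
) -> CovarianceBuild:
    """Generating joint-angle covariance with controlled covariation structure.

    ``J`` is the (6, d) task Jacobian at the mean posture; ``baseline_sd`` the
    per-DOF angle SD (rad).  A null-space gain of g for a variable adds
    compensatory cross-joint covariance raising its decorrelated task variance
    by about g times the baseline task variance (so linearized COV ~ 1 + g)
    while leaving every variable's empirical task variance unchanged; a
    range-space gain of g inflates the variable's task variance by g times its
    baseline value.
    """
    J = np.asarray(J, dtype=float)
    d = J.shape[1]
    sd = np.broadcast_to(np.asarray(baseline_sd, dtype=float), (d,))
    if np.any(sd <= 0):
        raise ValueError("baseline SDs must be > 0")
    if not 0 <= within_joint_corr < 1:
        raise ValueError("within_joint_corr must lie in [0, 1)")
    null_space_gain = dict(null_space_gain or {})
    range_space_gain = dict(range_space_gain or {})
    if any(g < 0 for g in null_space_gain.values()) or any(
        g < 0 for g in range_space_gain.values()
    ):
        raise ValueError("gains must be >= 0")

    # block-diagonal baseline: within-joint structure only
    D = np.zeros((d, d))
    for b in joint_blocks:
        s = sd[b]
        block = np.outer(s, s) * within_joint_corr
        block[np.diag_indices(len(b))] = s**2
        D[np.ix_(b, b)] = block

    # independent rows of the forward map (step rows are sums of b and f)
    J_ind = J[[TASK_VARIABLES.index(v) for v in ("bCoMX", "bCoMY", "fCoMX", "fCoMY")]]

    C = D.copy()
    for name, gain in null_space_gain.items():
        if gain == 0:
            continue
        j = J[TASK_VARIABLES.index(name)]
        N = _null_space_component(j, J_ind, joint_blocks)
        q = float(j @ decorrelate(N, joint_blocks) @ j)
        if q <= 0:
            raise ValueError(f"no usable null-space structure for {name}")
        tv_base = float(j @ D @ j)
        C = C + gain * (tv_base / q) * N
    for name, gain in range_space_gain.items():
        if gain == 0:
            continue
        j = J[TASK_VARIABLES.index(name)]
        tv_base = float(j @ D @ j)
        C = C + gain * tv_base * np.outer(j, j) / float(j @ j) ** 2

    for direction, target in (step_com_corr or {}).items():
        if target is None:
            continue
        jb = J[TASK_VARIABLES.index("bCoM" + direction)]
        jf = J[TASK_VARIABLES.index("fCoM" + direction)]
        C = _tune_step_com(C, jb, jf, float(target))

    C, clip = psd_clip(C)
    cov_true = {
        name: covariation_from_cov(C, J[i], joint_blocks)[2]
        for i, name in enumerate(TASK_VARIABLES)
    }
    return CovarianceBuild(C=C, baseline=D, clip_magnitude=clip, cov_true=cov_true)


# -- posture-level ensembles -------------------------------------------------


@dataclass
class SyntheticSpec:
    """Generative parameters for simulated step-posture data.

    Defaults describe the study conditions emulated throughout: 20 step
    postures per (trial, side), 1.5 deg baseline angle SD, 2 mm marker noise.
    """

    model: KinematicModel
    baseline_sd_deg: float | np.ndarray = 1.5
    within_joint_corr: float = 0.2
    null_space_gain: dict[str, float] = field(default_factory=dict)
    range_space_gain: dict[str, float] = field(default_factory=dict)
    step_com_corr: dict[str, float | None] = field(
        default_factory=lambda: {"X": None, "Y": None}
    )
    n_steps: int = 20
    marker_noise_sd_m: float = 0.002
    max_sd_deg: float | None = None  # cap on any DOF's total angle SD
    seed: int = 0
    _design_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.n_steps < 3:
            raise ValueError("n_steps must be >= 3")
        for g in (self.null_space_gain, self.range_space_gain):
            if any(v < 0 for v in g.values()):
                raise ValueError("gains must be >= 0")

    def design(self, front_side: str, speed_factor: float = 1.0):
        """(theta_bar, J, CovarianceBuild) for one side and speed, cached."""
        key = (front_side, round(float(speed_factor), 9))
        if key not in self._design_cache:
            theta_bar = mean_step_posture(self.model, front_side, speed_factor)
            J = task_jacobian(self.model, theta_bar, front_side)
            sd = np.asarray(self.baseline_sd_deg, dtype=float) * DEG
            # step-to-step variability grows mildly with walking speed
            sd = sd * np.sqrt(speed_factor)
            build = build_covariance(
                J,
                sd,
                self.model.joint_blocks,
                within_joint_corr=self.within_joint_corr,
                null_space_gain=self.null_space_gain,
                range_space_gain=self.range_space_gain,
                step_com_corr=self.step_com_corr,
            )
            if self.max_sd_deg is not None:
                # uniform shrinkage keeps every covariation index (a ratio of
                # quadratic forms) unchanged while enforcing the requested
                # small-amplitude regime
                top = float(np.sqrt(np.diag(build.C).max()))
                cap = self.max_sd_deg * DEG
                if top > cap:
                    build = CovarianceBuild(
                        C=build.C * (cap / top) ** 2,
                        baseline=build.baseline * (cap / top) ** 2,
                        clip_magnitude=build.clip_magnitude,
                        cov_true=build.cov_true,
                    )
            self._design_cache[key] = (theta_bar, J, build)
        return self._design_cache[key]


def generate_ensemble(
    spec: SyntheticSpec,
    participant: str = "p01",
    speed: float = 1.0,
    trial: int = 1,
    side: str = "left",
    meta: Mapping | None = None,
) -> tuple[StepPostureEnsemble, dict]:
    """One step-posture ensemble plus its generative ground truth.

    Deterministic under (spec.seed, participant, speed, trial, side): the
    same cell regenerates bit-identically in isolation.
    """
    theta_bar, J, build = spec.design(side, speed)
    sub = stable_seed(spec.seed, "ensemble", participant, speed, trial, side)
    rng = np.random.default_rng(sub)
    L = np.linalg.cholesky(build.C + 1e-18 * np.eye(spec.model.d))
    U = rng.standard_normal((spec.n_steps, spec.model.d)) @ L.T
    ens = StepPostureEnsemble(
        angles=theta_bar + U,
        front_side=side,
        frames=list(range(spec.n_steps)),
        meta={"participant": participant, "speed": speed, "trial": trial,
              "side": side, **(meta or {})},
    )
    truth = {
        "theta_bar": theta_bar,
        "C_gen": build.C,
        "J": J,
        "cov_true": build.cov_true,
        "clip_magnitude": build.clip_magnitude,
        "seed": sub,
    }
    return ens, truth


# -- marker-level gait trials ------------------------------------------------

# periodic gait primitives: per-joint (constant, cos phi, cos 2 phi) Fourier
# coefficients in degrees, for the side striking at phase 0; the opposite
# side is the same pattern advanced by half a cycle.  All harmonics are even
# around the strike so the anterior-extreme detection signal peaks exactly at
# the true event.
_PRIMITIVES = {
    "hip": {"same": (5.0, 17.0, 0.0), "opp": (5.0, -17.0, 0.0)},
    "knee": {"same": (12.5, -12.5, 0.0), "opp": (12.5, 12.5, 0.0)},
    "ankle": {"same": (-2.0, 8.0, 0.0), "opp": (-2.0, -8.0, 0.0)},
    "shoulder": {"same": (0.0, -12.0, 0.0), "opp": (0.0, 12.0, 0.0)},
    "elbow": {"same": (15.0, -5.0, 0.0), "opp": (15.0, 5.0, 0.0)},
    "spine": {"any": (3.0, 0.0, 1.5)},
    "thorax": {"any": (0.0, 0.0, -1.5)},
}


@dataclass
class GaitTrial:
    traj: TrajectorySet
    events_true: GaitEvents
    angles: np.ndarray  # (n_frames, d)
    root_trans: np.ndarray  # (n_frames, 3)
    rate_hz: float
    meta: dict = field(default_factory=dict)

    def true_angles_at(self, frames: Sequence[int]) -> np.ndarray:
        return self.angles[np.asarray(frames, dtype=int)]


def generate_gait_trial(
    model: KinematicModel,
    cadence_hz: float = 0.9,
    speed_factor: float = 1.0,
    duration_s: float = 60.0,
    marker_noise_sd_m: float = 0.002,
    dropout_rate: float = 0.0,
    seed: int = 0,
    rate_hz: float = 200.0,
    spec: SyntheticSpec | None = None,
) -> GaitTrial:
    """Synthetic treadmill walking trial at marker level.

    ``cadence_hz`` is strides per second per side; the stride period is
    snapped to an even number of frames so heel strikes fall exactly on
    sampled frames.  Per-step posture perturbations are drawn from the
    spec's generating covariance and interpolated with a cosine-squared
    partition of unity, so each logged strike posture equals the drawn one
    exactly.  ``dropout_rate`` is the expected invalid-frame fraction per
    marker.
    """
    if cadence_hz <= 0 or duration_s <= 0:
        raise ValueError("cadence and duration must be > 0")
    if spec is None:
        spec = SyntheticSpec(model, seed=seed)
    rng = np.random.default_rng(stable_seed(seed, "trial", cadence_hz, duration_s))

    stride = 2 * max(2, int(round(rate_hz / (2.0 * cadence_hz))))  # frames, even
    half = stride // 2
    n_frames = int(round(duration_s * rate_hz))
    phase = 2.0 * np.pi * np.arange(n_frames) / stride  # left strikes at 0 mod 2pi

    # primitive joint-angle trajectories
    theta = np.zeros((n_frames, model.d))
    c1, c2 = np.cos(phase), np.cos(2.0 * phase)
    for jid, sl in model.dof_slices.items():
        base, _, suffix = jid.rpartition("_")
        prim = _PRIMITIVES.get(base if suffix in ("l", "r") else jid)
        if prim is None:
            continue
        if "any" in prim:
            a0, a1, a2 = prim["any"]
        else:
            a0, a1, a2 = prim["same" if suffix == "l" else "opp"]
        scale = speed_factor if base in _SAGITTAL_SCALED else 1.0
        theta[:, sl.start] = (a0 + a1 * scale * c1 + a2 * c2) * DEG

    # per-step perturbations: strikes alternate left (even k) / right (odd k)
    strike_frames = np.arange(0, n_frames, half)
    pert = np.zeros((n_frames, model.d))
    events = []
    frames_idx = np.arange(n_frames)
    for k, f0 in enumerate(strike_frames):
        side = "left" if k % 2 == 0 else "right"
        _, _, build = spec.design(side, speed_factor)
        L = np.linalg.cholesky(build.C + 1e-18 * np.eye(model.d))
        u = L @ rng.standard_normal(model.d)
        tau = frames_idx - f0
        w = np.where(np.abs(tau) < half, np.cos(np.pi * tau / stride) ** 2, 0.0)
        pert += np.outer(w, u)
        if half <= f0 <= n_frames - half - 1:
            events.append((int(f0), side))
    theta = theta + pert

    # pelvis (root) motion: small even fore-aft/vertical bob, lateral sway
    root_trans = np.stack(
        [0.01 * np.cos(2 * phase), 0.02 * np.sin(phase), 0.015 * np.cos(2 * phase)],
        axis=1,
    )

    poses = forward_kinematics(model, theta, root_trans=root_trans)
    data: dict[str, np.ndarray] = {}
    for label in model.marker_labels:
        pos = poses.marker_position(model, label)
        if marker_noise_sd_m > 0:
            pos = pos + rng.normal(0.0, marker_noise_sd_m, pos.shape)
        data[label] = pos

    if dropout_rate > 0:
        span = 20  # frames per dropout episode
        for label in data:
            n_spans = rng.poisson(dropout_rate * n_frames / span)
            for _ in range(n_spans):
                s = rng.integers(0, max(1, n_frames - span))
                data[label][s : s + span] = np.nan

    traj = TrajectorySet(data, rate_hz)
    return GaitTrial(
        traj=traj,
        events_true=GaitEvents(events),
        angles=theta,
        root_trans=root_trans,
        rate_hz=rate_hz,
        meta={
            "cadence_hz": rate_hz / stride,
            "stride_frames": stride,
            "speed_factor": speed_factor,
            "marker_noise_sd_m": marker_noise_sd_m,
            "dropout_rate": dropout_rate,
            "seed": seed,
        },
    )


# -- two-group studies -------------------------------------------------------


@dataclass
class GroupSpec:
    """Per-group deltas applied on top of the study's base parameters."""

    null_space_gain: dict[str, float] = field(default_factory=dict)
    sd_scale: float = 1.0
    step_com_corr: dict[str, float | None] = field(default_factory=dict)


def default_group_specs() -> dict[str, GroupSpec]:
    """Study conditions: the older group has weaker step-length covariation,
    inflated angle variability, and no fore-aft bCoM-fCoM coupling."""
    return {
        "younger": GroupSpec(
            null_space_gain={"stepX": 1.0},
            step_com_corr={"X": -0.4, "Y": 0.6},
        ),
        "older": GroupSpec(
            null_space_gain={"stepX": 0.2},
            sd_scale=1.3,
            step_com_corr={"X": 0.0, "Y": 0.6},
        ),
    }


@dataclass
class StudySpec:
    """Full factorial design: groups x participants x speeds x trials."""

    model: KinematicModel
    groups: dict[str, GroupSpec] = field(default_factory=default_group_specs)
    n_participants: int = 16
    speeds: tuple[float, ...] = (0.8, 1.0, 1.2)
    n_trials: int = 2
    base_null_space_gain: dict[str, float] = field(
        default_factory=lambda: {
            "stepY": 0.6, "bCoMX": 0.8, "bCoMY": 0.8, "fCoMX": 1.5, "fCoMY": 1.5,
        }
    )
    baseline_sd_deg: float = 1.5
    n_steps: int = 20
    participant_gain_jitter: float = 0.15
    seed: int = 0

    @property
    def n_trial_recordings(self) -> int:
        return len(self.groups) * self.n_participants * len(self.speeds) * self.n_trials

    def roster(self) -> list[dict]:
        rows = []
        for gi, group in enumerate(self.groups):
            for p in range(1, self.n_participants + 1):
                pid = f"{group[0]}{p:02d}"
                for speed in self.speeds:
                    for trial in range(1, self.n_trials + 1):
                        rows.append(
                            {"group": group, "participant": pid,
                             "speed": speed, "trial": trial}
                        )
        return rows


def participant_spec(study: StudySpec, group: str, participant: str) -> SyntheticSpec:
    """Resolve the generative spec for one participant (group deltas plus a
    mild participant-level multiplicative jitter on gains and SDs)."""
    gspec = study.groups[group]
    gains = dict(study.base_null_space_gain)
    gains.update(gspec.null_space_gain)
    rng = np.random.default_rng(stable_seed(study.seed, "participant", participant))
    if study.participant_gain_jitter > 0:
        jit = study.participant_gain_jitter
        gains = {
            k: v * float(np.exp(rng.normal(0.0, jit))) for k, v in gains.items()
        }
        sd_jit = float(np.exp(rng.normal(0.0, jit / 2)))
    else:
        sd_jit = 1.0
    return SyntheticSpec(
        model=study.model,
        baseline_sd_deg=study.baseline_sd_deg * gspec.sd_scale * sd_jit,
        null_space_gain=gains,
        step_com_corr={"X": None, "Y": None, **gspec.step_com_corr},
        n_steps=study.n_steps,
        seed=stable_seed(study.seed, "data", participant),
    )


@dataclass
class SyntheticStudy:
    spec: StudySpec
    ensembles: list[StepPostureEnsemble]
    ground_truth: dict[str, dict]

    def __len__(self) -> int:
        return len(self.ensembles)


def generate_study(
    study: StudySpec,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> SyntheticStudy:
    """Generate every (trial, side) step-posture ensemble of the design.

    With ``out_dir``, writes ensembles as labeled CSV plus a manifest and a
    ground-truth JSON (generating COV per ensemble, clip magnitudes); refuses
    a non-empty existing directory unless ``overwrite`` is set.
    """
    if seed is not None:
        study = replace(study, seed=seed)
    ensembles: list[StepPostureEnsemble] = []
    truths: dict[str, dict] = {}
    for row in study.roster():
        spec = participant_spec(study, row["group"], row["participant"])
        for side in SIDES:
            ens, truth = generate_ensemble(
                spec,
                participant=row["participant"],
                speed=row["speed"],
                trial=row["trial"],
                side=side,
                meta={"group": row["group"]},
            )
            key = "{participant}_s{speed}_t{trial}_{side}".format(**row, side=side)
            ensembles.append(ens)
            truths[key] = {
                "cov_true": truth["cov_true"],
                "clip_magnitude": truth["clip_magnitude"],
                "group": row["group"],
                **{k: row[k] for k in ("participant", "speed", "trial")},
                "side": side,
            }
    result = SyntheticStudy(study, ensembles, truths)
    if out_dir is not None:
        _write_study(result, Path(out_dir), overwrite)
    return result


def _write_study(study: SyntheticStudy, out_dir: Path, overwrite: bool) -> None:
    from .io import write_ensemble

    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty")
    ens_dir = out_dir / "ensembles"
    ens_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"design": {
        "groups": list(study.spec.groups),
        "n_participants": study.spec.n_participants,
        "speeds": list(study.spec.speeds),
        "n_trials": study.spec.n_trials,
        "n_trial_recordings": study.spec.n_trial_recordings,
        "seed": study.spec.seed,
    }, "ensembles": []}
    for ens in study.ensembles:
        m = ens.meta
        name = "{participant}_s{speed}_t{trial}_{side}.csv".format(**m)
        write_ensemble(ens, ens_dir / name)
        manifest["ensembles"].append({"path": f"ensembles/{name}", **m})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out_dir / "ground_truth.json").write_text(
        json.dumps(study.ground_truth, indent=1, default=float)
    )
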