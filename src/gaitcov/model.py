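"""Whole-body kinematic chain: forward model, CoM, task variables, Jacobian,
marker-based pose fitting and joint-angle extraction.

The model is a configurable tree of rigid segments connected by Cardan joints.
The forward map takes the joint-angle vector ``theta`` (default configuration:
35 angles over 15 joints) to segment poses in the lab frame, from which the
whole-body centre of mass and the six gait task variables are computed:

========  =====================================================
stepX     fore-aft distance back toe -> front heel (step length)
stepY     lateral distance back toe -> front heel (step width)
bCoMX/Y   CoM position relative to the back toe
fCoMX/Y   front heel position relative to the CoM
========  =====================================================

so that ``step = bCoM + fCoM`` holds exactly in both directions.  Lateral
quantities are signed along the axis pointing from the back-foot side toward
the front-foot side, which makes them typically positive in normal gait.

Lab frame: X fore-aft (+ = walking direction), Y lateral (+ = left), Z up.
All task variables are invariant under global translation; the pelvis (root)
pose enters only as per-frame context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

TASK_VARIABLES = ("stepX", "stepY", "bCoMX", "bCoMY", "fCoMX", "fCoMY")
SIDES = ("left", "right")

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def _parse_axis_token(token: str) -> tuple[str, float]:
    """'-y' -> ('y', -1.0); 'x' -> ('x', +1.0)."""
    token = token.strip().lower()
    sign = 1.0
    if token.startswith("-"):
        sign = -1.0
        token = token[1:]
    if token not in _AXIS_INDEX:
        raise ValueError(f"invalid Cardan axis token {token!r}")
    return token, sign


@dataclass(frozen=True)
class SegmentSpec:
    """Rigid segment: geometry, anthropometrics and marker attachments.

    ``axis`` is the unit proximal->distal direction in the segment's local
    frame; the distal endpoint lies at ``axis * length`` and the segment CoM
    at ``axis * length * com_offset``.
    """

    id: str
    length: float
    axis: np.ndarray
    mass_fraction: float
    com_offset: float
    markers: Mapping[str, np.ndarray]

    def __post_init__(self):
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: length must be > 0")
        if not 0.0 <= self.com_offset <= 1.0:
            raise ValueError(f"segment {self.id}: com_offset outside [0, 1]")
        if not np.isclose(np.linalg.norm(self.axis), 1.0, atol=1e-9):
            raise ValueError(f"segment {self.id}: axis must be a unit vector")
        object.__setattr__(
            self,
            "markers",
            {k: np.asarray(v, dtype=float) for k, v in self.markers.items()},
        )

    @property
    def distal(self) -> np.ndarray:
        return self.axis * self.length

    @property
    def com_local(self) -> np.ndarray:
        return self.axis * self.length * self.com_offset


@dataclass(frozen=True)
class JointSpec:
    """Cardan joint between a parent and a child segment.

    ``rotation_order`` lists one axis token per DOF, e.g. ``("-y", "x", "z")``
    for flexion -> abduction -> rotation; a '-' prefix flips the angle's sign
    about that axis.  Rotations are intrinsic (body-fixed), applied in order.
    """

    id: str
    parent: str
    child: str
    offset: np.ndarray
    rotation_order: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        object.__setattr__(self, "rotation_order", tuple(self.rotation_order))
        if not 1 <= len(self.rotation_order) <= 3:
            raise ValueError(f"joint {self.id}: n_dof must be 1-3")
        letters, signs = zip(*(_parse_axis_token(t) for t in self.rotation_order))
        if len(set(letters)) != len(letters):
            raise ValueError(f"joint {self.id}: repeated Cardan axis")
        object.__setattr__(self, "_letters", letters)
        object.__setattr__(self, "_signs", np.asarray(signs))

    @property
    def n_dof(self) -> int:
        return len(self.rotation_order)

    @property
    def seq(self) -> str:
        """Intrinsic-rotation sequence string for scipy (uppercase)."""
        return "".join(self._letters).upper()

    @property
    def signs(self) -> np.ndarray:
        return self._signs

    @property
    def extended_seq(self) -> str:
        """seq padded to three distinct axes (locked axes appended last)."""
        rest = [a for a in "xyz" if a not in self._letters]
        return ("".join(self._letters) + "".join(rest)).upper()


class KinematicModel:
    """Segment/joint tree with an ordered joint-angle layout.

    The DOF vector theta concatenates each joint's angles in the order the
    joints are declared; ``dof_layout`` records the (joint id, axis index)
    pair of every entry and ``joint_blocks`` partitions DOF indices by joint
    (the block structure used by the covariation analysis).
    """

    def __init__(
        self,
        segments: Iterable[SegmentSpec],
        joints: Iterable[JointSpec],
        root_segment: str,
        task_markers: Mapping[str, Mapping[str, str]],
        name: str = "model",
    ):
        self.name = name
        self.segments: dict[str, SegmentSpec] = {s.id: s for s in segments}
        self.joints: dict[str, JointSpec] = {j.id: j for j in joints}
        self.root_segment = root_segment
        self.task_markers = {s: dict(task_markers[s]) for s in SIDES}
        self._validate_tree()

        self.dof_layout: tuple[tuple[str, int], ...] = tuple(
            (j.id, k) for j in self.joints.values() for k in range(j.n_dof)
        )
        self.dof_slices: dict[str, slice] = {}
        pos = 0
        for j in self.joints.values():
            self.dof_slices[j.id] = slice(pos, pos + j.n_dof)
            pos += j.n_dof

        total = sum(s.mass_fraction for s in self.segments.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass fractions sum to {total}, expected 1")

        # marker label -> owning segment
        self.marker_segment: dict[str, str] = {}
        for s in self.segments.values():
            for label in s.markers:
                if label in self.marker_segment:
                    raise ValueError(f"duplicate marker label {label}")
                self.marker_segment[label] = s.id

    def _validate_tree(self):
        parent_of: dict[str, str] = {}
        for j in self.joints.values():
            for sid in (j.parent, j.child):
                if sid not in self.segments:
                    raise ValueError(f"joint {j.id} references unknown segment {sid}")
            if j.child in parent_of:
                raise ValueError(f"segment {j.child} has multiple parent joints")
            if j.child == self.root_segment:
                raise ValueError("root segment cannot be a joint child")
            parent_of[j.child] = j.parent
        # connectivity / acyclicity: walking up from every segment must reach root
        for sid in self.segments:
            seen = set()
            cur = sid
            while cur != self.root_segment:
                if cur in seen or cur not in parent_of:
                    raise ValueError(f"segment graph is not a tree rooted at "
                                     f"{self.root_segment} (checking {sid})")
                seen.add(cur)
                cur = parent_of[cur]
        # topological order of joints (parents fitted before children)
        order: list[JointSpec] = []
        placed = {self.root_segment}
        pending = list(self.joints.values())
        while pending:
            progressed = False
            for j in list(pending):
                if j.parent in placed:
                    order.append(j)
                    placed.add(j.child)
                    pending.remove(j)
                    progressed = True
            if not progressed:  # pragma: no cover - caught by tree check above
                raise ValueError("joint graph has no topological order")
        self.topo_joints = tuple(order)

    # -- introspection -------------------------------------------------------

    @property
    def d(self) -> int:
        return len(self.dof_layout)

    @property
    def n_joints(self) -> int:
        return len(self.joints)

    @property
    def joint_blocks(self) -> list[np.ndarray]:
        """DOF-index partition by anatomical joint, in dof_layout order."""
        return [np.arange(sl.start, sl.stop) for sl in self.dof_slices.values()]

    def foot_markers(self, side: str) -> tuple[str, str]:
        """(heel label, toe/MTPJ label) for a side."""
        if side not in SIDES:
            raise ValueError(f"invalid side {side!r}")
        tm = self.task_markers[side]
        return tm["heel"], tm["toe"]

    @property
    def marker_labels(self) -> list[str]:
        return list(self.marker_segment)

    # -- construction --------------------------------------------------------

    @classmethod
    def from_config(cls, config: Mapping | str) -> "KinematicModel":
        """Build from a YAML path or an already-parsed mapping."""
        if not isinstance(config, Mapping):
            with open(config) as fh:
                config = yaml.safe_load(fh)
        segments = [
            SegmentSpec(
                id=s["id"],
                length=float(s["length"]),
                axis=s["axis"],
                mass_fraction=float(s["mass_fraction"]),
                com_offset=float(s["com_offset"]),
                markers=s.get("markers", {}),
            )
            for s in config["segments"]
        ]
        joints = [
            JointSpec(
                id=j["id"],
                parent=j["parent"],
                child=j["child"],
                offset=j["offset"],
                rotation_order=tuple(j["rotation_order"]),
            )
            for j in config["joints"]
        ]
        return cls(
            segments,
            joints,
            root_segment=config["root_segment"],
            task_markers=config["task_markers"],
            name=config.get("name", "model"),
        )

    @classmethod
    def default(cls) -> "KinematicModel":
        """The shipped 35-DOF / 15-joint whole-body gait model."""
        text = resources.files("gaitcov.configs").joinpath("pig35.yaml").read_text()
        return cls.from_config(yaml.safe_load(text))


@dataclass
class SegmentPoses:
    """Lab-frame rigid transforms per segment; supports batched leading axes.

    ``rot[seg]`` has shape (..., 3, 3) and ``trans[seg]`` shape (..., 3).
    """

    rot: dict[str, np.ndarray]
    trans: dict[str, np.ndarray]
    validate: bool = True  # False for poses composed from validated rotations

    def __post_init__(self):
        if not self.validate:
            return
        for sid, R in self.rot.items():
            RtR = np.swapaxes(R, -1, -2) @ R
            eye = np.broadcast_to(np.eye(3), RtR.shape)
            if not np.allclose(RtR, eye, atol=1e-9):
                raise ValueError(f"segment {sid}: rotation not orthonormal")
            if not np.allclose(np.linalg.det(R), 1.0, atol=1e-9):
                raise ValueError(f"segment {sid}: rotation determinant != +1")

    @property
    def segments(self) -> list[str]:
        return list(self.rot)

    def point(self, segment: str, local: np.ndarray) -> np.ndarray:
        """Map a local point on a segment to the lab frame."""
        R, t = self.rot[segment], self.trans[segment]
        return np.einsum("...ij,j->...i", R, np.asarray(local, float)) + t

    def marker_position(self, model: KinematicModel, label: str) -> np.ndarray:
        sid = model.marker_segment[label]
        return self.point(sid, model.segments[sid].markers[label])

    def translated(self, v: np.ndarray) -> "SegmentPoses":
        v = np.asarray(v, float)
        return SegmentPoses(
            dict(self.rot), {s: t + v for s, t in self.trans.items()}, validate=False
        )


def _joint_rotation(joint: JointSpec, angles: np.ndarray) -> np.ndarray:
    """Rotation matrices (..., 3, 3) for a joint's Cardan angles (..., n_dof)."""
    angles = np.asarray(angles, float)
    batch = angles.shape[:-1]
    flat = (angles * joint.signs).reshape(-1, joint.n_dof)
    mats = Rotation.from_euler(joint.seq, flat).as_matrix()
    return mats.reshape(*batch, 3, 3)


def forward_kinematics(
    model: KinematicModel,
    theta: np.ndarray,
    root_rot: np.ndarray | None = None,
    root_trans: np.ndarray | None = None,
) -> SegmentPoses:
    """Reconstruct all segment poses from joint angles.

    ``theta`` may be a single (d,) vector or a batch (..., d); poses then carry
    matching leading axes.  The root segment's pose defaults to the identity
    (it is external context, not part of the DOF vector).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape[-1] != model.d:
        raise ValueError(f"theta has {theta.shape[-1]} entries, model d = {model.d}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta contains non-finite angles")
    batch = theta.shape[:-1]

    if root_rot is None:
        root_rot = np.broadcast_to(np.eye(3), (*batch, 3, 3))
    else:
        root_rot = np.broadcast_to(np.asarray(root_rot, float), (*batch, 3, 3))
    if root_trans is None:
        root_trans = np.broadcast_to(np.zeros(3), (*batch, 3))
    else:
        root_trans = np.broadcast_to(np.asarray(root_trans, float), (*batch, 3))

    rot = {model.root_segment: np.array(root_rot, copy=True)}
    trans = {model.root_segment: np.array(root_trans, copy=True)}
    for joint in model.topo_joints:
        Rp, tp = rot[joint.parent], trans[joint.parent]
        Rj = _joint_rotation(joint, theta[..., model.dof_slices[joint.id]])
        rot[joint.child] = Rp @ Rj
        trans[joint.child] = tp + np.einsum("...ij,j->...i", Rp, joint.offset)
    # rotations are products of unit quaternion matrices: orthonormal by
    # construction, so skip the validation pass
    return SegmentPoses(rot, trans, validate=False)


def compute_com(model: KinematicModel, poses: SegmentPoses) -> np.ndarray:
    """Whole-body CoM: mass-fraction-weighted sum of segment CoM points."""
    missing = [s for s in model.segments if s not in poses.rot]
    if missing:
        raise ValueError(f"poses missing segments: {missing}")
    com = None
    for seg in model.segments.values():
        pt = poses.point(seg.id, seg.com_local) * seg.mass_fraction
        com = pt if com is None else com + pt
    return com


def task_variables_from_points(
    back_toe: np.ndarray, front_heel: np.ndarray, com: np.ndarray, front_side: str
) -> np.ndarray:
    """Six task variables from horizontal-plane projections of the three points.

    Returns an array (..., 6) ordered as TASK_VARIABLES.  The lateral sign
    convention points from the back-foot side toward the front-foot side
    (+Y is left in the lab frame, so the axis flips when the right foot leads).
    """
    if front_side not in SIDES:
        raise ValueError(f"invalid front_side {front_side!r}")
    ysign = 1.0 if front_side == "left" else -1.0
    bx = com[..., 0] - back_toe[..., 0]
    fx = front_heel[..., 0] - com[..., 0]
    by = ysign * (com[..., 1] - back_toe[..., 1])
    fy = ysign * (front_heel[..., 1] - com[..., 1])
    # step defined as b + f so the additivity identity is exact by construction
    return np.stack([bx + fx, by + fy, bx, by, fx, fy], axis=-1)


def task_variables_from_poses(
    model: KinematicModel, poses: SegmentPoses, front_side: str
) -> np.ndarray:
    if front_side not in SIDES:
        raise ValueError(f"invalid front_side {front_side!r}")
    back_side = "right" if front_side == "left" else "left"
    _, toe_label = model.foot_markers(back_side)
    heel_label, _ = model.foot_markers(front_side)
    back_toe = poses.marker_position(model, toe_label)
    front_heel = poses.marker_position(model, heel_label)
    com = compute_com(model, poses)
    return task_variables_from_points(back_toe, front_heel, com, front_side)


def compute_task_variables(
    model: KinematicModel,
    theta: np.ndarray,
    front_side: str,
    root_rot: np.ndarray | None = None,
    root_trans: np.ndarray | None = None,
) -> np.ndarray:
    """Forward map theta -> (stepX, stepY, bCoMX, bCoMY, fCoMX, fCoMY), (..., 6)."""
    poses = forward_kinematics(model, theta, root_rot=root_rot, root_trans=root_trans)
    return task_variables_from_poses(model, poses, front_side)


@dataclass(frozen=True)
class TaskDefinition:
    """One task variable (by name) with the side of the leading foot."""

    name: str
    front_side: str

    def __post_init__(self):
        if self.name not in TASK_VARIABLES:
            raise ValueError(f"unknown task variable {self.name!r}")
        if self.front_side not in SIDES:
            raise ValueError(f"invalid front_side {self.front_side!r}")

    @property
    def index(self) -> int:
        return TASK_VARIABLES.index(self.name)


@dataclass(frozen=True)
class JacobianRow:
    task: TaskDefinition
    theta_bar: np.ndarray
    gradient: np.ndarray
    step_size: float


def task_jacobian(
    model: KinematicModel,
    theta_bar: np.ndarray,
    front_side: str,
    step_size: float = 1e-4,
    root_rot: np.ndarray | None = None,
) -> np.ndarray:
    """Jacobian (6, d) of all task variables by central finite differences.

    One batched forward-kinematics evaluation over the 2d perturbed postures;
    entries in m/rad.
    """
    if step_size <= 0:
        raise ValueError("step_size must be > 0")
    theta_bar = np.asarray(theta_bar, dtype=float)
    if theta_bar.shape != (model.d,):
        raise ValueError(f"theta_bar must have shape ({model.d},)")
    d = model.d
    pts = np.tile(theta_bar, (2 * d, 1))
    idx = np.arange(d)
    pts[idx, idx] += step_size
    pts[d + idx, idx] -= step_size
    vals = compute_task_variables(model, pts, front_side, root_rot=root_rot)
    return (vals[:d] - vals[d:]).T / (2.0 * step_size)


def numerical_jacobian(
    model: KinematicModel,
    theta_bar: np.ndarray,
    task: TaskDefinition,
    step_size: float = 1e-4,
) -> JacobianRow:
    """Gradient of a single task variable at theta_bar."""
    J = task_jacobian(model, theta_bar, task.front_side, step_size=step_size)
    return JacobianRow(
        task=task,
        theta_bar=np.asarray(theta_bar, float).copy(),
        gradient=J[task.index],
        step_size=step_size,
    )


# -- marker-based inverse ----------------------------------------------------


@dataclass
class SegmentFit:
    rotation: np.ndarray
    translation: np.ndarray
    residual_rms: float
    n_markers: int


@dataclass
class PoseFitResult:
    """Per-segment rigid registrations for one frame.

    ``unfittable`` lists segments with fewer than three valid, non-collinear
    markers; a frame with any unfittable segment is incomplete and must be
    excluded downstream.
    """

    poses: SegmentPoses
    fits: dict[str, SegmentFit]
    unfittable: list[str]

    @property
    def complete(self) -> bool:
        return not self.unfittable


def rigid_register(local: np.ndarray, world: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform local -> world (Kabsch, via SVD).

    Returns (R, t, residual RMS).  Raises ValueError on < 3 points or a
    collinear configuration (second singular value of the centred local
    cloud below 1e-9 of the first).
    """
    local = np.asarray(local, float)
    world = np.asarray(world, float)
    if local.shape != world.shape or local.ndim != 2 or local.shape[1] != 3:
        raise ValueError("local and world must both have shape (n, 3)")
    n = local.shape[0]
    if n < 3:
        raise ValueError("need at least 3 markers for pose fitting")
    lc = local - local.mean(axis=0)
    wc = world - world.mean(axis=0)
    sv = np.linalg.svd(lc, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        raise ValueError("marker configuration is collinear")
    H = lc.T @ wc
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = world.mean(axis=0) - R @ local.mean(axis=0)
    resid = world - (local @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return R, t, rms


def fit_segment_poses(
    markers: Mapping[str, np.ndarray], model: KinematicModel
) -> PoseFitResult:
    """Fit every segment's pose to measured markers at one frame.

    ``markers`` maps label -> lab-frame 3D point (m); missing markers may be
    absent from the mapping or contain NaNs.
    """
    rot: dict[str, np.ndarray] = {}
    trans: dict[str, np.ndarray] = {}
    fits: dict[str, SegmentFit] = {}
    unfittable: list[str] = []
    for seg in model.segments.values():
        local, world = [], []
        for label, lpos in seg.markers.items():
            w = markers.get(label)
            if w is None:
                continue
            w = np.asarray(w, float)
            if not np.all(np.isfinite(w)):
                continue
            local.append(lpos)
            world.append(w)
        try:
            R, t, rms = rigid_register(np.array(local).reshape(-1, 3),
                                       np.array(world).reshape(-1, 3))
        except ValueError:
            unfittable.append(seg.id)
            continue
        rot[seg.id] = R
        trans[seg.id] = t
        fits[seg.id] = SegmentFit(R, t, rms, len(local))
    return PoseFitResult(SegmentPoses(rot, trans), fits, unfittable)


GIMBAL_TOL = 1e-6


@dataclass
class AngleExtractionReport:
    gimbal_joints: list[str] = field(default_factory=list)
    locked_axis_residuals: dict[str, float] = field(default_factory=dict)


def extract_joint_angles(
    poses: SegmentPoses,
    model: KinematicModel,
    return_report: bool = False,
):
    """Joint angles from relative segment rotations.

    Each joint's relative rotation (parent^T child) is decomposed by its
    Cardan sequence; angles lie in (-pi, pi].  Joints with fewer than three
    DOF are decomposed over the sequence padded with the remaining axes and
    the locked-axis components are dropped (their magnitude is reported).
    Gimbal-lock configurations (middle angle within 1e-6 of +-pi/2) are
    flagged; the indeterminate rotation is absorbed by the first Cardan axis.
    """
    theta = np.empty(model.d)
    report = AngleExtractionReport()
    for joint in model.topo_joints:
        if joint.parent not in poses.rot or joint.child not in poses.rot:
            raise ValueError(f"poses missing parent/child of joint {joint.id}")
        R_rel = poses.rot[joint.parent].T @ poses.rot[joint.child]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns at gimbal lock
            angles = Rotation.from_matrix(R_rel).as_euler(joint.extended_seq)
        if abs(abs(angles[1]) - np.pi / 2) < GIMBAL_TOL:
            report.gimbal_joints.append(joint.id)
        free = angles[: joint.n_dof] * joint.signs
        locked = angles[joint.n_dof :]
        if locked.size:
            report.locked_axis_residuals[joint.id] = float(np.max(np.abs(locked)))
        theta[model.dof_slices[joint.id]] = free
    if return_report:
        return theta, report
    return theta


def model_error(measured: np.ndarray, fitted: np.ndarray) -> np.ndarray:
    """Absolute per-variable deviation |measured - fitted| between the task
    variables computed from fitted segment poses and from the joint-angle
    reconstruction, both for the same frame(s)."""
    measured = np.asarray(measured, float)
    fitted = np.asarray(fitted, float)
    if measured.shape != fitted.shape:
        raise ValueError("measured and fitted task vectors differ in shape")
    return np.abs(measured - fitted)
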