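"""Linearized covariation-by-randomization analysis.

Step-to-step fluctuations of the joint-angle vector are summarized by their
sample covariance C.  Removing pairwise correlations between angles of
*different* joints (zeroing the corresponding entries of C) yields the
decorrelated covariance C0; propagating both through the linearized forward
model (Jacobian row J of one task variable, evaluated at the mean posture)
gives the empirical and decorrelated task variances

    TV  = J C  J',      TV0 = J C0 J'

and the covariation index COV = TV0 / TV.  COV > 1 (log COV > 0) means the
cross-joint covariation reduces task variability relative to what the same
per-joint variability would produce without coordination — motor-equivalent
stabilization of that task variable.

A non-linearized permutation oracle is included: it destroys cross-joint
correlations by independently permuting each joint's angle block across
steps and re-propagates each surrogate posture through the full nonlinear
forward model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import (
    KinematicModel,
    TaskDefinition,
    compute_task_variables,
    task_jacobian,
)
from .preprocessing import StepPostureEnsemble

TV_FLOOR = 1e-16  # m^2; below this the ratio TV0/TV is numerically undefined


def _check_partition(joint_blocks: Sequence[np.ndarray], d: int) -> list[np.ndarray]:
    blocks = [np.asarray(b, dtype=int) for b in joint_blocks]
    flat = np.concatenate(blocks) if blocks else np.array([], dtype=int)
    if len(flat) != d or len(np.unique(flat)) != d or flat.min(initial=0) < 0 or (
        len(flat) and flat.max() >= d
    ):
        raise ValueError("joint_blocks must partition the DOF indices 0..d-1")
    return blocks


def sample_covariance(angles: np.ndarray) -> np.ndarray:
    """Unbiased (n-1 divisor) sample covariance of step-posture rows."""
    X = np.asarray(angles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (n >= 2, d) matrix of step postures")
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    return 0.5 * (C + C.T)


def block_mask(joint_blocks: Sequence[np.ndarray], d: int) -> np.ndarray:
    """Boolean (d, d) mask, True where row and column DOF share a joint."""
    blocks = _check_partition(joint_blocks, d)
    owner = np.empty(d, dtype=int)
    for k, b in enumerate(blocks):
        owner[b] = k
    return owner[:, None] == owner[None, :]


def decorrelate(C: np.ndarray, joint_blocks: Sequence[np.ndarray]) -> np.ndarray:
    """Zero all covariance entries between angles of different joints.

    Within-joint covariances (and hence every DOF's variance) are preserved.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    mask = block_mask(joint_blocks, C.shape[0])
    return np.where(mask, C, 0.0)


def linearized_task_variance(j_row: np.ndarray, C: np.ndarray) -> float:
    """Quadratic form J C J' (m^2)."""
    j = np.asarray(j_row, dtype=float).ravel()
    C = np.asarray(C, dtype=float)
    if C.shape != (j.size, j.size):
        raise ValueError(f"dimension mismatch: J has {j.size} entries, C is {C.shape}")
    return float(j @ C @ j)


@dataclass
class CovarianceDecomposition:
    C: np.ndarray
    C0: np.ndarray
    joint_blocks: list[np.ndarray]


def decompose_covariance(
    angles: np.ndarray, joint_blocks: Sequence[np.ndarray]
) -> CovarianceDecomposition:
    C = sample_covariance(angles)
    C0 = decorrelate(C, joint_blocks)
    return CovarianceDecomposition(C, C0, list(joint_blocks))


@dataclass
class CovariationResult:
    task: TaskDefinition
    tv: float
    tv0: float
    cov: float
    log_cov: float
    n: int
    front_side: str
    flagged: bool = False
    meta: dict | None = None

    @property
    def stabilized(self) -> bool:
        return self.cov > 1.0


def covariation_from_cov(
    C: np.ndarray, j_row: np.ndarray, joint_blocks: Sequence[np.ndarray]
) -> tuple[float, float, float]:
    """(TV, TV0, COV) for a given covariance matrix and Jacobian row."""
    C0 = decorrelate(C, joint_blocks)
    tv = linearized_task_variance(j_row, C)
    tv0 = linearized_task_variance(j_row, C0)
    cov = tv0 / tv if tv > TV_FLOOR else np.nan
    return tv, tv0, cov


def covariation_index(
    ensemble: StepPostureEnsemble,
    model: KinematicModel,
    task: TaskDefinition,
    step_size: float = 1e-4,
    jacobian: np.ndarray | None = None,
) -> CovariationResult:
    """Covariation index of one task variable for one step-posture ensemble.

    The Jacobian is evaluated at the ensemble mean posture (pass a
    precomputed (6, d) ``jacobian`` to share it across the six variables).
    A TV below 1e-16 m^2 yields a flagged result with COV = NaN instead of an
    infinite log index.
    """
    if task.front_side != ensemble.front_side:
        raise ValueError("task front_side does not match the ensemble side")
    C = sample_covariance(ensemble.angles)
    if jacobian is None:
        jacobian = task_jacobian(
            model, ensemble.mean_posture, ensemble.front_side,
            step_size=step_size, root_rot=ensemble.root_rot,
        )
    j_row = jacobian[task.index]
    tv, tv0, cov = covariation_from_cov(C, j_row, model.joint_blocks)
    flagged = not np.isfinite(cov) or cov <= 0
    return CovariationResult(
        task=task,
        tv=tv,
        tv0=tv0,
        cov=cov,
        log_cov=float(np.log(cov)) if not flagged else np.nan,
        n=ensemble.n,
        front_side=ensemble.front_side,
        flagged=flagged,
        meta=dict(ensemble.meta),
    )


def covariation_indices(
    ensemble: StepPostureEnsemble,
    model: KinematicModel,
    step_size: float = 1e-4,
) -> dict[str, CovariationResult]:
    """All six task variables for one ensemble, sharing one Jacobian."""
    from .model import TASK_VARIABLES

    J = task_jacobian(
        model, ensemble.mean_posture, ensemble.front_side,
        step_size=step_size, root_rot=ensemble.root_rot,
    )
    return {
        name: covariation_index(
            ensemble, model, TaskDefinition(name, ensemble.front_side), jacobian=J
        )
        for name in TASK_VARIABLES
    }


# -- nonlinear permutation oracle --------------------------------------------


@dataclass
class RandomizationResult:
    tv: float
    tv0_perm: float
    cov: float
    log_cov: float
    se_cov: float
    n_perm: int


def permute_within_blocks(
    X: np.ndarray,
    joint_blocks: Sequence[np.ndarray],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Surrogate ensembles destroying cross-joint step-to-step correlations.

    For each permutation, every joint block's rows are independently shuffled
    (whole blocks move together, preserving within-joint structure).  Returns
    an array (n_perm, n, d).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    blocks = _check_partition(joint_blocks, d)
    out = np.empty((n_perm, n, d))
    for p in range(n_perm):
        for b in blocks:
            out[p][:, b] = X[rng.permutation(n)][:, b]
    return out


def randomization_oracle_values(
    X: np.ndarray,
    joint_blocks: Sequence[np.ndarray],
    task_fn: Callable[[np.ndarray], np.ndarray],
    n_perm: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core of the permutation oracle for an arbitrary forward map.

    ``task_fn`` maps posture rows (m, d) -> task values (m,) or (m, k).
    Returns (tv, tv0_perm, se_tv0) each of shape (k,).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if n < 3:
        raise ValueError("need at least 3 postures for the permutation oracle")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 (Monte-Carlo SE unusable below)")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    vals = np.atleast_2d(task_fn(X).T).T  # (n, k)
    tv = vals.var(axis=0, ddof=1)
    surr = permute_within_blocks(X, joint_blocks, n_perm, rng)
    surr_vals = np.atleast_2d(task_fn(surr.reshape(n_perm * n, d)).T).T
    per_perm = surr_vals.reshape(n_perm, n, -1).var(axis=1, ddof=1)  # (n_perm, k)
    tv0 = per_perm.mean(axis=0)
    se = per_perm.std(axis=0, ddof=1) / np.sqrt(n_perm)
    return tv, tv0, se


def randomization_oracle(
    ensemble: StepPostureEnsemble,
    model: KinematicModel,
    task: TaskDefinition,
    n_perm: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """COV estimate by block permutation through the full nonlinear model."""
    if task.front_side != ensemble.front_side:
        raise ValueError("task front_side does not match the ensemble side")

    def task_fn(rows: np.ndarray) -> np.ndarray:
        vals = compute_task_variables(
            model, rows, ensemble.front_side, root_rot=ensemble.root_rot
        )
        return vals[:, task.index]

    tv, tv0, se = randomization_oracle_values(
        ensemble.angles, model.joint_blocks, task_fn, n_perm, seed
    )
    tv, tv0, se = float(tv[0]), float(tv0[0]), float(se[0])
    cov = tv0 / tv if tv > TV_FLOOR else np.nan
    return RandomizationResult(
        tv=tv,
        tv0_perm=tv0,
        cov=cov,
        log_cov=float(np.log(cov)) if np.isfinite(cov) and cov > 0 else np.nan,
        se_cov=se / tv if tv > TV_FLOOR else np.nan,
        n_perm=n_perm,
    )


def randomization_oracle_all(
    ensemble: StepPostureEnsemble,
    model: KinematicModel,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, RandomizationResult]:
    """Permutation oracle for all six task variables from one surrogate set."""
    from .model import TASK_VARIABLES

    def task_fn(rows: np.ndarray) -> np.ndarray:
        return compute_task_variables(
            model, rows, ensemble.front_side, root_rot=ensemble.root_rot
        )

    tv, tv0, se = randomization_oracle_values(
        ensemble.angles, model.joint_blocks, task_fn, n_perm, seed
    )
    out = {}
    for i, name in enumerate(TASK_VARIABLES):
        cov = tv0[i] / tv[i] if tv[i] > TV_FLOOR else np.nan
        out[name] = RandomizationResult(
            tv=float(tv[i]),
            tv0_perm=float(tv0[i]),
            cov=float(cov),
            log_cov=float(np.log(cov)) if np.isfinite(cov) and cov > 0 else np.nan,
            se_cov=float(se[i] / tv[i]) if tv[i] > TV_FLOOR else np.nan,
            n_perm=n_perm,
        )
    return out
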