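"""End-to-end orchestration: trials -> step postures -> covariation and
step-CoM tables -> participant summaries -> group statistics."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariation import covariation_indices
from .io import RosterEntry, RunConfig, read_ensemble, read_trajectories
from .model import (
    SIDES,
    TASK_VARIABLES,
    KinematicModel,
    compute_task_variables,
    extract_joint_angles,
    fit_segment_poses,
    model_error,
    task_variables_from_poses,
)
from .preprocessing import (
    GaitEvents,
    StepPosture,
    StepPostureEnsemble,
    TrajectorySet,
    detect_heel_strikes,
    extract_step_postures,
    lowpass_filter,
)
from .step_com import step_com_correlation
from .stats_report import aggregate, holm, one_sample_t, welch_t

logger = logging.getLogger(__name__)


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


@dataclass
class TrialResult:
    ensembles: dict[str, StepPostureEnsemble | None]
    ensemble_errors: dict[str, str]
    model_error_mean: dict[str, float]  # per task variable, metres
    model_error_sd: dict[str, float]
    n_events: int
    n_complete: int


def process_trial(
    traj: TrajectorySet,
    model: KinematicModel,
    filter_cutoff_hz: float | None = 10.0,
    filter_order: int = 3,
    max_postures: int = 20,
    events: GaitEvents | None = None,
    meta: dict | None = None,
) -> TrialResult:
    """Run the kinematic pipeline on one trial's marker trajectories.

    Markers are low-pass filtered (unless ``filter_cutoff_hz`` is None), heel
    strikes detected per side (unless ground-truth ``events`` are supplied),
    segment poses fitted and joint angles extracted at each strike frame, and
    per-side ensembles assembled under the completeness / last-``max_postures``
    rule.  Model errors (|measured - fitted| task variables) are accumulated
    over all complete strike frames.
    """
    if filter_cutoff_hz is not None:
        traj = lowpass_filter(traj, filter_cutoff_hz, filter_order)
    if events is None:
        per_side = []
        for side in SIDES:
            try:
                per_side.append(detect_heel_strikes(traj, side))
            except ValueError as exc:
                logger.warning("heel-strike detection failed on %s: %s", side, exc)
        if not per_side:
            raise ValueError("heel-strike detection failed on both sides")
        events = GaitEvents.merge(*per_side)

    required = model.marker_labels
    postures: list[StepPosture] = []
    errors: list[np.ndarray] = []
    pelvis_rots: dict[str, list[np.ndarray]] = {s: [] for s in SIDES}
    for frame, side in events.events:
        if not 0 <= frame < traj.n_frames:
            raise ValueError(f"event frame {frame} outside trial")
        markers = traj.frame_markers(frame)
        complete = all(lab in markers for lab in required)
        theta = np.full(model.d, np.nan)
        if complete:
            fit = fit_segment_poses(markers, model)
            complete = fit.complete
            if complete:
                theta = extract_joint_angles(fit.poses, model)
                root_R = fit.poses.rot[model.root_segment]
                root_t = fit.poses.trans[model.root_segment]
                measured = task_variables_from_poses(model, fit.poses, side)
                fitted = compute_task_variables(
                    model, theta, side, root_rot=root_R, root_trans=root_t
                )
                errors.append(model_error(measured, fitted))
                pelvis_rots[side].append(root_R)
        back_side = "right" if side == "left" else "left"
        _, toe = model.foot_markers(back_side)
        postures.append(
            StepPosture(
                theta=theta,
                front_side=side,
                frame=frame,
                complete=bool(complete),
                back_mtp=markers.get(toe),
            )
        )

    ensembles: dict[str, StepPostureEnsemble | None] = {}
    ens_errors: dict[str, str] = {}
    for side in SIDES:
        root_rot = None
        if pelvis_rots[side]:
            root_rot = _orthonormalize(np.mean(pelvis_rots[side], axis=0))
        try:
            ensembles[side] = extract_step_postures(
                postures, side, max_postures=max_postures, meta=meta, root_rot=root_rot
            )
        except ValueError as exc:
            ensembles[side] = None
            ens_errors[side] = str(exc)

    err = np.array(errors) if errors else np.empty((0, 6))
    return TrialResult(
        ensembles=ensembles,
        ensemble_errors=ens_errors,
        model_error_mean={
            v: float(err[:, i].mean()) if len(err) else np.nan
            for i, v in enumerate(TASK_VARIABLES)
        },
        model_error_sd={
            v: float(err[:, i].std(ddof=1)) if len(err) > 1 else np.nan
            for i, v in enumerate(TASK_VARIABLES)
        },
        n_events=len(events),
        n_complete=sum(p.complete for p in postures),
    )


def ensemble_tables(
    ens: StepPostureEnsemble, model: KinematicModel
) -> tuple[list[dict], list[dict]]:
    """Covariation rows (6 variables) and step-CoM rows (2 directions)."""
    meta = {
        "participant": ens.meta.get("participant", "p"),
        "group": ens.meta.get("group", "all"),
        "speed": ens.meta.get("speed", 1.0),
        "trial": ens.meta.get("trial", 1),
        "side": ens.front_side,
    }
    cov_rows = []
    for name, res in covariation_indices(ens, model).items():
        cov_rows.append(
            {**meta, "variable": name, "value": res.log_cov, "cov": res.cov,
             "tv": res.tv, "tv0": res.tv0, "n": res.n, "flagged": res.flagged}
        )
    vals = compute_task_variables(
        model, ens.angles, ens.front_side, root_rot=ens.root_rot
    )
    sc_rows = []
    for direction in ("X", "Y"):
        b = vals[:, TASK_VARIABLES.index("bCoM" + direction)]
        f = vals[:, TASK_VARIABLES.index("fCoM" + direction)]
        s = vals[:, TASK_VARIABLES.index("step" + direction)]
        res = step_com_correlation(b, f, direction, ens.front_side, step=s)
        sc_rows.append(
            {**meta, "variable": "z" + direction, "value": res.z, "r": res.r,
             "n": res.n, "flagged": res.flagged}
        )
    return cov_rows, sc_rows


@dataclass
class PipelineResult:
    covariation: pd.DataFrame
    step_com: pd.DataFrame
    summary: pd.DataFrame
    trial_log: pd.DataFrame
    failures: list[dict] = field(default_factory=list)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis over a roster of trials/ensembles.

    Per-trial failures are recorded and the run continues; the result is
    deterministic given the configuration and seed.  Output tables (and a
    JSON manifest echoing the configuration) are written to ``out_dir`` when
    set.
    """
    model = (
        KinematicModel.default()
        if config.model_config == "default"
        else KinematicModel.from_config(config.model_config)
    )
    cov_rows: list[dict] = []
    sc_rows: list[dict] = []
    trial_log: list[dict] = []
    failures: list[dict] = []

    for entry in config.roster:
        try:
            for ens, extra in _entry_ensembles(entry, model, config):
                c, s = ensemble_tables(ens, model)
                cov_rows.extend(c)
                sc_rows.extend(s)
                if extra:
                    trial_log.append(extra)
        except Exception as exc:  # noqa: BLE001 - per-trial isolation
            logger.error("roster entry %s failed: %s", entry.path, exc)
            failures.append({"path": str(entry.path), "error": str(exc)})

    if not cov_rows:
        raise RuntimeError("all roster entries failed; nothing to report")
    covariation = pd.DataFrame(cov_rows)
    step_com = pd.DataFrame(sc_rows)
    long = pd.concat(
        [
            covariation[~covariation["flagged"]],
            step_com[~step_com["flagged"]],
        ],
        ignore_index=True,
    )[["participant", "group", "speed", "trial", "side", "variable", "value"]]
    summary = aggregate(long)
    # carry group labels onto the summary
    groups = long[["participant", "group"]].drop_duplicates()
    summary = summary.drop(columns=["group"]).merge(groups, on="participant")
    log_df = pd.DataFrame(trial_log)

    result = PipelineResult(covariation, step_com, summary, log_df, failures)
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def _entry_ensembles(entry: RosterEntry, model: KinematicModel, config: RunConfig):
    meta = {
        "participant": entry.participant,
        "group": entry.group,
        "speed": entry.speed,
        "trial": entry.trial,
    }
    if entry.kind == "ensemble":
        ens = read_ensemble(entry.path)
        ens.meta = {**ens.meta, **meta}
        yield ens, None
    elif entry.kind == "trajectory":
        traj = read_trajectories(entry.path)
        res = process_trial(
            traj,
            model,
            filter_cutoff_hz=config.filter_cutoff_hz,
            filter_order=config.filter_order,
            max_postures=config.max_postures,
            meta=meta,
        )
        log = {
            "path": str(entry.path), **meta,
            "n_events": res.n_events, "n_complete": res.n_complete,
            **{f"err_{v}_mean_m": res.model_error_mean[v] for v in TASK_VARIABLES},
            **{f"err_{v}_sd_m": res.model_error_sd[v] for v in TASK_VARIABLES},
        }
        if all(res.ensembles[s] is None for s in SIDES):
            raise ValueError(f"no usable ensembles: {res.ensemble_errors}")
        for side in SIDES:
            if res.ensembles[side] is not None:
                yield res.ensembles[side], log
                log = None  # one log row per trial
    else:
        raise ValueError(f"unknown roster kind {entry.kind!r}")


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.covariation.to_csv(out / "covariation.csv", index=False)
    result.step_com.to_csv(out / "step_com.csv", index=False)
    result.summary.to_csv(out / "participant_summary.csv", index=False)
    if len(result.trial_log):
        result.trial_log.to_csv(out / "trial_log.csv", index=False)
    manifest = {
        "gaitcov_version": __version__,
        "seed": config.seed,
        "n_roster": len(config.roster),
        "n_failures": len(result.failures),
        "failures": result.failures,
        "config": {
            k: v for k, v in config.raw.items() if k != "roster"
        } or {
            "model_config": config.model_config,
            "filter_cutoff_hz": config.filter_cutoff_hz,
            "max_postures": config.max_postures,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def group_statistics(summary: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """The report's inferential statistics from a participant summary table.

    One-sample t-tests per (group, variable) check stabilization (mean
    transformed index > 0); Welch t-tests compare groups per variable on
    participant-level means (averaged across speeds).  Holm correction is
    applied within each test family.
    """
    part = (
        summary.groupby(["participant", "group", "variable"])["value"]
        .mean()
        .reset_index()
    )
    rows = []
    for (group, var), sub in part.groupby(["group", "variable"]):
        res = one_sample_t(sub["value"].to_numpy(), 0.0, name=f"{group}:{var}>0")
        rows.append(
            {"family": "one_sample", "group": group, "variable": var,
             "t": res.t, "df": res.df, "p": res.p, "effect_size": res.effect_size}
        )
    groups = sorted(part["group"].unique())
    if len(groups) == 2:
        a_name, b_name = groups
        for var, sub in part.groupby("variable"):
            a = sub.loc[sub["group"] == a_name, "value"].to_numpy()
            b = sub.loc[sub["group"] == b_name, "value"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            res = welch_t(a, b, name=f"{a_name}-vs-{b_name}:{var}")
            rows.append(
                {"family": "welch", "group": f"{a_name}-{b_name}", "variable": var,
                 "t": res.t, "df": res.df, "p": res.p,
                 "effect_size": res.effect_size}
            )
    df = pd.DataFrame(rows)
    df["p_holm"] = np.nan
    df["reject"] = False
    for fam, sub in df.groupby("family"):
        p_adj, rej = holm(sub["p"].to_numpy(), alpha=alpha)
        df.loc[sub.index, "p_holm"] = p_adj
        df.loc[sub.index, "reject"] = rej
    return df
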