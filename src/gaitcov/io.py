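"""File formats: labeled wide-CSV marker trajectories, step-posture ensemble
CSVs, and YAML run configurations.

Trajectory dialect (one row per frame, units declared in the header)::

    # gaitcov-trajectory v1
    # rate_hz: 200
    # units: m
    frame,LHEE_X,LHEE_Y,LHEE_Z,...

Gaps are NaN cells; they mark the marker invalid at that frame only.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import StepPostureEnsemble, TrajectorySet

_AXES = ("X", "Y", "Z")


def _read_header_comments(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_trajectories(path: str | Path) -> TrajectorySet:
    """Read a labeled wide-CSV trajectory file into a TrajectorySet (metres)."""
    path = Path(path)
    if path.suffix.lower() == ".c3d":
        raise ValueError(
            "C3D input is not supported in this build; export the trial to the "
            "labeled wide-CSV dialect (see gaitcov.io docstring)"
        )
    if path.suffix.lower() != ".csv":
        raise ValueError(f"unknown trajectory format {path.suffix!r}")
    meta = _read_header_comments(path)
    if "rate_hz" not in meta:
        raise ValueError(f"{path}: missing '# rate_hz:' header")
    rate = float(meta["rate_hz"])
    units = meta.get("units", "m").lower()
    if units not in ("m", "mm"):
        raise ValueError(f"{path}: units must be 'm' or 'mm', got {units!r}")
    scale = 1.0 if units == "m" else 1e-3

    # detect duplicate columns before pandas mangles them
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = [c.strip() for c in line.split(",")]
                break
        else:
            raise ValueError(f"{path}: no data header found")
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate column labels")

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    labels: dict[str, dict[str, str]] = {}
    for col in df.columns:
        if col == "frame":
            continue
        if "_" not in col or col.rsplit("_", 1)[1] not in _AXES:
            raise ValueError(f"{path}: column {col!r} is not marker_AXIS")
        label, axis = col.rsplit("_", 1)
        labels.setdefault(label, {})[axis] = col
    data = {}
    for label, axes in labels.items():
        if set(axes) != set(_AXES):
            raise ValueError(f"{path}: marker {label} missing axes")
        data[label] = df[[axes[a] for a in _AXES]].to_numpy(dtype=float) * scale
    return TrajectorySet(data, rate)


def write_trajectories(traj: TrajectorySet, path: str | Path) -> None:
    path = Path(path)
    cols = {"frame": np.arange(traj.n_frames)}
    for label, arr in traj.data.items():
        arr = arr.copy()
        arr[~traj.valid[label]] = np.nan
        for i, axis in enumerate(_AXES):
            cols[f"{label}_{axis}"] = arr[:, i]
    buf = _io.StringIO()
    buf.write("# gaitcov-trajectory v1\n")
    buf.write(f"# rate_hz: {traj.rate_hz:g}\n")
    buf.write("# units: m\n")
    pd.DataFrame(cols).to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue())


def write_ensemble(ens: StepPostureEnsemble, path: str | Path) -> None:
    """Step-posture ensemble as CSV with metadata in header comments."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write("# gaitcov-ensemble v1\n")
    buf.write(f"# front_side: {ens.front_side}\n")
    buf.write(f"# meta: {json.dumps(ens.meta, default=str)}\n")
    d = ens.d
    cols = {"frame": ens.frames}
    for k in range(d):
        cols[f"dof{k:02d}"] = ens.angles[:, k]
    pd.DataFrame(cols).to_csv(buf, index=False, lineterminator="\n", float_format="%.17g")
    path.write_text(buf.getvalue())


def read_ensemble(path: str | Path) -> StepPostureEnsemble:
    path = Path(path)
    meta = _read_header_comments(path)
    if "front_side" not in meta:
        raise ValueError(f"{path}: missing '# front_side:' header")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    dof_cols = [c for c in df.columns if c.startswith("dof")]
    return StepPostureEnsemble(
        angles=df[dof_cols].to_numpy(dtype=float),
        front_side=meta["front_side"],
        frames=[int(f) for f in df["frame"]],
        meta=json.loads(meta.get("meta", "{}")),
    )


@dataclass
class RosterEntry:
    kind: str  # 'trajectory' | 'ensemble'
    path: Path
    participant: str
    group: str
    speed: object
    trial: int
    side: str | None = None  # for ensembles; trajectories yield both sides


@dataclass
class RunConfig:
    """Validated analysis-run configuration.

    Settings are echoed verbatim into the output manifest; every referenced
    file must exist at validation time.
    """

    roster: list[RosterEntry]
    model_config: str = "default"
    filter_cutoff_hz: float | None = 10.0
    filter_order: int = 3
    max_postures: int = 20
    n_perm: int = 0
    seed: int = 0
    out_dir: Path | None = None
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        cfg = yaml.safe_load(path.read_text())
        base = path.parent
        entries = []
        for row in cfg.get("roster", []):
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"roster file does not exist: {p}")
            entries.append(
                RosterEntry(
                    kind=row.get("kind", "trajectory"),
                    path=p,
                    participant=str(row["participant"]),
                    group=str(row.get("group", "all")),
                    speed=row.get("speed", 1.0),
                    trial=int(row.get("trial", 1)),
                    side=row.get("side"),
                )
            )
        if not entries:
            raise ValueError(f"{path}: empty roster")
        model_config = cfg.get("model_config", "default")
        if model_config != "default":
            mc = Path(model_config)
            if not mc.is_absolute():
                mc = base / mc
            if not mc.exists():
                raise FileNotFoundError(f"model config does not exist: {mc}")
            model_config = str(mc)
        filt = cfg.get("filter", {}) or {}
        out_dir = cfg.get("out_dir")
        return cls(
            roster=entries,
            model_config=model_config,
            filter_cutoff_hz=filt.get("cutoff_hz", 10.0),
            filter_order=int(filt.get("order", 3)),
            max_postures=int(cfg.get("max_postures", 20)),
            n_perm=int(cfg.get("n_perm", 0)),
            seed=int(cfg.get("seed", 0)),
            out_dir=Path(out_dir) if out_dir else None,
            raw=cfg,
        )


def study_roster_config(study_dir: str | Path) -> list[RosterEntry]:
    """Roster entries for a study directory written by generate_study."""
    study_dir = Path(study_dir)
    manifest = json.loads((study_dir / "manifest.json").read_text())
    entries = []
    for row in manifest["ensembles"]:
        entries.append(
            RosterEntry(
                kind="ensemble",
                path=study_dir / row["path"],
                participant=row["participant"],
                group=row.get("group", "all"),
                speed=row["speed"],
                trial=int(row["trial"]),
                side=row["side"],
            )
        )
    return entries
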