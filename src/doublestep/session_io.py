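"""Session file formats and run configuration.

A session is stored either as a long-format CSV (one row per time stamp per
marker) with a JSON sidecar holding per-trial events and labels, or as a
single HDF5 file with the same schema.  CSV is the inspectable interchange
default; HDF5 round-trips positions exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .simulate import Session, SimParams, TargetLayout, Trial, make_target_layout

__all__ = ["write_session", "read_session", "RunConfig", "load_config", "stage_seed"]

_CSV_COLUMNS = ["trial_id", "participant", "experiment", "dimension", "condition",
                "initial_id", "final_id", "t_s", "marker", "x", "y", "z"]


def _trial_meta(trial: Trial) -> dict:
    return {
        "trial_id": trial.trial_id,
        "participant_id": trial.participant_id,
        "experiment": trial.experiment,
        "dimension": trial.dimension,
        "condition": trial.condition,
        "initial_endpoint_id": trial.initial_endpoint_id,
        "final_endpoint_id": trial.final_endpoint_id,
        "cue_on_s": trial.cue_on_s,
        "movement_onset_s": trial.movement_onset_s,
        "shift_s": trial.shift_s,
        "touch_s": trial.touch_s,
        "endpoint_touch_xy": [float(v) for v in trial.endpoint_touch_xy],
        "corrected": trial.corrected,
    }


def _session_frame(session: Session) -> pd.DataFrame:
    rows = []
    for tr in session.trials:
        for marker, xyz in (("index", tr.index_xyz), ("wrist", tr.wrist_xyz)):
            rows.append(pd.DataFrame({
                "trial_id": tr.trial_id,
                "participant": tr.participant_id,
                "experiment": tr.experiment,
                "dimension": tr.dimension,
                "condition": tr.condition,
                "initial_id": tr.initial_endpoint_id,
                "final_id": tr.final_endpoint_id,
                "t_s": tr.t,
                "marker": marker,
                "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
            }))
    return pd.concat(rows, ignore_index=True)[_CSV_COLUMNS]


def write_session(session: Session, path) -> Path:
    """Write a session to ``path`` (.csv + .events.json sidecar, or .h5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _write_h5(session, path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    df = _session_frame(session)
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {
        "participant_id": session.participant_id,
        "experiment": session.experiment,
        "layout": {"static_distance": session.layout.static_distance,
                   "shift_distance": session.layout.shift_distance},
        "trials": [_trial_meta(t) for t in session.trials],
    }
    path.with_suffix(".events.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_session(path) -> Session:
    """Read a session written by :func:`write_session`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_h5(path)
    sidecar_path = path.with_suffix(".events.json")
    if not sidecar_path.exists():
        raise ValueError(f"missing events sidecar {sidecar_path.name}")
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session CSV is missing columns: {missing}")
    meta = json.loads(sidecar_path.read_text())
    layout = make_target_layout(meta["layout"]["static_distance"],
                                meta["layout"]["shift_distance"])
    trials = []
    grouped = dict(tuple(df.groupby("trial_id", sort=True)))
    for tm in meta["trials"]:
        g = grouped[tm["trial_id"]]
        idx = g[g.marker == "index"].sort_values("t_s")
        wst = g[g.marker == "wrist"].sort_values("t_s")
        t = idx["t_s"].to_numpy()
        if len(t) > 1:
            steps = np.diff(t)
            if np.ptp(steps) > 1e-6:
                raise ValueError(f"non-uniform time base in trial {tm['trial_id']}")
        trials.append(Trial(
            trial_id=tm["trial_id"],
            participant_id=tm["participant_id"],
            experiment=tm["experiment"],
            dimension=tm["dimension"],
            condition=tm["condition"],
            initial_endpoint_id=tm["initial_endpoint_id"],
            final_endpoint_id=tm["final_endpoint_id"],
            t=t,
            index_xyz=idx[["x", "y", "z"]].to_numpy(),
            wrist_xyz=wst[["x", "y", "z"]].to_numpy(),
            cue_on_s=tm["cue_on_s"],
            movement_onset_s=tm["movement_onset_s"],
            shift_s=tm["shift_s"],
            touch_s=tm["touch_s"],
            endpoint_touch_xy=np.array(tm["endpoint_touch_xy"]),
            corrected=tm["corrected"],
        ))
    return Session(meta["participant_id"], meta["experiment"], trials, layout, SimParams())


def _write_h5(session: Session, path: Path) -> Path:
    import h5py
    with h5py.File(path, "w") as f:
        f.attrs["participant_id"] = session.participant_id
        f.attrs["experiment"] = session.experiment
        f.attrs["static_distance"] = session.layout.static_distance
        f.attrs["shift_distance"] = session.layout.shift_distance
        for tr in session.trials:
            g = f.create_group(f"trial_{tr.trial_id:04d}")
            g.create_dataset("t", data=tr.t)
            g.create_dataset("index_xyz", data=tr.index_xyz)
            g.create_dataset("wrist_xyz", data=tr.wrist_xyz)
            g.create_dataset("endpoint_touch_xy", data=tr.endpoint_touch_xy)
            for key, val in _trial_meta(tr).items():
                if key == "endpoint_touch_xy":
                    continue
                g.attrs[key] = val if val is not None else np.nan
    return path


def _read_h5(path: Path) -> Session:
    import h5py
    trials = []
    with h5py.File(path, "r") as f:
        layout = make_target_layout(float(f.attrs["static_distance"]),
                                    float(f.attrs["shift_distance"]))
        for name in sorted(f.keys()):
            g = f[name]
            shift = g.attrs["shift_s"]
            trials.append(Trial(
                trial_id=int(g.attrs["trial_id"]),
                participant_id=str(g.attrs["participant_id"]),
                experiment=int(g.attrs["experiment"]),
                dimension=str(g.attrs["dimension"]),
                condition=str(g.attrs["condition"]),
                initial_endpoint_id=str(g.attrs["initial_endpoint_id"]),
                final_endpoint_id=str(g.attrs["final_endpoint_id"]),
                t=g["t"][:],
                index_xyz=g["index_xyz"][:],
                wrist_xyz=g["wrist_xyz"][:],
                cue_on_s=float(g.attrs["cue_on_s"]),
                movement_onset_s=float(g.attrs["movement_onset_s"]),
                shift_s=None if np.isnan(shift) else float(shift),
                touch_s=float(g.attrs["touch_s"]),
                endpoint_touch_xy=g["endpoint_touch_xy"][:],
                corrected=bool(g.attrs["corrected"]),
            ))
        sess = Session(str(f.attrs["participant_id"]), int(f.attrs["experiment"]),
                       trials, layout, SimParams())
    return sess


@dataclass
class RunConfig:
    """Resolved configuration of a full experiment run."""

    seed: int = 0
    n_participants_exp1: int = 12
    n_participants_exp2: int = 11
    n_static: int = 60
    n_shifted: int = 60
    static_distance: float = 8.0
    shift_distance: float = 2.4
    # decoding
    hidden_units: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 120
    patience: int = 15
    n_folds: int = 5
    offsets: tuple = (4, 6, 8, 10, 12, 20, 30)
    # stats
    alpha: float = 0.05
    n_permutations: int = 1000
    deviation_run_length: int = 10
    crossing_run_length: int = 3
    out_dir: str = "doublestep_run"

    def validate(self) -> "RunConfig":
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_static % 4 or self.n_shifted % 4:
            raise ValueError("trial counts must be divisible by 4")
        return self

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["offsets"] = list(d["offsets"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "offsets" in data:
        data["offsets"] = tuple(data["offsets"])
    return RunConfig(**data).validate()


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed fan-out from one global seed.

    Stages are independently reproducible: the derived seed depends only on
    the global seed, a stage name, and an index (participant, fold, ...).
    """
    import zlib
    ss = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode()), index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
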