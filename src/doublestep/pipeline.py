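"""End-to-end experiment driver.

Simulates cohorts for the two perturbation latencies, runs the kinematic
analyses, all goal-decoding problems, trajectory regression, and the
temporal statistics, and collects everything into an
:class:`ExperimentReport` of tidy tables that can be written to disk.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import kinematics as kin
from . import temporal_stats as ts
from .decoding import (CLUSTERS, DecodingProblem, TrainConfig, chance_level,
                       cluster_trials, cross_validated_goal_decoding,
                       cross_validated_regression, select_problem_trials)
from .session_io import RunConfig, stage_seed, write_session
from .simulate import (HORIZONTAL_STATIC, SAGITTAL_STATIC, Session, SimParams,
                       make_target_layout, simulate_session)

__all__ = ["ExperimentReport", "run_experiment", "simulate_cohort"]


@dataclass
class ExperimentReport:
    """All result tables of one run, each a tidy DataFrame."""

    config: RunConfig
    config_hash: str
    deviation_times: pd.DataFrame
    endpoint_errors: pd.DataFrame
    reaction_times: pd.DataFrame
    variability: pd.DataFrame
    accuracy_curves: pd.DataFrame
    curve_comparisons: pd.DataFrame
    crossing_times: pd.DataFrame
    ellipses: pd.DataFrame
    r2_scores: pd.DataFrame
    ks_tests: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {k: v for k, v in self.__dict__.items() if isinstance(v, pd.DataFrame)}

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "config.yaml")
        (out / "provenance.json").write_text(json.dumps(
            {"config_hash": self.config_hash, "seed": self.config.seed}, indent=1))
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.csv", index=False)
        return out


def simulate_cohort(config: RunConfig, experiment: int) -> list[Session]:
    """One session per participant for the given perturbation latency."""
    n = config.n_participants_exp1 if experiment == 1 else config.n_participants_exp2
    layout = make_target_layout(config.static_distance, config.shift_distance)
    sessions = []
    for i in range(n):
        seed = stage_seed(config.seed, f"simulate-exp{experiment}", i)
        params = SimParams.for_experiment(experiment, rng_seed=seed)
        sessions.append(simulate_session(
            params, layout, config.n_static, config.n_shifted,
            participant_id=f"E{experiment}P{i:02d}", experiment=experiment))
    return sessions


def _deviation_rows(sessions: list[Session], experiment: int, run_length: int) -> list[dict]:
    rows = []
    layout = sessions[0].layout
    for parent in ("left", "right", "near", "far"):
        dim = layout.dimension_of(parent)
        axis = "x" if dim == "horizontal" else "y"
        neg, pos = layout.children(parent)
        a = [kin.lateral_velocity(t, axis=axis)
             for s in sessions for t in s.select(condition="shifted", final_endpoint_id=neg)]
        b = [kin.lateral_velocity(t, axis=axis)
             for s in sessions for t in s.select(condition="shifted", final_endpoint_id=pos)]
        res = kin.detect_deviation_time(a, b, run_length=run_length)
        rows.append({"experiment": experiment, "target_group": parent, "dimension": dim,
                     "n_a": len(a), "n_b": len(b),
                     "deviation_time_ms": res.deviation_time_ms})
    return rows


def run_experiment(config: RunConfig, out_dir: Optional[str] = None,
                   dimensions: tuple = ("horizontal", "sagittal"),
                   include_sixway: bool = True,
                   clusters: tuple = CLUSTERS) -> ExperimentReport:
    """Run the full analysis pipeline on simulated cohorts.

    Deterministic under ``config.seed`` (all stage seeds are fanned out from
    it).  ``dimensions``, ``include_sixway`` and ``clusters`` allow reduced
    smoke runs; the defaults cover everything.
    """
    config.validate()
    cfg_hash = hashlib.sha256(json.dumps(config.__dict__, sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]
    train_cfg = TrainConfig(hidden_units=config.hidden_units,
                            learning_rate=config.learning_rate,
                            batch_size=config.batch_size,
                            max_epochs=config.max_epochs,
                            patience=config.patience)

    cohorts = {e: simulate_cohort(config, e) for e in (1, 2)}
    layout = cohorts[1][0].layout

    dev_rows, err_rows, rt_rows, var_rows = [], [], [], []
    curve_rows, cross_rows = [], []
    curves_by_key: dict[tuple, list[np.ndarray]] = {}
    crossing_by_key: dict[tuple, dict[str, float]] = {}

    for e, sessions in cohorts.items():
        dev_rows.extend(_deviation_rows(sessions, e, config.deviation_run_length))
        for s in sessions:
            for dim in ("horizontal", "sagittal"):
                shifted = s.select(condition="shifted", dimension=dim)
                errs = [kin.trial_endpoint_error(t, layout) for t in shifted]
                err_rows.append({"experiment": e, "participant": s.participant_id,
                                 "dimension": dim, "mean_error_cm": float(np.mean(errs))})
            for cond in ("static", "shifted"):
                rts = [kin.reaction_time(t) for t in s.select(condition=cond)]
                rt_rows.append({"experiment": e, "participant": s.participant_id,
                                "condition": cond, "mean_rt_ms": float(np.mean(rts))})
                axis_trials = {"x": s.select(condition=cond, dimension="horizontal"),
                               "y": s.select(condition=cond, dimension="sagittal")}
                for axis, trs in axis_trials.items():
                    if len(trs) >= 2:
                        var_rows.append({
                            "experiment": e, "participant": s.participant_id,
                            "condition": cond, "axis": axis,
                            "sd_cm": kin.peak_velocity_variability(trs, axis)})

        # goal decoding per participant
        for dim in dimensions:
            problems = [("static", DecodingProblem(dim, "static"))]
            statics = HORIZONTAL_STATIC if dim == "horizontal" else SAGITTAL_STATIC
            for parent in statics:
                problems.append((f"shifted-{parent}", DecodingProblem(dim, f"shifted:{parent}")))
            if include_sixway:
                problems.append(("sixway", DecodingProblem(dim, "sixway")))
            for pname, problem in problems:
                for i, s in enumerate(sessions):
                    seed = stage_seed(config.seed, f"decode-{e}-{dim}-{pname}", i)
                    curve = cross_validated_goal_decoding(
                        s, problem, config=train_cfg, seed=seed, n_folds=config.n_folds)
                    key = (e, dim, pname)
                    curves_by_key.setdefault(key, []).append(curve.accuracy)
                    for node, pct, acc in zip(curve.end_indices, curve.pct_movement,
                                              curve.accuracy):
                        curve_rows.append({"experiment": e, "dimension": dim,
                                           "problem": pname,
                                           "participant": s.participant_id,
                                           "end_index": int(node),
                                           "pct_movement": float(pct),
                                           "accuracy": float(acc)})
                    if pname.startswith("shifted"):
                        cr = ts.chance_crossing_time(curve.accuracy, curve.chance,
                                                     config.crossing_run_length,
                                                     node_pct=curve.pct_movement)
                        crossing_by_key.setdefault((e, dim), {})[s.participant_id] = cr
                        cross_rows.append({"experiment": e, "dimension": dim,
                                           "problem": pname,
                                           "participant": s.participant_id,
                                           "crossing_pct": cr})

    # curve comparisons: static vs each shifted pair, within experiment/dimension
    comp_rows = []
    for (e, dim, pname), curves in curves_by_key.items():
        if not pname.startswith("shifted"):
            continue
        base = curves_by_key.get((e, dim, "static"))
        if base is None or len(base) < 2 or len(curves) < 2:
            continue
        seed = stage_seed(config.seed, f"hotelling-{e}-{dim}-{pname}")
        res = ts.hotelling_curve_test(np.stack(base), np.stack(curves),
                                      alpha=config.alpha,
                                      n_perm=config.n_permutations, seed=seed)
        comp_rows.append({"experiment": e, "dimension": dim,
                          "comparison": f"static-vs-{pname}",
                          "threshold": res.threshold,
                          "n_significant_nodes": int(res.significant.sum()),
                          "intervals_pct": json.dumps(res.intervals_pct)})

    # confidence ellipses of per-participant crossing times (horiz vs sagittal)
    ell_rows = []
    for e in cohorts:
        h = crossing_by_key.get((e, "horizontal"), {})
        s_ = crossing_by_key.get((e, "sagittal"), {})
        common = [p for p in h if p in s_ and h[p] is not None and s_[p] is not None]
        if len(common) >= 3:
            pts = np.array([[h[p], s_[p]] for p in common])
            try:
                ell = ts.confidence_ellipse(pts)
                ell_rows.append({"experiment": e, "n_points": ell.n_points,
                                 "center_x": ell.center[0], "center_y": ell.center[1],
                                 "eig1": ell.eigenvalues[0], "eig2": ell.eigenvalues[1],
                                 "area": ell.area, "area_sigma": ell.area_sigma})
            except ValueError:
                pass

    # trajectory regression
    r2_rows = []
    for e, sessions in cohorts.items():
        for cluster in clusters:
            for offset in config.offsets:
                for i, s in enumerate(sessions):
                    seed = stage_seed(config.seed, f"regress-{e}-{cluster}-{offset}", i)
                    sc = cross_validated_regression(cluster_trials(s, cluster), offset,
                                                    config=train_cfg, seed=seed,
                                                    n_folds=config.n_folds)
                    for comp, val in zip("xyz", sc.r2_index_xyz):
                        r2_rows.append({"experiment": e, "cluster": cluster,
                                        "offset": offset, "component": comp,
                                        "participant": s.participant_id,
                                        "r2": float(val)})
    r2_df = pd.DataFrame(r2_rows)

    ks_rows = []
    if not r2_df.empty:
        for e in cohorts:
            sub = r2_df[r2_df.experiment == e]
            horiz = sub[sub.cluster.isin(("left", "right"))]["r2"].to_numpy()
            sag = sub[sub.cluster.isin(("near", "far"))]["r2"].to_numpy()
            if len(horiz) >= 5 and len(sag) >= 5:
                stat, p = ts.compare_r2_distributions(horiz, sag)
                ks_rows.append({"experiment": e, "comparison": "horizontal-vs-sagittal-r2",
                                "ks_statistic": stat, "p_value": p})

    report = ExperimentReport(
        config=config, config_hash=cfg_hash,
        deviation_times=pd.DataFrame(dev_rows),
        endpoint_errors=pd.DataFrame(err_rows),
        reaction_times=pd.DataFrame(rt_rows),
        variability=pd.DataFrame(var_rows),
        accuracy_curves=pd.DataFrame(curve_rows),
        curve_comparisons=pd.DataFrame(comp_rows),
        crossing_times=pd.DataFrame(cross_rows),
        ellipses=pd.DataFrame(ell_rows),
        r2_scores=r2_df,
        ks_tests=pd.DataFrame(ks_rows),
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
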