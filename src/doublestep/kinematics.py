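"""Kinematic analyses of reaching trials.

Covers the classical (non-decoding) analyses of a double-step reaching
session: extraction of the movement segment, lateral (x) velocity traces,
detection of the online-correction time as the first sustained statistical
divergence between two groups of velocity traces, endpoint accuracy,
reaction times, trajectory variability at peak velocity, and per-condition
movement summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .simulate import Session, Trial

__all__ = [
    "VelocityTrace",
    "DeviationResult",
    "movement_segment",
    "lateral_velocity",
    "detect_deviation_time",
    "endpoint_error",
    "reaction_time",
    "peak_velocity_variability",
    "movement_summary",
]


@dataclass
class VelocityTrace:
    """Lateral velocity of one trial, timestamped relative to the target
    shift (or to movement onset for static trials)."""

    t_rel_ms: np.ndarray
    v_lat: np.ndarray  # cm/s
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.t_rel_ms) != len(self.v_lat):
            raise ValueError("time base and velocity must have equal length")
        if not np.all(np.isfinite(self.v_lat)):
            raise ValueError("velocity trace contains non-finite values")


@dataclass
class DeviationResult:
    """Outcome of the per-sample two-group divergence test."""

    deviation_time_ms: Optional[float]
    t_rel_ms: np.ndarray
    p_values: np.ndarray
    alpha: float
    run_length: int


def movement_segment(trial: Trial) -> np.ndarray:
    """Index positions between movement onset and touch (inclusive)."""
    if trial.touch_s is None or trial.movement_onset_s is None:
        raise ValueError("trial is missing onset/touch events")
    if trial.touch_s <= trial.movement_onset_s:
        raise ValueError("malformed trial: touch precedes movement onset")
    mask = (trial.t >= trial.movement_onset_s - 1e-9) & (trial.t <= trial.touch_s + 1e-9)
    seg = trial.index_xyz[mask]
    if len(seg) == 0:
        raise ValueError("movement segment is empty")
    return seg


def _segment_mask(trial: Trial) -> np.ndarray:
    return (trial.t >= trial.movement_onset_s - 1e-9) & (trial.t <= trial.touch_s + 1e-9)


def lateral_velocity(trial: Trial, smooth_window: int = 0, axis: str = "x") -> VelocityTrace:
    """Central-difference x-velocity of the index over the movement segment.

    Timestamps are reported relative to the target shift for shifted trials
    and to movement onset for static trials.  ``smooth_window`` > 1 applies a
    centred moving average of that many samples (default: no smoothing).
    ``axis`` selects the component: "x" (lateral, the default) for
    direction shifts, "y" (depth) when probing sagittal corrections.
    """
    mask = _segment_mask(trial)
    t = trial.t[mask]
    x = trial.index_xyz[mask, {"x": 0, "y": 1}[axis]]
    if len(t) < 3:
        raise ValueError("movement segment too short for velocity estimation")
    v = np.gradient(x, t)
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        v = np.convolve(v, kernel, mode="same")
    origin = trial.shift_s if trial.shift_s is not None else trial.movement_onset_s
    return VelocityTrace((t - origin) * 1000.0, v, group=trial.final_endpoint_id)


def _stack_traces(traces: Sequence[VelocityTrace]) -> tuple[np.ndarray, np.ndarray]:
    """Truncate a group of traces to the shortest and stack them.

    Traces must share the sampling interval; the common time base starts at
    each trace's own origin, so trials are aligned on the shift (or onset).
    """
    steps = {np.round(np.median(np.diff(tr.t_rel_ms)), 6) for tr in traces}
    if len(steps) != 1:
        raise ValueError("traces have mismatched sampling rates")
    n = min(len(tr.v_lat) for tr in traces)
    mat = np.stack([tr.v_lat[:n] for tr in traces])
    return traces[0].t_rel_ms[:n], mat


def detect_deviation_time(
    traces_a: Sequence[VelocityTrace],
    traces_b: Sequence[VelocityTrace],
    alpha: float = 0.05,
    run_length: int = 10,
) -> DeviationResult:
    """First sustained divergence time between two groups of velocity traces.

    Runs a two-tailed two-sample t-test at every sample (after truncating all
    traces to the shortest) and reports the time of the first sample opening a
    run of at least ``run_length`` consecutive significant samples, restricted
    to non-negative times (at or after the shift).  ``deviation_time_ms`` is
    None when no such run exists — e.g. when neither group corrects.
    """
    if len(traces_a) < 2 or len(traces_b) < 2:
        raise ValueError("need at least two traces per group")
    t_a, mat_a = _stack_traces(list(traces_a))
    t_b, mat_b = _stack_traces(list(traces_b))
    n = min(mat_a.shape[1], mat_b.shape[1])
    t_ms, mat_a, mat_b = t_a[:n], mat_a[:, :n], mat_b[:, :n]
    _, p = stats.ttest_ind(mat_a, mat_b, axis=0)
    p = np.nan_to_num(p, nan=1.0)
    sig = (p < alpha) & (t_ms >= 0)
    dev: Optional[float] = None
    run = 0
    for i in range(n - 1, -1, -1):  # scan backwards: run[i] = consecutive sig from i
        run = run + 1 if sig[i] else 0
        if run >= run_length:
            dev = float(t_ms[i])
    return DeviationResult(dev, t_ms, p, alpha, run_length)


def endpoint_error(touch_xy, target_xy) -> float:
    """Euclidean distance (cm) between touch point and target in the screen
    plane — the endpoint accuracy measure."""
    touch_xy = np.asarray(touch_xy, dtype=float)
    target_xy = np.asarray(target_xy, dtype=float)
    if not (np.all(np.isfinite(touch_xy)) and np.all(np.isfinite(target_xy))):
        raise ValueError("coordinates must be finite")
    return float(np.hypot(touch_xy[0] - target_xy[0], touch_xy[1] - target_xy[1]))


def trial_endpoint_error(trial: Trial, layout) -> float:
    """Endpoint error of a trial against its labelled final target."""
    return endpoint_error(trial.endpoint_touch_xy, layout.position(trial.final_endpoint_id))


def reaction_time(trial: Trial) -> float:
    """Cue-to-movement-onset interval in ms."""
    rt = (trial.movement_onset_s - trial.cue_on_s) * 1000.0
    if rt <= 0:
        raise ValueError("movement onset precedes the cue")
    return rt


def peak_velocity_variability(trials: Sequence[Trial], axis: str) -> float:
    """Across-trial sd (cm) of the x or y index coordinate at the moment of
    peak 3D speed — a summary of trajectory variability at the most dynamic
    point of the reach."""
    if len(trials) < 2:
        raise ValueError("need at least two trials")
    col = {"x": 0, "y": 1}[axis]
    coords = []
    for tr in trials:
        mask = _segment_mask(tr)
        seg = tr.index_xyz[mask]
        t = tr.t[mask]
        speed = np.linalg.norm(np.gradient(seg, t, axis=0), axis=1)
        coords.append(seg[int(np.argmax(speed)), col])
    return float(np.std(coords, ddof=1))


def latency_recovery(
    injected_latency_ms: float,
    n_per_group: int = 200,
    seed: int = 0,
    latency_sd_ms: float = 20.0,
    run_length: int = 10,
) -> Optional[float]:
    """Simulator round-trip: inject a known mean correction latency into
    horizontal shifted trials and return the detected deviation time (ms).

    Generates ``n_per_group`` trials to each shifted child of the left static
    target and runs :func:`detect_deviation_time` on their lateral-velocity
    traces.  Used to validate that the statistical deviation time tracks the
    generative correction latency.
    """
    from .simulate import SimParams, make_target_layout, simulate_trial

    layout = make_target_layout()
    params = SimParams.for_experiment(
        1, correction_latency_horizontal_ms=(injected_latency_ms, latency_sd_ms))
    rng = np.random.default_rng(seed)
    a = [simulate_trial(layout, params, "horizontal", "shifted", "left", "left-", rng)
         for _ in range(n_per_group)]
    b = [simulate_trial(layout, params, "horizontal", "shifted", "left", "left+", rng)
         for _ in range(n_per_group)]
    res = detect_deviation_time([lateral_velocity(t) for t in a],
                                [lateral_velocity(t) for t in b], run_length=run_length)
    return res.deviation_time_ms


def movement_summary(session: Session) -> dict:
    """Per-condition movement durations and mean speeds.

    Returns ``{condition: {"durations_s": array, "mean_speeds_cm_s": array}}``.
    """
    out: dict = {}
    for cond in ("static", "shifted"):
        trials = session.select(condition=cond)
        if not trials:
            raise ValueError(f"no trials in condition {cond!r}")
        durs, speeds = [], []
        for tr in trials:
            mask = _segment_mask(tr)
            seg = tr.index_xyz[mask]
            t = tr.t[mask]
            durs.append(tr.touch_s - tr.movement_onset_s)
            speeds.append(float(np.mean(np.linalg.norm(np.gradient(seg, t, axis=0), axis=1))))
        out[cond] = {"durations_s": np.array(durs), "mean_speeds_cm_s": np.array(speeds)}
    return out
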