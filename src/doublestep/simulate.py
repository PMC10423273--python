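"""Synthetic double-step reaching sessions.

Generates sessions of simulated centre-out reaching trials in which the
target either stays put (static trials) or jumps 2.4 cm to a neighbouring
location at, or shortly after, movement onset (shifted trials), forcing an
online correction of the hand path.  The simulated observables mirror a
motion-capture recording of two markers (index fingertip and wrist) sampled
at 100 Hz, together with per-trial event times and a touchscreen endpoint.

Coordinate convention: x = horizontal (rightward positive), y = sagittal
depth (away from the body positive), z = vertical (up positive).  The screen
lies in the z = 0 plane; all positions are in cm, times in seconds.

Movements are modelled as minimum-jerk point-to-point reaches; corrections
are a second minimum-jerk submovement superposed on the primary one, the
standard kinematic model for double-step reaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "TargetLayout",
    "SimParams",
    "Trial",
    "Session",
    "make_target_layout",
    "minimum_jerk",
    "simulate_trial",
    "simulate_session",
    "STATIC_IDS",
    "HORIZONTAL_STATIC",
    "SAGITTAL_STATIC",
]

#: static endpoint identifiers, two per workspace dimension
HORIZONTAL_STATIC = ("left", "right")
SAGITTAL_STATIC = ("near", "far")
STATIC_IDS = HORIZONTAL_STATIC + SAGITTAL_STATIC

# unit displacement axis of each static target's shifted children
_CHILD_AXIS = {"left": 0, "right": 0, "near": 1, "far": 1}


@dataclass(frozen=True)
class TargetLayout:
    """Fixation point plus 4 static and 8 shifted targets on the screen plane.

    Each static target sits at ``static_distance`` from fixation along one of
    the four cardinal directions; each has two shifted children displaced by
    ``shift_distance`` along its own dimension's axis (x for horizontal
    targets, y for sagittal ones).
    """

    fixation: np.ndarray
    static_targets: dict[str, np.ndarray]
    shifted_targets: dict[str, tuple[str, np.ndarray]]
    static_distance: float
    shift_distance: float

    def position(self, endpoint_id: str) -> np.ndarray:
        """2D screen position (cm) of any endpoint id."""
        if endpoint_id in self.static_targets:
            return self.static_targets[endpoint_id]
        return self.shifted_targets[endpoint_id][1]

    def children(self, static_id: str) -> tuple[str, str]:
        """The two shifted children of a static target, negative axis first."""
        kids = sorted(
            (sid for sid, (parent, _) in self.shifted_targets.items() if parent == static_id),
        )
        assert len(kids) == 2
        return kids[0], kids[1]

    def dimension_of(self, endpoint_id: str) -> str:
        sid = endpoint_id if endpoint_id in self.static_targets else self.shifted_targets[endpoint_id][0]
        return "horizontal" if sid in HORIZONTAL_STATIC else "sagittal"


def make_target_layout(static_distance: float = 8.0, shift_distance: float = 2.4) -> TargetLayout:
    """Build the 12-endpoint layout: 4 static targets at ``static_distance``
    from fixation (left/right along x, near/far along y) and, for each, two
    shifted children at ``shift_distance`` along the same axis.

    Shifted ids are ``"<parent>-"`` (negative axis direction) and
    ``"<parent>+"`` (positive direction).
    """
    if static_distance <= 0 or shift_distance <= 0:
        raise ValueError("layout distances must be positive")
    fixation = np.zeros(2)
    static = {
        "left": np.array([-static_distance, 0.0]),
        "right": np.array([static_distance, 0.0]),
        "near": np.array([0.0, -static_distance]),
        "far": np.array([0.0, static_distance]),
    }
    shifted: dict[str, tuple[str, np.ndarray]] = {}
    for sid, pos in static.items():
        axis = _CHILD_AXIS[sid]
        for sign, suffix in ((-1.0, "-"), (1.0, "+")):
            delta = np.zeros(2)
            delta[axis] = sign * shift_distance
            shifted[f"{sid}{suffix}"] = (sid, pos + delta)
    return TargetLayout(fixation, static, shifted, float(static_distance), float(shift_distance))


@dataclass(frozen=True)
class SimParams:
    """Simulator parameters.

    Times are ms unless suffixed otherwise; positions cm.  Defaults emulate
    the study conditions: shift at movement onset (experiment 1) or 100 ms
    after (experiment 2), horizontal corrections initiated after ~195 ms
    (experiment 1) / ~140 ms (experiment 2), sagittal corrections after
    ~290 ms, and — under the experiment-2 defaults — no sagittal correction
    at all, leaving the endpoint near the original target.
    """

    shift_latency_ms: float = 0.0
    movement_duration_mean_ms: float = 630.0
    movement_duration_sd_ms: float = 60.0
    movement_duration_min_ms: float = 400.0
    correction_latency_horizontal_ms: tuple[float, float] = (195.0, 20.0)
    correction_latency_sagittal_ms: tuple[float, float] = (290.0, 30.0)
    p_no_correction_sagittal: float = 0.0
    position_noise_sd_cm: float = 0.05
    endpoint_sd_cm: float = 0.4
    wrist_offset_cm: tuple[float, float, float] = (0.0, -5.0, 3.0)
    reaction_time_mean_ms: float = 350.0
    reaction_time_sd_ms: float = 50.0
    reaction_time_min_ms: float = 150.0
    fixation_period_s: float = 1.5
    start_position_cm: tuple[float, float, float] = (0.0, -15.0, 5.0)
    sample_rate_hz: float = 100.0
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("movement_duration_sd_ms", "position_noise_sd_cm", "endpoint_sd_cm", "reaction_time_sd_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.p_no_correction_sagittal <= 1.0:
            raise ValueError("p_no_correction_sagittal must lie in [0, 1]")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")

    @classmethod
    def for_experiment(cls, experiment: int, **overrides) -> "SimParams":
        """Default parameter sets for the two perturbation latencies.

        Experiment 1: shift at movement onset, all shifts corrected.
        Experiment 2: shift 100 ms after onset, faster horizontal corrections
        but no sagittal correction (the empirical signature of late depth
        perturbations).
        """
        if experiment == 1:
            base = cls(shift_latency_ms=0.0,
                       correction_latency_horizontal_ms=(195.0, 20.0),
                       correction_latency_sagittal_ms=(290.0, 30.0),
                       p_no_correction_sagittal=0.0)
        elif experiment == 2:
            base = cls(shift_latency_ms=100.0,
                       correction_latency_horizontal_ms=(140.0, 20.0),
                       correction_latency_sagittal_ms=(290.0, 30.0),
                       p_no_correction_sagittal=1.0)
        else:
            raise ValueError("experiment must be 1 or 2")
        return replace(base, **overrides) if overrides else base


@dataclass
class Trial:
    """One reaching trial: marker time series, events, and condition labels."""

    trial_id: int
    participant_id: str
    experiment: int
    dimension: str  # horizontal | sagittal
    condition: str  # static | shifted
    initial_endpoint_id: str
    final_endpoint_id: str
    t: np.ndarray  # s, uniform at sample_rate
    index_xyz: np.ndarray  # (n, 3) cm
    wrist_xyz: np.ndarray  # (n, 3) cm
    cue_on_s: float
    movement_onset_s: float
    shift_s: Optional[float]
    touch_s: float
    endpoint_touch_xy: np.ndarray  # (2,) cm
    corrected: bool = True

    def __post_init__(self) -> None:
        if len(self.t) != len(self.index_xyz) or len(self.t) != len(self.wrist_xyz):
            raise ValueError("marker series must match the time base length")
        if not self.movement_onset_s < self.touch_s:
            raise ValueError("movement onset must precede touch")
        if self.shift_s is not None and self.shift_s < self.movement_onset_s:
            raise ValueError("target shift cannot precede movement onset")


@dataclass
class Session:
    """An ordered block of trials for one participant."""

    participant_id: str
    experiment: int
    trials: list[Trial]
    layout: TargetLayout
    params: SimParams

    def select(self, **labels) -> list[Trial]:
        """Trials matching all given label equalities, e.g.
        ``select(condition="static", dimension="horizontal")``."""
        out = []
        for tr in self.trials:
            if all(getattr(tr, key) == val for key, val in labels.items()):
                out.append(tr)
        return out


def minimum_jerk(start, goal, duration: float, n: int) -> np.ndarray:
    """Minimum-jerk point-to-point path: the smoothest (fifth-order
    polynomial) trajectory with zero velocity and acceleration at both ends.

    Position along the straight line from ``start`` to ``goal`` follows
    s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5 with tau = t/duration, giving a
    symmetric bell-shaped speed profile peaking at 1.875 * |goal-start| /
    duration.

    Parameters
    ----------
    start, goal : array-like, shape (d,)
    duration : movement time, s (> 0)
    n : number of samples (>= 2), endpoints included

    Returns
    -------
    (n, d) array of positions.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n < 2:
        raise ValueError("need at least two samples")
    start = np.asarray(start, dtype=float)
    goal = np.asarray(goal, dtype=float)
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return start[None, :] + s[:, None] * (goal - start)[None, :]


def _minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile, clipped outside [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    if sd == 0:
        return max(mean, lo)
    while True:  # simple rejection; lo is far in the bulk for all defaults
        x = rng.normal(mean, sd)
        if x >= lo:
            return x


def simulate_trial(
    layout: TargetLayout,
    params: SimParams,
    dimension: str,
    condition: str,
    initial_id: str,
    final_id: str,
    rng: np.random.Generator,
    trial_id: int = 0,
    participant_id: str = "sim",
    experiment: int = 1,
) -> Trial:
    """Simulate a single trial.

    The index path is a minimum-jerk reach from the start position to the
    initial target.  In shifted trials a corrective minimum-jerk submovement
    toward the final target is superposed from (shift time + a
    dimension-specific correction latency draw) until touch; if the latency
    leaves no time to correct, or with probability ``p_no_correction_sagittal``
    for sagittal shifts, the correction is omitted and the hand lands near the
    original target (a large endpoint error).  I.i.d. Gaussian noise is added
    per sample; the wrist is the index plus a rigid offset plus independent
    noise; the touch point is the planned landing point plus endpoint noise.
    """
    if condition == "static":
        if initial_id != final_id:
            raise ValueError("static trials must have identical initial and final endpoints")
    elif condition == "shifted":
        if final_id not in layout.shifted_targets or layout.shifted_targets[final_id][0] != initial_id:
            raise ValueError("shifted trials need final endpoint to be a child of the initial one")
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if layout.dimension_of(initial_id) != dimension:
        raise ValueError("dimension label inconsistent with endpoint ids")

    dt = 1.0 / params.sample_rate_hz
    cue_on = params.fixation_period_s
    rt_s = _truncnorm(rng, params.reaction_time_mean_ms, params.reaction_time_sd_ms,
                      params.reaction_time_min_ms) / 1000.0
    dur_s = _truncnorm(rng, params.movement_duration_mean_ms, params.movement_duration_sd_ms,
                       params.movement_duration_min_ms) / 1000.0
    onset = cue_on + rt_s
    touch = onset + dur_s

    start = np.asarray(params.start_position_cm, dtype=float)
    tgt0 = np.append(layout.position(initial_id), 0.0)  # targets on screen plane z=0
    tgt1 = np.append(layout.position(final_id), 0.0)

    # snap events onto the sample grid so segment extraction is exact
    onset = round(onset / dt) * dt
    touch = round(touch / dt) * dt
    n = int(round(touch / dt)) + 1
    t = np.arange(n) * dt

    # primary reach
    pos = np.tile(start, (n, 1))
    moving = t >= onset - 1e-9
    tau = (t[moving] - onset) / (touch - onset)
    pos[moving] = start + _minimum_jerk_profile(tau)[:, None] * (tgt0 - start)

    shift_s: Optional[float] = None
    corrected = True
    planned_end = tgt0
    if condition == "shifted":
        shift_s = onset + params.shift_latency_ms / 1000.0
        if dimension == "horizontal":
            lat_mean, lat_sd = params.correction_latency_horizontal_ms
        else:
            lat_mean, lat_sd = params.correction_latency_sagittal_ms
        latency_s = _truncnorm(rng, lat_mean, lat_sd, 0.0) / 1000.0
        t_corr = shift_s + latency_s
        skip = dimension == "sagittal" and rng.random() < params.p_no_correction_sagittal
        if skip or t_corr >= touch - dt:
            corrected = False
        else:
            ctau = (t - t_corr) / (touch - t_corr)
            corr = _minimum_jerk_profile(ctau)[:, None] * (tgt1 - tgt0)
            pos = pos + corr
            planned_end = tgt1

    index = pos + rng.normal(0.0, params.position_noise_sd_cm, size=pos.shape)
    wrist = pos + np.asarray(params.wrist_offset_cm) + rng.normal(
        0.0, params.position_noise_sd_cm, size=pos.shape)
    touch_xy = planned_end[:2] + rng.normal(0.0, params.endpoint_sd_cm, size=2)

    return Trial(
        trial_id=trial_id,
        participant_id=participant_id,
        experiment=experiment,
        dimension=dimension,
        condition=condition,
        initial_endpoint_id=initial_id,
        final_endpoint_id=final_id,
        t=t,
        index_xyz=index,
        wrist_xyz=wrist,
        cue_on_s=cue_on,
        movement_onset_s=onset,
        shift_s=shift_s,
        touch_s=touch,
        endpoint_touch_xy=touch_xy,
        corrected=corrected,
    )


def _trial_plan(layout: TargetLayout, n_static: int, n_shifted: int) -> list[tuple[str, str, str, str]]:
    """Balanced (dimension, condition, initial, final) tuples.

    Static trials split evenly over the 4 static targets; shifted trials split
    evenly over the 4 static parents, and each parent's share is divided
    between its two children as evenly as possible (the larger half going to
    alternating children so no direction is systematically favoured).
    """
    if n_static % 4 or n_shifted % 4:
        raise ValueError(
            "trial counts must divide evenly over the 4 static targets "
            f"(got n_static={n_static}, n_shifted={n_shifted})")
    plan: list[tuple[str, str, str, str]] = []
    for sid in STATIC_IDS:
        dim = "horizontal" if sid in HORIZONTAL_STATIC else "sagittal"
        plan.extend((dim, "static", sid, sid) for _ in range(n_static // 4))
    per_parent = n_shifted // 4
    for k, sid in enumerate(STATIC_IDS):
        dim = "horizontal" if sid in HORIZONTAL_STATIC else "sagittal"
        neg, pos = layout.children(sid)
        n_first = (per_parent + (k % 2)) // 2  # 8/7 split alternates by parent
        counts = {neg: n_first, pos: per_parent - n_first}
        for child, cnt in counts.items():
            plan.extend((dim, "shifted", sid, child) for _ in range(cnt))
    return plan


def simulate_session(
    params: SimParams,
    layout: Optional[TargetLayout] = None,
    n_static: int = 60,
    n_shifted: int = 60,
    rng: Optional[np.random.Generator] = None,
    participant_id: str = "sim",
    experiment: int = 1,
) -> Session:
    """Simulate a session: ``n_static`` + ``n_shifted`` trials (default
    60 + 60 = 120) in seed-randomized order, balanced across the four static
    targets and their shifted children."""
    layout = layout or make_target_layout()
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    plan = _trial_plan(layout, n_static, n_shifted)
    order = rng.permutation(len(plan))
    trials = []
    for i, k in enumerate(order):
        dim, cond, init_id, fin_id = plan[k]
        trials.append(simulate_trial(layout, params, dim, cond, init_id, fin_id, rng,
                                     trial_id=i, participant_id=participant_id,
                                     experiment=experiment))
    return Session(participant_id, experiment, trials, layout, params)
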