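"""Sliding-window decoding of reaching goals and future trajectory values.

Each trial's movement segment is time-normalized to 100 samples of K = 6
kinematic features (index x, y, z; wrist x, y, z).  Short windows ("chunks")
of T = 8 consecutive samples are slid over the trial — stride 4 for training,
stride 1 for inference — and fed to a recurrent (GRU) network that either
classifies the trial's final target (goal decoding) or regresses the
kinematic state a fixed offset of normalized time into the future
(trajectory decoding).  Evaluation uses fivefold stratified cross-validation
split at the *trial* level, so all chunks of a trial stay on one side of
every fold; inference at stride 1 yields a time-resolved accuracy curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import r2_score
from sklearn.model_selection import StratifiedKFold

from .gru import GRUNet, TrainConfig, train_network
from .simulate import Session, Trial

__all__ = [
    "NormalizedTrial",
    "Chunk",
    "DecodingProblem",
    "AccuracyCurve",
    "RegressionScores",
    "normalize_trial",
    "extract_chunks",
    "build_goal_dataset",
    "train_goal_classifier",
    "evaluate_accuracy_curve",
    "cross_validated_goal_decoding",
    "empirical_chance_curve",
    "train_trajectory_regressor",
    "evaluate_r2",
    "chance_level",
    "select_problem_trials",
    "REGRESSION_OFFSETS",
    "CLUSTERS",
]

N_NORM = 100  # samples after time normalization
K_FEATURES = 6
T_WINDOW = 8
TRAIN_STRIDE = 4
INFER_STRIDE = 1
REGRESSION_OFFSETS = (4, 6, 8, 10, 12, 20, 30)
CLUSTERS = ("left", "right", "near", "far")


@dataclass
class NormalizedTrial:
    """Movement segment resampled to 100 steps x 6 features, labels kept."""

    features: np.ndarray  # (100, 6)
    final_endpoint_id: str
    condition: str
    dimension: str
    trial_id: int
    participant_id: str

    def __post_init__(self) -> None:
        if self.features.shape != (N_NORM, K_FEATURES):
            raise ValueError(f"expected ({N_NORM}, {K_FEATURES}) features")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite values in normalized trial")


@dataclass
class Chunk:
    """A T x K window of a trial, tagged with the position of its last sample."""

    data: np.ndarray  # (T, K)
    end_index: int
    trial_id: int
    final_endpoint_id: str


@dataclass(frozen=True)
class DecodingProblem:
    """Selection of trials and classes for one decoding task.

    kind:
      - "static": the two static endpoints of ``dimension`` (static trials)
      - "shifted:<static_id>": the two shifted children of one static target
      - "sixway": all 6 endpoints of ``dimension`` (2 static + 4 shifted)
    """

    dimension: str
    kind: str

    @property
    def n_classes(self) -> int:
        return 6 if self.kind == "sixway" else 2


def select_problem_trials(session: Session, problem: DecodingProblem) -> tuple[list[Trial], list[str]]:
    """Trials entering the problem plus the ordered class (endpoint) list."""
    layout = session.layout
    if problem.kind == "static":
        from .simulate import HORIZONTAL_STATIC, SAGITTAL_STATIC
        ids = list(HORIZONTAL_STATIC if problem.dimension == "horizontal" else SAGITTAL_STATIC)
        trials = [t for t in session.trials
                  if t.condition == "static" and t.final_endpoint_id in ids]
    elif problem.kind.startswith("shifted:"):
        parent = problem.kind.split(":", 1)[1]
        if layout.dimension_of(parent) != problem.dimension:
            raise ValueError("shifted-pair parent inconsistent with dimension")
        ids = list(layout.children(parent))
        trials = [t for t in session.trials
                  if t.condition == "shifted" and t.final_endpoint_id in ids]
    elif problem.kind == "sixway":
        from .simulate import HORIZONTAL_STATIC, SAGITTAL_STATIC
        statics = HORIZONTAL_STATIC if problem.dimension == "horizontal" else SAGITTAL_STATIC
        ids = list(statics)
        for s in statics:
            ids.extend(layout.children(s))
        trials = [t for t in session.trials if t.final_endpoint_id in ids]
    else:
        raise ValueError(f"unknown problem kind {problem.kind!r}")
    present = {t.final_endpoint_id for t in trials}
    if not set(ids) <= present:
        raise ValueError(f"empty class(es): {sorted(set(ids) - present)}")
    return trials, ids


def normalize_trial(trial: Trial) -> NormalizedTrial:
    """Resample the movement segment onto 100 equally spaced points of
    normalized movement time, by linear interpolation of each of the 6
    feature series (index xyz, wrist xyz)."""
    mask = (trial.t >= trial.movement_onset_s - 1e-9) & (trial.t <= trial.touch_s + 1e-9)
    t = trial.t[mask]
    if len(t) < 2:
        raise ValueError("movement segment too short to normalize")
    raw = np.concatenate([trial.index_xyz[mask], trial.wrist_xyz[mask]], axis=1)
    xi = np.linspace(t[0], t[-1], N_NORM)
    feats = np.column_stack([np.interp(xi, t, raw[:, k]) for k in range(K_FEATURES)])
    return NormalizedTrial(feats, trial.final_endpoint_id, trial.condition,
                           trial.dimension, trial.trial_id, trial.participant_id)


def extract_chunks(norm: NormalizedTrial, T: int = T_WINDOW, stride: int = TRAIN_STRIDE,
                   n_samples: Optional[int] = None) -> list[Chunk]:
    """Windows of ``T`` consecutive samples starting at 0, stride, 2*stride, ...
    while they fit inside the trial; each carries the index of its last
    sample (``end_index``)."""
    n = n_samples if n_samples is not None else len(norm.features)
    if T > n:
        raise ValueError("window longer than the trial")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    chunks = []
    for start in range(0, n - T + 1, stride):
        chunks.append(Chunk(norm.features[start:start + T], start + T - 1,
                            norm.trial_id, norm.final_endpoint_id))
    return chunks


def _pre_movement_features(trial: Trial, window_s: float = 0.5) -> Optional[np.ndarray]:
    """The 500 ms of raw (un-normalized) kinematics before movement onset."""
    n_samp = int(round(window_s * 100))
    mask = trial.t < trial.movement_onset_s - 1e-9
    raw = np.concatenate([trial.index_xyz[mask], trial.wrist_xyz[mask]], axis=1)
    if len(raw) < n_samp:
        return None
    return raw[-n_samp:]


def build_goal_dataset(
    trials: Sequence[Trial],
    class_ids: Sequence[str],
    window: str = "all",
    T: int = T_WINDOW,
    stride: int = TRAIN_STRIDE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chunked dataset for goal classification.

    window="all" chunks the normalized movement; window="pre_movement" chunks
    the raw 500 ms (50 samples) preceding movement onset instead — the
    control analysis checking that nothing before the reach predicts the goal.

    Returns (X, y, end_indices) with X of shape (n_chunks, T, K) and y the
    integer class of each chunk's *trial* final endpoint.
    """
    label_of = {cid: i for i, cid in enumerate(class_ids)}
    X, y, ends = [], [], []
    for tr in trials:
        if window == "pre_movement":
            feats = _pre_movement_features(tr)
            if feats is None:
                continue
            norm = NormalizedTrial.__new__(NormalizedTrial)
            norm.features = feats
            norm.final_endpoint_id = tr.final_endpoint_id
            norm.condition, norm.dimension = tr.condition, tr.dimension
            norm.trial_id, norm.participant_id = tr.trial_id, tr.participant_id
            chunks = extract_chunks(norm, T=T, stride=stride, n_samples=len(feats))
        elif window == "all":
            chunks = extract_chunks(normalize_trial(tr), T=T, stride=stride)
        else:
            raise ValueError("window must be 'all' or 'pre_movement'")
        for ch in chunks:
            X.append(ch.data)
            y.append(label_of[ch.final_endpoint_id])
            ends.append(ch.end_index)
    return np.array(X), np.array(y), np.array(ends)


@dataclass
class AccuracyCurve:
    """Time-resolved classification accuracy: one value per window end
    position (stride-1 inference), optionally fold-resolved."""

    end_indices: np.ndarray
    accuracy: np.ndarray
    chance: float
    per_fold: Optional[np.ndarray] = None  # (n_folds, n_nodes)
    participant_id: str = ""

    @property
    def pct_movement(self) -> np.ndarray:
        """Window end positions as % of normalized movement."""
        return self.end_indices / (N_NORM - 1) * 100.0


@dataclass
class RegressionScores:
    """Per-component R^2 of future-trajectory prediction."""

    offset: int
    r2_per_component: np.ndarray  # (6,) index xyz then wrist xyz
    cluster: str = ""

    @property
    def r2_index_xyz(self) -> np.ndarray:
        return self.r2_per_component[:3]


class _Standardizer:
    """Per-feature z-scoring fitted on training chunks only."""

    def fit(self, X: np.ndarray) -> "_Standardizer":
        flat = X.reshape(-1, X.shape[-1])
        self.mean_ = flat.mean(axis=0)
        self.std_ = flat.std(axis=0)
        self.std_[self.std_ < 1e-12] = 1.0
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.std_


def chance_level(n_classes: int) -> float:
    """Theoretical chance accuracy 1/n for balanced n-class problems
    (0.5 for pairs, 0.1667 — displayed 0.16 — for the 6-way problem)."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    return 1.0 / n_classes


def train_goal_classifier(X: np.ndarray, y: np.ndarray, config: TrainConfig,
                          n_classes: Optional[int] = None) -> GRUNet:
    """Train the GRU goal classifier on (already standardized) chunks."""
    n_classes = n_classes if n_classes is not None else int(np.max(y)) + 1
    return train_network(X, y, task="classify", n_out=n_classes, config=config)


def evaluate_accuracy_curve(model: GRUNet, test_trials: Sequence[Trial],
                            class_ids: Sequence[str],
                            standardizer: Optional[_Standardizer] = None,
                            window: str = "all") -> AccuracyCurve:
    """Stride-1 accuracy per window end position over the test trials."""
    X, y, ends = build_goal_dataset(test_trials, class_ids, window=window,
                                    stride=INFER_STRIDE)
    if standardizer is not None:
        X = standardizer.transform(X)
    pred = model.predict(X)
    nodes = np.unique(ends)
    acc = np.array([(pred[ends == e] == y[ends == e]).mean() for e in nodes])
    return AccuracyCurve(nodes, acc, chance_level(len(class_ids)))


def _stratified_trial_folds(trials: Sequence[Trial], class_ids: Sequence[str],
                            n_folds: int, seed: int):
    labels = np.array([class_ids.index(t.final_endpoint_id) for t in trials])
    counts = np.bincount(labels, minlength=len(class_ids))
    if counts.min() < n_folds:
        raise ValueError(
            f"cannot stratify: smallest class has {counts.min()} trials for {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(trials)), labels))


def cross_validated_goal_decoding(
    session_or_trials,
    problem: Optional[DecodingProblem] = None,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
    n_folds: int = 5,
    window: str = "all",
    class_ids: Optional[Sequence[str]] = None,
    permute_labels: bool = False,
) -> AccuracyCurve:
    """Fivefold stratified goal decoding.

    Folds are split at the trial level (all chunks of a trial stay together),
    stratified on the final endpoint.  Each fold trains a fresh classifier on
    stride-4 chunks of its training trials and evaluates a stride-1 accuracy
    curve on its test trials; the returned curve is the pointwise fold mean,
    with per-fold curves attached.

    ``permute_labels=True`` randomly permutes trial labels before splitting —
    the empirical-chance control.
    """
    config = config or TrainConfig()
    if isinstance(session_or_trials, Session):
        if problem is None:
            raise ValueError("a DecodingProblem is required with a Session input")
        trials, class_ids = select_problem_trials(session_or_trials, problem)
    else:
        trials = list(session_or_trials)
        if class_ids is None:
            class_ids = sorted({t.final_endpoint_id for t in trials})
    class_ids = list(class_ids)

    rng = np.random.default_rng(seed)
    if permute_labels:
        trials = _permuted_label_view(trials, rng)

    folds = _stratified_trial_folds(trials, class_ids, n_folds, int(rng.integers(2**31 - 1)))
    per_fold = []
    nodes = None
    for k, (tr_idx, te_idx) in enumerate(folds):
        train_trials = [trials[i] for i in tr_idx]
        test_trials = [trials[i] for i in te_idx]
        X, y, _ = build_goal_dataset(train_trials, class_ids, window=window)
        std = _Standardizer().fit(X)
        fold_cfg = TrainConfig(**{**config.__dict__, "seed": int(rng.integers(2**31 - 1))})
        model = train_goal_classifier(std.transform(X), y, fold_cfg,
                                      n_classes=len(class_ids))
        curve = evaluate_accuracy_curve(model, test_trials, class_ids,
                                        standardizer=std, window=window)
        per_fold.append(curve.accuracy)
        nodes = curve.end_indices
    per_fold = np.stack(per_fold)
    return AccuracyCurve(nodes, per_fold.mean(axis=0), chance_level(len(class_ids)),
                         per_fold=per_fold)


def empirical_chance_curve(
    session_or_trials,
    problem: Optional[DecodingProblem] = None,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
    n_folds: int = 5,
    n_perm: int = 10,
    class_ids: Optional[Sequence[str]] = None,
) -> AccuracyCurve:
    """Empirical chance level of a goal-decoding problem.

    Runs the usual cross-validated decoding once (true labels), collects the
    per-trial stride-1 predictions, and scores them against ``n_perm`` random
    permutations of the trial labels.  Because the predictions are fixed and
    the permuted label marginal matches the class marginal, the expected
    accuracy is exactly the chance level (1/n for balanced classes) —
    unlike the permute-then-retrain null, which at small trials-per-class is
    biased above 1/n whenever the features form separable clusters (the
    retrained model recovers the majority permuted label of each cluster).
    The permute-then-retrain null remains available via
    ``cross_validated_goal_decoding(..., permute_labels=True)``.
    """
    config = config or TrainConfig()
    if isinstance(session_or_trials, Session):
        if problem is None:
            raise ValueError("a DecodingProblem is required with a Session input")
        trials, class_ids = select_problem_trials(session_or_trials, problem)
    else:
        trials = list(session_or_trials)
        if class_ids is None:
            class_ids = sorted({t.final_endpoint_id for t in trials})
    class_ids = list(class_ids)
    rng = np.random.default_rng(seed)
    folds = _stratified_trial_folds(trials, class_ids, n_folds, int(rng.integers(2**31 - 1)))

    n_trials = len(trials)
    labels = np.array([class_ids.index(t.final_endpoint_id) for t in trials])
    pred_matrix = None
    for tr_idx, te_idx in folds:
        train_trials = [trials[i] for i in tr_idx]
        X, y, _ = build_goal_dataset(train_trials, class_ids)
        std = _Standardizer().fit(X)
        fold_cfg = TrainConfig(**{**config.__dict__, "seed": int(rng.integers(2**31 - 1))})
        model = train_goal_classifier(std.transform(X), y, fold_cfg,
                                      n_classes=len(class_ids))
        for i in te_idx:
            Xi, _, ends = build_goal_dataset([trials[i]], class_ids, stride=INFER_STRIDE)
            pred = model.predict(std.transform(Xi))
            if pred_matrix is None:
                pred_matrix = np.zeros((n_trials, len(ends)), dtype=int)
                nodes = ends
            pred_matrix[i] = pred
    acc_sum = np.zeros(pred_matrix.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n_trials)
        acc_sum += (pred_matrix == labels[perm][:, None]).mean(axis=0)
    return AccuracyCurve(nodes, acc_sum / n_perm, chance_level(len(class_ids)))


def _permuted_label_view(trials: list[Trial], rng: np.random.Generator) -> list[Trial]:
    """Shallow trial copies with final-endpoint labels permuted across trials."""
    import copy
    perm = rng.permutation(len(trials))
    out = []
    for i, tr in enumerate(trials):
        clone = copy.copy(tr)
        clone.final_endpoint_id = trials[perm[i]].final_endpoint_id
        out.append(clone)
    return out


# -- trajectory regression -------------------------------------------------

def build_regression_dataset(trials: Sequence[Trial], offset: int,
                             stride: int = TRAIN_STRIDE) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chunks paired with the 6 feature values ``offset`` samples after each
    chunk's end; chunks whose future sample falls outside the trial are
    dropped."""
    X, Y, ends = [], [], []
    for tr in trials:
        norm = normalize_trial(tr)
        for ch in extract_chunks(norm, stride=stride):
            fut = ch.end_index + offset
            if fut > N_NORM - 1:
                continue
            X.append(ch.data)
            Y.append(norm.features[fut])
            ends.append(ch.end_index)
    if not X:
        raise ValueError(f"offset {offset} leaves no valid chunks")
    return np.array(X), np.array(Y), np.array(ends)


def train_trajectory_regressor(X: np.ndarray, Y: np.ndarray, config: TrainConfig) -> GRUNet:
    """Train the GRU future-trajectory regressor (6 linear outputs, MSE)."""
    return train_network(X, Y, task="regress", n_out=K_FEATURES, config=config)


def evaluate_r2(model: GRUNet, test_trials: Sequence[Trial], offset: int,
                x_std: _Standardizer, y_std: _Standardizer) -> RegressionScores:
    """Per-component R^2 pooled over all valid stride-1 test chunks."""
    X, Y, _ = build_regression_dataset(test_trials, offset, stride=INFER_STRIDE)
    pred_std = model.forward(x_std.transform(X))
    pred = pred_std * y_std.std_ + y_std.mean_
    r2 = np.array([r2_score(Y[:, k], pred[:, k]) for k in range(K_FEATURES)])
    return RegressionScores(offset, r2)


def cluster_trials(session: Session, cluster: str) -> list[Trial]:
    """Trials of a target cluster: one static target plus its two shifted
    children (e.g. cluster "left" = static left + both left-shifted goals)."""
    if cluster not in CLUSTERS:
        raise ValueError(f"cluster must be one of {CLUSTERS}")
    kids = set(session.layout.children(cluster))
    return [t for t in session.trials
            if t.final_endpoint_id == cluster or t.final_endpoint_id in kids]


def cross_validated_regression(
    trials: Sequence[Trial],
    offset: int,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
    n_folds: int = 5,
) -> RegressionScores:
    """Fold-averaged per-component R^2 for one offset on one trial set.

    Folds are trial-level, stratified on final endpoint so every fold sees
    all goals of the cluster; targets are z-scored on the training folds and
    predictions mapped back before scoring.
    """
    config = config or TrainConfig()
    trials = list(trials)
    class_ids = sorted({t.final_endpoint_id for t in trials})
    rng = np.random.default_rng(seed)
    folds = _stratified_trial_folds(trials, class_ids, n_folds, int(rng.integers(2**31 - 1)))
    scores = []
    for tr_idx, te_idx in folds:
        train_trials = [trials[i] for i in tr_idx]
        test_trials = [trials[i] for i in te_idx]
        X, Y, _ = build_regression_dataset(train_trials, offset)
        x_std = _Standardizer().fit(X)
        y_std = _Standardizer().fit(Y)
        fold_cfg = TrainConfig(**{**config.__dict__, "seed": int(rng.integers(2**31 - 1))})
        model = train_trajectory_regressor(x_std.transform(X), y_std.transform(Y), fold_cfg)
        scores.append(evaluate_r2(model, test_trials, offset, x_std, y_std).r2_per_component)
    mean = np.mean(scores, axis=0)
    return RegressionScores(offset, mean)
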