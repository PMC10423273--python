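"""Statistics on accuracy time-courses and decoding summaries.

Implements the group-level comparisons applied to decoding output: a
pointwise two-sample Hotelling's T^2 test along accuracy curves with
family-wise control by max-statistic permutation, chance-crossing times,
95% confidence ellipses of 2D summaries (eigen-decomposition of the sample
covariance, chi-square scaled axes), Kolmogorov–Smirnov comparison of R^2
distributions, and Bonferroni-corrected two-sample t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CurveComparison",
    "EllipseSummary",
    "hotelling_curve_test",
    "chance_crossing_time",
    "confidence_ellipse",
    "compare_r2_distributions",
    "corrected_two_sample_test",
]


@dataclass
class CurveComparison:
    """Pointwise two-sample curve comparison with family-wise control."""

    statistic: np.ndarray  # per-node T^2 (squared two-sample t for scalars)
    threshold: float  # (1 - alpha) quantile of the permutation max statistic
    significant: np.ndarray  # bool per node
    intervals_pct: list[tuple[float, float]]  # significant runs, % of movement
    alpha: float
    n_permutations: int


def _t2_nodes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sample squared-t statistic at every node (pooled variance)."""
    n1, n2 = len(a), len(b)
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    s2 = ((a - m1) ** 2).sum(axis=0) + ((b - m2) ** 2).sum(axis=0)
    s2 = s2 / (n1 + n2 - 2)
    s2 = np.maximum(s2, 1e-300)
    return (m1 - m2) ** 2 / (s2 * (1.0 / n1 + 1.0 / n2))


def hotelling_curve_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    node_pct: Optional[np.ndarray] = None,
) -> CurveComparison:
    """Compare two groups of per-participant accuracy curves node by node.

    The per-node statistic is the two-sample Hotelling T^2, which for the
    scalar accuracy reduces to the squared pooled-variance t statistic.  The
    family-wise threshold is the (1 - alpha) quantile of the maximum node
    statistic under random relabelling of participants into the two groups
    (``n_perm`` seeded draws), so the probability of any node exceeding it
    under the null is ~alpha.  Contiguous supra-threshold runs are reported
    as [start%, end%] intervals of normalized movement.
    """
    a = np.asarray(curves_a, dtype=float)
    b = np.asarray(curves_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("curve groups must be 2D with equal node counts")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two curves per group")
    n_nodes = a.shape[1]
    obs = _t2_nodes(a, b)

    pooled = np.concatenate([a, b], axis=0)
    n1 = len(a)
    rng = np.random.default_rng(seed)
    max_stats = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(pooled))
        max_stats[i] = _t2_nodes(pooled[perm[:n1]], pooled[perm[n1:]]).max()
    threshold = float(np.quantile(max_stats, 1.0 - alpha))
    sig = obs > threshold

    if node_pct is None:
        node_pct = np.linspace(0.0, 100.0, n_nodes)
    intervals = []
    start = None
    for i, flag in enumerate(sig):
        if flag and start is None:
            start = i
        if (not flag or i == n_nodes - 1) and start is not None:
            end = i if flag else i - 1
            intervals.append((float(node_pct[start]), float(node_pct[end])))
            start = None
    return CurveComparison(obs, threshold, sig, intervals, alpha, n_perm)


def chance_crossing_time(
    curve: np.ndarray,
    level: float = 0.5,
    run_length: int = 3,
    node_pct: Optional[np.ndarray] = None,
) -> Optional[float]:
    """First % of movement at which the curve rises above ``level``.

    The crossing must open a run of at least ``run_length`` consecutive
    nodes strictly above the level; returns None if the curve never does.
    """
    curve = np.asarray(curve, dtype=float)
    if np.any(curve < -1e-9) or np.any(curve > 1 + 1e-9):
        raise ValueError("accuracy curve must lie in [0, 1]")
    if node_pct is None:
        node_pct = np.linspace(0.0, 100.0, len(curve))
    above = curve > level
    run = 0
    first = None
    for i in range(len(curve) - 1, -1, -1):
        run = run + 1 if above[i] else 0
        if run >= run_length:
            first = float(node_pct[i])
    return first


@dataclass
class EllipseSummary:
    """Confidence ellipse of a 2D point cloud."""

    center: np.ndarray
    eigenvalues: np.ndarray  # descending, covariance eigenvalues
    eigenvectors: np.ndarray  # columns, matching eigenvalues
    area: float  # pi * a * b with chi-square scaled semi-axes
    area_sigma: float  # pi * sqrt(l1 * l2), raw one-sigma axes
    coverage: float
    n_points: int
    degenerate: bool = False


def confidence_ellipse(points: np.ndarray, coverage: float = 0.95) -> EllipseSummary:
    """Confidence ellipse for 2D (approximately normal) data.

    Eigenvectors of the sample covariance give the axis directions, the
    eigenvalues the variance along them; semi-axes are scaled by the square
    root of the chi-square(2) quantile at ``coverage`` so the ellipse covers
    that fraction of the population.  Collinear input is allowed and flagged
    (zero minor axis, zero area).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need >= 3 two-dimensional points")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    scale2 = stats.chi2.ppf(coverage, df=2)
    a, b = np.sqrt(scale2 * evals)
    return EllipseSummary(
        center=center,
        eigenvalues=evals,
        eigenvectors=evecs,
        area=float(np.pi * a * b),
        area_sigma=float(np.pi * np.sqrt(evals[0] * evals[1])),
        coverage=coverage,
        n_points=len(pts),
        degenerate=bool(evals[1] < 1e-12 * max(evals[0], 1.0)),
    )


def points_in_ellipse(points: np.ndarray, ellipse: EllipseSummary) -> np.ndarray:
    """Boolean mask of points inside the ellipse (Mahalanobis test)."""
    pts = np.asarray(points, dtype=float) - ellipse.center
    proj = pts @ ellipse.eigenvectors
    scale2 = stats.chi2.ppf(ellipse.coverage, df=2)
    lam = np.maximum(ellipse.eigenvalues, 1e-300)
    return (proj ** 2 / lam).sum(axis=1) <= scale2


def compare_r2_distributions(scores_a: Sequence[float], scores_b: Sequence[float]):
    """Two-sample Kolmogorov–Smirnov test on pooled R^2 values."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need at least five values per sample")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def corrected_two_sample_test(a: Sequence[float], b: Sequence[float],
                              alpha: float = 0.05, n_comparisons: int = 1):
    """Welch two-sample t-test with Bonferroni-corrected significance.

    Returns (statistic, p, significant) where significance is declared at
    alpha / n_comparisons (e.g. 0.05 / 4 = 0.0125).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):  # zero variance in both groups (e.g. identical inputs)
        t, p = 0.0, 1.0
    return float(t), float(p), bool(p < alpha / n_comparisons)
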