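"""Behavioral and brain-environment coupling metrics.

Quantifies how richly the agent moves (Shannon entropy of the joint motor
signals; box-counting fractal dimension of the trajectory image) and how
tightly neural variables track the environment (Pearson correlations
between wall distance, network-mean activity, and network-mean threshold),
plus the group-comparison statistics used to contrast model variants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from skimage.draw import line as _pixel_line

from embodied_gh.embodiment import Arena, RunRecord

__all__ = [
    "RunMetrics",
    "movement_entropy",
    "fractal_dimension",
    "wall_distance_series",
    "coupling_correlations",
    "compare_groups",
    "one_sample_correlation_test",
    "compute_run_metrics",
    "TTestResult",
]


@dataclass(frozen=True)
class RunMetrics:
    """Per-run summary of neural, behavioral, and coupling measures.

    ``activity_node_sd`` is the across-node SD of binarized activity at
    each epoch, averaged over epochs; ``activity_temporal_sd`` is the
    alternative reading (SD over time of the network-mean activity) and is
    reported alongside.  ``threshold_sd`` / ``threshold_cv`` are the SD and
    coefficient of variation over time of the network-mean threshold.
    """

    mean_activity: float
    activity_node_sd: float
    activity_temporal_sd: float
    movement_entropy: float
    fractal_dimension: float
    r_wall_activity: float
    r_wall_threshold: float
    r_threshold_activity: float
    threshold_sd: float
    threshold_cv: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TTestResult:
    """A t statistic with its degrees of freedom and two-sided p-value."""

    statistic: float
    df: int
    p_value: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.statistic, self.df, self.p_value))


def movement_entropy(
    v_series: np.ndarray, h_series: np.ndarray, n_bins: int = 16
) -> float:
    """Shannon entropy (bits) of the joint (move, turn) command histogram.

    The two series are discretized into ``n_bins`` equal-width bins per
    axis over each series' observed range; a constant axis collapses to a
    single bin.  The joint form (rather than the sum of marginal
    entropies) captures dependence between the two motor signals.
    """
    v = np.asarray(v_series, dtype=float)
    h = np.asarray(h_series, dtype=float)
    if v.size == 0 or v.shape != h.shape:
        raise ValueError("v and h series must be non-empty and equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    bins_v = 1 if v.min() == v.max() else n_bins
    bins_h = 1 if h.min() == h.max() else n_bins
    hist, _, _ = np.histogram2d(v, h, bins=[bins_v, bins_h])
    p = hist.ravel() / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _rasterize(trajectory: np.ndarray, arena: Arena, resolution: int) -> np.ndarray:
    """Draw the trajectory polyline onto a binary pixel grid."""
    pts = np.asarray(trajectory, dtype=float)
    ix = np.clip((pts[:, 0] / arena.width * resolution).astype(int), 0, resolution - 1)
    iy = np.clip((pts[:, 1] / arena.height * resolution).astype(int), 0, resolution - 1)
    grid = np.zeros((resolution, resolution), dtype=bool)
    for k in range(len(pts) - 1):
        rr, cc = _pixel_line(iy[k], ix[k], iy[k + 1], ix[k + 1])
        grid[rr, cc] = True
    grid[iy[-1], ix[-1]] = True
    return grid


def _box_counts(grid: np.ndarray, box_sizes: list[int]) -> np.ndarray:
    res = grid.shape[0]
    counts = []
    for s in box_sizes:
        blocks = grid.reshape(res // s, s, res // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    return np.array(counts)


def fractal_dimension(
    trajectory: np.ndarray, arena: Arena, resolution: int = 1024
) -> float:
    """Box-counting dimension of the rasterized trajectory.

    The polyline is drawn onto a resolution x resolution binary grid
    covering the arena (Bresenham segment drawing); occupied boxes N(s)
    are counted for box sizes s = resolution/2^k, k = 1 .. log2(res) - 2,
    and the dimension is the negative least-squares slope of log2 N(s)
    against log2 s.  The two largest box sizes are excluded from the fit
    (standard box-counting practice: the coarsest scales saturate).
    Returns 1 for a straight line and 2 for a filled plane, up to raster
    discretisation.  An all-identical trajectory is degenerate and returns
    0 with a warning.
    """
    pts = np.asarray(trajectory, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("trajectory must be a sequence of >= 2 (x, y) points")
    if resolution < 16 or resolution & (resolution - 1):
        raise ValueError("resolution must be a power of 2, >= 16")
    if np.allclose(pts, pts[0]):
        warnings.warn("degenerate trajectory (all points identical); dimension 0")
        return 0.0
    grid = _rasterize(pts, arena, resolution)
    n_levels = int(math.log2(resolution))
    box_sizes = [resolution // 2 ** k for k in range(1, n_levels - 1)]
    counts = _box_counts(grid, box_sizes)
    # drop the two largest boxes from the fit
    log_s = np.log2(box_sizes[2:])
    log_n = np.log2(counts[2:])
    slope = np.polyfit(log_s, log_n, 1)[0]
    return float(-slope)


def wall_distance_series(trajectory: np.ndarray, arena: Arena) -> np.ndarray:
    """Per-point minimum Euclidean distance to the four bounding walls."""
    pts = np.asarray(trajectory, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    if np.any(x < 0) or np.any(x > arena.width) or np.any(y < 0) or np.any(y > arena.height):
        raise ValueError("trajectory point outside arena")
    return np.minimum.reduce([x, arena.width - x, y, arena.height - y])


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 (flagged by a warning) for constant series."""
    if a.std() == 0 or b.std() == 0:
        warnings.warn("constant series in correlation; reporting r = 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def coupling_correlations(record: RunRecord) -> tuple[float, float, float]:
    """Brain-environment coupling correlations over epochs.

    Returns Pearson correlations of (wall distance, mean activity),
    (wall distance, mean threshold), and (mean threshold, mean activity),
    computed on the raw epoch series.
    """
    if record.epochs < 3:
        raise ValueError("need >= 3 epochs for correlations")
    wall = record.wall_distance
    act = record.mean_activity_series
    thr = record.mean_threshold_series
    return (
        _safe_pearson(wall, act),
        _safe_pearson(wall, thr),
        _safe_pearson(thr, act),
    )


def compare_groups(metric_a, metric_b) -> TTestResult:
    """Pooled-variance two-sample t-test between two groups of run metrics.

    df = n_a + n_b - 2 (58 for two groups of 30); two-sided p-value.  With
    zero pooled variance the result is degenerate: t = 0 if the means are
    equal, +-inf otherwise.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    df = a.size + b.size - 2
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled == 0:
        if a.mean() == b.mean():
            return TTestResult(0.0, df, 1.0, degenerate=True)
        t = math.inf if a.mean() > b.mean() else -math.inf
        return TTestResult(t, df, 0.0, degenerate=True)
    t = (a.mean() - b.mean()) / math.sqrt(pooled * (1 / a.size + 1 / b.size))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


def one_sample_correlation_test(r_values) -> TTestResult:
    """One-sample t-test of Fisher-z-transformed correlations against 0.

    df = n - 1.  |r| = 1 overflows the transform and is rejected; zero
    variance across runs yields a degenerate result (t = 0 when the mean
    is 0, +-inf otherwise).
    """
    r = np.asarray(r_values, dtype=float)
    if r.size < 3:
        raise ValueError("need >= 3 correlation values")
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| = 1 overflows the Fisher z-transform")
    z = np.arctanh(r)
    df = r.size - 1
    if z.std(ddof=1) == 0:
        if z.mean() == 0:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        t = math.inf if z.mean() > 0 else -math.inf
        return TTestResult(t, df, 0.0, degenerate=True)
    t = z.mean() / (z.std(ddof=1) / math.sqrt(r.size))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


def compute_run_metrics(
    record: RunRecord,
    n_bins: int = 16,
    resolution: int = 1024,
) -> RunMetrics:
    """All per-run metrics from a closed-loop run record."""
    act = record.activity.astype(float)
    mean_act = float(act.mean())
    node_sd = float(act.std(axis=1).mean())
    temporal_sd = float(act.mean(axis=1).std())
    entropy = movement_entropy(record.v, record.h, n_bins=n_bins)
    fd = fractal_dimension(record.trajectory, record.arena, resolution=resolution)
    r_wa, r_wt, r_ta = coupling_correlations(record)
    mean_thr = record.mean_threshold_series
    thr_sd = float(mean_thr.std())
    thr_mean = float(mean_thr.mean())
    thr_cv = float(thr_sd / abs(thr_mean)) if thr_mean != 0 else math.inf
    return RunMetrics(
        mean_activity=mean_act,
        activity_node_sd=node_sd,
        activity_temporal_sd=temporal_sd,
        movement_entropy=entropy,
        fractal_dimension=fd,
        r_wall_activity=r_wa,
        r_wall_threshold=r_wt,
        r_threshold_activity=r_ta,
        threshold_sd=thr_sd,
        threshold_cv=thr_cv,
    )
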