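"""Ordination, lineage trajectories, stability classification and
structure–function statistics.

NMDS is Kruskal's non-metric MDS (SMACOF with monotone regression) on a
Bray–Curtis dissimilarity matrix, reporting Stress-1; restarts are looped
explicitly over derived seeds so that results are deterministic and the
best-of-n stress can only improve as restarts are added.

The stability classifier is an explicit, threshold-based surrogate for the
visual grouping of lineages into stable / drifting / successional dynamics:
it looks at the mean adjacent-step Bray–Curtis dissimilarity, its trend
across the series, and whether the dominant community category switches
between the first and last steps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import smacof

from .community_metrics import DynamicsSummary
from .io_formats import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinationResult",
    "TrajectoryStats",
    "BreakpointFit",
    "StabilityLabel",
    "nmds",
    "lineage_trajectory",
    "trajectory_parallelism",
    "classify_stability",
    "pearson_trend",
    "correlate_structure_function",
    "breakpoint_regression",
]


@dataclass
class OrdinationResult:
    coords: pd.DataFrame  # samples x k, centered per axis
    stress: float  # Kruskal Stress-1 in [0, 1]
    seed: int
    n_restarts: int


@dataclass
class TrajectoryStats:
    lineage_id: str
    segment_lengths: list[float]
    total_length: float
    net_displacement: float
    direction_angle: float  # radians of the first->last displacement vector


@dataclass
class BreakpointFit:
    breakpoint: float
    slope_left: float
    slope_right: float
    intercept_left: float
    rss: float
    rss_single_line: float
    p_left: float
    p_right: float
    flags: tuple[str, ...] = ()


@dataclass
class StabilityLabel:
    lineage_id: str
    label: str  # stable | drifting | successional | unclassified
    evidence: dict = field(default_factory=dict)


def nmds(
    dissimilarity: np.ndarray | pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 32,
    max_iter: int = 300,
) -> OrdinationResult:
    """Non-metric MDS of a square symmetric dissimilarity matrix.

    Runs ``n_restarts`` independent SMACOF fits from seeds derived from
    ``seed`` and keeps the configuration with the lowest Stress-1.
    Coordinates are centered per axis.  An all-zero matrix (all samples
    identical) short-circuits to coincident points with stress 0.
    """
    labels = None
    if isinstance(dissimilarity, pd.DataFrame):
        labels = list(dissimilarity.index)
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = d.shape[0]
    if labels is None:
        labels = list(range(n))

    if np.all(d == 0):
        coords = pd.DataFrame(np.zeros((n, k)), index=labels,
                              columns=[f"axis{i+1}" for i in range(k)])
        return OrdinationResult(coords, 0.0, seed, n_restarts)

    best_pos, best_stress = None, math.inf
    for i in range(n_restarts):
        pos, stress = smacof(
            d,
            metric=False,
            n_components=k,
            n_init=1,
            max_iter=max_iter,
            random_state=seed + i,
            normalized_stress=True,
        )
        if stress < best_stress:
            best_pos, best_stress = pos, stress
    best_pos = best_pos - best_pos.mean(axis=0, keepdims=True)
    coords = pd.DataFrame(best_pos, index=labels,
                          columns=[f"axis{i+1}" for i in range(k)])
    return OrdinationResult(coords, float(best_stress), seed, n_restarts)


def lineage_trajectory(
    ordination: OrdinationResult | pd.DataFrame,
    sample_order: list,
    lineage_id: str = "",
) -> TrajectoryStats:
    """Path statistics of one lineage through ordination space.

    ``sample_order`` lists the lineage's sample labels in propagation order
    (F2..F6).  Segment lengths are Euclidean; the direction angle is the
    atan2 of the first-to-last displacement.
    """
    coords = ordination.coords if isinstance(ordination, OrdinationResult) else ordination
    missing = [s for s in sample_order if s not in coords.index]
    if missing:
        raise ValueError(f"samples missing from ordination: {missing}")
    if len(sample_order) < 2:
        raise ValueError("need at least two steps for a trajectory")
    pts = coords.loc[sample_order].to_numpy(dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    net_vec = pts[-1] - pts[0]
    return TrajectoryStats(
        lineage_id=lineage_id,
        segment_lengths=[float(s) for s in seg],
        total_length=float(seg.sum()),
        net_displacement=float(np.linalg.norm(net_vec)),
        direction_angle=float(math.atan2(net_vec[1], net_vec[0])) if pts.shape[1] >= 2
        else (0.0 if net_vec[0] >= 0 else math.pi),
    )


def trajectory_parallelism(trajectories: list[TrajectoryStats]) -> float:
    """Mean pairwise cosine of trajectory direction angles.

    1 means perfectly parallel, 0 orthogonal on average, −1 antiparallel.
    Zero-net-displacement trajectories carry no direction and are excluded
    with a warning.
    """
    usable = [t for t in trajectories if t.net_displacement > 0]
    dropped = len(trajectories) - len(usable)
    if dropped:
        logger.warning("excluded %d zero-displacement trajectories", dropped)
    if len(usable) < 2:
        raise ValueError("need >= 2 trajectories with nonzero net displacement")
    angles = np.array([t.direction_angle for t in usable])
    i, j = np.triu_indices(len(angles), k=1)
    return float(np.mean(np.cos(angles[i] - angles[j])))


def pearson_trend(values, steps) -> tuple[float, float, tuple[str, ...]]:
    """Pearson correlation of a series against step position.

    Returns (r, two-sided p from the t distribution with n−2 df, flags).
    A zero-variance input yields NaN with an ``undefined`` flag.
    """
    x = np.asarray(steps, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), ("undefined_zero_variance",)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), ()


def correlate_structure_function(
    bc_values, delta_final_ph, use_abs: bool = True
) -> tuple[float, float, int]:
    """Pearson correlation between adjacent-step Bray–Curtis dissimilarity and
    the adjacent-step change in final pH, pooled over lineages and pairs.

    ``use_abs`` (default) correlates against |Δ final pH|, i.e. the magnitude
    of the functional change; pairs with a missing member must already have
    been dropped by the caller.
    """
    bc = np.asarray(bc_values, dtype=float)
    dph = np.asarray(delta_final_ph, dtype=float)
    mask = np.isfinite(bc) & np.isfinite(dph)
    bc, dph = bc[mask], dph[mask]
    if len(bc) < 3:
        raise ValueError("need >= 3 pooled pairs")
    if use_abs:
        dph = np.abs(dph)
    r, p = stats.pearsonr(dph, bc)
    return float(r), float(p), int(len(bc))


def classify_stability(
    summary: DynamicsSummary,
    config: PipelineConfig | None = None,
) -> StabilityLabel:
    """Threshold-based lineage stability label.

    * ``stable``: mean adjacent BC below ``stability_bc_low`` (default 0.08),
    * ``successional``: the dominant community category differs between the
      first and last steps, or the mean BC is at least ``stability_bc_high``
      (default 0.20) with a decreasing BC trend (succession completes and the
      community settles),
    * ``drifting``: everything else;
    * ``unclassified`` when fewer than 3 adjacent pairs are available.

    The evidence tuple (mean BC, BC trend r, dominance switch) is always
    attached.
    """
    config = config or PipelineConfig()
    bc = [v for _, v in summary.bc_adjacent]
    doms = [summary.dominant_taxon_series[s]
            for s in sorted(summary.dominant_taxon_series)
            if s != "F1"]
    switch = bool(doms and doms[0] != doms[-1])
    if len(bc) < 3:
        return StabilityLabel(summary.lineage_id, "unclassified",
                              {"mean_bc": float("nan"), "bc_trend_r": float("nan"),
                               "dominance_switch": switch})
    mean_bc = float(np.mean(bc))
    r, _, flags = pearson_trend(bc, np.arange(len(bc)))
    evidence = {"mean_bc": mean_bc, "bc_trend_r": r, "dominance_switch": switch}
    if mean_bc < config.stability_bc_low:
        label = "stable"
    elif switch or (mean_bc >= config.stability_bc_high and np.isfinite(r) and r < 0):
        label = "successional"
    else:
        label = "drifting"
    return StabilityLabel(summary.lineage_id, label, evidence)


def _hinge_rss(x: np.ndarray, y: np.ndarray, bp: float) -> tuple[float, np.ndarray]:
    """RSS of the continuous two-segment fit y ~ a + b·x + c·(x−bp)₊."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - bp, 0.0)])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def breakpoint_regression(
    x, y, grid_step: float = 0.005, min_per_side: int = 2
) -> BreakpointFit:
    """Continuous two-segment ("broken-stick") linear regression.

    The breakpoint is chosen by grid search on multiples of ``grid_step``
    strictly inside the x-range (ties toward the smaller candidate), with
    the two OLS segments constrained to meet at the breakpoint.  Reports
    both slopes, the left intercept, the fitted RSS, the single-line RSS,
    and per-segment two-sided slope p-values.  When no candidate leaves
    ``min_per_side`` points on each side the fit falls back to a single line
    with a ``single_line_fallback`` flag; a breakpoint that does not improve
    on the single line is flagged ``no_breakpoint_support``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 10:
        raise ValueError("need n >= 10 observations")

    single = stats.linregress(x, y)
    rss_single = float(np.sum((y - (single.intercept + single.slope * x)) ** 2))

    lo, hi = float(x.min()), float(x.max())
    cands = np.arange(math.ceil(lo / grid_step), math.floor(hi / grid_step) + 1) * grid_step
    cands = [c for c in cands
             if lo < c < hi
             and (x < c).sum() >= min_per_side and (x > c).sum() >= min_per_side]
    if not cands:
        return BreakpointFit(
            breakpoint=float("nan"),
            slope_left=float(single.slope),
            slope_right=float(single.slope),
            intercept_left=float(single.intercept),
            rss=rss_single,
            rss_single_line=rss_single,
            p_left=float(single.pvalue),
            p_right=float(single.pvalue),
            flags=("single_line_fallback",),
        )

    best_bp, best_rss, best_beta = None, math.inf, None
    for c in cands:
        rss, beta = _hinge_rss(x, y, c)
        if rss < best_rss - 0.0:  # strict improvement keeps the earliest tie
            best_bp, best_rss, best_beta = float(c), rss, beta

    a, b, cc = best_beta
    left, right = x <= best_bp, x >= best_bp
    p_left = float(stats.linregress(x[left], y[left]).pvalue) if left.sum() >= 3 else float("nan")
    p_right = float(stats.linregress(x[right], y[right]).pvalue) if right.sum() >= 3 else float("nan")
    flags: tuple[str, ...] = ()
    improvement = rss_single - best_rss
    if improvement <= 1e-9 * max(rss_single, 1e-12):
        flags = ("no_breakpoint_support",)
    return BreakpointFit(
        breakpoint=best_bp,
        slope_left=float(b),
        slope_right=float(b + cc),
        intercept_left=float(a),
        rss=min(best_rss, rss_single),
        rss_single_line=rss_single,
        p_left=p_left,
        p_right=p_right,
        flags=flags,
    )
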