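"""Natural connectivity and the random-node-removal invulnerability analysis.

Natural connectivity is a spectral robustness measure: with adjacency
eigenvalues lambda_1..lambda_N,

    lambda_bar = ln( (1/N) * sum_i exp(lambda_i) )

It counts (log-average) closed walks of all lengths, so it is a proxy for the
redundancy of alternative paths, and it changes strictly monotonically when
edges are added or removed.  The invulnerability experiment removes 0..m_max
nodes uniformly at random and tracks lambda_bar; a linear decline is read as
absence of functional redundancy, while a gentle-then-steep (concave) decline
indicates redundancy in the early stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = ["RemovalTrajectory", "natural_connectivity", "removal_experiment", "classify_trend"]


def _adjacency(net) -> np.ndarray:
    if isinstance(net, GeneNetwork):
        A = nx.to_numpy_array(net.graph, weight=None)
    elif isinstance(net, nx.Graph):
        A = nx.to_numpy_array(net, weight=None)
    else:
        A = np.asarray(net, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric (undirected graph)")
    return A


def natural_connectivity(net) -> float:
    """Overflow-safe lambda_bar = logsumexp(eigenvalues) - ln(N)."""
    A = _adjacency(net)
    n = A.shape[0]
    if n < 2:
        raise ValueError("natural connectivity needs >= 2 nodes")
    lam = np.linalg.eigvalsh(A)
    return float(logsumexp(lam) - np.log(n))


@dataclass
class RemovalTrajectory:
    """Natural connectivity vs number of randomly removed nodes."""

    removed: np.ndarray          # 0..m_max
    lambda_bar: np.ndarray       # replicates x len(removed)
    seed: int | None = None

    @property
    def replicates(self) -> int:
        return self.lambda_bar.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.lambda_bar.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.lambda_bar.std(axis=0, ddof=1) if self.replicates > 1 else np.zeros_like(self.mean)


def removal_experiment(
    net: GeneNetwork | nx.Graph,
    m_max: int | None = None,
    replicates: int = 100,
    seed: int | None = None,
) -> RemovalTrajectory:
    """Remove 0..m_max nodes uniformly at random (without replacement),
    recomputing natural connectivity on each induced surviving subgraph.

    Each replicate draws an independent removal order.  The value at
    removed = 0 equals the intact network's natural connectivity exactly.
    """
    A = _adjacency(net)
    n = A.shape[0]
    if n < 3:
        raise ValueError("removal experiment needs >= 3 nodes")
    limit = n - 2
    if m_max is None:
        m_max = min(200, limit)
    if m_max > limit:
        logger.warning("removal_experiment: m_max=%d clipped to N-2=%d", m_max, limit)
        m_max = limit
    rng = np.random.default_rng(seed)
    removed = np.arange(m_max + 1)
    out = np.empty((replicates, m_max + 1))
    lam0 = float(logsumexp(np.linalg.eigvalsh(A)) - np.log(n))
    for rep in range(replicates):
        order = rng.permutation(n)
        out[rep, 0] = lam0
        for m in range(1, m_max + 1):
            alive = np.sort(order[m:])
            sub = A[np.ix_(alive, alive)]
            lam = np.linalg.eigvalsh(sub)
            out[rep, m] = logsumexp(lam) - np.log(sub.shape[0])
    return RemovalTrajectory(removed, out, seed)


def classify_trend(
    traj: RemovalTrajectory,
    aic_margin: float = 4.0,
    min_slope_ratio: float = 1.5,
) -> tuple[str, dict]:
    """Classify the mean trajectory as ``linear``, ``concave_then_steep`` or
    ``other``.

    Fits (a) simple linear least squares and (b) a continuous two-segment
    piecewise-linear model with the breakpoint searched over every integer
    removal count in the middle 80% of the range.  The linear model wins when
    AIC(a) <= AIC(b) + margin, or when the fitted segments are practically
    equivalent (slope magnitudes within a factor ``min_slope_ratio`` of each
    other — a redundancy verdict requires a *biologically meaningful*
    gentle-then-steep bend, not a statistically resolvable few-percent one);
    otherwise the trend is concave_then_steep when the first segment is
    gentler than the second (|slope1| < |slope2|), and ``other`` when the
    bend goes the opposite way.

    Removal trajectories are serially correlated (consecutive points share
    almost all of their surviving subgraph), so the AIC uses an effective
    sample size n_eff = n / (1 + 2 sum_k rho_k), with rho_k the residual
    autocorrelation sequence of the piecewise fit truncated at the first
    non-positive term (the standard initial-positive-sequence estimator);
    with independent noise all rho_k ~ 0 and n_eff ~ n.
    """
    x = traj.removed.astype(float)
    y = traj.mean
    if not np.all(np.isfinite(y)):
        raise ValueError("trajectory contains non-finite values")
    n = x.size
    if n < 20:
        raise ValueError("need >= 20 trajectory points to classify a trend")

    # (a) linear
    X1 = np.column_stack([np.ones(n), x])
    beta1, res1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(res1[0]) if res1.size else float(((y - X1 @ beta1) ** 2).sum())

    # (b) continuous two-segment piecewise linear, breakpoint on integer grid
    lo, hi = x[0] + 0.1 * (x[-1] - x[0]), x[0] + 0.9 * (x[-1] - x[0])
    grid = x[(x >= lo) & (x <= hi)]
    best = None
    for b in grid:
        X2 = np.column_stack([np.ones(n), x, np.clip(x - b, 0.0, None)])
        beta2, res2, *_ = np.linalg.lstsq(X2, y, rcond=None)
        rss2 = float(res2[0]) if res2.size else float(((y - X2 @ beta2) ** 2).sum())
        if best is None or rss2 < best[0]:
            best = (rss2, float(b), beta2)
    rss2, breakpoint_, beta2 = best
    slope1 = float(beta2[1])
    slope2 = float(beta2[1] + beta2[2])

    # effective sample size from serial correlation of the rich model's residuals
    Xb = np.column_stack([np.ones(n), x, np.clip(x - breakpoint_, 0.0, None)])
    resid = y - Xb @ beta2
    denom = float((resid ** 2).sum())
    rho_sum = 0.0
    rho1 = 0.0
    if denom > 0:
        for lag in range(1, n // 2):
            rho_k = float((resid[:-lag] * resid[lag:]).sum() / denom)
            if lag == 1:
                rho1 = rho_k
            if rho_k <= 0:
                break
            rho_sum += rho_k
    n_eff = max(n / (1.0 + 2.0 * rho_sum), 6.0)

    def aic(rss: float, k: int) -> float:
        rss = max(rss, 1e-300)
        return n_eff * np.log(rss / n) + 2 * k

    aic_lin = aic(rss1, 3)
    aic_pw = aic(rss2, 5)

    fit_stats = {
        "slope_linear": float(beta1[1]),
        "aic_linear": float(aic_lin),
        "aic_piecewise": float(aic_pw),
        "breakpoint": breakpoint_,
        "slope_segment1": slope1,
        "slope_segment2": slope2,
        "rho_resid": rho1,
        "n_eff": float(n_eff),
    }
    mags = sorted([abs(slope1), abs(slope2)])
    ratio = mags[1] / max(mags[0], 1e-12)
    if aic_lin <= aic_pw + aic_margin or ratio < min_slope_ratio:
        trend = "linear"
    elif abs(slope1) < abs(slope2):
        trend = "concave_then_steep"
    else:
        trend = "other"
    fit_stats = {**fit_stats, "slope_ratio": float(ratio)}
    fit_stats["trend"] = trend
    return trend, fit_stats
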