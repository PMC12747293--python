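"""Correlation layer: Spearman tests, BCa bootstrap intervals, the
subsampling null, and per-node correlations mapped onto a phylogeny."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from selscape.errors import EstimationDegenerateError, InvalidArgumentError
from selscape.trees import Phylogeny

__all__ = [
    "CorrelationResult",
    "spearman",
    "spearman_rho",
    "bca_ci",
    "correlate_with_ci",
    "SubsampleNull",
    "subsample_null",
    "per_node_correlations",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_bootstrap: int = 0
    method: str = "spearman"


def _check_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise InvalidArgumentError("x and y must be equal-length vectors")
    if x.size < min_n:
        raise InvalidArgumentError(f"need at least {min_n} observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidArgumentError("inputs must be finite")
    return x, y


def spearman_rho(x, y) -> float:
    """Spearman rho via Pearson correlation of midranks (no p-value)."""
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    xr = xr - xr.mean()
    yr = yr - yr.mean()
    denom = math.sqrt(float(xr @ xr) * float(yr @ yr))
    if denom == 0:
        raise EstimationDegenerateError("constant vector: rho undefined")
    return float(xr @ yr) / denom


def spearman(x, y) -> tuple[float, float]:
    """Spearman correlation with the asymptotic (t-approximation) p-value."""
    x, y = _check_xy(x, y)
    rho = spearman_rho(x, y)
    n = x.size
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def bca_ci(
    x,
    y,
    statistic: Callable[[np.ndarray, np.ndarray], float] = spearman_rho,
    n_bootstrap: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    max_failure_fraction: float = 0.1,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap CI for a paired statistic.

    Pairs ``(x_i, y_i)`` are resampled jointly. The bias correction z0 uses
    the fraction of bootstrap statistics strictly below the point estimate
    plus half the ties; the acceleration comes from the jackknife
    third-moment formula. A degenerate bootstrap distribution (all values
    equal) collapses the interval to that value.
    """
    x, y = _check_xy(x, y, min_n=8)
    n = x.size
    point = statistic(x, y)
    rng = np.random.default_rng(seed)

    boots = np.empty(n_bootstrap)
    failures = 0
    filled = 0
    budget = int(n_bootstrap * (1 + max_failure_fraction)) + 10
    draws = 0
    while filled < n_bootstrap and draws < budget:
        draws += 1
        idx = rng.integers(0, n, size=n)
        try:
            boots[filled] = statistic(x[idx], y[idx])
        except Exception:
            failures += 1
            continue
        filled += 1
    if filled < n_bootstrap:
        raise EstimationDegenerateError(
            f"statistic failed on {failures}/{draws} bootstrap resamples"
        )

    if np.ptp(boots) == 0:
        return float(boots[0]), float(boots[0])

    below = np.mean(boots < point) + 0.5 * np.mean(boots == point)
    below = min(max(below, 1.0 / (2 * n_bootstrap)), 1 - 1.0 / (2 * n_bootstrap))
    z0 = sps.norm.ppf(below)

    jack = np.empty(n)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        jack[i] = statistic(x[keep], y[keep])
        keep[i] = True
    jmean = jack.mean()
    num = ((jmean - jack) ** 3).sum()
    den = 6.0 * (((jmean - jack) ** 2).sum()) ** 1.5
    accel = 0.0 if den == 0 else num / den

    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for a in (alpha, 1.0 - alpha):
        z = sps.norm.ppf(a)
        adj = sps.norm.cdf(z0 + (z0 + z) / (1.0 - accel * (z0 + z)))
        lo_hi.append(float(np.quantile(boots, adj)))
    return lo_hi[0], lo_hi[1]


def correlate_with_ci(
    x, y, n_bootstrap: int = 1000, level: float = 0.95, seed: int = 0
) -> CorrelationResult:
    """Spearman correlation with asymptotic p-value and a BCa bootstrap CI."""
    x, y = _check_xy(x, y, min_n=8)
    rho, p = spearman(x, y)
    lo, hi = bca_ci(
        x, y, spearman_rho, n_bootstrap=n_bootstrap, level=level, seed=seed
    )
    return CorrelationResult(
        rho, p, int(x.size), lo, hi, n_bootstrap, "spearman+bca"
    )


@dataclass(frozen=True)
class SubsampleNull:
    """Distribution of correlations over repeated small subsamples."""

    rhos: np.ndarray
    minimum: float
    subsample_size: int

    def fraction_at_or_below(self, threshold: float) -> float:
        return float(np.mean(self.rhos <= threshold))


def subsample_null(
    x,
    y,
    subsample_size: int = 19,
    n_draws: int = 10000,
    seed: int = 0,
) -> SubsampleNull:
    """Spearman correlation over ``n_draws`` subsamples without replacement.

    Mirrors drawing pseudo-replicate sets of ``subsample_size`` lineages from
    a larger pool to ask how extreme a small-sample correlation can get.
    """
    if subsample_size < 3:
        raise InvalidArgumentError("subsample_size must be at least 3")
    x, y = _check_xy(x, y)
    if x.size <= subsample_size:
        raise InvalidArgumentError("need more observations than subsample_size")
    rng = np.random.default_rng(seed)
    rhos = np.empty(n_draws)
    for d in range(n_draws):
        idx = rng.choice(x.size, size=subsample_size, replace=False)
        try:
            rhos[d] = spearman_rho(x[idx], y[idx])
        except EstimationDegenerateError:
            rhos[d] = 0.0
    return SubsampleNull(rhos, float(rhos.min()), subsample_size)


def per_node_correlations(
    lineage_tree: Phylogeny,
    covariate: Mapping[str, float],
    constraint: Mapping[str, float],
    min_descendants: int = 15,
) -> pd.DataFrame:
    """Spearman correlation per internal node over its descendant lineages.

    Only internal nodes with strictly more than ``min_descendants``
    descendant tips receive a value; others are omitted. Returns a table with
    node_id, n_descendants, rho and p_value.
    """
    tips = set(lineage_tree.tip_labels)
    missing = tips - set(covariate) - set(constraint)
    if not tips.issubset(set(covariate) & set(constraint)):
        bad = sorted(tips - (set(covariate) & set(constraint)))
        raise InvalidArgumentError(f"missing values for lineage {bad[0]!r}")
    del missing

    below: dict[int, list[str]] = {}
    for node in lineage_tree.postorder():
        if node.is_leaf:
            below[id(node)] = [node.label]
        else:
            acc: list[str] = []
            for child in node.children:
                acc.extend(below[id(child)])
            below[id(node)] = acc

    rows = []
    for node in lineage_tree.preorder():
        if node.is_leaf:
            continue
        descendants = below[id(node)]
        if len(descendants) <= min_descendants:
            continue
        xs = [covariate[t] for t in descendants]
        ys = [constraint[t] for t in descendants]
        try:
            rho, p = spearman(xs, ys)
        except EstimationDegenerateError:
            continue
        rows.append(
            {
                "node_id": node.label,
                "n_descendants": len(descendants),
                "rho": rho,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows, columns=["node_id", "n_descendants", "rho", "p_value"])
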