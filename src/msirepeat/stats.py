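"""Exact and empirical statistics used throughout the package.

Two-sided Fisher's exact test (point-probability ordering), nearest-rank
empirical thresholds, ROC curves and the Mann-Whitney AUC.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.stats import hypergeom, rankdata

from .datamodel import ValidationError

#: relative guard when comparing hypergeometric point probabilities; large
#: enough to absorb floating-point noise between exactly equal
#: probabilities, far smaller than any genuine gap in realistic tables
_TIE_EPS = 1e-12


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 count table.

    Uses the standard point-probability definition: with both margins
    fixed, the p-value is the sum of hypergeometric probabilities of all
    tables whose point probability does not exceed that of the observed
    table.  A table with a zero margin admits only one configuration, so
    p = 1.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValidationError("table counts must be non-negative")
    a, b = arr[0]
    c, d = arr[1]
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    support = np.arange(max(0, c1 - r2), min(c1, r1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_EPS)].sum())
    return min(p, 1.0)


def empirical_threshold(values: Sequence[float], coverage: float = 0.95) -> float:
    """Nearest-rank upper quantile of observed values.

    Sorting ascending, returns ``x_(k)`` with ``k = ceil(coverage * n)``
    (1-based), so at most ``n - k`` values lie strictly above the returned
    threshold.  Used to set the per-marker deletion-frequency cutoff so
    that ~95% of MSS samples fall below it.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("empirical_threshold requires a non-empty input")
    if not 0.0 < coverage < 1.0:
        raise ValidationError(f"coverage {coverage} outside (0, 1)")
    k = int(np.ceil(coverage * values.size))
    return float(np.sort(values)[k - 1])


def roc_curve(
    pos: Sequence[float], neg: Sequence[float]
) -> list[tuple[float, float]]:
    """ROC points for the rule "value above threshold => positive".

    One point per candidate threshold: every distinct observed value plus
    a sentinel below the minimum and one above the maximum.  Ordered by
    increasing threshold, the curve runs from (1, 1) to (0, 0) and is
    monotone in both coordinates.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("roc_curve requires non-empty classes")
    observed = np.unique(np.concatenate([pos, neg]))
    thresholds = np.concatenate(
        [[observed[0] - 1.0], observed, [observed[-1] + 1.0]]
    )
    points = []
    for t in thresholds:
        tpr = float(np.mean(pos > t))
        fpr = float(np.mean(neg > t))
        points.append((fpr, tpr))
    return points


def roc_area(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC polyline (orientation-insensitive)."""
    fpr = np.asarray([p[0] for p in points])
    tpr = np.asarray([p[1] for p in points])
    return float(abs(np.trapezoid(tpr, fpr)))


def auc(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals (wins + 0.5 * ties) / (n_pos * n_neg), where a win is a
    positive-class value strictly exceeding a negative-class value; this
    is identical to the trapezoidal area under :func:`roc_curve`.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("auc requires non-empty classes")
    ranks = rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    u = rank_sum - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_bootstrap_ci(
    pos: Sequence[float],
    neg: Sequence[float],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap confidence interval for the AUC."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for i in range(n_boot):
        stats[i] = auc(
            rng.choice(pos, size=pos.size, replace=True),
            rng.choice(neg, size=neg.size, replace=True),
        )
    lo, hi = np.quantile(stats, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    from scipy.stats import norm

    if n == 0:
        return (0.0, 1.0)
    z = norm.ppf(1 - (1 - level) / 2)
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))
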