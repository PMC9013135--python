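"""Small shared statistical primitives.

Weighted proportions use the effective-sample-size (Kish) approximation for
their standard errors; no full survey linearisation is attempted.
"""

from __future__ import annotations

import numpy as np

from .exceptions import EstimationError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def effective_n(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


def weighted_proportion(y, weights) -> tuple[float, float, float]:
    """Weighted proportion with SE on the proportion scale.

    Returns ``(p, se, n_eff)`` where ``se = sqrt(p (1-p) / n_eff)``.
    Invariant to rescaling all weights by a positive constant.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.size == 0:
        raise EstimationError("cannot estimate a proportion from an empty subgroup")
    if np.any(w <= 0):
        raise EstimationError("sampling weights must be strictly positive")
    p = float(np.sum(w * y) / np.sum(w))
    n_eff = effective_n(w)
    se = float(np.sqrt(max(p * (1.0 - p), 0.0) / n_eff))
    return p, se, n_eff


def weighted_quantile_groups(
    scores: np.ndarray,
    weights: np.ndarray,
    n_groups: int = 5,
    tiebreak: np.ndarray | None = None,
) -> np.ndarray:
    """Assign 1..n_groups by cutting at weighted 1/n_groups points of ``scores``.

    Records are ordered by score (ties broken by ``tiebreak`` when given,
    record order otherwise) and each record is placed by the midpoint of its
    weight interval on the cumulative-weight scale, so equal weights and
    n divisible by n_groups give exactly equal groups.
    """
    scores = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = scores.size
    if tiebreak is None:
        order = np.argsort(scores, kind="stable")
    else:
        order = np.lexsort((np.asarray(tiebreak), scores))
    cw = np.cumsum(w[order])
    mid = (cw - 0.5 * w[order]) / cw[-1]
    cuts = np.arange(1, n_groups) / n_groups
    grp_sorted = np.searchsorted(cuts, mid, side="right") + 1
    groups = np.empty(n, dtype=int)
    groups[order] = grp_sorted
    return groups
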