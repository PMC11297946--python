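"""Penalized mean-shift changepoint detection.

Two solvers of the same penalized optimisation problem are provided:

* :func:`pelt` — pruned exact linear-time dynamic programming (PELT),
* :func:`exact_segmentation` — the un-pruned O(n^2) dynamic program
  (optimal-partitioning / segment-neighbourhood style), kept as the
  reference solver for validation.

Both minimise, over all segmentations 0 = t_0 < t_1 < ... < t_m = n with
every segment length t_{j+1} - t_j >= ``min_seg``,

    sum_j  C(x[t_j : t_{j+1}])  +  (m - 1) * beta

with the Gaussian fixed-variance mean-shift cost

    C(x[a:b]) = sum_{a<=i<b} (x_i - mean(x[a:b]))^2 / sigma^2 .

``sigma^2`` is a single session-level variance estimate with a small floor
so that near-degenerate binary input (the coincident-immobility vector this
package feeds in) stays well defined. The default penalty is the MBIC
magnitude ``beta = 3 log n`` for a mean shift — one parameter per extra
segment plus the changepoint location terms — applied as a constant
per-changepoint penalty, which keeps the cost subadditive and the PELT
pruning rule exact.

PELT pruning with a minimum segment length needs care: a candidate last
changepoint shown dominated at time ``t`` is only provably dominated once
the dominating configuration (a changepoint at ``t``) is itself admissible,
i.e. for times ``>= t + min_seg``. Candidate removal is therefore delayed by
``min_seg`` steps; with that modification PELT returns exactly the optimum
of the exhaustive program (property-tested against it).
"""

from __future__ import annotations

import math

import numpy as np

VARIANCE_FLOOR = 1e-8


def mbic_penalty(n: int) -> float:
    """MBIC-magnitude constant penalty for a single mean shift: 3 log n."""
    return 3.0 * math.log(max(n, 2))


def _prepare(x: np.ndarray, sigma2: float | None):
    x = np.asarray(x, dtype=float)
    n = x.size
    if sigma2 is None:
        sigma2 = float(np.var(x))
    sigma2 = max(sigma2, VARIANCE_FLOOR)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    return x, n, sigma2, cs, cs2


def _segment_cost(cs, cs2, sigma2, a, b):
    """Vectorized C(x[a:b]) for array-like a (or b)."""
    length = b - a
    s = cs[b] - cs[a]
    ss = cs2[b] - cs2[a]
    return (ss - s * s / length) / sigma2


def exact_segmentation(x, penalty: float | None = None, min_seg: int = 30,
                       sigma2: float | None = None) -> list[int]:
    """Exhaustive O(n^2) penalized dynamic program. Returns internal
    changepoint indices (segment boundaries, excluding 0 and n)."""
    x, n, sigma2, cs, cs2 = _prepare(x, sigma2)
    if penalty is None:
        penalty = mbic_penalty(n)
    if n < 2 * min_seg:
        return []
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    for t in range(min_seg, n + 1):
        # admissible last changepoints: 0, or tau in [min_seg, t - min_seg]
        taus = np.arange(min_seg, t - min_seg + 1)
        taus = np.concatenate(([0], taus)) if len(taus) else np.array([0])
        vals = F[taus] + _segment_cost(cs, cs2, sigma2, taus, t) + penalty
        k = int(np.argmin(vals))
        F[t] = vals[k]
        prev[t] = taus[k]
    return _backtrack(prev, n)


def pelt(x, penalty: float | None = None, min_seg: int = 30,
         sigma2: float | None = None) -> list[int]:
    """PELT solver; exact for this cost/penalty (see module docstring)."""
    x, n, sigma2, cs, cs2 = _prepare(x, sigma2)
    if penalty is None:
        penalty = mbic_penalty(n)
    if n < 2 * min_seg:
        return []
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=int)
    cands = np.array([0], dtype=int)
    kill_at = {0: np.inf}  # candidate -> first time it may be dropped
    for t in range(min_seg, n + 1):
        tau = t - min_seg
        if tau >= min_seg:  # tau=0 seeded; interior candidates enter here
            cands = np.append(cands, tau)
            kill_at[tau] = np.inf
        valid = cands[cands <= t - min_seg]
        base = F[valid] + _segment_cost(cs, cs2, sigma2, valid, t)
        vals = base + penalty
        k = int(np.argmin(vals))
        F[t] = vals[k]
        prev[t] = valid[k]
        # pruning: tau dominated now is provably dominated from t + min_seg on
        dominated = valid[base > F[t]]
        for d in dominated:
            kill_at[d] = min(kill_at[d], t + min_seg)
        if dominated.size:
            cands = np.array([c for c in cands if kill_at[c] > t], dtype=int)
    return _backtrack(prev, n)


def _backtrack(prev: np.ndarray, n: int) -> list[int]:
    cps = []
    t = n
    while t > 0:
        t = int(prev[t])
        if t > 0:
            cps.append(t)
    return cps[::-1]


def segment_means(x, changepoints) -> np.ndarray:
    """Per-segment means for boundaries ``changepoints`` (internal indices)."""
    x = np.asarray(x, dtype=float)
    bounds = [0, *changepoints, x.size]
    return np.array([x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
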