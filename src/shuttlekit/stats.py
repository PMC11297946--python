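"""Per-bin group comparisons with two-stage linear step-up FDR control.

The multiple-comparison machinery is the Benjamini–Krieger–Yekutieli (BKY)
two-stage linear step-up procedure:

* stage 1: Benjamini–Hochberg linear step-up at alpha' = alpha / (1 + alpha),
  giving r1 rejections (an estimate m0_hat = m - r1 of true nulls);
* stage 2: linear step-up at alpha' * m / (m - r1); its rejections are the
  procedure's output (all hypotheses rejected outright if r1 = m).

Bin-level tests are trial-level Welch two-sample t-tests (between trial
types or light conditions) and paired t-tests of each bin against its
predecessor (within trial type); each event type and comparison class forms
its own family for the correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class BinComparison:
    bin_index: int
    edges: tuple[float, float]
    comparison: str           # e.g. "avoidance_vs_escape", "bin_vs_previous"
    p: float
    reject: bool
    direction: int            # sign of the effect (A - B, or later - earlier)
    statistic: float = float("nan")


def _step_up(p_sorted: np.ndarray, q: float) -> int:
    """Number of rejections of the linear step-up procedure at level q."""
    m = p_sorted.size
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(p_sorted <= thresholds)
    return int(passing[-1] + 1) if passing.size else 0


def bky_fdr(pvals, alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, float]:
    """Two-stage linear step-up FDR procedure.

    Returns (reject flags aligned with the input order, the stage-2 step-up
    level actually used). Empty input yields an empty flag vector.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), alpha / (1.0 + alpha)
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    alpha1 = alpha / (1.0 + alpha)
    r1 = _step_up(p_sorted, alpha1)
    if r1 == 0:
        return np.zeros(m, dtype=bool), alpha1
    if r1 == m:
        return np.ones(m, dtype=bool), alpha1
    alpha2 = alpha1 * m / (m - r1)
    r2 = _step_up(p_sorted, alpha2)
    reject = np.zeros(m, dtype=bool)
    reject[order[:r2]] = True
    return reject, alpha2


def compare_bins_between(auc_a: np.ndarray, auc_b: np.ndarray,
                         edges: Optional[np.ndarray] = None,
                         comparison: str = "group_a_vs_group_b",
                         alpha: float = DEFAULT_ALPHA) -> list[BinComparison]:
    """Per-bin Welch t-tests between two groups of trials, BKY-corrected.

    ``auc_a``/``auc_b`` are trials x bins matrices over the same bin grid.
    Bins with fewer than 2 trials in either group are excluded (logged) and
    do not enter the family.
    """
    a = np.atleast_2d(np.asarray(auc_a, float))
    b = np.atleast_2d(np.asarray(auc_b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("bin grids differ between groups")
    n_bins = a.shape[1]
    if edges is None:
        edges = np.arange(n_bins + 1, dtype=float)
    usable, ps, stats_, dirs = [], [], [], []
    for j in range(n_bins):
        xa, xb = a[:, j], b[:, j]
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        if xa.size < 2 or xb.size < 2:
            logger.warning("bin %d has <2 trials in a group; excluded from the family", j)
            continue
        res = sps.ttest_ind(xa, xb, equal_var=False)
        usable.append(j)
        ps.append(float(res.pvalue))
        stats_.append(float(res.statistic))
        dirs.append(int(np.sign(xa.mean() - xb.mean())))
    reject, _ = bky_fdr(np.array(ps), alpha) if ps else (np.zeros(0, bool), alpha)
    return [BinComparison(j, (float(edges[j]), float(edges[j + 1])), comparison,
                          p, bool(r), d, s)
            for j, p, r, d, s in zip(usable, ps, reject, dirs, stats_)]


def first_significant_change(auc_within: np.ndarray,
                             edges: Optional[np.ndarray] = None,
                             comparison: str = "bin_vs_previous",
                             alpha: float = DEFAULT_ALPHA
                             ) -> tuple[Optional[int], list[BinComparison]]:
    """Earliest bin whose AUC differs from its predecessor within one group.

    Paired t-tests of each bin against the previous bin (trials x bins
    input); the family is all adjacent pairs, BKY-corrected. Returns the
    later bin's index of the earliest rejected pair (or None) plus the full
    comparison list.
    """
    x = np.atleast_2d(np.asarray(auc_within, float))
    n_bins = x.shape[1]
    if edges is None:
        edges = np.arange(n_bins + 1, dtype=float)
    if n_bins < 2 or x.shape[0] < 2:
        return None, []
    ps, stats_, dirs, pairs = [], [], [], []
    for j in range(1, n_bins):
        cur, prev = x[:, j], x[:, j - 1]
        ok = np.isfinite(cur) & np.isfinite(prev)
        if ok.sum() < 2:
            continue
        d = cur[ok] - prev[ok]
        if np.allclose(d, 0):
            p, stat = 1.0, 0.0
        else:
            res = sps.ttest_rel(cur[ok], prev[ok])
            p, stat = float(res.pvalue), float(res.statistic)
        pairs.append(j)
        ps.append(p)
        stats_.append(stat)
        dirs.append(int(np.sign(d.mean())))
    reject, _ = bky_fdr(np.array(ps), alpha) if ps else (np.zeros(0, bool), alpha)
    comparisons = [BinComparison(j, (float(edges[j]), float(edges[j + 1])),
                                 comparison, p, bool(r), d, s)
                   for j, p, r, d, s in zip(pairs, ps, reject, dirs, stats_)]
    first = next((c.bin_index for c in comparisons if c.reject), None)
    return first, comparisons
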