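"""Branch-wise affinity-shift scan with FDR control and robustness checks.

Each non-root branch is tested by a two-tailed unequal-variance t test of the
child node's replicate pKd values against its parent's, with
Benjamini-Hochberg correction applied jointly across all branches.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .affinity import AffinityProfile
from .core_io import Tree
from .errors import DomainError, PairingError

__all__ = [
    "welch_t",
    "bh_fdr",
    "ShiftCall",
    "branch_scan",
    "robustness_test",
    "ambiguity_correlation",
    "kde_mode",
]


def welch_t(a, b) -> tuple[float, float]:
    """Welch statistic with Satterthwaite df and two-tailed p.

    Convention: if both samples are exactly constant, p = 1 for equal means
    and p = 0 (t = +/-inf) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each sample needs n >= 2")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_fdr(pvals) -> list[float]:
    """Benjamini-Hochberg step-up q-values in input order."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise DomainError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in q]


@dataclass
class ShiftCall:
    """Result of one branch-wise affinity-shift test."""

    parent: str
    child: str
    delta: float          # child mean - parent mean pKd
    t: float
    p: float
    q: float = math.nan
    significant: bool = False
    robust: bool | None = None


def branch_scan(
    tree: Tree,
    profiles: dict[str, AffinityProfile],
    alpha: float = 0.05,
) -> list[ShiftCall]:
    """One ShiftCall per non-root branch, BH-corrected jointly.

    Output order is fixed (preorder by child id position in the tree), so the
    result is invariant to the enumeration order of ``profiles``.
    """
    calls = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        for nid in (node.id, node.parent.id):
            if nid not in profiles:
                raise PairingError(f"no affinity profile for node {nid!r}")
        child_p = profiles[node.id]
        parent_p = profiles[node.parent.id]
        t, p = welch_t(parent_p.replicates, child_p.replicates)
        calls.append(ShiftCall(
            parent=node.parent.id,
            child=node.id,
            delta=child_p.mean - parent_p.mean,
            t=-t,  # orient: positive t for an affinity increase on the branch
            p=p,
        ))
    qvals = bh_fdr([c.p for c in calls])
    for call, q in zip(calls, qvals):
        call.q = q
        call.significant = q < alpha
    return calls


def scan_report(calls: list[ShiftCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "parent": c.parent, "child": c.child, "delta": c.delta,
            "t": c.t, "p": c.p, "q": c.q,
            "significant": c.significant, "robust": c.robust,
        }
        for c in calls
    ])


def robustness_test(ml_reps, sampled_reps, alpha: float = 0.05) -> tuple[float, bool]:
    """Welch test of ML-sequence replicate pKds against the pooled
    posterior-draw replicates; robust iff p > alpha."""
    _, p = welch_t(ml_reps, sampled_reps)
    return p, p > alpha


def ambiguity_correlation(
    mean_posteriors: dict[str, float], pkds: dict[str, float]
) -> dict[str, float]:
    """Pearson r and Spearman rho between reconstruction certainty and pKd."""
    shared = sorted(set(mean_posteriors) & set(pkds))
    if len(shared) < 3:
        raise DomainError("need >= 3 paired nodes")
    x = np.array([mean_posteriors[k] for k in shared])
    y = np.array([pkds[k] for k in shared])
    if x.std() == 0 or y.std() == 0:
        raise DomainError("correlation undefined for a constant vector")
    r, rp = stats.pearsonr(x, y)
    rho, sp = stats.spearmanr(x, y)
    return {
        "pearson_r": float(r), "pearson_p": float(rp),
        "spearman_rho": float(rho), "spearman_p": float(sp),
        "n": len(shared),
    }


def kde_mode(values, bandwidth="silverman") -> float:
    """Mode of a Gaussian KDE on a 512-point grid over range +/- 3 bandwidths.

    ``bandwidth`` is Silverman's rule by default or a numeric bandwidth (in
    data units).  Ties break toward the lower grid value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DomainError("need n >= 2 for a KDE")
    if isinstance(bandwidth, str):
        kde = stats.gaussian_kde(arr, bw_method=bandwidth)
    else:
        if bandwidth <= 0:
            raise DomainError("bandwidth must be > 0")
        kde = stats.gaussian_kde(arr, bw_method=bandwidth / max(arr.std(ddof=1), 1e-12))
    h = math.sqrt(float(kde.covariance[0, 0]))
    grid = np.linspace(arr.min() - 3 * h, arr.max() + 3 * h, 512)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])  # argmax returns first (lowest) tie
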