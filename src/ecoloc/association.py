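"""Non-survival association tests: Jonckheere-Terpstra, Fisher, Kruskal-Wallis.

The Jonckheere-Terpstra statistic tests for a monotone trend of a continuous
measurement across ordered groups (e.g. the Morisita index across the
four-tier visual colocalization scale focal < low < moderate < marked):

    J = Σ_{g<h} U_{gh},   U_{gh} = #{(a,b): a in group g, b in group h, a < b}
                                   + ½ #{ties},

with a tie-corrected normal approximation for the p-value, or exact
enumeration of the group-label permutation null for small samples.  Fisher's
exact test (two-sided by the probability-mass rule, log-space hypergeometric
so p-values of order 1e-37 stay representable) and the tie-corrected
Kruskal-Wallis test delegate to scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table; rows = category, columns = group."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table must have a positive total")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def _jt_statistic(values: np.ndarray, group_idx: np.ndarray, k: int) -> float:
    j = 0.0
    for g, h in combinations(range(k), 2):
        a = values[group_idx == g]
        b = values[group_idx == h]
        diff = b[None, :] - a[:, None]
        j += float((diff > 0).sum()) + 0.5 * float((diff == 0).sum())
    return j


def jt_trend_test(
    values, groups, order=None, exact: bool | None = None
) -> tuple[float, float]:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    Parameters
    ----------
    values : array-like of float
        Continuous measurements.
    groups : array-like
        Group label per value.
    order : sequence, optional
        Explicit ascending group order; defaults to sorted unique labels.
    exact : bool, optional
        Force exact enumeration of the permutation null (all distinct
        assignments of values to the group sizes).  Defaults to exact for
        total n <= 12, normal approximation otherwise.

    Returns
    -------
    (J, p) : the statistic and the two-sided p-value.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if order is None:
        order = sorted(set(groups.tolist()))
    order = list(order)
    if len(order) < 2:
        raise ValueError("need at least 2 groups for a trend test")
    pos = {g: i for i, g in enumerate(order)}
    try:
        group_idx = np.array([pos[g] for g in groups])
    except KeyError as e:  # label not covered by the stated order
        raise ValueError(f"group label {e.args[0]!r} not in the stated order") from None
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 observations")
    sizes = np.bincount(group_idx, minlength=len(order))
    if (sizes == 0).sum() > len(order) - 2:
        raise ValueError("need at least 2 non-empty groups")
    k = len(order)
    j_obs = _jt_statistic(values, group_idx, k)

    # null mean under random assignment
    pair_total = (n * n - int((sizes**2).sum())) / 2
    mean = pair_total / 2

    if exact is None:
        exact = n <= 12
    if exact:
        # enumerate all distinct assignments of the pooled values to groups
        stats_null = []

        def recurse(remaining_idx: tuple[int, ...], g: int, assign: np.ndarray) -> None:
            if g == k - 1:
                a = assign.copy()
                a[list(remaining_idx)] = g
                stats_null.append(_jt_statistic(values, a, k))
                return
            for chosen in combinations(remaining_idx, int(sizes[g])):
                a = assign.copy()
                a[list(chosen)] = g
                rest = tuple(i for i in remaining_idx if i not in chosen)
                recurse(rest, g + 1, a)

        recurse(tuple(range(n)), 0, np.full(n, -1, dtype=np.int64))
        null = np.array(stats_null)
        dev = abs(j_obs - mean)
        p = float((np.abs(null - mean) >= dev - 1e-12).mean())
        return j_obs, min(p, 1.0)

    # tie-corrected normal approximation (standard JT variance with ties)
    _, tie_counts = np.unique(values, return_counts=True)
    t = tie_counts.astype(float)
    ns = sizes.astype(float)
    n_f = float(n)
    term1 = (
        n_f * (n_f - 1) * (2 * n_f + 5)
        - (ns * (ns - 1) * (2 * ns + 5)).sum()
        - (t * (t - 1) * (2 * t + 5)).sum()
    ) / 72.0
    term2 = (
        (ns * (ns - 1) * (ns - 2)).sum() * (t * (t - 1) * (t - 2)).sum()
    ) / (36.0 * n_f * (n_f - 1) * (n_f - 2))
    term3 = ((ns * (ns - 1)).sum() * (t * (t - 1)).sum()) / (8.0 * n_f * (n_f - 1))
    var = term1 + term2 + term3
    if var <= 0:
        return j_obs, 1.0
    z = (j_obs - mean) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return j_obs, min(p, 1.0)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p-value sums the hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's (the probability-mass rule).  A zero margin makes the
    table degenerate: p = 1 by convention, with a warning.

    Accepts a :class:`TwoByTwo` or any 2x2 array-like; returns
    ``(odds_ratio, p)`` with the sample odds ratio.
    """
    if isinstance(table, TwoByTwo):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=np.int64)
        if arr.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        if (arr < 0).any():
            raise ValueError("contingency counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table: p = 1 by convention")
        return float("nan"), 1.0
    orr, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(orr), float(p)


def hypergeom_table_probs(table) -> np.ndarray:
    """Probabilities of every 2x2 table with the observed margins.

    Exposed for diagnostics and testing: the returned probabilities sum to 1.
    """
    arr = table.as_array() if isinstance(table, TwoByTwo) else np.asarray(table)
    r1 = int(arr[0].sum())
    c1 = int(arr[:, 0].sum())
    n = int(arr.sum())
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    return stats.hypergeom.pmf(np.arange(lo, hi + 1), n, r1, c1)


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H test across ≥ 2 groups.

    All-tied data (zero rank variance) returns H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if len(np.unique(values)) == 1:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)
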