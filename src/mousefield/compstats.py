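"""Compositional analysis of behavioral time budgets.

A mouse's time budget over the eight behavioral classes is a composition
(fractions summing to one), so ordinary multivariate statistics on the
raw fractions are invalid.  The budget is mapped to isometric log-ratio
(ILR) coordinates, group differences are assessed with a rank-based
Wilks'-lambda-type statistic whose null distribution comes from label
permutations, and per-behavior effects are summarized as centered
log-ratio (clr) differences of the group geometric-mean compositions
with percentile-bootstrap confidence intervals (N = 5000 by default).

The per-behavior "log-ratio difference" is defined as::

    clr_b(gmean(group 1)) - clr_b(gmean(group 2))

i.e. the log fold-change of behavior ``b`` relative to the geometric mean
of all behaviors, contrasted between groups — the standard per-part
summary in compositional data analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.stats import rankdata

__all__ = [
    "zero_replace",
    "clr",
    "clr_inv",
    "ilr",
    "ilr_inv",
    "ilr_basis",
    "CompTestResult",
    "multivariate_group_test",
    "logratio_difference_ci",
]


def _as_comp(table: np.ndarray | pd.DataFrame) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    return x


def zero_replace(
    table: np.ndarray | pd.DataFrame, delta: float | None = None
) -> np.ndarray:
    """Multiplicative zero replacement.

    Zeros become ``delta`` (default: half the smallest nonzero fraction
    observed anywhere in the table) and the nonzero parts of each row are
    rescaled so the row still sums to one.  Rows with no zeros pass
    through unchanged.
    """
    x = _as_comp(table)
    if np.any(x < 0):
        raise ValueError("fractions must be non-negative")
    if np.any(np.all(x == 0, axis=1)):
        raise ValueError("a row is entirely zero")
    if delta is None:
        nz = x[x > 0]
        delta = 0.5 * nz.min()
    out = x.copy()
    zero = out == 0
    for i in range(len(out)):
        zi = zero[i]
        if zi.any():
            out[i, zi] = delta
            out[i, ~zi] *= 1.0 - delta * zi.sum()
    return out


def clr(x: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform (rows are compositions)."""
    x = _as_comp(x)
    if np.any(x <= 0):
        raise ValueError("clr requires strictly positive entries")
    lx = np.log(x)
    return lx - lx.mean(axis=1, keepdims=True)


def clr_inv(y: np.ndarray) -> np.ndarray:
    e = np.exp(np.asarray(y, dtype=float))
    return e / e.sum(axis=-1, keepdims=True)


def ilr_basis(d: int) -> np.ndarray:
    """Orthonormal balance basis (d-1, d) from a sequential binary
    partition in the fixed class order (Helmert contrasts, normalized)."""
    return helmert(d, full=False)


def ilr(table: np.ndarray | pd.DataFrame, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates, shape (n, D-1)."""
    x = _as_comp(table)
    if basis is None:
        basis = ilr_basis(x.shape[1])
    return clr(x) @ basis.T


def ilr_inv(coords: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    y = np.asarray(coords, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
    if basis is None:
        basis = ilr_basis(y.shape[1] + 1)
    return clr_inv(y @ basis)


@dataclass
class CompTestResult:
    """Result of the nonparametric multivariate group test."""

    statistic: float  # rank-based Wilks' lambda (small = separated groups)
    p_value: float
    n_permutations: int
    seed: int
    dropped_coords: list[int]


def _wilks_lambda(x: np.ndarray, groups: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) on (already ranked) coordinates."""
    grand = x.mean(axis=0)
    t_mat = (x - grand).T @ (x - grand)
    w_mat = np.zeros_like(t_mat)
    for g in np.unique(groups):
        sub = x[groups == g]
        c = sub - sub.mean(axis=0)
        w_mat += c.T @ c
    sign_t, logdet_t = np.linalg.slogdet(t_mat)
    sign_w, logdet_w = np.linalg.slogdet(w_mat)
    if sign_t <= 0:
        return 1.0
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def multivariate_group_test(
    coords: np.ndarray,
    groups: np.ndarray | list,
    n_perm: int = 10000,
    seed: int = 0,
) -> CompTestResult:
    """Rank-based Wilks'-lambda-type test with a permutation null.

    Each ILR coordinate is rank-transformed across all mice; Wilks'
    lambda is computed from the between/within scatter of the ranks, and
    the p-value is the permutation tail probability
    ``(1 + #{perm <= observed}) / (1 + n_perm)`` (small lambda indicates
    group separation).  Constant coordinates are dropped with a warning.
    """
    x = np.asarray(coords, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    for g in uniq:
        if np.sum(groups == g) < 3:
            raise ValueError("each group needs at least three mice")
    keep = [j for j in range(x.shape[1]) if np.ptp(x[:, j]) > 0]
    dropped = [j for j in range(x.shape[1]) if j not in keep]
    if dropped:
        import warnings

        warnings.warn(f"dropping constant coordinates {dropped}")
    x = x[:, keep]
    ranks = np.column_stack([rankdata(x[:, j]) for j in range(x.shape[1])])
    observed = _wilks_lambda(ranks, groups)
    rng = np.random.default_rng(seed)
    count = 0
    perm_groups = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_groups)
        if _wilks_lambda(ranks, perm_groups) <= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return CompTestResult(
        statistic=observed,
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        dropped_coords=dropped,
    )


def logratio_difference_ci(
    table: np.ndarray | pd.DataFrame,
    groups: np.ndarray | list,
    pair: tuple | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    class_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-behavior clr difference between two groups with bootstrap CIs.

    The point estimate for behavior ``b`` is the clr coordinate of the
    first group's geometric-mean composition minus the second's.  The 95%
    CI is a percentile bootstrap resampling mice within each group
    (``n_boot`` resamples, seeded).
    """
    x = _as_comp(table)
    if np.any(x <= 0):
        x = zero_replace(x)
    groups = np.asarray(groups)
    if pair is None:
        uniq = list(dict.fromkeys(groups))
        if len(uniq) != 2:
            raise ValueError("specify `pair` when more than two groups are present")
        pair = (uniq[0], uniq[1])
    a = x[groups == pair[0]]
    b = x[groups == pair[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least three mice")

    def group_clr(comp: np.ndarray) -> np.ndarray:
        # clr of the geometric-mean composition == mean of row-wise clrs
        return clr(comp).mean(axis=0)

    estimate = group_clr(a) - group_clr(b)
    rng = np.random.default_rng(seed)
    clr_a = clr(a)
    clr_b = clr(b)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    boots = clr_a[ia].mean(axis=1) - clr_b[ib].mean(axis=1)  # (n_boot, D)
    lo = np.percentile(boots, 2.5, axis=0)
    hi = np.percentile(boots, 97.5, axis=0)
    if class_names is None:
        class_names = [f"class_{i + 1}" for i in range(x.shape[1])]
    return pd.DataFrame(
        {
            "behavior": class_names,
            "estimate": estimate,
            "ci_lo": lo,
            "ci_hi": hi,
            "excludes_zero": (lo > 0) | (hi < 0),
        }
    )
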