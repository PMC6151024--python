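"""Mantel and partial Mantel tests, and the plain Pearson correlation test.

The Mantel statistic is the Pearson correlation of the lower-triangle
entries of two labelled distance matrices; significance comes from random
simultaneous row/column label permutations with a one-sided (positive
association) alternative and +1 smoothing, the convention of the standard
ecology tooling.  The partial form uses the first-order partial
correlation r12.3 and permutes the first matrix's labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formats import DistanceMatrix


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    n_labels: int
    partial: bool
    seed: int
    tail: str = "greater"


@dataclass
class CorResult:
    r: float
    t_statistic: float
    df: int
    p_value: float
    exact_fit: bool = False  # |r| = 1 within floating point


def _complete_case_labels(*mats: DistanceMatrix) -> list[str]:
    """Common labels with no missing cell in any matrix."""
    common = set(mats[0].labels)
    for m in mats[1:]:
        common &= set(m.labels)
    drop: set[str] = set()
    for m in mats:
        for a, b in m.missing_pairs():
            if a in common and b in common:
                # drop the label involved in more missing cells; tie -> later name
                drop.add(max(a, b))
    # conservative second pass: drop any label still paired with NaN
    labels = [l for l in sorted(common) if l not in drop]
    for m in mats:
        sub = m.submatrix(labels)
        while np.isnan(sub.values).any():
            counts = np.isnan(sub.values).sum(axis=0)
            worst = labels[int(np.argmax(counts))]
            labels = [l for l in labels if l != worst]
            sub = m.submatrix(labels)
    return labels


def _tri(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x ** 2).sum() * (y ** 2).sum())
    if denom == 0:
        raise ValueError("zero variance in distance vector")
    return float((x * y).sum() / denom)


def _perm_pvalue(r_obs: float, r_perm: np.ndarray, tail: str) -> float:
    if tail == "greater":
        n_exceed = int((r_perm >= r_obs).sum())
    elif tail == "two-sided":
        n_exceed = int((np.abs(r_perm) >= abs(r_obs)).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (n_exceed + 1) / (len(r_perm) + 1)


def mantel(D1: DistanceMatrix, D2: DistanceMatrix, n_perm: int = 1000,
           seed: int = 0, tail: str = "greater") -> MantelResult:
    """Mantel test between two distance matrices.

    Labels are matched by name (order-insensitive); labels carrying missing
    cells in either matrix are dropped complete-case.  The null permutes
    D2's labels simultaneously in rows and columns.
    """
    labels = _complete_case_labels(D1, D2)
    if len(labels) < 4:
        raise ValueError("Mantel test needs at least 4 usable labels")
    m1 = D1.submatrix(labels).values
    m2 = D2.submatrix(labels).values
    v1 = _tri(m1)
    r_obs = _pearson(v1, _tri(m2))
    rng = np.random.default_rng(seed)
    n = len(labels)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        r_perm[k] = _pearson(v1, _tri(m2[np.ix_(p, p)]))
    return MantelResult(r=r_obs, p_value=_perm_pvalue(r_obs, r_perm, tail),
                        n_perm=n_perm, n_labels=n, partial=False, seed=seed,
                        tail=tail)


def _partial_r(r12: float, r13: float, r23: float) -> float:
    denom = (1 - r13 ** 2) * (1 - r23 ** 2)
    if denom <= 0:
        raise ValueError("control matrix collinear with an input "
                         "(|r| = 1); partial correlation undefined")
    return (r12 - r13 * r23) / np.sqrt(denom)


def partial_mantel(D1: DistanceMatrix, D2: DistanceMatrix,
                   D3: DistanceMatrix, n_perm: int = 1000, seed: int = 0,
                   tail: str = "greater") -> MantelResult:
    """Partial Mantel test of D1 vs D2 controlling for D3.

    r = r12.3 = (r12 - r13 r23) / sqrt((1 - r13^2)(1 - r23^2)); the null
    permutes D1's labels and recomputes r12.3 each time (r23 is invariant).
    """
    labels = _complete_case_labels(D1, D2, D3)
    if len(labels) < 4:
        raise ValueError("partial Mantel test needs at least 4 usable labels")
    m1 = D1.submatrix(labels).values
    v2 = _tri(D2.submatrix(labels).values)
    v3 = _tri(D3.submatrix(labels).values)
    v1 = _tri(m1)
    r12 = _pearson(v1, v2)
    r13 = _pearson(v1, v3)
    r23 = _pearson(v2, v3)
    r_obs = _partial_r(r12, r13, r23)
    rng = np.random.default_rng(seed)
    n = len(labels)
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        v1p = _tri(m1[np.ix_(p, p)])
        r_perm[k] = _partial_r(_pearson(v1p, v2), _pearson(v1p, v3), r23)
    return MantelResult(r=float(r_obs), p_value=_perm_pvalue(r_obs, r_perm, tail),
                        n_perm=n_perm, n_labels=n, partial=True, seed=seed,
                        tail=tail)


def pearson_cor_test(x: np.ndarray, y: np.ndarray) -> CorResult:
    """Pearson correlation with the textbook t-test (two-sided).

    t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom; an exact
    fit (|r| = 1) is flagged and reported with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r = _pearson(x, y)
    df = n - 2
    if abs(r) >= 1.0 - 1e-14:
        return CorResult(r=float(np.sign(r)), t_statistic=float("inf") * np.sign(r),
                         df=df, p_value=0.0, exact_fit=True)
    t = r * np.sqrt(df / (1 - r ** 2))
    p = 2 * stats.t.sf(abs(t), df)
    return CorResult(r=float(r), t_statistic=float(t), df=df, p_value=float(p))
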