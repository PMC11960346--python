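"""Simplex operations for 4-part time-use compositions.

A day is treated as a composition of total sleep time (TST), sedentary
behaviour (SB), light physical activity (LPA) and moderate-to-vigorous
physical activity (MVPA), closed to 1440 minutes.  This module provides
closure, zero handling, the geometric-mean composition, the variation
matrix, and isometric log-ratio (ILR) coordinates built from a
sequential-binary-partition (SBP) pivot scheme, together with the inverse
transform.

Part order is fixed as (tst, sb, lpa, mvpa) throughout the package;
alternative pivots are expressed through ``sbp_pivot``'s ``pivot_index``,
never by reordering columns.
"""

from __future__ import annotations

import numpy as np

#: Canonical part order used everywhere in the package.
PART_ORDER: tuple[str, ...] = ("tst", "sb", "lpa", "mvpa")

#: Closure constant: minutes in a day.
TOTAL_MIN: float = 1440.0

#: Relative tolerance for closure / round-trip identities.
CLOSURE_RTOL: float = 1e-9


class CompositionError(ValueError):
    """Raised for invalid compositional input (zeros, negatives, bad shapes)."""


def closure(raw, total: float = TOTAL_MIN) -> np.ndarray:
    """Rescale positive parts so they sum to ``total``.

    Accepts a 1-d vector or a 2-d array (rows = observations).  Idempotent:
    ``closure(closure(x)) == closure(x)``.

    Raises
    ------
    CompositionError
        If any entry is <= 0.  Zeros must be handled first via
        :func:`replace_zeros` (see :func:`check_zeros`).
    """
    x = np.asarray(raw, dtype=float)
    if np.any(x <= 0):
        raise CompositionError(
            "closure requires strictly positive parts; "
            "run check_zeros / replace_zeros on data containing zeros"
        )
    s = x.sum(axis=-1, keepdims=True)
    return x * (total / s)


def check_zeros(dataset) -> dict[str, int]:
    """Count zero entries per part across a dataset of raw 4-vectors.

    Returns a dict keyed by part name with the number of zero entries.
    The analysis may proceed untransformed iff every count is 0; otherwise
    the caller must recode zeros (:func:`replace_zeros`) or abort.
    """
    x = np.atleast_2d(np.asarray(dataset, dtype=float))
    if x.size == 0:
        return {}
    counts = (x == 0).sum(axis=0)
    return {part: int(c) for part, c in zip(PART_ORDER, counts)}


def replace_zeros(raw, delta: float = 1.0, total: float | None = None) -> np.ndarray:
    """Multiplicative zero replacement.

    Zeros are set to ``delta`` (minutes) and the non-zero parts are scaled
    by ``1 - n_zeros * delta / total`` so the vector total is preserved.

    Raises
    ------
    CompositionError
        If ``delta <= 0`` or ``n_zeros * delta >= total`` (infeasible delta).
    """
    if delta <= 0:
        raise CompositionError("delta must be > 0")
    x = np.asarray(raw, dtype=float)
    zeros = x == 0
    n_zeros = int(zeros.sum())
    if n_zeros == 0:
        return x.copy()
    t = float(x.sum()) if total is None else float(total)
    if n_zeros * delta >= t:
        raise CompositionError(
            f"infeasible delta: {n_zeros} zeros x delta={delta} >= total={t}"
        )
    out = x * (1.0 - n_zeros * delta / t)
    out[zeros] = delta
    return out


def geometric_mean_composition(dataset, total: float = TOTAL_MIN) -> np.ndarray:
    """Part-wise geometric mean across observations, closed to ``total``.

    This is the standard centre of a compositional sample and the reference
    composition for substitution modelling.
    """
    x = np.atleast_2d(np.asarray(dataset, dtype=float))
    if x.size == 0:
        raise CompositionError("geometric mean of an empty dataset")
    if np.any(x <= 0):
        raise CompositionError("geometric mean requires strictly positive parts")
    gm = np.exp(np.log(x).mean(axis=0))
    return closure(gm, total)


def variation_matrix(dataset) -> np.ndarray:
    """Pairwise log-ratio variances: v[i, j] = var(ln x_i / ln x_j).

    Entries near zero indicate strong co-dependence of the two parts.
    Sample variances use the n-1 denominator.  Symmetric with a zero
    diagonal; invariant under closure of the input.
    """
    x = np.atleast_2d(np.asarray(dataset, dtype=float))
    if x.shape[0] < 2:
        raise CompositionError("variation matrix needs at least 2 observations")
    if np.any(x <= 0):
        raise CompositionError("variation matrix requires strictly positive parts")
    logx = np.log(x)
    d = logx.shape[1]
    v = np.empty((d, d))
    for i in range(d):
        for j in range(d):
            v[i, j] = np.var(logx[:, i] - logx[:, j], ddof=1) if i != j else 0.0
    return v


def sbp_pivot(d: int, pivot_index: int = 1) -> np.ndarray:
    """Pivot sequential-binary-partition sign matrix for ``d`` parts.

    Row 1 contrasts the pivot part (+1) against all remaining parts (-1);
    each later row drops the previous numerator and promotes the next part
    (in cyclic order starting from the pivot) to the numerator.
    ``pivot_index`` is 1-based; rotating it changes which behaviour sits in
    the interpretable first coordinate without reordering the data columns.
    """
    if not 1 <= pivot_index <= d:
        raise ValueError(f"pivot_index must be in 1..{d}, got {pivot_index}")
    order = [(pivot_index - 1 + k) % d for k in range(d)]
    signs = np.zeros((d - 1, d), dtype=int)
    for row in range(d - 1):
        signs[row, order[row]] = 1
        for col in order[row + 1 :]:
            signs[row, col] = -1
    return signs


def contrast_matrix(sbp: np.ndarray) -> np.ndarray:
    """Orthonormal balance (contrast) matrix V, shape (d, d-1).

    For a balance with r numerator and s denominator parts, numerator
    entries are sqrt(s / (r (r+s))) and denominator entries
    -sqrt(r / (s (r+s))), so that ilr coordinates are z = V.T @ ln(x) and
    sum to the classic sqrt(rs/(r+s)) * ln(gmean(num)/gmean(den)) form.
    """
    sbp = np.asarray(sbp)
    n_bal, d = sbp.shape
    v = np.zeros((d, n_bal))
    for k in range(n_bal):
        num = sbp[k] == 1
        den = sbp[k] == -1
        r, s = int(num.sum()), int(den.sum())
        if r == 0 or s == 0:
            raise ValueError(f"SBP row {k} lacks a numerator or denominator")
        v[num, k] = np.sqrt(s / (r * (r + s)))
        v[den, k] = -np.sqrt(r / (s * (r + s)))
    return v


def ilr(x, sbp: np.ndarray) -> np.ndarray:
    """ILR coordinates of composition(s) ``x`` under the balance basis ``sbp``.

    Coordinate k equals sqrt(r s / (r+s)) * ln(g(numerator)/g(denominator))
    with g the geometric mean and r, s the numerator/denominator part
    counts.  Scale-invariant: ilr(c * x) == ilr(x).
    """
    xx = np.asarray(x, dtype=float)
    if np.any(xx <= 0):
        raise CompositionError("ilr requires strictly positive parts")
    return np.log(xx) @ contrast_matrix(sbp)


def ilr_inverse(z, sbp: np.ndarray, total: float = TOTAL_MIN) -> np.ndarray:
    """Unique composition (closed to ``total``) whose ILR coordinates are ``z``."""
    zz = np.asarray(z, dtype=float)
    v = contrast_matrix(sbp)
    return closure(np.exp(zz @ v.T), total)
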