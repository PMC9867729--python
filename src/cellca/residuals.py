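"""Chi-squared residual transformations of count tables.

Correspondence analysis decomposes a residual matrix rather than the
raw counts. Three residual families are provided:

* **Pearson** ``(p_ij - p_i. p_.j) / sqrt(p_i. p_.j)`` — the classical
  standardized residual; ``N * sum(r^2)`` is the Pearson chi-squared
  statistic of the table (the "total inertia").
* **Freeman–Tukey** ``sqrt(p_ij) + sqrt(p_ij + 1/N) -
  sqrt(4 p_i. p_.j + 1/N)`` — a variance-stabilized member of the same
  power-divergence family, better behaved for sparse overdispersed
  counts.
* **Indexed** ``(p_ij - p_i. p_.j) / (p_i. p_.j)`` — observed relative
  excess over expected (r = 0.5 means 50% above expectation); used for
  multi-table integration because it down-weights high-mass columns
  (deeply sequenced cells).

Variance-stabilizing count transforms (square root, Anscombe,
Freeman–Tukey) may be applied to the table first, and a sign-preserving
power deflation ``sgn(r) |r|^alpha`` may be applied to the residuals
afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .containers import CountMatrix, ResidualMatrix, VstMode, WeightModel

logger = logging.getLogger(__name__)

# expected proportions below this would overflow the indexed residual
_MIN_EXPECTED = 1e-300


def compute_weights(counts: CountMatrix) -> WeightModel:
    """Grand total, proportion matrix and marginal row/column weights.

    Raises
    ------
    ValueError
        If any row or column sums to zero (filter with
        :func:`drop_empty` first).
    """
    X = counts.values
    row_sums = X.sum(axis=1)
    col_sums = X.sum(axis=0)
    zero_rows = np.flatnonzero(row_sums == 0)
    zero_cols = np.flatnonzero(col_sums == 0)
    if zero_rows.size or zero_cols.size:
        bad_f = [counts.feature_ids[i] for i in zero_rows[:10]]
        bad_c = [counts.cell_ids[j] for j in zero_cols[:10]]
        raise ValueError(
            "table has zero-sum margins; drop them first "
            f"(features: {bad_f}, cells: {bad_c})"
        )
    N = float(X.sum())
    P = X / N
    return WeightModel(N=N, P=P, row_w=P.sum(axis=1), col_w=P.sum(axis=0))


def drop_empty(counts: CountMatrix) -> CountMatrix:
    """Remove all-zero rows and columns; error if the result degenerates."""
    X = counts.values
    keep_rows = X.sum(axis=1) > 0
    keep_cols = X.sum(axis=0) > 0
    n_drop_rows = int((~keep_rows).sum())
    n_drop_cols = int((~keep_cols).sum())
    if n_drop_rows == 0 and n_drop_cols == 0:
        return counts
    logger.warning(
        "dropping %d all-zero features and %d all-zero cells",
        n_drop_rows,
        n_drop_cols,
    )
    if keep_rows.sum() < 2 or keep_cols.sum() < 2:
        raise ValueError("degenerate table after filtering")
    return CountMatrix(
        values=X[np.ix_(keep_rows, keep_cols)],
        feature_ids=[f for f, k in zip(counts.feature_ids, keep_rows) if k],
        cell_ids=[c for c, k in zip(counts.cell_ids, keep_cols) if k],
        batch=None if counts.batch is None else counts.batch[keep_cols],
    )


def vst_transform(counts: CountMatrix, mode: VstMode) -> CountMatrix:
    """Element-wise variance-stabilizing transform of the counts.

    ``sqrt``: ``sqrt(x)``; ``anscombe``: ``2 sqrt(x + 3/8)``;
    ``freeman_tukey_counts``: ``sqrt(x) + sqrt(x + 1)``. All three are
    square-root-family stabilizers for Poisson-like counts and are
    well defined for any non-negative real input.
    """
    x = counts.values
    if mode == "none":
        return counts
    if mode == "sqrt":
        out = np.sqrt(x)
    elif mode == "anscombe":
        out = 2.0 * np.sqrt(x + 0.375)
    elif mode == "freeman_tukey_counts":
        out = np.sqrt(x) + np.sqrt(x + 1.0)
    else:
        raise ValueError(f"unknown vst mode: {mode!r}")
    return counts.with_values(out)


def _expected_checked(w: WeightModel) -> np.ndarray:
    E = w.expected()
    if E.min() < _MIN_EXPECTED:
        raise ValueError(
            "expected proportion underflow (< 1e-300); table too extreme"
        )
    return E


def pearson_residuals(counts: CountMatrix) -> ResidualMatrix:
    """Standardized (Pearson) residuals of the proportion table."""
    w = compute_weights(counts)
    E = _expected_checked(w)
    r = (w.P - E) / np.sqrt(E)
    return ResidualMatrix(
        values=r,
        residual_kind="pearson",
        feature_ids=counts.feature_ids,
        cell_ids=counts.cell_ids,
    )


def freeman_tukey_residuals(counts: CountMatrix) -> ResidualMatrix:
    """Freeman–Tukey residuals.

    As ``N`` grows with the proportions fixed, each residual converges
    to the Hellinger-type limit ``2 (sqrt(p_ij) - sqrt(p_i. p_.j))``;
    unlike Pearson residuals they are not exactly centered at finite N.
    """
    w = compute_weights(counts)
    E = _expected_checked(w)
    inv_n = 1.0 / w.N
    r = np.sqrt(w.P) + np.sqrt(w.P + inv_n) - np.sqrt(4.0 * E + inv_n)
    return ResidualMatrix(
        values=r,
        residual_kind="freeman_tukey",
        feature_ids=counts.feature_ids,
        cell_ids=counts.cell_ids,
    )


def indexed_residuals(counts: CountMatrix) -> ResidualMatrix:
    """Indexed residuals: relative excess of observed over expected."""
    w = compute_weights(counts)
    E = _expected_checked(w)
    r = (w.P - E) / E
    return ResidualMatrix(
        values=r,
        residual_kind="indexed",
        feature_ids=counts.feature_ids,
        cell_ids=counts.cell_ids,
    )


def power_deflate(residuals: ResidualMatrix, alpha: float) -> ResidualMatrix:
    """Sign-preserving element-wise power ``sgn(r) |r|^alpha``.

    ``alpha`` slightly below 1 (default 0.9 elsewhere in the package)
    softly shrinks large residuals while preserving sign, zeros and the
    ranking of magnitudes; ``alpha = 1`` is the identity.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if alpha == 1.0:
        return replace(residuals, alpha=residuals.alpha)
    r = residuals.values
    out = np.sign(r) * np.abs(r) ** alpha
    return replace(residuals, values=out, alpha=alpha)


def residuals_for(
    counts: CountMatrix,
    kind: str,
    vst: VstMode = "none",
    alpha: float = 1.0,
) -> ResidualMatrix:
    """Full residual pipeline: VST, residual transform, power deflation."""
    transformed = vst_transform(counts, vst)
    if kind == "pearson":
        res = pearson_residuals(transformed)
    elif kind == "freeman_tukey":
        res = freeman_tukey_residuals(transformed)
    elif kind == "indexed":
        res = indexed_residuals(transformed)
    else:
        raise ValueError(f"unknown residual kind: {kind!r}")
    res = replace(res, vst=vst)
    return power_deflate(res, alpha)
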