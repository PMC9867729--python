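"""Truncated SVD of residual matrices and CA coordinate scores.

The residual matrix ``M = U D V^T`` is decomposed with a truncated SVD.
For Pearson residuals the singular values are canonical correlations
and never exceed 1; the squared singular values partition the table's
total inertia (chi-squared / N). Dense LAPACK SVD is used for small
problems (min(m, n) <= 100) or full-rank requests; otherwise a
deterministic Lanczos solver computes the leading components.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.sparse.linalg as spla

from .containers import CAResult, CountMatrix, ResidualMatrix, WeightModel
from .residuals import compute_weights, drop_empty, residuals_for, vst_transform

logger = logging.getLogger(__name__)

_DENSE_CUTOFF = 100
_SVDS_TOL = 1e-10


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # SVD sign ambiguity: make the largest-|.| entry of each U column
    # positive so repeated runs are bit-identical.
    for k in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, k])))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
            V[:, k] = -V[:, k]
    return U, V


def svd_decompose(residuals: ResidualMatrix, n_components: int) -> CAResult:
    """Truncated SVD of a residual matrix.

    Returns a :class:`CAResult` with ``U``, ``d``, ``V`` populated
    (coordinate scores are attached by :func:`coordinate_scores`).
    Output is deterministic: singular values are sorted non-increasing
    and each component's sign is fixed by its dominant feature loading.
    """
    M = residuals.values
    m, n = M.shape
    if n_components < 1 or n_components > min(m, n):
        raise ValueError(
            f"n_components must be in [1, {min(m, n)}], got {n_components}"
        )
    if min(m, n) <= _DENSE_CUTOFF or n_components >= min(m, n) - 1:
        U, d, Vt = np.linalg.svd(M, full_matrices=False)
        U = U[:, :n_components]
        d = d[:n_components]
        V = Vt[:n_components].T
    else:
        # deterministic start vector keeps repeated runs identical
        v0 = np.ones(min(m, n)) / np.sqrt(min(m, n))
        try:
            U, d, Vt = spla.svds(
                M, k=n_components, tol=_SVDS_TOL, v0=v0, maxiter=10000
            )
        except spla.ArpackNoConvergence as err:
            raise RuntimeError(
                f"truncated SVD did not converge at tol={_SVDS_TOL}"
            ) from err
        order = np.argsort(d)[::-1]
        U = U[:, order]
        d = d[order]
        V = Vt[order].T
    d = np.maximum(d, 0.0)
    U, V = _fix_signs(U, V)
    return CAResult(
        U=U,
        V=V,
        d=d,
        feature_ids=residuals.feature_ids,
        cell_ids=residuals.cell_ids,
        residual_kind=residuals.residual_kind,
        vst=residuals.vst,
        alpha=residuals.alpha,
        n_components=n_components,
    )


def coordinate_scores(result: CAResult, weights: WeightModel) -> CAResult:
    """Attach standard and principal coordinate scores.

    Standard coordinates divide each singular vector row-wise by the
    square root of its weight (the convention under which row standard
    coordinates have unit weighted variance per component); principal
    coordinates scale the standard coordinates column-wise by the
    singular values.
    """
    if weights.row_w.shape[0] != result.U.shape[0]:
        raise ValueError("row weights do not match singular vectors")
    if weights.col_w.shape[0] != result.V.shape[0]:
        raise ValueError("column weights do not match singular vectors")
    result.row_sc = result.U / np.sqrt(weights.row_w)[:, None]
    result.col_sc = result.V / np.sqrt(weights.col_w)[:, None]
    result.row_pc = result.row_sc * result.d[None, :]
    result.col_pc = result.col_sc * result.d[None, :]
    return result


def ca_fit(
    counts: CountMatrix,
    method: str = "pearson",
    vst: str = "none",
    alpha: float = 1.0,
    n_components: int = 30,
) -> CAResult:
    """End-to-end single-table correspondence analysis.

    Composes empty-margin filtering, the optional variance-stabilizing
    count transform, the chosen residual family (``pearson`` or
    ``freeman_tukey``), optional power deflation, truncated SVD, and
    coordinate scores.

    Parameters
    ----------
    method
        Residual family decomposed: ``pearson`` (standard CA) or
        ``freeman_tukey`` (CA-FT).
    vst
        Count transform applied first: ``none``, ``sqrt``,
        ``anscombe``, or ``freeman_tukey_counts``.
    alpha
        Power-deflation exponent in (0, 1]; 1 disables it. Values
        around 0.9 give a soft smoothing of outlying residuals.
    n_components
        Number of singular components, clipped nowhere — must satisfy
        ``1 <= n_components <= min(m, n)`` after filtering.
    """
    if method not in ("pearson", "freeman_tukey"):
        raise ValueError(f"unknown method: {method!r}")
    counts = drop_empty(counts)
    res = residuals_for(counts, kind=method, vst=vst, alpha=alpha)
    # weights come from the same (possibly VST-transformed) table the
    # residuals were computed on
    weights = compute_weights(vst_transform(counts, vst))
    result = svd_decompose(res, n_components)
    return coordinate_scores(result, weights)


def select_components_elbow(d: np.ndarray) -> int:
    """Elbow of a scree curve by maximum perpendicular distance.

    Considers the interior points of the scree plot ``(k, d_k)`` and
    returns the 1-based index furthest from the chord joining the first
    and last points; ties (including flat or perfectly linear screes)
    resolve to the smallest interior index.
    """
    d = np.asarray(d, dtype=float)
    if d.size < 3:
        raise ValueError("elbow selection needs at least 3 singular values")
    L = d.size
    x = np.arange(1, L + 1, dtype=float)
    # chord from (1, d_1) to (L, d_L)
    dx, dy = x[-1] - x[0], d[-1] - d[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (d - d[0])) / norm
    interior = dist[1:-1]
    return int(np.argmax(interior)) + 2  # 1-based, offset past the endpoint


def biplot_prepare(
    result: CAResult, k_features: int, coord: str = "principal"
) -> dict:
    """Cell and top-feature coordinates for a 2-D CA biplot.

    Returns all cells in components 1–2 plus the ``k_features``
    features furthest from the origin in that plane (largest L2 norm);
    ties in norm break by feature-id lexicographic order.
    """
    if result.d.size < 2:
        raise ValueError("biplot needs at least 2 computed components")
    if coord == "principal":
        if result.row_pc is None or result.col_pc is None:
            raise ValueError("principal coordinates not computed")
        F, C = result.row_pc[:, :2], result.col_pc[:, :2]
    elif coord == "standard":
        if result.row_sc is None or result.col_sc is None:
            raise ValueError("standard coordinates not computed")
        F, C = result.row_sc[:, :2], result.col_sc[:, :2]
    else:
        raise ValueError(f"unknown coordinate type: {coord!r}")
    m = F.shape[0]
    if k_features > m:
        warnings.warn(
            f"k_features={k_features} exceeds {m} features; clipping",
            stacklevel=2,
        )
        k_features = m
    norms = np.linalg.norm(F, axis=1)
    order = sorted(
        range(m), key=lambda i: (-norms[i], result.feature_ids[i])
    )
    top = order[:k_features]
    return {
        "cells": {"ids": list(result.cell_ids), "coords": C},
        "features": {
            "ids": [result.feature_ids[i] for i in top],
            "coords": F[top],
        },
        "coord_type": coord,
    }
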