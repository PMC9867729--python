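"""Core in-memory containers shared across the package.

A count table is stored features-by-cells (genes in rows, cells in
columns), matching the 10x on-disk convention. All containers are plain
dataclasses around NumPy arrays; residual matrices are always dense
because subtracting the rank-1 independence expectation destroys
sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

ResidualKind = Literal["pearson", "freeman_tukey", "indexed"]
VstMode = Literal["none", "sqrt", "anscombe", "freeman_tukey_counts"]


def _as_unique_list(ids: Sequence[str], what: str) -> list[str]:
    out = [str(x) for x in ids]
    if len(set(out)) != len(out):
        raise ValueError(f"{what} are not unique")
    return out


@dataclass
class CountMatrix:
    """Non-negative feature-by-cell matrix with identifiers.

    Parameters
    ----------
    values
        ``(m, n)`` array of non-negative, finite values. Integer counts
        are typical but any non-negative real input (e.g. logcounts) is
        accepted: the chi-squared residual machinery only needs a
        non-negative table.
    feature_ids, cell_ids
        Unique string identifiers for the ``m`` rows and ``n`` columns.
    batch
        Optional per-cell categorical label (length ``n``).
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    batch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-dimensional")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValueError(
                f"count matrix must be at least 2x2, got {m}x{n}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("count matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("count matrix contains negative values")
        self.feature_ids = _as_unique_list(self.feature_ids, "feature_ids")
        self.cell_ids = _as_unique_list(self.cell_ids, "cell_ids")
        if len(self.feature_ids) != m:
            raise ValueError(
                f"{len(self.feature_ids)} feature_ids for {m} rows"
            )
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {n} columns")
        if self.batch is not None:
            self.batch = np.asarray(self.batch)
            if self.batch.shape != (n,):
                raise ValueError("batch labels must have one entry per cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "CountMatrix":
        """Copy of this container with new values, identifiers preserved."""
        return replace(self, values=values)


@dataclass
class WeightModel:
    """Proportion table and marginal weights of one count matrix.

    ``N`` is the grand total, ``P = X / N`` the proportion matrix,
    ``row_w`` and ``col_w`` its marginal sums (the row and column
    "masses" of correspondence analysis). The expected proportion under
    row/column independence is the outer product ``row_w[:, None] *
    col_w[None, :]``.
    """

    N: float
    P: np.ndarray
    row_w: np.ndarray
    col_w: np.ndarray

    def expected(self) -> np.ndarray:
        return np.outer(self.row_w, self.col_w)


@dataclass
class ResidualMatrix:
    """Dense chi-squared residual matrix plus transformation provenance."""

    values: np.ndarray
    residual_kind: ResidualKind
    feature_ids: list[str]
    cell_ids: list[str]
    vst: VstMode = "none"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("residual matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CAResult:
    """Truncated SVD of a residual matrix with CA coordinate scores.

    ``U`` (features x k) and ``V`` (cells x k) are orthonormal singular
    vectors, ``d`` the non-increasing singular values. Standard
    coordinates divide the singular vectors row-wise by the square root
    of the corresponding weight; principal coordinates additionally
    scale each component by its singular value. ``pct_inertia`` is
    ``d_k^2`` as a percentage of the total squared singular value over
    the computed components.
    """

    U: np.ndarray
    V: np.ndarray
    d: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    residual_kind: ResidualKind = "pearson"
    vst: VstMode = "none"
    alpha: float = 1.0
    n_components: int = 0
    row_sc: np.ndarray | None = None
    col_sc: np.ndarray | None = None
    row_pc: np.ndarray | None = None
    col_pc: np.ndarray | None = None

    @property
    def pct_inertia(self) -> np.ndarray:
        total = float(np.sum(self.d**2))
        if total == 0.0:
            return np.zeros_like(self.d)
        return 100.0 * self.d**2 / total

    def embedding(self, kind: str = "singular_vectors") -> np.ndarray:
        """Cell-side embedding: raw singular vectors or principal coords."""
        if kind == "singular_vectors":
            return self.V
        if kind == "principal_coords":
            if self.col_pc is None:
                raise ValueError("principal coordinates not computed")
            return self.col_pc
        raise ValueError(f"unknown embedding kind: {kind!r}")


@dataclass
class MultiTableResult:
    """Joint embedding of several batches over their shared features."""

    embedding: np.ndarray
    batch_index: np.ndarray
    cell_ids: list[str]
    shared_features: list[str]
    d: np.ndarray
    feature_coords: np.ndarray
    residual_kind: ResidualKind = "indexed"

    @property
    def n_cells(self) -> int:
        return self.embedding.shape[0]
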