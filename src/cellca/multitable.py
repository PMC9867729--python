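"""corralm: joint correspondence analysis of several count tables.

Batches are integrated by (1) intersecting their features, (2)
computing residuals for each table separately — so each batch keeps its
own weights and internal structure — (3) concatenating the residual
blocks column-wise into one matrix over the shared features, and (4) a
single truncated SVD of the concatenation. Indexed residuals are the
default because they normalize each cell by its expected mass, which
removes per-batch sequencing-depth differences; Freeman–Tukey residuals
are the alternative. There is no explicit batch-correction step: the
per-table scaling is the whole integration mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import CountMatrix, MultiTableResult, ResidualMatrix
from .decomposition import svd_decompose
from .residuals import residuals_for

logger = logging.getLogger(__name__)


@dataclass
class MultiTableSpec:
    """Inputs of a multi-table fit.

    ``batch_names`` defaults to each table's uniform batch label if set,
    otherwise ``batch0``, ``batch1``, ...
    """

    tables: list[CountMatrix]
    residual_kind: str = "indexed"
    n_components: int = 30
    batch_names: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.tables:
            raise ValueError("at least one table required")
        if self.residual_kind not in ("indexed", "freeman_tukey"):
            raise ValueError(
                f"residual_kind must be indexed or freeman_tukey, "
                f"got {self.residual_kind!r}"
            )
        if self.batch_names is None:
            self.batch_names = [f"batch{i}" for i in range(len(self.tables))]
        if len(self.batch_names) != len(self.tables):
            raise ValueError("one batch name per table required")
        if len(set(self.batch_names)) != len(self.batch_names):
            raise ValueError("batch names must be unique")


def match_features(tables: list[CountMatrix]) -> list[CountMatrix]:
    """Subset every table to the shared features, in sorted order.

    The canonical shared order is the lexicographic sort of the feature
    intersection; the SVD downstream is equivariant to any fixed order.
    """
    if not tables:
        raise ValueError("at least one table required")
    shared: set[str] = set(tables[0].feature_ids)
    for t in tables[1:]:
        shared &= set(t.feature_ids)
    if len(shared) < 2:
        raise ValueError(
            f"feature intersection has {len(shared)} features; need >= 2"
        )
    order = sorted(shared)
    logger.info("matched %d shared features across %d tables",
                len(order), len(tables))
    out = []
    for t in tables:
        idx = {f: i for i, f in enumerate(t.feature_ids)}
        rows = [idx[f] for f in order]
        dropped = len(t.feature_ids) - len(rows)
        if dropped:
            logger.info("dropping %d unshared features from a table", dropped)
        out.append(
            CountMatrix(
                values=t.values[rows, :],
                feature_ids=order,
                cell_ids=t.cell_ids,
                batch=t.batch,
            )
        )
    return out


def corralm_fit(spec: MultiTableSpec) -> MultiTableResult:
    """Joint embedding of the tables in ``spec``.

    Cell identifiers are prefixed with their batch name so they stay
    unique in the concatenation; embedding rows follow the input table
    order.
    """
    matched = match_features(spec.tables)
    blocks = []
    for name, table in zip(spec.batch_names, matched):
        try:
            res = residuals_for(table, kind=spec.residual_kind)
        except ValueError as err:
            raise ValueError(f"batch {name!r}: {err}") from err
        blocks.append(res.values)
    M_C = np.concatenate(blocks, axis=1)
    cell_ids = [
        f"{name}_{c}"
        for name, table in zip(spec.batch_names, matched)
        for c in table.cell_ids
    ]
    batch_index = np.concatenate(
        [
            np.repeat(name, table.shape[1])
            for name, table in zip(spec.batch_names, matched)
        ]
    )
    joint = ResidualMatrix(
        values=M_C,
        residual_kind=spec.residual_kind,  # type: ignore[arg-type]
        feature_ids=matched[0].feature_ids,
        cell_ids=cell_ids,
    )
    k = min(spec.n_components, min(M_C.shape))
    result = svd_decompose(joint, k)
    return MultiTableResult(
        embedding=result.V,
        batch_index=batch_index,
        cell_ids=cell_ids,
        shared_features=matched[0].feature_ids,
        d=result.d,
        feature_coords=result.U,
        residual_kind=spec.residual_kind,  # type: ignore[arg-type]
    )
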