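"""Embedding quality metrics: scaled variance, ARI, reference clustering.

Scaled variance (SV) is a batch-integration heuristic: for each batch
and embedding component it is the batch's variance along the component
divided by the overall variance of the component. Well-integrated
batches have SV near 1 — each batch disperses like the whole dataset.
SV assumes batches share a cell-type composition; it cannot flag a
batch whose biology genuinely differs. Sample variance (n-1
denominator) is used on both sides of the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score


@dataclass
class ScaledVarianceResult:
    """SV per batch per component, long-format accessor included."""

    SV: np.ndarray  # (n_batches, n_components)
    batches: list[str]
    components: list[int]  # 1-based component indices evaluated

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"batch": b, "component": c, "SV": self.SV[i, j]}
            for i, b in enumerate(self.batches)
            for j, c in enumerate(self.components)
        ]
        return pd.DataFrame(rows)


def scaled_variance(
    E: np.ndarray,
    batch: np.ndarray,
    components: list[int] | None = None,
) -> ScaledVarianceResult:
    """Per-batch scaled variance of embedding components.

    Parameters
    ----------
    E
        Cells-by-components embedding matrix.
    batch
        Per-cell batch label, length ``E.shape[0]``.
    components
        1-based component indices to evaluate; defaults to the first
        three (or fewer if the embedding is narrower).
    """
    E = np.asarray(E, dtype=float)
    batch = np.asarray(batch)
    if E.ndim != 2 or batch.shape[0] != E.shape[0]:
        raise ValueError("embedding and batch labels are misaligned")
    if not np.all(np.isfinite(E)):
        raise ValueError("embedding contains non-finite values")
    if components is None:
        components = list(range(1, min(3, E.shape[1]) + 1))
    cols = [c - 1 for c in components]
    if min(cols) < 0 or max(cols) >= E.shape[1]:
        raise ValueError("component index out of range")
    batches = sorted(pd.unique(batch).tolist())
    total_var = E[:, cols].var(axis=0, ddof=1)
    SV = np.empty((len(batches), len(cols)))
    for i, b in enumerate(batches):
        mask = batch == b
        if mask.sum() < 2:
            raise ValueError(
                f"batch {b!r} has fewer than 2 cells; variance undefined"
            )
        SV[i] = E[np.ix_(mask, cols)].var(axis=0, ddof=1) / total_var
    return ScaledVarianceResult(SV=SV, batches=[str(b) for b in batches],
                                components=list(components))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    1 for identical partitions up to relabeling, ~0 for chance-level
    agreement. In the degenerate case where the maximum index equals
    the expected index (e.g. all-singletons vs one cluster) the value
    is 1 if the partitions are identical, else 0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(
            f"partition lengths differ: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    return float(adjusted_rand_score(a, b))


def reference_cluster(E: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded k-means partition of an embedding.

    A deliberately simple, deterministic clusterer so that cluster
    recovery can be scored without a graph-clustering dependency; not
    intended to match any particular community-detection algorithm.
    """
    E = np.asarray(E, dtype=float)
    n = E.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} observations")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(E)
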