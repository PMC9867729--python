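"""Synthetic scRNA-seq-like count matrices with known structure.

The generator emulates the standard count model for droplet scRNA-seq:
each cell's transcript counts are multinomial draws from a cluster
expression profile, approximated here as Poisson with a log-normal
library size, optionally with gene-wise gamma multipliers that induce
negative-binomial (gamma-Poisson) overdispersion. Batches can differ in
a library-size multiplier (sequencing depth) and a multiplicative
fold-effect on a subset of genes.

What it does not emulate: zero inflation beyond the count model,
trajectories, gene-length effects, or batch-specific dropout — so
passing tests demonstrate behavior under the stated count model, not
on arbitrary real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import CountMatrix


@dataclass
class BatchConfig:
    """One batch: a name, depth multiplier, and multiplicative effect.

    ``effect_fold`` scales a fraction ``effect_frac`` of genes (a block
    chosen deterministically from the end of the gene list) to mimic a
    technical batch effect; 1.0 disables it.
    """

    name: str = "batch0"
    libsize_multiplier: float = 1.0
    effect_fold: float = 1.0
    effect_frac: float = 0.05


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults generate a moderately easy 3-cluster dataset: 300 genes,
    200 cells per cluster, 10% of genes up-regulated 4-fold per
    cluster, gamma-Poisson dispersion 0.3, and log-normal library
    sizes with median ~2500 counts per cell — magnitudes typical of a
    feature-selected droplet experiment.
    """

    m: int = 300
    n_per_cluster: int = 200
    k_clusters: int = 3
    de_frac: float = 0.1
    de_fold: float = 4.0
    libsize_log_mean: float = float(np.log(2500.0))
    libsize_log_sd: float = 0.35
    dispersion: float = 0.3
    batches: list[BatchConfig] = field(default_factory=lambda: [BatchConfig()])
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.m, self.n_per_cluster, self.k_clusters) < 1:
            raise ValueError("m, n_per_cluster and k_clusters must be >= 1")
        if not (0.0 <= self.de_frac <= 1.0):
            raise ValueError("de_frac must be in [0, 1]")
        if self.de_fold <= 0:
            raise ValueError("de_fold must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not self.batches:
            raise ValueError("at least one batch required")


def make_profiles(config: SimulationConfig) -> np.ndarray:
    """Per-cluster gene proportion vectors, shape (k_clusters, m).

    A shared log-normal base profile is drawn, then each cluster
    up-regulates its own disjoint block of ``de_frac * m`` genes by
    ``de_fold`` and renormalizes. Blocks overlap (with a warning) only
    when ``k_clusters * de_frac > 1``.
    """
    rng = np.random.default_rng(config.seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.m)
    base /= base.sum()
    n_de = int(round(config.de_frac * config.m))
    if config.k_clusters * n_de > config.m:
        warnings.warn(
            "k_clusters * de_frac > 1: differential blocks overlap",
            stacklevel=2,
        )
    profiles = np.tile(base, (config.k_clusters, 1))
    for c in range(config.k_clusters):
        start = (c * n_de) % max(config.m, 1)
        idx = (np.arange(n_de) + start) % config.m
        profiles[c, idx] *= config.de_fold
        profiles[c] /= profiles[c].sum()
    return profiles


def sample_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Draw a count matrix; returns (counts, cluster labels, batch labels).

    Each batch contains the full cluster design (``n_per_cluster``
    cells per cluster). Per cell: library size L ~ log-normal times the
    batch multiplier; with dispersion > 0, counts ~ Poisson(L * pi_g *
    gamma_g) with gene-wise gamma multipliers of mean 1 and variance
    ``dispersion``; with dispersion = 0 counts are multinomial(L, pi).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    profiles = make_profiles(config)

    cols: list[np.ndarray] = []
    clusters: list[int] = []
    batches: list[str] = []
    for b in config.batches:
        batch_profiles = profiles.copy()
        if b.effect_fold != 1.0:
            n_eff = int(round(b.effect_frac * config.m))
            if n_eff:
                batch_profiles[:, config.m - n_eff:] *= b.effect_fold
                batch_profiles /= batch_profiles.sum(axis=1, keepdims=True)
        for c in range(config.k_clusters):
            pi = batch_profiles[c]
            L = (
                rng.lognormal(config.libsize_log_mean, config.libsize_log_sd,
                              size=config.n_per_cluster)
                * b.libsize_multiplier
            )
            if config.dispersion > 0:
                shape = 1.0 / config.dispersion
                gamma = rng.gamma(
                    shape, config.dispersion,
                    size=(config.n_per_cluster, config.m),
                )
                lam = L[:, None] * pi[None, :] * gamma
                block = rng.poisson(lam)
            else:
                block = np.stack(
                    [
                        rng.multinomial(int(round(l)), pi)
                        for l in L
                    ]
                )
            cols.append(block.T)  # genes x cells
            clusters.extend([c] * config.n_per_cluster)
            batches.extend([b.name] * config.n_per_cluster)
    values = np.concatenate(cols, axis=1).astype(float)
    n_total = values.shape[1]
    counts = CountMatrix(
        values=values,
        feature_ids=[f"gene{i:05d}" for i in range(config.m)],
        cell_ids=[f"cell{j:06d}" for j in range(n_total)],
        batch=np.asarray(batches),
    )
    return counts, np.asarray(clusters), np.asarray(batches)
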