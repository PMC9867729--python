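# Methods

## Model

Correspondence analysis treats a non-negative feature-by-cell table as
a contingency table. With grand total `N`, proportions
`p_ij = x_ij / N` and marginal masses `p_i.` (features) and `p_.j`
(cells), the independence expectation for a cell of the table is
`p_i. p_.j`. The package decomposes one of three residual matrices
with a truncated SVD `M = U D Vᵀ`, `UᵀU = VᵀV = I`:

| residual | formula | use |
|---|---|---|
| Pearson | `(p − E)/√E`, `E = p_i. p_.j` | standard CA; `N·Σr²` = chi-squared statistic |
| Freeman–Tukey | `√p + √(p + 1/N) − √(4E + 1/N)` | overdispersed sparse counts (CA-FT) |
| Indexed | `(p − E)/E` | multi-table integration; `observed = (1+r)·expected` |

Pearson residuals are exactly independence-centered: rank-1 tables
`X = a bᵀ` give a zero matrix, and `Σ_i √p_i. r_ij = 0` per column
(dually per row), so the decomposition never spends a component on the
grand mean. Pearson and indexed residuals depend only on the
proportions and are invariant to a global rescaling of the table.
Freeman–Tukey residuals depend on `N`: as the table grows at fixed
proportions each entry converges to the Hellinger-type limit
`2(√p − √E)`. At finite `N` the FT matrix is *not* exactly centered
(the uniform 2×2 table gives ≈0.089 per cell, not 0), so its leading
component can absorb a near-constant term. We decompose the FT matrix
as-is — no component is discarded — and in practice the
structure-bearing components follow immediately; this is a documented
behavior, not a defect.

Optional pre-transforms (square root, Anscombe `2√(x + 3/8)`,
Freeman–Tukey `√x + √(x+1)`) stabilize Poisson-family variance before
Pearson residuals; when a transform is applied, weights, residuals and
the inertia identity all refer to the transformed table. They compose
freely with either residual family in the API, although combining a
VST with FT residuals buys little — the FT residual is already
variance-stabilizing. Power deflation `r* = sgn(r)·|r|^α` softly
shrinks outlying residuals; it preserves sign, zeros and the magnitude
ranking and is the identity at `α = 1`. Default `α = 0.9`, in the
recommended "just below 1" band; the package makes no optimality
claim for any particular α.

Non-integer input (e.g. logcounts) is accepted everywhere: every
formula above is well defined for non-negative reals.

## Coordinates and embeddings

Standard coordinates divide each singular vector row-wise by the
square root of its mass (`row_sc = U / √p_i.`, `col_sc = V / √p_.j`);
principal coordinates scale them column-wise by the singular values.
Written descriptions of CA sometimes say "divide by the weights"
without the square root; we use the √-mass convention, under which
standard coordinates have unit weighted variance per component and the
two coordinate systems differ per component exactly by `d_k`. The cell
embedding handed to clustering is `V` by default; principal
coordinates are available behind a flag. Percent inertia is reported
relative to the computed components only — with a truncated
decomposition the full-rank total is not available.

Degenerate inputs: all-zero rows/columns are dropped with a warning
before weighting (every residual divides by the masses); a table that
degenerates below 2×2 is an error, as are expected proportions below
1e−300. SVD sign ambiguity is resolved by flipping each component so
its largest-magnitude feature loading is positive, making repeated
runs bit-identical. Dense LAPACK SVD is used when `min(m, n) ≤ 100` or
a near-full-rank decomposition is requested; otherwise a Lanczos
solver with tolerance 1e−10 and a fixed deterministic start vector.

Component selection uses the scree elbow: the interior scree point
with the largest perpendicular distance to the chord joining the first
and last points; ties (flat or linear screes) resolve to the smallest
interior index. Biplot preparation pairs all cell coordinates in
components 1–2 with the `k` features furthest from the origin in that
plane (ties in norm break lexicographically by feature id).

## Multi-table integration

`corralm_fit` intersects the feature lists (sorted order; SVD is
order-equivariant), computes residuals per table — each batch keeps
its own `N` and masses, preserving internal structure — concatenates
the residual blocks column-wise and runs one joint SVD. Indexed
residuals are the default because dividing by the expected proportion
removes per-cell depth, so a global depth shift between batches
cancels exactly (scaling one table's counts by any `c > 0` leaves its
residual block unchanged); Freeman–Tukey residuals are the
alternative. There is no explicit correction step, so strong nonlinear
batch effects are out of scope by design. Cell ids are prefixed with
the batch name on concatenation.

## Evaluation

Scaled variance of batch `b` in component `d` is
`SV = Var(E_{b,d}) / Var(E_d)` with sample variances (n−1) on both
sides — the variance convention is a package choice and shifts SV
slightly for small batches. SV ≈ 1 for every batch indicates matched
dispersion. SV is meaningful only on ranked, structure-bearing
components; on a pure-noise component the batch with deeper sequencing
necessarily shows less residual noise, and SV will flag that even
though nothing failed to integrate. It also cannot detect a batch
whose cell-type composition genuinely differs. Default: first three
components.

ARI is the Hubert–Arabie pair-counting index (delegated to
scikit-learn; tested against a brute-force pair-enumeration oracle).
`reference_cluster` is seeded k-means (`n_init = 10`) — a deliberately
simple, deterministic stand-in for graph-based clustering so that
recovery scores are self-contained; it is not an emulation of
walktrap.

## Synthetic data

The generator draws a shared log-normal expression profile, gives each
cluster a disjoint block of `de_frac · m` genes up-regulated
`de_fold`-fold (renormalized), log-normal library sizes, and
gamma-Poisson counts: gene-wise gamma multipliers with mean 1 and
variance `dispersion` make the counts negative-binomial;
`dispersion = 0` falls back to multinomial sampling. Batches replicate
the cluster design and may differ in a depth multiplier and a
multiplicative fold-effect on a trailing gene block. One seed governs
all draws.

Defaults — 300 genes, 3 clusters × 200 cells, `de_frac = 0.1`,
`de_fold = 4`, `dispersion = 0.3`, median depth ≈ 2500 — describe a
moderately easy, feature-selected droplet-style experiment and are the
conditions under which the package's cluster-recovery behavior is
demonstrated (CA-FT, 10 components, 20 replicates). The integration
demonstration uses two such batches at 1× and 2× depth with **four**
clusters so that the three components SV is evaluated on each carry
population structure; with three clusters only two structural
components exist and the third would measure depth-dependent sampling
noise, which SV is not designed to assess. Problem sizes (600–1600
cells, 300 genes) are deliberately compact so the full demonstration
suite re-runs in seconds.

What the generator does not emulate: zero inflation beyond the count
model, dropout, trajectories, gene-length or cell-cycle effects, or
batch-specific cell-type composition. Passing tests therefore
demonstrate correctness under the stated count model, not performance
on arbitrary real data.

## Known limitations

- Residual matrices are materialized dense; bound `m` with feature
  selection (the CLI's `--feature-top-k`) for large tables.
- No supplementary projection of new cells/batches into an existing
  space.
- The cell-matched (multi-omic) variant of multi-table CA is not
  implemented.
- SV and ARI are heuristics with the caveats above; neither replaces a
  full integration benchmark.
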