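# Methods

## Model and procedure

`carousel` compresses a sparse cell-by-region accessibility count matrix
`X ∈ R^{n×p}` into a metacell-by-region matrix. The driving assumption is
that cells of one type form tight neighbourhoods in a TF-IDF/PCA embedding
of the binarized matrix, so small graph communities are type-homogeneous
and their average raw profile is a faithful, far denser representative.

The pipeline is strictly chunked: cells are split, in their stored order,
into `⌈n/c⌉` contiguous chunks of `c` cells, and **metacells never span
chunks**. This is what bounds memory — only one chunk's dense intermediate
objects exist per worker — at the price that cells of one type landing in
different chunks are never merged. Chunks are processed independently
(joblib, up to `m` processes) and every per-chunk step is deterministic
given the configuration, so the combined output is identical for any `m`
and any completion order; results are assembled in chunk order.

### Per-chunk graph construction

1. **Binarization**: any positive count becomes 1; scCAS counts are
   near-binary and binarization is the standard first step.
2. **Region filter**: keep regions open in strictly more than `frac·c`
   cells (default `frac = 0.01`). The inequality is strict ("more than"),
   so at `c = 1000` a column sum of 10 is dropped and 11 kept. Filtering
   affects only the graph; aggregation always uses raw counts over all `p`
   regions.
3. **TF-IDF**: `TF[i,j] = B[i,j]/rowsum_i`, `IDF[j] = ln(1 + n_chunk/df_j)`.
   This variant is smooth and zero-safe: all-zero rows map to zero rows
   (such cells stay in the pipeline and embed at the centred origin — no
   cell is ever dropped), and `df = 0` columns get IDF 0 rather than ∞.
4. **PCA** to `min(50, cells−1, regions)` components, mean-centred,
   components ordered by explained variance; the sklearn solver is seeded
   so randomized SVD (chosen automatically for large inputs) is
   deterministic.
5. **kNN connectivity** (`k = 15`): exact Euclidean k-nearest neighbours,
   self excluded, with locally-scaled Gaussian weights

       w_ij = exp(−(d_ij² − ρ_i ρ_j)/(σ_i σ_j)),

   where `ρ_i` is the distance from `i` to its nearest neighbour and `σ_i`
   to its k-th. For any kNN edge `ρ_i ≤ d_ij` and `ρ_j ≤ d_ij`, so weights
   lie in (0, 1] with the mutual-nearest pair at exactly 1; the graph is
   symmetrized by elementwise maximum and the diagonal forced to zero.
   The `ρ_i ρ_j` shift (rather than a plain `exp(−d²/σσ)`) anchors the
   scale at each cell's own neighbourhood; the downstream random walk only
   needs a bounded, symmetric, locally-adaptive affinity, and partitions
   are stable for `k` in roughly [10, 30] on the synthetic fixtures.

### Walktrap with a community-count cut

Degrees `d_a = Σ_b U_ab`, transition matrix `P = V⁻¹U` (`V = diag(d)`),
walk length `l = 4` (the conventional choice; configurable). Embedding each
vertex as `φ_a = V^{−1/2} P^l_{a·}` makes the walk distance
`r_ab = ‖φ_a − φ_b‖₂` and the community distance the distance of member
means. The merge cost

    Δσ(Y₁,Y₂) = (1/c)[Σ_{a∈Y₃} r²_{aY₃} − Σ_{a∈Y₁} r²_{aY₁} − Σ_{a∈Y₂} r²_{aY₂}]

is, by the standard Ward identity in φ-space, equal to
`(1/c)·|Y₁||Y₂|/(|Y₁|+|Y₂|)·r²_{Y₁Y₂}`; the merge loop maintains per-community
φ-sums and uses the closed form, while `merge_cost()` evaluates the
definitional sum — the test suite checks, against an independent
brute-force implementation, that both produce identical merge sequences on
random graphs.

Design points:

- **Cut rule**: the dendrogram is cut at a *requested community count*
  `⌈n_i/γ⌉` (γ = cells-per-metacell resolution, ceiling so every chunk
  yields ≥ 1 metacell), not at the modularity-optimal level.
- **Tie-break**: among candidate pairs within 1e-12 of the minimum cost,
  the lexicographically smallest pair of community representatives (each
  community represented by its minimum member index) merges. The tolerance
  band also absorbs float differences between the closed-form and
  definitional evaluations, keeping the sequence deterministic.
- **Only adjacent pairs merge** (pairs joined by at least one graph edge).
- **Disconnected graphs**: the loop runs per connected component; the
  community budget is split across components proportionally to size by
  largest remainder, every component receiving at least one and at most
  its size. Isolated vertices are size-1 components and become singleton
  metacells. (The kNN construction itself never produces isolated
  vertices.)
- `P^l` is computed exactly as a dense matrix power per component. At the
  chunk sizes this package targets (≤ a few thousand cells per chunk) the
  dense `c×c` walk matrix is cheap; chunking is what keeps `c` small.

### Aggregation

Each community's raw integer rows are averaged elementwise, giving a real
valued metacell row over all `p` regions. Mass conservation —
`Σ_j size_j · row_j` equals the raw column sums — holds to float64
round-off (≈1 ulp per division), which is what tests assert (`rtol 1e-10`);
exact bit-level equality is not attainable after an integer sum is divided
and re-multiplied. Member cell identifiers are stored in the output's
`obs["members"]`, joined by `";"`, with `n_members` and source `chunk`
alongside; the full configuration goes into `uns["carousel_config"]`.

## Evaluation protocol

The metacell matrix is binarized (strictly positive means count as open —
0.2 → 1), then regions open in strictly more than `0.01·s_mc/s_o` of the
metacells are kept, where `s_o` and `s_mc` are the non-zero proportions of
the raw and metacell matrices. Aggregation densifies (`s_mc/s_o` ≈ 10 on
the default fixture), so the threshold scales up to remain selective.

Clustering reuses the preprocessing TF-IDF/PCA/kNN with one deliberate
departure: the number of PCA components requested is capped at
`(n_metacells − 1)//2` (still at most 50). With only a few dozen
metacells, retaining nearly full rank reproduces the raw pairwise
distances, the binarization noise floor dominates, and type separation
collapses; halving the rank is the usual small-sample PCA adjustment and
restores separation without affecting runs with hundreds of metacells.

Louvain is igraph's weighted multilevel algorithm (seeded through Python's
`random`, which igraph's default RNG delegates to); Leiden is `leidenalg`
with the RBConfiguration objective and an explicit seed. D-strategies use
resolution 1.0 (the common default). C-strategies bisect the resolution on
[1e-3, 10] (≤ 50 halvings) until the cluster count equals the known number
of cell types, assuming the count is weakly increasing in resolution; if
the target is never hit, the probed resolution with the closest count (ties
→ lower resolution) is used and a warning logged, with the full search
trace kept in the report. Metacell labels propagate to member cells, and
agreement uses sklearn: AMI and NMI with arithmetic-mean normalization
(variants differ, so this is pinned in the docstring), Hubert–Arabie ARI,
entropy-based homogeneity/completeness, Fowlkes–Mallows. Purity is the
fraction of a metacell's members sharing its dominant true type; dominant
type ties break to the lexicographically smallest label.

## Synthetic data

The generator draws each cell's type from given proportions, gives type
`t` a disjoint block of `markers_per_type` marker regions open with
probability `p_marker` in matching cells, and opens every other entry with
probability `p_background`; dropout then zeroes exactly
`⌊dropout·nnz⌋` uniformly chosen non-zeros (never creating any), and an
optional Poisson lift (`1 + Poisson(0.2)` on open entries) produces counts
above 1 to exercise binarization. Defaults: 3000 cells × 5000 regions,
5 equal types, 200 markers/type, `p_marker = 0.25`, `p_background = 0.01`,
no dropout — a desk-scale regime where marker signal (≈50 open markers per
cell) and background (≈50 open background regions) are balanced enough to
be non-trivial yet separable.

What the fixture does *not* emulate: fragment-level sampling depth,
batch effects, doublets, correlated peaks, or gradual (trajectory-like)
population structure. Passing tests therefore demonstrate correctness of
the algorithmic machinery and robustness to random dropout at the stated
rates, not performance on real tissue atlases.

## Numerical choices and limitations

- Walk length `l = 4`; region-filter fraction 0.01; `k = 15`; 50 PCA
  components; resolution default γ = 75 in the CLI (typical atlas-scale
  choice), γ = 20 in the desk-scale examples so chunks of 500 yield 25-cell
  metacells.
- Merge-cost non-negativity is asserted at 1e-12; the dispersion
  decomposition (total within-community dispersion rises by exactly Δσ per
  merge) at 1e-10.
- Degenerate chunks (no retained regions, fewer than 2 cells, or a target
  community count ≥ cell count) fall back to singleton metacells.
- Chunking in stored order means the method inherits any ordering bias of
  the input file; cross-chunk merging is intentionally out of scope.
- Problem sizes in the tests (3000 cells, chunks of 250–1000, 200 random
  graphs of ≤ 12 vertices for the oracle comparison) were chosen as the
  smallest scales at which every contract — conservation, determinism,
  structure recovery under noise, oracle equivalence — is informative.
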