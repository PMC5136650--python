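# Methods

This note documents the models and procedures implemented in
`ecostream`, the conventions and numerical choices behind them, what
the synthetic data generator does and does not emulate, and the known
limitations.

## Taxonomic distances (taxa2dist)

Input is a classification aggregation table: one row per species, one
column per taxonomic rank ordered lowest (e.g. genus) to highest. The
table must be strictly hierarchical — two species sharing a category at
some rank must share categories at all higher ranks — and this is
validated at load time with an error naming the offending pair.

Category richness r_k is the number of distinct categories at rank k.
With `check` enabled (the default), ranks with r_k == S (every species
distinct) or r_k == 1 (every species identical) carry no grouping
information and are dropped; if nothing remains the computation fails
rather than producing degenerate zero-length steps. Kept ranks are
ordered by decreasing richness, which for a hierarchical table is
lowest rank first; ties preserve input order, making the output
deterministic.

Path lengths through the K+1 levels (species → rank 1 → … → rank K →
root) are either equal, each 100/(K+1), or, with `varstep`,
proportional to the relative drop in richness:
raw steps ((S−r₁)/S, (r₁−r₂)/r₁, …, (r_K−1)/r_K), normalised to sum
to 100. The distance ω(i,j) is the cumulative step length up to the
lowest level at which i and j agree; the species level itself is the
first step, so two distinct species sharing every kept rank are one
increment apart and ω = 0 only on the diagonal. Scaling to a maximum of
100 is always applied; it fixes the funnel-plot and Δ⁺ scales. The
construction is the classic path-length distance used for distinctness
indices; our equal-step and varstep outputs were cross-checked against
an independent R implementation to ten significant digits on a frozen
fixture (see `tests/test_reference_values.py`).

With `check` disabled all ranks are kept but the same species-level
base step applies; we deliberately keep ω positive for distinct species
in this mode as well, trading exact parity with other implementations
for the invariant that ω = 0 identifies identical species.

The computational primitive is the row block: rows [r0, r1) of ω are
computed vectorially from integer category codes (base step plus one
masked add per kept rank) without reference to any other row. Blocks of
any size concatenate to exactly the same matrix, which the tests assert
for block sizes {1, 7, 64, S}. The default block size targets ~64 MiB
of float64 per block; the dense assembler refuses pools whose S×S
matrix would exceed a 2 GiB budget and points the caller to the
streaming pipeline instead.

## Diversity indices (taxondive) and the streaming pipeline

Per sample with abundances x and presence indicators p:

- Δ  = Σ_{i<j} ω_ij x_i x_j / (N(N−1)/2), N = Σx
- Δ* = Σ_{i<j} ω_ij x_i x_j / Σ_{i<j} x_i x_j
- Δ⁺ = Σ_{i<j present} ω_ij / (S_s(S_s−1)/2), sΔ⁺ = S_s Δ⁺
- Λ⁺ = Σ_{i<j present} ω_ij² / (S_s(S_s−1)/2) − (Δ⁺)²
- EΔ⁺ = mean ω over all pool pairs.

The Σxx denominator of Δ* uses i<j pairs only (no self-pairs),
consistent with the numerator. Indices whose denominator vanishes
(S_s < 2 for Δ⁺/Λ⁺, N < 2 for Δ, Σxx = 0 for Δ*) are NaN with a logged
warning rather than an error, keeping batch runs alive in the style R
users expect of propagating NAs.

Every index is a pair sum, so the streaming pipeline folds each ω row
block (strict upper triangle only) into five per-sample accumulators —
Σωxx, Σω over present pairs, Σω² over present pairs, plus closed-form
pair counts — and discards the block. Distances are computed once and
consumed by all accumulators in the same pass; no pairwise distance is
ever computed twice, and peak distance memory is a single block
(recorded in the result as `peak_block_nbytes`). Streaming and dense
paths agree to better than 1e-12 relative in practice; the acceptance
tests require 1e-10 across 20 random fixtures and all block sizes. The
scale test in the default suite runs S = 20,000 (a ~3 GiB dense matrix,
never allocated) in well under a minute; this size was chosen as a
desk-scale stand-in for the six-digit pools the pipeline targets, with
the same code path and accounting.

Blocks may optionally be spilled to a block store: an in-memory dict or
a directory backend writing one raw binary file per key with a JSON
sidecar of shape and dtype (so the store survives restarts). The store
contract is deliberately minimal — keyed, write-once, bitwise get —
abstracting over any particular secondary-storage technology.

## Funnel tables

The funnel of Δ⁺ against subsample richness m is estimated by Monte
Carlo: draw n_draws uniform m-subsets of the pool, compute Δ⁺ of each,
report the mean and the empirical 2.5%/97.5% quantiles. Δ⁺ of a random
subset is unbiased for EΔ⁺, which the tests check. A closed-form
variance exists in the literature but is not implemented; Monte Carlo
is assumption-free, and the draw count and seed are explicit arguments
so tables are reproducible.

## The permutation engine

A permutation budget nperm is split into chunks of `chunk_size`
executed by a thread pool. The engine's central contract is
per-permutation seeding: the random stream of permutation t is
`PCG64(SeedSequence([master_seed, t]))`, a splitmix-style hash
derivation that depends only on the pair (master_seed, t). Chunk layout
and worker count therefore cannot affect which permutation is drawn at
index t, exceedance counts are integers summed over chunks, and the
full result of every downstream test is bitwise identical for workers
∈ {1, 2, 4, …} and any chunk size — asserted directly in the tests.
This is deliberately stronger than requiring correct aggregate counts:
it makes parallel runs auditable against serial ones.

p-values use (1 + #{perm stat ≥ observed}) / (1 + nperm), ties counting
as exceedances, so p is never zero and the test is exact-level
conservative. Under exchangeable nulls the suite checks rejection at
the 5% level stays within [0.02, 0.08] over hundreds of replicates.
Statistics may be vectors (SIMPER's per-species contributions), in
which case exceedance counts and p-values are aligned vectors.

Threads rather than processes back the pool: the statistics spend their
time in numpy kernels that release the GIL, and threads avoid
serialising the dataset per chunk. Nothing in the contract depends on
the backend.

## Group tests

**ANOSIM.** All n(n−1)/2 dissimilarities are ranked once with midranks
for ties; R = (mean between-group rank − mean within-group rank) /
(M/2) with M = n(n−1)/2, so R ∈ [−1, 1] and the statistic is invariant
to any strictly monotone transform of the dissimilarities. The null
permutes sample labels; ranks are not recomputed.

**One-way PERMANOVA.** SS_total = (1/n) Σ_{i<j} d_ij²; SS_within =
Σ_g (1/n_g) Σ_{i<j∈g} d_ij²; pseudo-F = (SS_among/(a−1)) /
(SS_within/(n−a)). On univariate Euclidean data this is exactly the
classical one-way ANOVA F, and it matches a dense Gower-centred
hat-matrix formulation to 1e-9 (both are test oracles). Zero
within-group SS yields an infinite F, reported with a flag rather than
an error; permuted statistics that are also infinite count as
exceedances under the ≥ convention, so p remains well defined. Scope is
a single factor — sequential multi-factor decompositions are
out of scope.

**SIMPER.** For each between-group sample pair (u, v), species k
contributes |u_k − v_k| / Σ_l(u_l + v_l); averaging over pairs makes
the per-species contributions sum exactly (to 1e-12, asserted) to the
mean between-group Bray-Curtis dissimilarity. Contributions are
reported on the 0–1 dissimilarity scale (the CLI offers `--percent`).
Raw abundances are used — no transformation is applied implicitly. The
permutation test keeps sample profiles intact and permutes group
labels only, drawing group-sized index sets from a permutation of all
samples; each species' p asks whether its average contribution exceeds
the label-shuffled expectation.

## Relation tests

**Mantel.** r is the Pearson correlation of the two condensed vectors
(Spearman = Pearson on midranks). The null permutes rows and columns of
the first matrix simultaneously by one sample permutation — the second
matrix is never touched. The partial statistic is
r_xy·z = (r_xy − r_xz r_yz) / √((1−r_xz²)(1−r_yz²)), with the first
matrix permuted and r_yz held fixed. When a control correlation is
exactly ±1 the control is an affine copy of one matrix, which forces
the numerator to zero as well; the 0/0 degenerate case is reported as
partial r = 0, and a genuinely inconsistent near-singular case raises.

**BioEnv.** Environmental variables are centred and scaled to unit
sample standard deviation (n−1 denominator — stated so tests can be
exact); candidate subsets get Euclidean distances and a Spearman rank
correlation ρ against the community dissimilarities. The search is
exhaustive over all non-empty subsets up to `max_size`, flattened in
size-then-lexicographic order and split into chunks for the worker
pool; per-size winners and the overall winner are reduced with a
deterministic tie-break (higher ρ, then smaller subset), so results are
independent of chunking — asserted bitwise in tests. Spearman is the
only correlation offered here, mirroring the method's definition;
Mantel defaults to Pearson with Spearman available. Because the number
of subsets is Σ_k C(ncol, k), exhaustive search is capped at ncol = 15
by default (overridable with `force`), and requesting more workers than
variables triggers a warning that the extra processors cannot help.

## Condensed form and I/O conventions

All pairwise dissimilarities live in condensed form: pair (i, j), i<j,
at index i(2n−i−1)/2 + (j−i−1) — the scipy `pdist` layout, asserted
against it in tests. Square matrices exist only at I/O boundaries.
Ranking uses midranks everywhere.

CSV dialect: comma separator, UTF-8, '.' decimal, first row header,
first column row labels. Community files are rows = samples (an
explicit `--transpose` flag exists; orientation is never guessed).
Species lists of the community and aggregation tables must match
exactly — no silent intersection, since dropping species silently
changes what the distinctness indices mean. Missing values are load
errors; none of the implemented statistics defines NA semantics.
Distance CSVs are written with 17 significant digits so read-back is
bit-exact.

## Synthetic data

The generator produces the four input kinds with deterministic output
given a master seed (all draws go through `SeedSequence([seed,
stream])`). Classifications are random nested assignments honouring a
strictly decreasing per-rank category-richness profile (each category
surjectively mapped to a parent). Abundances are zero-inflated
log-normal — log-mean 1.0, log-sd 1.0, 30% zeros by default, a typical
right-skewed sparse community shape — with species-level log-mean
jitter (sd 0.5). Two equal groups are built in; a group effect shifts
the log-mean of a random 30% of species in the second group, so effect
0 gives exchangeable groups for null simulations. Environmental
variables are independent standard normals except an optional planted
variable constructed as coupling·z + √(1−coupling²)·noise, where z is
the standardised first principal-coordinate axis of the community's
Bray-Curtis distances — a monotone function of the main ordination
gradient, giving subset search a known right answer.

Named scales tiny/small/medium/large/xl map to S = 30 / 1,700 / 16,900
/ 42,300 / 168,931 species; tests run at S ≤ 300 plus one S = 20,000
scale check, sizes chosen to exercise every code path at desk scale.
The generator emulates shape, sparsity, nestedness and effect
structure, not any real dataset: passing tests demonstrate algorithmic
correctness and statistical calibration under these models, not
ecological conclusions about real communities. In particular real
classification tables have unbalanced richness profiles and real
abundance data have taxon-correlated occupancy, neither of which the
generator attempts.

## Known limitations

- One-way designs only for PERMANOVA; no stratified or nested ANOSIM.
- Bray-Curtis and scaled Euclidean are the only built-in
  dissimilarities (external distance matrices are accepted everywhere).
- BioEnv is exhaustive only; no stepwise heuristic for large ncol.
- Sampled permutations only — no exact-enumeration shortcut for tiny
  designs (the enumeration appears in tests as an oracle).
- The funnel table uses Monte-Carlo bounds, not the closed-form
  variance.
- Parallelism is a single-machine worker pool; multi-node execution is
  out of scope, though the per-permutation seeding contract would make
  it straightforward.
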