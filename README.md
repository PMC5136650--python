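# ecostream

Blocked, reproducible community-ecology statistics for Python:
taxonomic distinctness indices computed in a streaming, block-wise
fashion that never materialises the full species distance matrix, plus
the standard permutation tests of community structure — ANOSIM, one-way
PERMANOVA (adonis), Mantel and partial Mantel, SIMPER — and the BioEnv
best-subset search, all run through a chunked permutation engine whose
results are bitwise invariant to the number of workers and the chunk
layout.

It is written for ecologists and microbiologists who analyse
sample-by-species abundance tables together with taxonomic
classifications, grouping factors and environmental measurements, and
who hit two practical walls with the conventional tools: species pools
whose S×S distance matrix no longer fits in memory, and permutation
budgets (up to 10⁷ and beyond) that beg for parallelism without
sacrificing exact reproducibility.

## The statistics

For species pairs *i < j* with taxonomic path-length distances
ω<sub>ij</sub> (scaled so the maximum is 100) and per-sample abundances
x<sub>i</sub> (N individuals, S<sub>s</sub> species present):

- **Δ** (taxonomic diversity) = Σ ω<sub>ij</sub> x<sub>i</sub> x<sub>j</sub> / (N(N−1)/2)
- **Δ\*** (taxonomic distinctness) = Σ ω<sub>ij</sub> x<sub>i</sub> x<sub>j</sub> / Σ x<sub>i</sub> x<sub>j</sub>
- **Δ⁺** = mean ω over species pairs present (presence/absence), with
  **sΔ⁺** = S<sub>s</sub>·Δ⁺ and **Λ⁺** = variance of ω over present pairs
- **EΔ⁺** = mean ω over the whole pool, the funnel-plot centre line.

ω comes from a classification aggregation table (species × ranks): the
distance between two species is the cumulative step length up to the
lowest rank at which they agree, with equal steps per level or steps
proportional to the relative drop in category richness (`varstep`).
Because each accumulator above is a sum over pairs, the S×S matrix can
be consumed as row blocks and discarded — the streaming pipeline's peak
distance memory is one block for any pool size.

The permutation tests use the standard estimator
p = (1 + #{perm ≥ obs}) / (1 + nperm). Every permutation draws its
random stream from (master seed, permutation index) alone, so chunks
can be executed by any number of workers in any layout and the counts,
p-values and statistics do not change by a single bit.

## A worked example

```python
import numpy as np
import ecostream as es

agg = es.AggregationTable(
    ["A", "B", "C"], ["genus", "family"],
    np.array([["g1", "f1"], ["g1", "f1"], ["g2", "f1"]], dtype=object))
omega, labels = es.taxa2dist_full(agg)
print(omega)
comm = es.CommunityMatrix(["site1"], ["A", "B", "C"], [[1.0, 1.0, 2.0]])
r = es.taxondive_naive(comm, omega)
print(r.delta[0], r.delta_star[0], r.delta_plus[0], r.lambda_plus[0])
```

prints

```
[[  0.  50. 100.]
 [ 50.   0. 100.]
 [100. 100.   0.]]
75.0 90.0 83.33333333333333 555.5555555555566
```

A and B share a genus (ω = 50); C sits in another genus (ω = 100, the
scale maximum, since the shared family rank is uninformative here and
dropped). With abundances (1, 1, 2) the expected distance between two
random individuals is Δ = 75; conditioning on the two individuals being
different species raises it to Δ\* = 90; ignoring abundances entirely,
the average distance between the three present species pairs is
Δ⁺ = 83.3 with variance Λ⁺ = 555.6.

The same numbers come out of the streaming path
(`es.taxondive_streaming(comm, agg, block_rows=1)`), which is the form
you use when S is five or six digits. See `examples/` for complete
narrative scripts (group tests, environmental association, a
5,000-species streaming run), and the `ecostream` command for the
shell interface:

```
ecostream fixtures --species 200 --samples 12 --effect 1 --seed 1 --out data/
ecostream taxondive --comm data/community.csv --agg data/aggregation.csv --out out/
ecostream anosim --comm data/community.csv --factor data/factor.csv \
    --nperm 999 --seed 1 --workers 4 --out out/
```

Every run writes a `manifest.json` (configuration, seed, version, wall
time); re-running with the same manifest reproduces the statistic files
byte for byte.

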