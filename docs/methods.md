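# Methods

## Model

A pathway over a gene set is a directed acyclic graph (DAG) on
gene-activity nodes whose skeleton is contained in an undirected
protein-interaction (PPI) scaffold. The phenotype (fitness) is the
implicit leaf of every local structure and never appears as a graph
node; the model uses only the conditional-independence consequence of
full epistasis: if *x* lies downstream of *y* (any directed path
*y → … → x*), the double-mutant fitness is independent of *y*'s state
given *x*'s, so its predicted value is `S(x)`. No conditional
probability tables are estimated — the data measure phenotype, not
gene-to-gene influence, so only the pairwise independence structure is
scored.

### Pair topologies

Ancestry (not adjacency) classifies each unordered pair under a
candidate DAG into exactly one of four kinds:

| kind | condition | predicted mean | default prior |
|---|---|---|---|
| x-downstream | y is an ancestor of x | `S(x)` | 1/4 |
| y-downstream | x is an ancestor of y | `S(y)` | 1/4 |
| parallel | same weak component, neither ancestral | `E(x, y)` | 1/4 |
| unlinked | different components | `E(x, y)` | 1/4 |

The score of a pair under a kind is `ln p_t + ln N(D(x,y); μ_t, σ²)`;
the global log-score of a network is the sum over all pairs, and the
posterior is proportional to its exponential. Parallel and unlinked
share a predicted mean and are distinguished only by their priors;
with the default equal priors they are interchangeable in the score,
but the classification (and hence reported substructures) still
separates them. Priors are configurable per run. All scores are kept
in log-space (nats): the exponential form overflows for realistic pair
counts.

### Parameters

- `σ²` — replicate variance of the fitness measurements (fitness²).
  A scalar by default (0.0025, i.e. replicate SD 0.05 on a 0–1 fitness
  scale, typical for colony-size screens), overridable by a per-pair
  matrix when replicate counts vary.
- `E(x, y)` — neutral expectation; `multiplicative` (`S(x)·S(y)`,
  default, the standard neutral model for fitness) or `minimum`.
- topology priors — four probabilities summing to 1; default uniform.

## Sampling

Annealed importance sampling with a ladder
`1 = β_0 > … > β_{m−1} = 0` (default m = 200, linear spacing; a
geometric option concentrates levels near β = 0). Tempered level *j*
targets `f(N)^{β_j}`; because every level shares the same support (all
acyclic orientation-subsets of the scaffold), the uniform base density
cancels and the weight update telescopes to
`ln ω = Σ_{j=0}^{m−2} (β_j − β_{j+1}) ln f(n_{j+1})` with `n_{j+1}` the
state entering level *j*.

Numerical and design choices:

- **Uniform initial draw by rejection.** Each scaffold edge is
  independently absent / forward / backward with probability 1/3;
  cyclic outcomes are redrawn wholesale. Every acyclic outcome is
  equally likely, so the draw is exactly uniform. Rejection cost grows
  with scaffold cyclomatic complexity but is negligible at the
  few-hundred-edge scale targeted.
- **Moves.** For each scaffold edge absent from the network, two add
  moves (one per orientation); for each present directed edge, one
  delete and one reverse; moves creating a cycle are excluded. The
  proposal is uniform over this legal set with a Hastings correction
  `|M(n)| / |M(n′)|` for the changing set size.
- **Temperatures.** A temperature-vector input is accepted and
  normalized/reversed into a β ladder; internally only β is used.
- **steps_per_level** defaults to 1 (one proposal per level);
  increase it for dense scaffolds where mixing is slow.
- **Cycle checks** use bitmask descendant sets recomputed per state —
  simple and exact; no persistent topological order is maintained at
  the graph sizes targeted (≤ a few hundred nodes).
- **Reproducibility.** K runs draw per-run generators spawned from a
  single seed via `numpy.random.SeedSequence`, so ensembles are
  bit-identical for a fixed seed.
- Log-weights stay unnormalized; pooling normalizes (confidence is
  invariant to rescaling all weights).

## Pooling

`C(s)` is the normalized weighted fraction of sampled networks
containing substructure *s*, computed from log-weights via a max-shift
(log-sum-exp). Edge constraints require the exact directed edge;
ordering constraints require ancestry, mirroring the scoring
convention. Enumerating "all structure forms" of a gene subset is
factorial, so built-in candidate generators cover single edges and all
linear orderings of subsets of ≤ 7 genes; arbitrary caller-supplied
candidates are accepted. Ties in the argmax go to the first-listed
candidate (deterministic output). For tiny scaffolds (≤ 12 edges)
`pathais.exact` computes the same confidences by exhaustive
enumeration, which the sampler is validated against.

## Preprocessing

- **Imputation.** A missing `D(x, y)` is predicted from each side and
  averaged (keeping the matrix symmetric): the x-side regresses x's
  observed profile (least squares with intercept) on the q = 5 genes
  whose profiles are most Pearson-correlated with x among those
  observed in column y, excluding column y from the fit. Predictions
  use only originally observed entries, so imputation is idempotent
  and order-independent. A fully missing profile is an error naming
  the gene.
- **Profile correlation** is computed over pairwise-complete entries
  and requires ≥ 10 shared observations (below that it is treated as
  0 for ranking and as absent for subset construction) — sparse
  profiles otherwise produce spurious perfect correlations.
- **Coherent subsets** are connected components (size ≥ k_min,
  default 2) of the graph with an edge wherever profile correlation
  ≥ r_min (default 0.8). Components rather than cliques keep the
  output deterministic and partition-like; genes with constant
  profiles are excluded with a warning.

## Synthetic data

The generator is the exact inverse of the scoring model: a ground-truth
DAG (chain, random tree, two parallel chains, or random DAG) fixes each
pair's topology; `D` is the topology's predicted mean plus
`N(0, σ²)` noise truncated at 0; `E` is the neutral expectation; the
scaffold is the true skeleton plus decoy edges sampled uniformly among
non-adjacent pairs. Defaults: single-mutant fitnesses uniform in
(0.3, 0.9) — wide enough that linear-topology means separate from
neutral products at the default noise — and σ = 0.05.

What it does *not* emulate: colony-size measurement pipelines, batch
and position effects, reporter-based phenotypes, missing-data patterns
of real screens, or false edges *in the data* (decoys only pad the
scaffold). Passing recovery tests therefore demonstrates correctness
of the inference machinery under the model's own assumptions, not
robustness to the systematic errors of real E-MAP data. The truncation
at 0 departs from the untruncated Gaussian the scores assume; at the
default parameters the truncated mass is ≪ 10⁻⁶ and the discrepancy is
negligible.

### Identifiability limits

The orientation of a chain's terminal edge is informed by a single
pair score (`D(head, next)` against predictions `S(next)` vs
`S(head)`). When the two single-mutant fitnesses differ by roughly the
replicate SD, one noise draw can flip the Bayes-optimal ordering
whenever a decoy edge makes the swapped ordering representable in the
scaffold. Enumeration (no sampling) puts the expected argmax recovery
of a 5-gene chain at σ = 0.05 with three decoys near 0.8, and the
sampler attains that ceiling; higher recovery requires better-separated
fitnesses, smaller noise, or replicated measurements, not a better
sampler.

## Problem sizes

The test suite and the reproduction script run at desk scale by
design: 3-gene triangle enumeration checks (K = 5000, m = 50),
5-gene chain recovery (20 simulations, K = 500, m = 100), 10⁴-state
constraint sweeps, and 15-gene imputation fixtures. The sampler itself
handles the few-hundred-gene scaffolds typical of curated interaction
subnetworks; wall-clock grows roughly as
`K · m · steps_per_level · (pairs + scaffold edges)`.

## Known limitations

- Gene membership of a pathway is taken as given (coherent subsets or
  caller-selected genes); the sampler does not add or remove genes.
- The neutral-expectation surface is a closed form, not fitted from
  the screen itself.
- Scores assume a single σ² per pair; replicate-count heterogeneity
  must be expressed through the per-pair σ² matrix.
- AIS weights can degenerate (low effective sample size) on very
  peaked targets with short ladders; the ESS is logged so runs can be
  repeated with larger m or steps_per_level.
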