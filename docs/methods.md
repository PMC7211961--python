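# Methods

## Model

A fixed rooted tree `T = (V, E)` with leaves `V_L = {1, …, n}` is given; it
is treated as data, not estimated, and nothing is assumed about how it was
produced.  Each leaf carries an independent response.  In the core binary
model `Y_i ~ Bern(p_i)` with

    p_i = p_0 + Σ_{j=1}^{k} c_j · 1{ i ∈ Off(v_j) },     p ∈ [0,1]^n,

where `Off(v)` denotes the offspring leaves of node `v`.  The nodes
`v_1, …, v_k` are the *active nodes*; `k` is the model order.  For
identifiability each active node must have at least one offspring leaf at
exactly its own level (equivalently, `p` takes exactly `k+1` distinct
values); signals violating this are representable with fewer nodes and are
treated as such.  Active-node sets are not always unique for a given `p`
(two different clades can induce the same leaf partition); the
implementation reports the first maximum-likelihood solution in a
deterministic search order and lists equivalent solutions separately.

A Gaussian family (`Y_i ~ N(p_i, σ²)`, σ estimated from first differences
or supplied) covers continuous traits; only the local statistic and its
inversion differ.

## Procedure

1. **Ordering.**  A tree-consistent leaf ordering makes every clade a
   contiguous interval of positions.  The *standard* ordering sorts, at
   every inner node, the children by (subtree leaf count, lexicographically
   smallest descendant label) and reads the leaves depth-first.  It is a
   frozen, documented convention: any serialisation of the same tree yields
   the same ordering, so results do not depend on how the user wrote the
   Newick.  Seeded random orderings are provided for robustness studies and
   aggregation.

2. **Multiscale constraint system.**  For threshold `q` and every interval
   `[i,j]` of length ≥ the minimal scale, the local likelihood-ratio test
   "`p` constant = b on `[i,j]`" is inverted into an admissible interval
   for `b`: `2·T_ij(b) ≤ (q + √pen)²` with `pen = 2 log(e·n/(j−i+1))`.
   Bernoulli inversion uses vectorised bisection (64 iterations, i.e. far
   below 1e−10); Gaussian inversion is closed-form.  Running max/min tables
   over the interval system reduce "intersect bounds over all sub-intervals
   of a run" to one lookup.

3. **Minimal-active-node estimate.**  `k̂(q)` is the smallest `k` such that
   some signal with `k` active nodes satisfies every constraint on its
   constancy intervals.  A candidate node set partitions the leaves into
   level-set regions (innermost covering clade); the set is feasible iff
   every region is non-empty and its admissible intervals — intersected
   across all its runs — are non-empty.  The search enumerates candidate
   clade intervals exhaustively by increasing `k` (vectorised for
   `k ∈ {1,2}`), starting from the lower bound `k ≥ ⌈(m̂−1)/2⌉` where `m̂`
   is the minimal ordered segmentation from a greedy leftmost-maximal scan
   (any `k`-node signal has at most `2k+1` runs).  Candidates are all
   non-root nodes, leaves included, deduplicated by induced interval.  For
   `k ≥ 3` beyond a subset cap (default 5·10⁶), candidates are restricted
   to nodes with a boundary near a greedy change gap; the exhaustive path
   is always used on small instances.

4. **Constrained MLE, confidence set, band.**  Constraints and likelihood
   decouple across regions, so the constrained MLE sets each region's level
   to its observed mean clipped into the region's admissible interval; the
   reported `p̂` maximises likelihood over all feasible node sets of size
   `k̂` (ties broken by search order, alternatives retained).  The node
   confidence set is the union of nodes over all feasible sets; the band is
   the per-leaf envelope of region bounds over all feasible sets.  Both are
   supersets of the reported solution by construction.

5. **Calibration.**  The threshold is `q_{1−α}`, the empirical (1−α)
   quantile ('higher' interpolation, conservative) of Monte-Carlo draws of

       M = sup_{0≤s<t≤1} |B(t)−B(s)|/√(t−s) − √(2 log(e/(t−s))),

   simulated as cumulative Gaussian sums on a grid (default
   `max(n, 512)` increments, 5,000 draws, fixed recorded seed, optional
   disk cache keyed by all parameters).  `M` stochastically bounds the
   limit of `T_n` at the true signal, which yields `P(k̂ > k) ≤ α`
   asymptotically; under-estimation vanishes exponentially in `n` for
   signals with segment-length fraction ≥ λ and probability gaps ≥ δ
   bounded away from zero.  A finite-sample alternative (Bernoulli noise at
   the actual `n`) is available for small samples.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | overall false-positive level; the only scientific tuning knob |
| `min_segment` | `max(2, min(⌈log(n)³⌉, ⌈n/10⌉))` | shortest tested interval (leaves); theory wants `n·λ / log(n)³ → ∞`, the `n/10` cap keeps small trees searchable |
| `grid_size` | `max(n, 512)` | Brownian grid for `M`; finer grids are (slightly) conservative |
| `n_draws` | 5,000 | Monte-Carlo draws; quantile error ≪ α at this size |
| `family` | bernoulli | `gaussian` for continuous traits |

The quantile simulation uses the *full* supremum over all scales, while the
data statistic omits intervals shorter than `min_segment`; the mismatch is
in the conservative direction (the omitted short scales could only increase
the statistic).

## Missing data

Leaves without a response are deleted and the remaining observations
re-indexed.  Deleting leaves preserves clade contiguity, so the machinery
is unchanged with observed counts as interval lengths — penalties and the
minimal scale refer to observed counts.  Clades whose observed leaf set is
empty cannot be active; fitted values and bands for unobserved leaves come
from the clade regions they belong to on the full tree.

## Numerical conventions

* Positions and intervals are 1-based inclusive; all serialised output uses
  leaf labels, never indices.  Unlabelled inner nodes are addressed as
  `MRCA(a,b)` by their extremal offspring labels.
* LR inversion at the mean-space boundary: an all-ones segment has upper
  bound exactly 1 (no clipping in testing; degenerate hypotheses with
  discordant data give an infinite statistic, i.e. rejection at any
  threshold).
* If `q + √pen < 0` for some length, no mean is admissible at that length
  and the constraint system is infeasible ("poisoned"); this cannot occur
  for quantiles of `M` at conventional α and is reported as an error.
* Feasibility treats region levels as free within their admissible
  intervals without enforcing pairwise distinctness (the closure of the
  confidence set `H(q)`); whenever the intervals have positive width,
  distinct levels exist, so `k̂` is unaffected outside probability-zero
  boundary cases.  Likelihood ties are called at 1e−9 relative tolerance.
* Branch lengths are read but ignored: only topology enters.

## Synthetic data

The generator realises exactly the model above: Yule (pure-birth) topology
by default — the standard neutral null for random phylogenies, with
coalescent and perfect-binary alternatives — plus disjoint active clades
chosen uniformly among nodes within ±25% of a requested leaf-count
fraction, and independent Bernoulli draws.  The study driver shares one
quantile table across replicates and spawns per-replicate seeds
deterministically, so a report is a pure function of (design, seed).

What the simulations do *not* emulate: correlated responses (the model
assumes independence given `p`), errors in the tree itself (the method
conditions on the input tree; robustness to tree noise holds only insofar
as the perturbed tree encodes the same neighbourhoods), non-binary
polytomy-rich topologies (supported by the code but not exercised by the
default generator), and covariate effects.  Passing tests therefore
certify the inference machinery under the stated model, not robustness to
model violations.

Study sizes used by the test suite: the null-specificity study runs 250
replicates at `n = 200` (the acceptance script runs the full 1,000); the
three-segment recovery study runs 200 replicates with clades of 41–67
leaves at probabilities 0.95/0.05 on a 0.47 baseline (fraction 0.27 with
the generator's ±25% size tolerance — the smallest fraction whose whole
tolerance band keeps every segment at ≥ 40 leaves); oracle equivalence is
verified on 500 fuzzed instances with `n ≤ 12` against exhaustive
enumeration, and the statistic against brute-force interval enumeration at
`n ≤ 50`.

## Known limitations

* Exhaustive subset search is exponential in `k̂`; practical for the small
  orders the method is designed to certify (the guarantee is about the
  *minimum* number of clades), with a documented pruned fallback beyond the
  cap.
* The `O(n²)` interval system bounds memory/time around `n ≲ 10⁴` in this
  implementation; a dyadic-scale approximation is the natural extension
  point for larger trees.
* Confidence sets and bands condition on `k(p) = k̂` (the definition of
  `H(q)`); they do not account for uncertainty in `k̂` beyond the α-level
  guarantee.
* Poisson and other exponential families are left as extension points.
* No response prediction for unobserved leaves beyond reporting their
  segment's fitted probability.
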