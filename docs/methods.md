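# Methods

## The quantity being estimated

Let a stochastic community-detection algorithm be run repeatedly on a
fixed graph.  For nodes *i*, *j* let *a*(*i*, *j*) be the indicator
that they are assigned to the same community in one run, and
*p*(*i*, *j*) = E[*a*(*i*, *j*)] its expectation, estimated by the
sample co-assignment frequency over the ensemble (the association
matrix).  The versatility of node *j* is

    V(j) = Σ_i f(p(i,j)) / g(j)

where *f* : [0,1] → [0,1] is continuous, concave, symmetric about 0.5,
with f(0) = f(1) = 0 and f(0.5) = 1, and *g* is a normalisation.
Implemented transforms: **S** f(x) = sin(πx); **E** the binary entropy
−x·log₂x − (1−x)·log₂(1−x) (0 at the endpoints by continuity); **T**
the triangle wave 2·min(x, 1−x).  Normalisations: **U** g = N (network
size); **C** g(j) = Σ_i p(i,j) (the expected size of the community
containing j).  The canonical estimator is **SC**; the six
combinations are all available for comparison.

The triangle transform is scaled by 2 so that it peaks at 1 like the
other two; the unscaled form (max 0.5) would violate the f(0.5) = 1
normalisation shared by the family and halve every TU/TC bound.

### The self term

Both sums run over **all** *i*, including *i* = *j*, with
*p*(*j*, *j*) ≡ 1.  The self term adds 0 to the numerator and 1 to the
denominator, making the C-denominator "the expected number of nodes in
j's community, counting j".  This convention is load-bearing: it is
the unique reading under which, simultaneously, (a) n-split
versatility is strictly increasing in cluster size c, (b) n-cluster
versatility is exactly independent of c, (c) a perfect two-way split
approaches V = 2 *in the limit* of large communities rather than
attaining it, and (d) the supremum over all networks is π.

### Scale and bounds

Versatility is deliberately **not** normalised by π or by the
finite-network maximum.  The raw scale has landmarks (V = 2: perfect
two-way split) and the finite-N maximum would reintroduce exactly the
network-size dependence the estimator is designed to avoid.  Bounds on
valid association matrices: all six estimators ≥ 0; SU, EU, TU ≤ 1;
SC < π; TC < 2; EC is unbounded (many vanishing co-assignment
probabilities push it up like ½·log₂M — one reason SC is preferred
over the otherwise near-identical EC; the other is that the entropy
formula suggests an information-theoretic meaning the quantity does
not have).  SC and EC rank nodes near-identically in the regime that
matters (a small number of competing communities); when every
probability is near an endpoint the ranks of near-zero values are not
meaningful for either estimator and they can disagree.

## Model networks and their oracles

Two idealised families, each with an exactly solvable expected
versatility for its distinguished ("indicator") node, calibrate the
estimators.  Both carry `x` extra nodes that enlarge the network
without affecting detection (realised as an isolated clique);
C-normalised estimators must be, and are, exactly invariant in `x`.

**n-split** (parameters n, c, x; N = n·c + x + 1): one indicator node
attached by a single edge to each of n c-cliques.  The idealised
algorithm puts each clique in its own community and the indicator into
one clique uniformly at random (probability 1/n).  Closed form:

    V_SC = n·c·sin(π/n) / (1 + c)            (→ 2 for n = 2, c → ∞)

**n-clusters** (parameters n, c, x, p; N = n·c + x): n c-cliques,
loosely interconnected.  Per run, each of the n − 1 non-indicator
cliques merges into the indicator clique's community independently
with probability p (a *star merge* centred on the indicator cluster).
A pairwise "any two cliques merge with probability p" rule is not
transitively consistent — independent pairwise merges contradict the
transitivity of community membership — so the star model is used: it
preserves exactly the quantity the closed form needs, a co-assignment
probability of p between the indicator clique and every other clique
(two non-indicator cliques co-occur with probability p²).  Closed
form, independent of c:

    V_SC = (n−1)·c·sin(πp) / (c·(1 + (n−1)p)) = (n−1)·sin(πp) / (1 + (n−1)p)

Property battery asserted in the tests: non-negativity; zero at n = 1
(n-split) and at p ∈ {0, 1} (n-clusters); x-invariance; monotonicity
in c (n-split) and exact c-invariance (n-clusters); monotonicity in n
(both); and splitting-over-breaking — at matched pairwise probability,
the split indicator is strictly more versatile than the absorbed
cluster node.

**Maximum versatility given network size.**  `max_versatility(N)`
searches the n-split family exhaustively over integer (n, c) with
n·c ≤ N − 1, the family that maximises nodal versatility; for fixed n
the closed form is increasing in c, so only c = ⌊(N−1)/n⌋ is
evaluated.  The fixed-c = 1 sub-family (n = N − 1 singleton clusters)
is *not* the maximiser under the self-term convention — its large-N
limit is π/2 — whereas the (n, c) search approaches π, with the
optimal n growing like N^⅓.  The result is non-decreasing in N and
< π for every finite N (3.1383 at N = 10⁵).

**Monte-Carlo pipeline.**  `monte_carlo_versatility` runs the
idealised sampler, pools all runs into one association matrix for the
point estimate, and takes the standard error from 10 equal
sub-ensembles.  The pooled estimate is used instead of the mean of
block estimates because the transform is nonlinear: a block of R runs
carries an O(1/R) Jensen bias (≈ −π²·sin(πp)·p(1−p)/(2R) per matrix
entry), which at R = 10³ is comparable to the Monte-Carlo standard
error of a 10⁴-run ensemble, while the pooled estimate's bias is ten
times smaller.

## The resolution sweep

`sweep_resolution` computes, per γ on an ascending grid: 1000 (by
default) Louvain runs → association matrix → SC versatility → mean
over nodes; the per-run community counts; a trivial-partition flag;
and a SEM.

* **Detector.**  Louvain greedy maximisation of the γ-scaled
  modularity Q_γ = (1/2m)·Σ_ij [A_ij − γ·k_i k_j/(2m)]·δ(c_i, c_j)
  with weighted degrees, as implemented by networkx, which randomises
  the node visitation order per seed.  That randomisation is the sole
  injected stochasticity and is essential: with a fixed order Louvain
  is deterministic and every versatility is zero regardless of
  ambiguity.  Same seed ⇒ same partition; run k at grid index g draws
  its seed from SeedSequence(base_seed, spawn_key=(g, k)), so sweeps
  are bit-reproducible end to end and ensembles are independent across
  grid points.  Any other detector can be supplied as a
  `DetectorAdapter` honouring the same-seed-same-partition contract.
* **Directed graphs** are symmetrised as (A + Aᵀ)/2 before Louvain,
  with a logged notice.  Negative weights are rejected (modularity is
  undefined).
* **Trivial partitions.**  Versatility is exactly zero at both
  extremes of γ — one all-encompassing community, or all singletons —
  so those grid points are excluded from optimum selection.  A point
  is flagged trivial when the *median* run has 1 community or ≥ N − 1
  communities; the median (not the mean) keeps a single aberrant run
  from flipping the flag.
* **SEM** is a nonparametric bootstrap over the ensemble's runs (100
  resamples with replacement, re-accumulating the association matrix
  and the mean versatility each time).  This prices in the full
  dependence structure of the ratio statistic without extra detector
  calls.
* **Optimum selection** (`find_optima`): local minima on the sub-curve
  of non-trivial points (ties keep the lower γ; endpoints compare
  against their single neighbour), sorted by mean versatility, plus
  plateaus — maximal runs of ≥ 3 consecutive non-trivial points all
  within one SEM of the run's minimum, each reported by its lowest
  point.  Plateaus serve the second selection style: a γ that is
  *stably* low beats a marginally lower but isolated dip.
* **Community counts** are reported alongside so the
  number-of-communities-as-proxy heuristic can be compared against the
  versatility curve; nothing is asserted about them beyond a monotone
  trend on the synthetic cluster graphs.
* **Convergence.**  `convergence_diagnostic` replicates ensembles on a
  10/30/100/300/1000 ladder and reports the across-replicate sd of the
  mean versatility, which shrinks roughly as 1/√runs; on karate-sized
  graphs ~1000 runs per γ is comfortably converged, which is the
  default run budget.

## What the synthetic generators do and do not emulate

The idealised samplers draw from the *defined* distribution of the
model networks — they are the ground truth the estimators are checked
against, not a simulation of any real algorithm.  Real detectors on
the concrete realisations (`build_nsplit_graph`,
`build_ncluster_graph`) need not reproduce those distributions; Louvain
in particular can behave near-deterministically on the n-split graphs
because node-order bias, not genuine degeneracy, decides the
indicator's side.  Passing the oracle grid therefore validates the
estimator arithmetic, not any claim that a particular algorithm
explores partition space ideally.  The directed-graph path is
exercised on synthetic weighted digraphs; no anatomical connectome
data is bundled, and conclusions about real connectomes require the
user's own data through the generic readers.

## Numerical and interface choices

* sin(πx) is forced to exactly 0 at x ∈ {0, 1} (floating sin(π)
  ≈ 1.2·10⁻¹⁶ would otherwise leak into the deterministic-ensemble
  zero guarantee); the entropy transform is 0 there by continuous
  extension.
* Association counts are accumulated as integers and divided once, so
  results are independent of accumulation order, and off-diagonal
  entries are exact multiples of 1/run_count.
* Community labels are compared only within a run; no cross-run label
  alignment exists anywhere.
* Node ids are opaque (strings in the file readers — `01` ≠ `1`);
  graphs are kept in sorted-id order; self-loops are dropped with a
  warning; duplicate edge-list rows are summed.
* Problem sizes in the shipped checks: the oracle grid uses 10⁴ runs
  per spec (Monte-Carlo error ≈ 10⁻³, three orders below the effect
  sizes); the karate sweep uses the default 1000 runs per γ on the
  0.1–2.0 grid; examples use 200 runs for a fast look at the same
  curve.

## Known limitations

* The association matrix is dense: memory is O(N²) and the bootstrap
  stores run-by-run co-assignments (runs × N² bytes), fine for
  hundreds of nodes, not for 10⁵-node graphs.
* Versatility characterises the *interaction* of an algorithm with a
  network.  A deterministic detector yields zero versatility
  everywhere, however ambiguous the structure; conclusions transfer
  across detectors only insofar as their stochasticity explores the
  same degeneracies.
* `find_optima` operates on the grid as given; a coarse grid can merge
  or miss minima, and the plateau rule inherits the bootstrap SEM's
  resampling noise.
* Directed modularity is not implemented; directed input is
  symmetrised, which discards asymmetry of flow.
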