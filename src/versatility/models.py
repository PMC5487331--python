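"""Idealised model networks for evaluating versatility estimators.

Two parametric families probe the two distinct ways a node's community
affiliation can be ambiguous:

* **n-split** — one *indicator node* attaches by a single edge to each
  of ``n`` identical c-cliques; an idealised stochastic algorithm
  assigns the indicator to exactly one cluster per run, uniformly
  (probability 1/n each).  The indicator is genuinely *split* between
  communities.
* **n-clusters** — ``n`` identical c-cliques, loosely interconnected;
  per run, each of the other ``n - 1`` clusters merges into the
  indicator cluster's community independently with probability ``p``
  (a star-merge centred on the indicator cluster, which keeps the
  pairwise co-assignment probability between the indicator cluster and
  every other cluster exactly ``p``).  The indicator's own community is
  stable but may be *absorbed* into larger ones.

Both families carry ``x`` extra nodes that enlarge the network without
touching the community detection (realised as an isolated clique); a
good estimator must be invariant to ``x``.

For each family this module provides an idealised partition sampler,
the exact closed-form expected versatility of the indicator node, the
expected (infinite-run) association matrix, and a concrete graph
realisation.  ``max_versatility`` computes the largest SC versatility
any node of an N-node network can attain, which approaches (but never
reaches) pi as N grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .association import AssociationMatrix, Partition, accumulate_streaming
from .metrics import EstimatorCode, SC

__all__ = [
    "NSplitSpec",
    "NClusterSpec",
    "sample_nsplit_partition",
    "sample_ncluster_partition",
    "analytic_versatility_nsplit",
    "analytic_versatility_ncluster",
    "nsplit_association",
    "ncluster_association",
    "build_nsplit_graph",
    "build_ncluster_graph",
    "monte_carlo_versatility",
    "max_versatility",
]


@dataclass(frozen=True)
class NSplitSpec:
    """n-split model: indicator node split uniformly over n c-cliques.

    Total network size is n*c + x + 1.  Node ids: 0 is the indicator;
    cluster k (k = 0..n-1) holds ids 1 + k*c .. k*c + c; the x extra
    nodes follow.
    """

    n: int
    c: int
    x: int = 0

    def __post_init__(self):
        if self.n < 1 or self.c < 1 or self.x < 0:
            raise ValueError("need n >= 1, c >= 1, x >= 0")

    @property
    def n_nodes(self) -> int:
        return self.n * self.c + self.x + 1

    def node_ids(self) -> tuple:
        return tuple(range(self.n_nodes))


@dataclass(frozen=True)
class NClusterSpec:
    """n-clusters model: n c-cliques; each other cluster joins the
    indicator cluster's community with probability p per run.

    Total network size is n*c + x.  Node ids: cluster k holds ids
    k*c .. k*c + c - 1 (cluster 0 is the indicator cluster); the x
    extra nodes follow.
    """

    n: int
    c: int
    x: int = 0
    p: float = 0.5

    def __post_init__(self):
        if self.n < 1 or self.c < 1 or self.x < 0:
            raise ValueError("need n >= 1, c >= 1, x >= 0")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.n * self.c + self.x

    def node_ids(self) -> tuple:
        return tuple(range(self.n_nodes))


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def sample_nsplit_partition(spec: NSplitSpec, rng_seed=None) -> Partition:
    """One idealised run on the n-split model.

    Each cluster is its own community; the indicator joins one cluster
    chosen uniformly at random; each extra node is a singleton.
    """
    rng = _as_rng(rng_seed)
    chosen = int(rng.integers(spec.n))
    labels = [chosen]  # indicator node
    for k in range(spec.n):
        labels.extend([k] * spec.c)
    labels.extend(range(spec.n, spec.n + spec.x))  # singleton extras
    return Partition(spec.node_ids(), labels)


def sample_ncluster_partition(spec: NClusterSpec, rng_seed=None) -> Partition:
    """One idealised run on the n-clusters model (star merge).

    Each of the n - 1 non-indicator clusters independently merges into
    the indicator cluster's community with probability p; unmerged
    clusters stay separate; extras are singletons.
    """
    rng = _as_rng(rng_seed)
    merged = rng.random(spec.n - 1) < spec.p if spec.n > 1 else np.zeros(0, bool)
    labels = [0] * spec.c  # indicator cluster = community 0
    for k in range(1, spec.n):
        lab = 0 if merged[k - 1] else k
        labels.extend([lab] * spec.c)
    labels.extend(range(spec.n, spec.n + spec.x))
    return Partition(spec.node_ids(), labels)


def analytic_versatility_nsplit(
    spec: NSplitSpec, estimator: "str | EstimatorCode" = SC
) -> float:
    """Exact expected versatility of the n-split indicator node.

    The indicator shares a community with each of the n*c cluster nodes
    with probability 1/n and with nothing else, so with transform f and
    community-size normalisation:

        V = n*c*f(1/n) / (1 + c)

    (the self term contributes 1 to the denominator).  With network-size
    normalisation the denominator is N = n*c + x + 1 instead.
    """
    estimator = EstimatorCode.parse(estimator)
    numer = spec.n * spec.c * float(estimator.apply_transform(np.array(1.0 / spec.n)))
    if estimator.normalisation == "C":
        denom = 1.0 + spec.c
    else:
        denom = float(spec.n_nodes)
    return numer / denom


def analytic_versatility_ncluster(
    spec: NClusterSpec, estimator: "str | EstimatorCode" = SC
) -> float:
    """Exact expected versatility of a node in the indicator cluster.

    A node j in the indicator cluster co-occurs with its c - 1 cluster
    mates always (f(1) = 0) and with each of the (n - 1)*c other-cluster
    nodes with probability p, so for community-size normalisation:

        V = (n - 1)*c*f(p) / (c + (n - 1)*c*p) = (n - 1)*f(p) / (1 + (n - 1)*p)

    — independent of cluster size c.  Network-size normalisation divides
    by N = n*c + x instead.
    """
    estimator = EstimatorCode.parse(estimator)
    fp = float(estimator.apply_transform(np.array(float(spec.p))))
    numer = (spec.n - 1) * spec.c * fp
    if estimator.normalisation == "C":
        denom = spec.c * (1.0 + (spec.n - 1) * spec.p)
    else:
        denom = float(spec.n_nodes)
    return numer / denom if numer else 0.0


def nsplit_association(spec: NSplitSpec) -> AssociationMatrix:
    """Expected (infinite-run) association matrix of the n-split model."""
    N = spec.n_nodes
    p = np.zeros((N, N))
    for k in range(spec.n):
        lo, hi = 1 + k * spec.c, 1 + (k + 1) * spec.c
        p[lo:hi, lo:hi] = 1.0
        p[0, lo:hi] = p[lo:hi, 0] = 1.0 / spec.n
    np.fill_diagonal(p, 1.0)
    return AssociationMatrix(spec.node_ids(), p, run_count=1)


def ncluster_association(spec: NClusterSpec) -> AssociationMatrix:
    """Expected association matrix of the n-clusters star-merge model.

    Pairs inside a cluster: 1.  Indicator cluster vs any other cluster:
    p.  Two non-indicator clusters co-occur only when both merged: p^2.
    """
    N = spec.n_nodes
    p = np.zeros((N, N))
    for k in range(spec.n):
        lo, hi = k * spec.c, (k + 1) * spec.c
        p[lo:hi, lo:hi] = 1.0
    for k in range(1, spec.n):
        lo, hi = k * spec.c, (k + 1) * spec.c
        p[0:spec.c, lo:hi] = p[lo:hi, 0:spec.c] = spec.p
        for m in range(1, k):
            mlo, mhi = m * spec.c, (m + 1) * spec.c
            p[mlo:mhi, lo:hi] = p[lo:hi, mlo:mhi] = spec.p**2
    np.fill_diagonal(p, 1.0)
    return AssociationMatrix(spec.node_ids(), p, run_count=1)


def build_nsplit_graph(spec: NSplitSpec) -> nx.Graph:
    """Concrete n-split graph: c-cliques, indicator wired once to each
    cluster's lowest-indexed node, extras an isolated clique."""
    G = nx.Graph()
    G.add_nodes_from(spec.node_ids())
    for k in range(spec.n):
        members = range(1 + k * spec.c, 1 + (k + 1) * spec.c)
        G.add_edges_from((a, b) for i, a in enumerate(members) for b in list(members)[i + 1:])
        G.add_edge(0, 1 + k * spec.c)
    extras = range(1 + spec.n * spec.c, spec.n_nodes)
    G.add_edges_from((a, b) for i, a in enumerate(extras) for b in list(extras)[i + 1:])
    return G


def build_ncluster_graph(spec: NClusterSpec, inter_weight: float = 0.1) -> nx.Graph:
    """Concrete n-clusters graph: unit-weight c-cliques plus one
    inter-cluster edge of weight ``inter_weight`` between every pair of
    cluster representatives (the lowest-indexed node of each cluster)."""
    if inter_weight < 0:
        raise ValueError("inter_weight must be >= 0")
    G = nx.Graph()
    G.add_nodes_from(spec.node_ids())
    for k in range(spec.n):
        members = range(k * spec.c, (k + 1) * spec.c)
        G.add_weighted_edges_from(
            (a, b, 1.0) for i, a in enumerate(members) for b in list(members)[i + 1:]
        )
    if inter_weight > 0:
        reps = [k * spec.c for k in range(spec.n)]
        G.add_weighted_edges_from(
            (reps[i], reps[j], float(inter_weight))
            for i in range(spec.n)
            for j in range(i + 1, spec.n)
        )
    extras = range(spec.n * spec.c, spec.n_nodes)
    G.add_weighted_edges_from(
        (a, b, 1.0) for i, a in enumerate(extras) for b in list(extras)[i + 1:]
    )
    return G


def monte_carlo_versatility(
    spec,
    runs: int = 10_000,
    seed: int = 0,
    blocks: int = 10,
    estimator: "str | EstimatorCode" = SC,
) -> tuple[float, float]:
    """Indicator-node versatility via the sample -> accumulate -> estimate
    pipeline, with a Monte-Carlo standard error.

    Samples ``runs`` idealised partitions of the given model spec, pools
    them into one association matrix for the point estimate, and
    estimates the standard error from ``blocks`` equal sub-ensembles
    (the pooled estimate is used rather than the mean of block
    estimates because the block estimates carry an O(1/block_size)
    Jensen bias from the nonlinear transform).

    Returns ``(estimate, standard_error)`` for node 0, the indicator.
    """
    if isinstance(spec, NSplitSpec):
        sample = sample_nsplit_partition
    elif isinstance(spec, NClusterSpec):
        sample = sample_ncluster_partition
    else:
        raise TypeError(f"unsupported model spec {type(spec).__name__}")
    if runs < blocks or blocks < 2:
        raise ValueError("need runs >= blocks >= 2")

    rng = _as_rng(seed)
    per = runs // blocks
    total = None
    block_vals = []
    from .metrics import versatility  # local import avoids a cycle at module load

    for _ in range(blocks):
        assoc = accumulate_streaming(sample(spec, rng) for _ in range(per))
        block_vals.append(float(versatility(assoc, estimator).values[0]))
        counts = assoc.p * per
        total = counts if total is None else total + counts

    pooled = total / (per * blocks)
    np.fill_diagonal(pooled, 1.0)
    pooled_assoc = AssociationMatrix(spec.node_ids(), pooled, per * blocks)
    estimate = float(versatility(pooled_assoc, estimator).values[0])
    se = float(np.std(block_vals, ddof=1) / np.sqrt(blocks))
    return estimate, se


def max_versatility(network_size: int) -> float:
    """Maximum attainable SC versatility of any node in an N-node network.

    Searches the n-split family exhaustively over integer (n, c) with
    n*c <= N - 1 nodes available for clusters, evaluating the closed
    form V = n*c*sin(pi/n)/(1 + c).  For fixed n the form is increasing
    in c, so only c = floor((N - 1)/n) need be checked.  The result is
    non-decreasing in N and strictly below pi; it approaches pi only as
    N tends to infinity.
    """
    if network_size < 2:
        raise ValueError("network_size must be >= 2")
    budget = network_size - 1
    n = np.arange(1, budget + 1, dtype=np.int64)
    c = budget // n
    v = n * c * np.sin(np.pi / n) / (1.0 + c)
    v[0] = 0.0  # n = 1: f(1) = 0 exactly
    return float(v.max())
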