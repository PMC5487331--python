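# versatility

**Nodal versatility of community affiliation for stochastic community
detection.**

Community detection assigns every node of a network to exactly one
community, but for many nodes that assignment is genuinely ambiguous —
rerun a stochastic algorithm and they land somewhere else.  This
package quantifies that ambiguity per node.  Run any stochastic
community detection algorithm many times, record for each pair of
nodes *i*, *j* the fraction of runs *p*(*i*, *j*) in which they shared
a community (the *association matrix*), and score each node *j* by

```
V(j) = Σ_i sin(π p(i,j)) / Σ_i p(i,j)
```

with both sums over all nodes *i* (including *i* = *j*, with
*p*(*j*, *j*) = 1).  The numerator rewards probabilities near the
maximally ambiguous 0.5; the denominator is the expected size of the
community containing *j*, so versatility depends only on community
assignment — never on degree.  *V* ≈ 0 means the node is consistently
assigned; *V* ≫ 0 means its affiliation is genuinely ambiguous.
Landmarks: *V* = 2 is a node split perfectly between two large
communities; π is the supremum over all (infinite) networks.

Because modularity's resolution parameter γ has no principled default,
the *global mean* versatility, swept over γ, doubles as an objective:
prefer the non-trivial resolutions where the decomposition is least
ambiguous.

Intended users: network scientists — in particular people analysing
brain connectomes or other biological networks — who need to know
which nodes of a partition to trust and which resolution to report.

## Worked example

```python
from versatility import Partition, PartitionEnsemble, accumulate, versatility

ensemble = PartitionEnsemble([
    Partition([1, 2, 3], ["a", "a", "b"]),   # run 1: {1,2 | 3}
    Partition([1, 2, 3], ["x", "y", "y"]),   # run 2: {1 | 2,3}
])
print(accumulate(ensemble).p)
print(versatility(accumulate(ensemble)).as_dict())
```

prints

```
[[1.  0.5 0. ]
 [0.5 1.  0.5]
 [0.  0.5 1. ]]
{1: 0.6666666666666666, 2: 1.0, 3: 0.6666666666666666}
```

Node 2 was grouped with each neighbour in exactly half the runs —
maximal ambiguity for this ensemble — while nodes 1 and 3 are partly
anchored by the run that isolates them.

The same pipeline at network scale (`examples/03_karate_sweep.py`, or
`versatility sweep --fixture karate --gamma 0.1:2.0:0.1 --runs 1000
--seed 1`) sweeps the Louvain resolution on Zachary's karate club and
prints the mean-versatility curve with its candidate optima; at 1000
runs per γ the best non-trivial minimum is γ = 0.5 with mean
versatility ≈ 0.03, the partition there has the club's two historical
factions, and the most versatile node is the member with exactly one
friendship on each side of the split.

More narrative walk-throughs live in `examples/`:

| script | shows |
| --- | --- |
| `01_toy_ensemble.py` | association matrix and versatility from a 2-run toy |
| `02_model_oracles.py` | closed-form model-network versatility vs Monte-Carlo |
| `03_karate_sweep.py` | γ sweep, optimum selection, most versatile node |
| `04_convergence.py` | how many runs a stable estimate needs |

## Command line

A thin CLI wraps the library: `versatility compute` (per-node
versatility from a graph or a stored ensemble CSV), `versatility
sweep` (γ curve + optima + plot), `versatility model` (idealised model
networks and their closed-form oracles), `versatility converge`
(ensemble-size diagnostic) and `versatility fixtures` (emit the karate
club graph).  Graphs are read as edge-list TSV (`u v [weight]`,
`#` comments), dense adjacency CSV, or GraphML; `--directed` inputs
are symmetrised as (A + Aᵀ)/2 before Louvain.  Every subcommand takes
`--seed` and echoes its full configuration into the output directory,
making runs bit-reproducible.

## Model networks

Two idealised families with exact closed-form versatilities calibrate
the estimator (see `docs/methods.md`): the **n-split** network (an
indicator node split uniformly over *n* cliques of size *c*;
V = n·c·sin(π/n)/(1+c)) and the **n-clusters** network (*n* cliques,
each merging into the indicator clique's community with probability
*p*; V = (n−1)·sin(πp)/(1+(n−1)p), independent of *c*).  Property
tests assert the full battery of desirable estimator behaviours on
these forms, and Monte-Carlo sampling of the idealised partitions
reproduces them within statistical error.

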