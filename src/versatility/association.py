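"""Co-assignment (association) matrices from ensembles of graph partitions.

A stochastic community-detection algorithm run many times over the same
graph yields an ensemble of partitions.  The association matrix records,
for every pair of nodes, the fraction of runs in which the pair shared a
community — the sample estimate of the co-assignment probability
p(i, j).  This matrix is the sole input the versatility estimators need:
they never look at the graph itself.

Community labels are opaque and are compared only *within* a run; no
label alignment across runs is attempted or needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Partition",
    "PartitionEnsemble",
    "AssociationMatrix",
    "accumulate",
    "accumulate_streaming",
    "read_ensemble_csv",
    "write_ensemble_csv",
    "read_association_csv",
    "write_association_csv",
]


@dataclass(frozen=True)
class Partition:
    """One run's assignment of every node to exactly one community.

    Parameters
    ----------
    node_ids
        Ordered node identifiers (strings or integers).
    labels
        One community label per node, aligned with ``node_ids``.  Labels
        are opaque: only equality within this partition matters.
    """

    node_ids: tuple
    labels: tuple

    def __init__(self, node_ids: Sequence, labels: Sequence):
        object.__setattr__(self, "node_ids", tuple(node_ids))
        object.__setattr__(self, "labels", tuple(labels))
        if len(self.node_ids) != len(self.labels):
            raise ValueError(
                f"{len(self.node_ids)} node ids but {len(self.labels)} labels"
            )
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids in partition")

    def __len__(self) -> int:
        return len(self.node_ids)

    @property
    def n_communities(self) -> int:
        return len(set(self.labels))

    def label_codes(self) -> np.ndarray:
        """Labels as dense integer codes (order of first appearance)."""
        codes: dict = {}
        return np.fromiter(
            (codes.setdefault(l, len(codes)) for l in self.labels),
            dtype=np.int64,
            count=len(self.labels),
        )

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable], node_order: Sequence | None = None) -> "Partition":
        """Build from a community list (e.g. networkx's list-of-sets output)."""
        lookup = {}
        for lab, group in enumerate(communities):
            for node in group:
                if node in lookup:
                    raise ValueError(f"node {node!r} appears in two communities")
                lookup[node] = lab
        if node_order is None:
            node_order = sorted(lookup, key=lambda x: (str(type(x)), x))
        return cls(node_order, [lookup[n] for n in node_order])


@dataclass(frozen=True)
class PartitionEnsemble:
    """A sequence of partitions over an identical, identically ordered node set."""

    partitions: tuple
    provenance: str = ""

    def __init__(self, partitions: Sequence[Partition], provenance: str = ""):
        partitions = tuple(partitions)
        if not partitions:
            raise ValueError("ensemble must contain at least one partition")
        ref = partitions[0].node_ids
        for k, part in enumerate(partitions):
            if part.node_ids != ref:
                raise ValueError(
                    f"partition {k} has a different node set/order than partition 0"
                )
        object.__setattr__(self, "partitions", partitions)
        object.__setattr__(self, "provenance", provenance)

    @property
    def node_ids(self) -> tuple:
        return self.partitions[0].node_ids

    @property
    def run_count(self) -> int:
        return len(self.partitions)

    def __len__(self) -> int:
        return self.run_count

    def __iter__(self) -> Iterator[Partition]:
        return iter(self.partitions)

    def label_matrix(self) -> np.ndarray:
        """(run_count, n_nodes) integer label codes, one row per run."""
        return np.vstack([p.label_codes() for p in self.partitions])


@dataclass(frozen=True)
class AssociationMatrix:
    """Sample co-assignment probabilities p(i, j) over an ensemble.

    Invariants: symmetric, unit diagonal (a node always shares its own
    community), and every off-diagonal entry is a multiple of
    ``1 / run_count``.
    """

    node_ids: tuple
    p: np.ndarray = field(repr=False)
    run_count: int = 1

    def __init__(self, node_ids: Sequence, p: np.ndarray, run_count: int):
        p = np.asarray(p, dtype=float)
        node_ids = tuple(node_ids)
        n = len(node_ids)
        if p.shape != (n, n):
            raise ValueError(f"p has shape {p.shape}, expected ({n}, {n})")
        if run_count < 1:
            raise ValueError("run_count must be >= 1")
        object.__setattr__(self, "node_ids", node_ids)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "run_count", int(run_count))

    def validate(self) -> None:
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("association entries must lie in [0, 1]")
        if not np.allclose(self.p, self.p.T):
            raise ValueError("association matrix must be symmetric")
        if not np.allclose(np.diag(self.p), 1.0):
            raise ValueError("association diagonal must be 1")

    def __len__(self) -> int:
        return len(self.node_ids)


def accumulate_streaming(partition_source: Iterable[Partition]) -> AssociationMatrix:
    """Accumulate an association matrix from an iterator of partitions.

    Equivalent to :func:`accumulate` on the materialised ensemble but
    keeps only one N x N integer count array in memory, so arbitrarily
    long streams of partitions can be processed.  Counts are integers
    divided once at the end, so the result is independent of the
    accumulation order.
    """
    it = iter(partition_source)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("empty partition source: need at least one partition") from None

    node_ids = first.node_ids
    counts = np.zeros((len(node_ids), len(node_ids)), dtype=np.int64)
    run_count = 0
    for k, part in enumerate(_chain_one(first, it)):
        if part.node_ids != node_ids:
            raise ValueError(
                f"partition {k} has a different node set/order than partition 0"
            )
        codes = part.label_codes()
        counts += codes[:, None] == codes[None, :]
        run_count += 1

    p = counts / run_count
    np.fill_diagonal(p, 1.0)  # a(j, j) = 1 by convention
    return AssociationMatrix(node_ids, p, run_count)


def _chain_one(first: Partition, rest: Iterator[Partition]) -> Iterator[Partition]:
    yield first
    yield from rest


def accumulate(ensemble: PartitionEnsemble) -> AssociationMatrix:
    """Association matrix of an in-memory partition ensemble.

    ``p(i, j)`` = (runs in which i and j share a label) / run_count,
    with the diagonal forced to 1 and symmetry by construction.
    """
    return accumulate_streaming(ensemble.partitions)


# ---------------------------------------------------------------------------
# CSV interchange.  Ensemble CSV: first column node id, one column per run,
# cells are community labels; header `node,run_0001,...`.  Association CSV:
# node ids as header row and first column.
# ---------------------------------------------------------------------------

def write_ensemble_csv(ensemble: PartitionEnsemble, path) -> None:
    data = {"node": [str(n) for n in ensemble.node_ids]}
    for k, part in enumerate(ensemble):
        data[f"run_{k + 1:04d}"] = [str(l) for l in part.labels]
    pd.DataFrame(data).to_csv(path, index=False)


def read_ensemble_csv(path, provenance: str | None = None) -> PartitionEnsemble:
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "node":
        raise ValueError(f"first column must be 'node', got {df.columns[0]!r}")
    node_ids = df["node"].tolist()
    parts = [Partition(node_ids, df[col].tolist()) for col in df.columns[1:]]
    return PartitionEnsemble(parts, provenance or f"read from {path}")


def write_association_csv(assoc: AssociationMatrix, path) -> None:
    ids = [str(n) for n in assoc.node_ids]
    pd.DataFrame(assoc.p, index=ids, columns=ids).to_csv(path, index_label="node")


def read_association_csv(path, run_count: int = 1) -> AssociationMatrix:
    df = pd.read_csv(path, index_col=0)
    return AssociationMatrix(list(df.columns), df.to_numpy(dtype=float), run_count)
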