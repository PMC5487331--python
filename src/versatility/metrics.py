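"""Versatility estimators and the participation coefficient.

Versatility V(j) measures how ambiguously a stochastic community
detection algorithm assigns node j: 0 when j is always co-assigned with
the same nodes, large when its co-assignment probabilities hover near
0.5.  The canonical estimator ("SC") transforms each co-assignment
probability with sin(pi * p) and normalises by the expected size of the
community containing j:

    V(j) = sum_i sin(pi * p(i, j)) / sum_i p(i, j)

Both sums run over *all* nodes i, including i = j with p(j, j) = 1; the
self term adds 0 to the numerator (sin(pi) = 0) and 1 to the
denominator, which makes the denominator the expected community size
including j itself.  Under this convention a perfect two-way split
approaches V = 2 as communities grow, and the supremum over all
networks is pi.

Six estimators are available, one per combination of a transform
f in {S: sine, E: entropy, T: triangle} with a normalisation
g in {U: network size, C: expected community size}.  Versatility is
deliberately *not* normalised by pi or by the finite-size maximum: the
raw scale carries interpretable landmarks (2.0 = perfect two-way
split).

The participation coefficient is provided for contrast only — it
measures how evenly a node's edge weight spreads over a fixed
partition's communities, so unlike versatility it depends on the graph
and on a single partition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .association import AssociationMatrix, Partition

__all__ = [
    "EstimatorCode",
    "VersatilityResult",
    "ParticipationResult",
    "versatility",
    "mean_versatility",
    "participation_coefficient",
    "write_result_tsv",
]

_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {}


def _transform_S(x: np.ndarray) -> np.ndarray:
    # exact zeros at the endpoints (sin(pi*1) would round to ~1e-16)
    out = np.sin(np.pi * np.asarray(x, dtype=float))
    return np.where((x == 0) | (x == 1), 0.0, out)


def _transform_E(x: np.ndarray) -> np.ndarray:
    # binary entropy in bits; 0 at x in {0, 1} by continuous extension
    out = np.zeros_like(x, dtype=float)
    inner = (x > 0) & (x < 1)
    xi = x[inner]
    out[inner] = -xi * np.log2(xi) - (1 - xi) * np.log2(1 - xi)
    return out


def _transform_T(x: np.ndarray) -> np.ndarray:
    # triangle wave scaled so f(0.5) = 1, matching the sine/entropy peaks
    return 2.0 * np.minimum(x, 1.0 - x)


_TRANSFORMS.update(S=_transform_S, E=_transform_E, T=_transform_T)


@dataclass(frozen=True)
class EstimatorCode:
    """Two-letter estimator code: transform (S/E/T) + normalisation (U/C).

    "SC" is the default and is what "versatility" means unqualified.
    """

    transform: str
    normalisation: str

    def __post_init__(self):
        if self.transform not in ("S", "E", "T"):
            raise ValueError(f"unknown transform {self.transform!r}; expected S, E or T")
        if self.normalisation not in ("U", "C"):
            raise ValueError(
                f"unknown normalisation {self.normalisation!r}; expected U or C"
            )

    @classmethod
    def parse(cls, code: "str | EstimatorCode") -> "EstimatorCode":
        if isinstance(code, EstimatorCode):
            return code
        code = str(code).upper()
        if len(code) != 2:
            raise ValueError(f"estimator code must be two letters, got {code!r}")
        return cls(code[0], code[1])

    def apply_transform(self, x: np.ndarray) -> np.ndarray:
        return _TRANSFORMS[self.transform](np.asarray(x, dtype=float))

    def __str__(self) -> str:
        return self.transform + self.normalisation


SC = EstimatorCode("S", "C")

ALL_ESTIMATORS = tuple(
    EstimatorCode(f, g) for f in ("S", "E", "T") for g in ("U", "C")
)


@dataclass(frozen=True)
class VersatilityResult:
    node_ids: tuple
    values: np.ndarray
    estimator: EstimatorCode
    run_count: int

    def as_dict(self) -> dict:
        return dict(zip(self.node_ids, self.values))

    def __len__(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True)
class ParticipationResult:
    node_ids: tuple
    values: np.ndarray

    def as_dict(self) -> dict:
        return dict(zip(self.node_ids, self.values))


def versatility(
    assoc: AssociationMatrix, estimator: "str | EstimatorCode" = SC
) -> VersatilityResult:
    """Per-node versatility from an association matrix.

    Parameters
    ----------
    assoc
        Co-assignment probabilities with unit diagonal.
    estimator
        Two-letter code; default "SC" (sine transform, community-size
        normalisation), the canonical versatility.
    """
    estimator = EstimatorCode.parse(estimator)
    p = assoc.p
    if len(assoc) < 2:
        raise ValueError("versatility needs at least 2 nodes")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("association entries must lie in [0, 1]")

    numer = estimator.apply_transform(p).sum(axis=0)
    if estimator.normalisation == "C":
        denom = p.sum(axis=0)  # expected size of j's community, incl. j
    else:
        denom = float(len(assoc))
    values = numer / denom
    # transforms vanish at 0 and 1, so exact-endpoint matrices give exact 0
    values[numer == 0.0] = 0.0
    return VersatilityResult(assoc.node_ids, values, estimator, assoc.run_count)


def mean_versatility(result: VersatilityResult) -> float:
    """Arithmetic mean of nodal versatility — the sweep's objective."""
    if len(result) == 0:
        raise ValueError("empty versatility result")
    return float(np.mean(result.values))


def participation_coefficient(graph, partition: Partition) -> ParticipationResult:
    """Guimera-Amaral participation coefficient for a fixed partition.

    PC(i) = 1 - sum_s (k_{i,s} / k_i)^2 over the K communities s, with
    k the (weighted) degree and k_{i,s} node i's (weighted) degree into
    community s.  0 when all of i's edge weight stays inside its own
    community, approaching 1 - 1/K when spread evenly.  Isolated nodes
    get PC = 0 by convention.
    """
    label_of = dict(zip(partition.node_ids, partition.labels))
    missing = [n for n in graph.nodes if n not in label_of]
    if missing:
        raise ValueError(f"graph node {missing[0]!r} missing from partition")

    values = []
    for node in partition.node_ids:
        if node not in graph:
            raise ValueError(f"partition node {node!r} missing from graph")
        if graph.is_directed():
            incident = [
                (v, w) for _, v, w in graph.out_edges(node, data="weight", default=1.0)
            ] + [(u, w) for u, _, w in graph.in_edges(node, data="weight", default=1.0)]
        else:
            incident = [
                (v, w) for _, v, w in graph.edges(node, data="weight", default=1.0)
            ]
        per_comm: dict = {}
        k_i = 0.0
        for nbr, w in incident:
            k_i += w
            lab = label_of[nbr]
            per_comm[lab] = per_comm.get(lab, 0.0) + w
        if k_i == 0:
            values.append(0.0)
            continue
        values.append(1.0 - sum((ks / k_i) ** 2 for ks in per_comm.values()))
    return ParticipationResult(partition.node_ids, np.asarray(values))


def write_result_tsv(result, path, value_name: str = "versatility") -> None:
    """Write per-node values as TSV plus a JSON metadata sidecar."""
    with open(path, "w") as fh:
        fh.write(f"node\t{value_name}\n")
        for node, val in zip(result.node_ids, result.values):
            fh.write(f"{node}\t{val:.10g}\n")
    meta = {"value": value_name}
    if isinstance(result, VersatilityResult):
        meta["estimator"] = str(result.estimator)
        meta["run_count"] = result.run_count
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2)
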