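"""Graph readers/writers, run configuration, and the embedded karate fixture.

Supported input formats: whitespace/tab-delimited edge lists (optional
third column = weight, default 1.0, ``#`` comments allowed), dense
adjacency CSV (node ids as header row and first column), and GraphML.
Node ids are treated as opaque strings throughout — numeric-looking ids
are never coerced, so ``01`` and ``1`` stay distinct.

All readers produce a graph with nodes in sorted-id order, self-loops
dropped (with a warning), duplicate edges summed, and negative weights
rejected.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "GraphInput",
    "RunConfig",
    "read_graph",
    "read_edgelist",
    "read_adjacency_csv",
    "read_graphml",
    "write_edgelist",
    "write_adjacency_csv",
    "karate_fixture",
]

logger = logging.getLogger(__name__)

# Zachary's karate club: 34 members, 78 friendships, transcribed from the
# original 1977 observational study (0-based ids, matching the copies
# bundled with common graph libraries).
_KARATE_EDGES = """\
0 1;0 2;0 3;0 4;0 5;0 6;0 7;0 8;0 10;0 11;0 12;0 13;0 17;0 19;0 21;0 31;\
1 2;1 3;1 7;1 13;1 17;1 19;1 21;1 30;2 3;2 7;2 8;2 9;2 13;2 27;2 28;2 32;\
3 7;3 12;3 13;4 6;4 10;5 6;5 10;5 16;6 16;8 30;8 32;8 33;9 33;13 33;14 32;\
14 33;15 32;15 33;18 32;18 33;19 33;20 32;20 33;22 32;22 33;23 25;23 27;\
23 29;23 32;23 33;24 25;24 27;24 31;25 31;26 29;26 33;27 33;28 31;28 33;\
29 32;29 33;30 32;30 33;31 32;31 33;32 33"""


def karate_fixture() -> nx.Graph:
    """The canonical 34-node, 78-edge unweighted karate club graph."""
    G = nx.Graph()
    G.add_nodes_from(range(34))
    for pair in _KARATE_EDGES.split(";"):
        u, v = pair.split()
        G.add_edge(int(u), int(v), weight=1.0)
    return G


@dataclass(frozen=True)
class GraphInput:
    """Declaration of a graph source: path (or fixture name) + format."""

    source: str
    format: str = "auto"  # edgelist | adjacency | graphml | auto
    directed: bool = False


@dataclass
class RunConfig:
    """A reproducible description of one analysis run.

    Serialises to/from JSON; every CLI run echoes its config into the
    output directory so results can be regenerated bit-identically.
    """

    estimator: str = "SC"
    detector: str = "louvain"
    detector_params: dict = field(default_factory=dict)
    gammas: list = field(default_factory=lambda: [round(0.1 * k, 1) for k in range(1, 31)])
    runs_per_gamma: int = 1000
    base_seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _finalise(G: nx.Graph, source="graph") -> nx.Graph:
    """Sort nodes, drop self-loops, reject negative weights."""
    loops = list(nx.selfloop_edges(G))
    if loops:
        warnings.warn(f"{source}: dropped {len(loops)} self-loop(s)")
        G.remove_edges_from(loops)
    for u, v, w in G.edges(data="weight", default=1.0):
        if w < 0:
            raise ValueError(f"{source}: negative weight {w} on edge ({u!r}, {v!r})")
    H = G.__class__()
    H.add_nodes_from(sorted(G.nodes, key=str))
    H.add_edges_from(G.edges(data=True))
    return H


def read_edgelist(path, directed: bool = False) -> nx.Graph:
    """Whitespace/tab edge list: `u v [weight]`; `#` starts a comment.

    Duplicate edges are summed; node ids kept as strings.
    """
    G = nx.DiGraph() if directed else nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 'u v [weight]', got {raw.rstrip()!r}"
                )
            u, v = parts[0], parts[1]
            try:
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: bad weight {parts[2]!r}"
                ) from None
            if G.has_edge(u, v):
                G[u][v]["weight"] += w
            else:
                G.add_edge(u, v, weight=w)
    return _finalise(G, source=str(path))


def read_adjacency_csv(path, directed: bool = False) -> nx.Graph:
    """Dense adjacency CSV with node ids as header row and first column."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: adjacency row and column ids differ")
    G = nx.DiGraph() if directed else nx.Graph()
    G.add_nodes_from(df.index)
    for i, u in enumerate(df.index):
        cols = df.columns if directed else df.columns[i:]
        for v in cols:
            w = float(df.at[u, v])
            if w != 0.0:
                G.add_edge(u, v, weight=w)
    return _finalise(G, source=str(path))


def read_graphml(path, directed: bool = False) -> nx.Graph:
    G = nx.read_graphml(path)
    if directed and not G.is_directed():
        G = G.to_directed()
    if not directed and G.is_directed():
        G = G.to_undirected()
    G = nx.relabel_nodes(G, {n: str(n) for n in G.nodes})
    for u, v in G.edges:
        G[u][v].setdefault("weight", 1.0)
    return _finalise(G, source=str(path))


_READERS = {
    "edgelist": read_edgelist,
    "adjacency": read_adjacency_csv,
    "graphml": read_graphml,
}

_EXT_FORMATS = {
    ".tsv": "edgelist",
    ".txt": "edgelist",
    ".edges": "edgelist",
    ".edgelist": "edgelist",
    ".csv": "adjacency",
    ".graphml": "graphml",
    ".xml": "graphml",
}


def read_graph(source, format: str = "auto", directed: bool = False) -> nx.Graph:
    """Read a graph, auto-detecting the format from the extension.

    ``source="karate"`` returns the embedded karate club fixture.
    """
    if isinstance(source, GraphInput):
        return read_graph(source.source, source.format, source.directed)
    if str(source) == "karate":
        return karate_fixture()
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"no such graph file: {source}")
    if format == "auto":
        try:
            format = _EXT_FORMATS[path.suffix.lower()]
        except KeyError:
            raise ValueError(
                f"cannot infer format from extension {path.suffix!r}; "
                "pass format='edgelist'|'adjacency'|'graphml'"
            ) from None
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}") from None
    return reader(path, directed=directed)


def write_edgelist(G: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\tweight\n")
        for u, v, w in G.edges(data="weight", default=1.0):
            fh.write(f"{u}\t{v}\t{w:g}\n")


def write_adjacency_csv(G: nx.Graph, path) -> None:
    nodes = list(G.nodes)
    df = pd.DataFrame(
        nx.to_numpy_array(G, nodelist=nodes, weight="weight"),
        index=[str(n) for n in nodes],
        columns=[str(n) for n in nodes],
    )
    df.to_csv(path, index_label="node")
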