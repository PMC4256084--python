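"""Labeled binary directed networks and their degree/neighbourhood statistics.

The central object is :class:`DirectedNetwork`, a thin immutable wrapper
around an N x N binary adjacency matrix with an ordered list of node
labels.  Entry ``(i, j) = 1`` means a directed projection ``i -> j``.
Networks of this kind arise from tract-tracing collations (e.g. the
CoCoMac macaque matrix) where projections are unweighted and
direction-specific.

Loaders accept three on-disk dialects: an edge-list CSV, standard
directed GraphML, and a MATLAB container holding the adjacency array and
a cell of labels (the layout used by the macaque dataset, arrays named
``CoCoMac_adjacency`` and ``Labels``, with generic ``adjacency`` /
``labels`` fallbacks).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DirectedNetwork",
    "DegreeProfile",
    "NeighbourhoodProfile",
    "load_network",
    "save_network",
    "degrees",
    "unidirectional_edges",
    "reciprocal_pairs",
    "in_neighbour_profile",
    "assortativity_profile",
]


class NetworkFormatError(ValueError):
    """Raised when an input file violates the binary directed-network contract."""


@dataclass(frozen=True)
class DirectedNetwork:
    """A labeled, binary, zero-diagonal directed graph.

    Parameters
    ----------
    node_labels:
        Ordered unique labels; file order is canonical and preserved in
        every downstream table.
    adjacency:
        N x N matrix with entries in {0, 1} and a zero diagonal.
    """

    node_labels: tuple[str, ...]
    adjacency: np.ndarray
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.node_labels)
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise NetworkFormatError(f"adjacency must be square, got shape {adj.shape}")
        if len(labels) != adj.shape[0]:
            raise NetworkFormatError(
                f"{len(labels)} labels for a {adj.shape[0]}-node adjacency matrix"
            )
        if len(set(labels)) != len(labels):
            raise NetworkFormatError("node labels must be unique")
        bad = ~np.isin(adj, (0, 1))
        if bad.any():
            raise NetworkFormatError(
                "adjacency entries must be 0 or 1 (weighted/signed matrices are "
                f"rejected); offending values include {np.unique(adj[bad])[:5]}"
            )
        if np.diagonal(adj).any():
            raise NetworkFormatError(
                "self-loops (nonzero diagonal) are not allowed; pass "
                "drop_self_loops=True to load_network to discard them"
            )
        adj = adj.astype(np.int8, copy=True)
        adj.setflags(write=False)
        object.__setattr__(self, "node_labels", labels)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(labels)})

    # -- basic interrogation -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node label {label!r}") from None

    def has_edge(self, source: str, target: str) -> bool:
        return bool(self.adjacency[self.index_of(source), self.index_of(target)])

    def edges(self) -> list[tuple[str, str]]:
        src, dst = np.nonzero(self.adjacency)
        return [(self.node_labels[i], self.node_labels[j]) for i, j in zip(src, dst)]

    def successors(self) -> list[np.ndarray]:
        """Per-node integer arrays of efferent targets, in node order."""
        return [np.flatnonzero(row) for row in self.adjacency]

    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_labels)
        g.add_edges_from(self.edges())
        return g

    def is_strongly_connected(self) -> bool:
        """Diagnostic only; strong connectivity is reported, never enforced."""
        return nx.is_strongly_connected(self.to_networkx())

    @classmethod
    def from_edges(
        cls,
        node_labels: Sequence[str],
        edges: Iterable[tuple[str, str]],
        drop_self_loops: bool = False,
    ) -> "DirectedNetwork":
        labels = [str(l) for l in node_labels]
        index = {l: i for i, l in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=np.int8)
        n_dropped = 0
        for s, t in edges:
            s, t = str(s), str(t)
            if s not in index or t not in index:
                raise NetworkFormatError(f"edge ({s!r}, {t!r}) references an undeclared node")
            if s == t:
                if drop_self_loops:
                    n_dropped += 1
                    continue
                raise NetworkFormatError(f"self-loop at node {s!r}")
            adj[index[s], index[t]] = 1
        if n_dropped:
            warnings.warn(f"dropped {n_dropped} self-loop(s)", stacklevel=3)
        return cls(tuple(labels), adj)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("edgelist-csv", "graphml", "mat-container")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "edgelist-csv"
    if suffix == ".graphml":
        return "graphml"
    if suffix == ".mat":
        return "mat-container"
    raise NetworkFormatError(
        f"cannot infer format from suffix {suffix!r}; pass format= explicitly"
    )


def load_network(
    path: str | Path,
    format: str | None = None,
    labels_path: str | Path | None = None,
    drop_self_loops: bool = False,
) -> DirectedNetwork:
    """Load a directed binary network from disk.

    Parameters
    ----------
    path:
        File to read.  Format is inferred from the suffix (``.csv``,
        ``.graphml``, ``.mat``) unless ``format`` is given explicitly as
        one of ``edgelist-csv``, ``graphml`` or ``mat-container``.
    labels_path:
        Optional companion file for the edge-list dialect, one label per
        line, declaring node order and any isolated nodes.
    drop_self_loops:
        If True, diagonal entries are discarded with a warning instead of
        raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise NetworkFormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "edgelist-csv":
        return _load_edgelist(path, labels_path, drop_self_loops)
    if fmt == "graphml":
        return _load_graphml(path, drop_self_loops)
    return _load_mat(path, drop_self_loops)


def _load_edgelist(
    path: Path, labels_path: str | Path | None, drop_self_loops: bool
) -> DirectedNetwork:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("source", "target"):
        if col not in df.columns:
            raise NetworkFormatError(f"edge-list CSV must have a {col!r} column")
    edges = list(zip(df["source"], df["target"]))
    if labels_path is not None:
        labels = [
            line.strip()
            for line in Path(labels_path).read_text().splitlines()
            if line.strip()
        ]
    else:
        # first-appearance order over sources then targets
        labels = list(dict.fromkeys([s for s, _ in edges] + [t for _, t in edges]))
    return DirectedNetwork.from_edges(labels, edges, drop_self_loops=drop_self_loops)


def _load_graphml(path: Path, drop_self_loops: bool) -> DirectedNetwork:
    g = nx.read_graphml(path)
    if not g.is_directed():
        raise NetworkFormatError("GraphML file does not declare a directed graph")
    labels = [str(n) for n in g.nodes()]
    return DirectedNetwork.from_edges(
        labels, [(str(s), str(t)) for s, t in g.edges()], drop_self_loops=drop_self_loops
    )


_MAT_ADJ_KEYS = ("CoCoMac_adjacency", "adjacency")
_MAT_LABEL_KEYS = ("Labels", "labels")


def _load_mat(path: Path, drop_self_loops: bool) -> DirectedNetwork:
    from scipy.io import loadmat

    contents = loadmat(path, squeeze_me=True)
    adj = next((contents[k] for k in _MAT_ADJ_KEYS if k in contents), None)
    raw_labels = next((contents[k] for k in _MAT_LABEL_KEYS if k in contents), None)
    if adj is None or raw_labels is None:
        raise NetworkFormatError(
            f"MAT container must hold one of {_MAT_ADJ_KEYS} and one of "
            f"{_MAT_LABEL_KEYS}; found keys {sorted(k for k in contents if not k.startswith('__'))}"
        )
    labels = [str(l).strip() for l in np.ravel(raw_labels)]
    adj = np.asarray(adj)
    if drop_self_loops and np.diagonal(adj).any():
        adj = adj.copy()
        np.fill_diagonal(adj, 0)
        warnings.warn("dropped self-loop diagonal entries", stacklevel=3)
    return DirectedNetwork(tuple(labels), adj)


def save_network(net: DirectedNetwork, path: str | Path, format: str | None = None) -> None:
    """Write a network as edge-list CSV (plus ``.labels`` sidecar) or GraphML."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "edgelist-csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target"])
            writer.writerows(net.edges())
        Path(str(path) + ".labels").write_text("\n".join(net.node_labels) + "\n")
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise NetworkFormatError(f"unsupported output format {fmt!r}")


# ---------------------------------------------------------------------------
# Degree and neighbourhood statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegreeProfile:
    """Per-node in/out degree table, in canonical node order."""

    node_labels: tuple[str, ...]
    in_degree: np.ndarray
    out_degree: np.ndarray

    def of(self, label: str) -> tuple[int, int]:
        i = self.node_labels.index(label)
        return int(self.in_degree[i]), int(self.out_degree[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"in_degree": self.in_degree, "out_degree": self.out_degree},
            index=pd.Index(self.node_labels, name="node"),
        )


@dataclass(frozen=True)
class NeighbourhoodProfile:
    """Degree statistics of the afferent (in-)neighbourhood of one node.

    ``mean_in`` / ``mean_out`` are NaN when the node has no afferents.
    """

    node: str
    in_neighbours: tuple[str, ...]
    mean_in: float
    mean_out: float


def degrees(net: DirectedNetwork) -> DegreeProfile:
    """Exact row/column sums of the adjacency matrix."""
    return DegreeProfile(net.node_labels, net.in_degrees(), net.out_degrees())


def unidirectional_edges(net: DirectedNetwork) -> list[tuple[str, str]]:
    """Ordered pairs (i, j) with i->j present and j->i absent."""
    a = net.adjacency
    mask = (a == 1) & (a.T == 0)
    src, dst = np.nonzero(mask)
    return [(net.node_labels[i], net.node_labels[j]) for i, j in zip(src, dst)]


def reciprocal_pairs(net: DirectedNetwork) -> list[tuple[str, str]]:
    """Unordered pairs {i, j} connected in both directions (i < j by index)."""
    a = net.adjacency
    mask = np.triu((a == 1) & (a.T == 1), k=1)
    src, dst = np.nonzero(mask)
    return [(net.node_labels[i], net.node_labels[j]) for i, j in zip(src, dst)]


def in_neighbour_profile(net: DirectedNetwork, node: str) -> NeighbourhoodProfile:
    """Mean in/out degree over the set of nodes projecting to ``node``."""
    j = net.index_of(node)
    sources = np.flatnonzero(net.adjacency[:, j])
    if sources.size == 0:
        return NeighbourhoodProfile(node, (), float("nan"), float("nan"))
    k_in = net.in_degrees()
    k_out = net.out_degrees()
    return NeighbourhoodProfile(
        node,
        tuple(net.node_labels[i] for i in sources),
        float(k_in[sources].mean()),
        float(k_out[sources].mean()),
    )


def assortativity_profile(net: DirectedNetwork) -> pd.DataFrame:
    """Per-node degrees next to the mean degrees of the node's in-neighbours.

    Rows for nodes with no afferents carry NaN neighbour means.  Index is
    canonical node order.
    """
    k_in = net.in_degrees().astype(float)
    k_out = net.out_degrees().astype(float)
    a = net.adjacency.astype(float)
    n_aff = a.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_in = np.where(n_aff > 0, (a.T @ k_in) / n_aff, np.nan)
        mean_out = np.where(n_aff > 0, (a.T @ k_out) / n_aff, np.nan)
    return pd.DataFrame(
        {
            "in_degree": k_in.astype(int),
            "out_degree": k_out.astype(int),
            "neighbours_mean_in_degree": mean_in,
            "neighbours_mean_out_degree": mean_out,
        },
        index=pd.Index(net.node_labels, name="node"),
    )
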