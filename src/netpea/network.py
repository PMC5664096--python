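"""Gene interaction network model.

An undirected, unweighted gene graph (e.g., a protein--protein interaction
network) together with the column-stochastic transition matrix ``M`` used by
the random walk with restart: ``M[i, j] = 1/degree(j)`` if genes *i* and *j*
interact, else 0.  Column *j* of ``M`` is the uniform distribution over the
neighbours of *j*; isolated nodes get an all-zero column, so any walk mass
placed there decays to the restart term.

Networks are read from and written to a plain two-column tab-separated edge
list of gene symbols.  Identifier matching everywhere in this package is
exact-string: no case folding and no alias mapping (identifier translation is
an upstream data-preparation concern).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "NetworkError",
    "EmptyNetworkError",
    "EdgeListParseError",
    "load_edge_list",
    "write_edge_list",
    "build_transition_matrix",
]


class NetworkError(ValueError):
    """Base class for network construction/validation failures."""


class EmptyNetworkError(NetworkError):
    """Raised when a network ends up with zero edges after filtering."""


class EdgeListParseError(NetworkError):
    """Raised for malformed edge-list lines."""


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneNetwork:
    """Undirected gene graph with a column-stochastic transition matrix.

    Attributes
    ----------
    nodes
        Gene identifiers in first-appearance order.
    edges
        Canonical (lexicographically sorted) unordered gene pairs; no
        self-loops, no duplicates.
    degree
        Per-node edge count, aligned with ``nodes``.
    transition
        Sparse CSR matrix ``M`` with ``M[i, j] = 1/degree(j)`` for edges.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    index: dict[str, int] = field(repr=False)
    degree: np.ndarray = field(repr=False)
    transition: sp.csr_array = field(repr=False)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Sequence[str] = (),
    ) -> "GeneNetwork":
        """Build a network from gene pairs.

        Self-loops are dropped and duplicate edges collapsed (counts logged).
        ``extra_nodes`` registers additional nodes that may end up isolated
        (degree 0); isolated nodes are retained, with an all-zero transition
        column.  ``extra_nodes`` are registered first, so passing a full node
        list fixes the node order (rewired networks rely on this to share the
        original's indexing).
        """
        nodes: list[str] = []
        index: dict[str, int] = {}

        def _register(g: str) -> int:
            i = index.get(g)
            if i is None:
                i = len(nodes)
                index[g] = i
                nodes.append(g)
            return i

        for g in extra_nodes:
            _register(g)
        edge_set: set[tuple[str, str]] = set()
        n_self = n_dup = 0
        for a, b in edges:
            if a == b:
                n_self += 1
                continue
            e = _canonical(a, b)
            if e in edge_set:
                n_dup += 1
                continue
            edge_set.add(e)
            _register(a)
            _register(b)
        if n_self or n_dup:
            logger.info(
                "dropped %d self-loop(s) and %d duplicate edge(s)", n_self, n_dup
            )
        if not edge_set:
            raise EmptyNetworkError("network has no edges after filtering")

        n = len(nodes)
        rows = np.fromiter(
            (index[e[i]] for e in edge_set for i in (0, 1)), dtype=np.int64
        ).reshape(-1, 2)
        net = cls(
            nodes=tuple(nodes),
            edges=frozenset(edge_set),
            index=index,
            degree=np.bincount(rows.ravel(), minlength=n),
            transition=sp.csr_array((n, n)),
        )
        return build_transition_matrix(net)

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def __contains__(self, gene: str) -> bool:
        return gene in self.index

    def neighbors(self, gene: str) -> tuple[str, ...]:
        """Genes adjacent to ``gene`` (empty for isolated nodes)."""
        j = self.index[gene]
        col = self.transition[:, [j]].tocoo()
        return tuple(self.nodes[i] for i in col.coords[0])

    def indicator(self, genes: Iterable[str]) -> np.ndarray:
        """0/1 membership vector over ``nodes`` for a gene collection."""
        v = np.zeros(self.n_nodes)
        for g in genes:
            v[self.index[g]] = 1.0
        return v


def build_transition_matrix(network: GeneNetwork) -> GeneNetwork:
    """(Re)build the column-stochastic transition matrix in place.

    Column *j* is uniform (``1/degree(j)``) over the neighbours of *j*;
    isolated nodes keep an all-zero column.  Returns ``network``.
    """
    n = network.n_nodes
    idx = network.index
    ij = np.array(
        [(idx[a], idx[b]) for a, b in network.edges], dtype=np.int64
    ).reshape(-1, 2)
    rows = np.concatenate([ij[:, 0], ij[:, 1]])
    cols = np.concatenate([ij[:, 1], ij[:, 0]])
    inv_deg = np.zeros(n)
    nz = network.degree > 0
    inv_deg[nz] = 1.0 / network.degree[nz]
    vals = inv_deg[cols]
    network.transition = sp.csr_array(
        sp.coo_array((vals, (rows, cols)), shape=(n, n))
    )
    return network


def load_edge_list(path: str | Path, comment_prefix: str = "#") -> GeneNetwork:
    """Read a tab-separated edge list into a :class:`GeneNetwork`.

    Each non-comment, non-blank line must carry at least two tab-separated
    fields; the first two are gene identifiers and extra columns (HPRD-style
    dumps carry several) are ignored.  Duplicate edges are collapsed and
    self-loops dropped, with counts logged.

    Raises
    ------
    EdgeListParseError
        For a line with fewer than two fields.
    EmptyNetworkError
        If no edges survive filtering.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(comment_prefix):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected >=2 tab-separated fields"
                )
            pairs.append((fields[0], fields[1]))
    try:
        net = GeneNetwork.from_edges(pairs)
    except EmptyNetworkError:
        raise EmptyNetworkError(f"{path}: no usable edges") from None
    logger.info(
        "loaded network: %d nodes, %d edges from %s", net.n_nodes, net.n_edges, path
    )
    return net


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write the network as a two-column TSV, edges sorted for determinism."""
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")
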