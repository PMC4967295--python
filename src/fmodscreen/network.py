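"""Weighted functional linkage network (FLN): loading, thresholding, queries.

The FLN is an undirected gene graph whose edge weight ``w_ij`` in (0, 1]
encodes the likelihood that genes *i* and *j* share biological function.
Every downstream score in the screen (seed scores, mutual predictability)
is computed on this substrate, usually after discarding all but the
strongest few percent of links so that what remains are tight clusters of
functionally related genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedGeneNetwork",
    "load_edge_list",
    "threshold_by_quantile",
    "neighbors_within",
]


class WeightedGeneNetwork:
    """Undirected weighted gene graph with weights in (0, 1].

    Thin wrapper over :class:`networkx.Graph` that enforces the FLN
    invariants (no self-loops, no duplicate pairs, strictly positive
    weights ≤ 1) and caches a CSR adjacency matrix for fast seed scoring.

    Gene identifiers are opaque, case-sensitive strings; no symbol or
    Entrez mapping is attempted.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]] = (),
                 nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b, w in edges:
            self._check_weight(a, b, w)
            if a == b:
                raise ValueError(f"self-loop on gene {a!r}")
            if g.has_edge(a, b):
                raise ValueError(f"duplicate edge {a!r}-{b!r}")
            g.add_edge(a, b, weight=float(w))
        self._graph = g
        self._cache: tuple[sparse.csr_matrix, dict[str, int], list[str]] | None = None

    @staticmethod
    def _check_weight(a: str, b: str, w: float) -> None:
        if not (0.0 < w <= 1.0):
            raise ValueError(
                f"edge {a!r}-{b!r}: weight {w} outside (0, 1]")

    @classmethod
    def _from_graph(cls, g: nx.Graph) -> "WeightedGeneNetwork":
        net = cls.__new__(cls)
        net._graph = g
        net._cache = None
        return net

    # -- basic queries ------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def universe_size(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def weight(self, a: str, b: str) -> float:
        """Weight of edge a-b, or 0.0 if absent."""
        data = self._graph.get_edge_data(a, b)
        return 0.0 if data is None else data["weight"]

    def edge_weights(self) -> np.ndarray:
        """All edge weights as an array (arbitrary but stable order)."""
        return np.fromiter(
            (d["weight"] for _, _, d in self._graph.edges(data=True)),
            dtype=float, count=self.n_edges)

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for a, b, d in self._graph.edges(data=True):
            yield a, b, d["weight"]

    def __contains__(self, gene: str) -> bool:
        return gene in self._graph

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedGeneNetwork):
            return NotImplemented
        return (self.nodes == other.nodes
                and sorted((min(a, b), max(a, b), w) for a, b, w in self.edges())
                == sorted((min(a, b), max(a, b), w) for a, b, w in other.edges()))

    def __repr__(self) -> str:
        return (f"WeightedGeneNetwork({self.universe_size} genes, "
                f"{self.n_edges} edges)")

    # -- matrix view ---------------------------------------------------

    def adjacency(self) -> tuple[sparse.csr_matrix, dict[str, int], list[str]]:
        """Symmetric CSR weight matrix plus gene<->index maps.

        Node order is sorted gene identifier, so the matrix is stable
        across runs and platforms. Cached; the network is immutable
        after construction as far as the public API is concerned.
        """
        if self._cache is None:
            order = sorted(self._graph.nodes)
            index = {g: i for i, g in enumerate(order)}
            n = len(order)
            rows, cols, vals = [], [], []
            for a, b, d in self._graph.edges(data=True):
                ia, ib = index[a], index[b]
                rows += [ia, ib]
                cols += [ib, ia]
                vals += [d["weight"], d["weight"]]
            mat = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(n, n), dtype=float)
            self._cache = (mat, index, order)
        return self._cache

    def restrict_edges(self, min_weight: float) -> "WeightedGeneNetwork":
        """Copy keeping only edges with weight >= min_weight; all nodes kept."""
        g = nx.Graph()
        g.add_nodes_from(self._graph.nodes)
        g.add_weighted_edges_from(
            (a, b, d["weight"]) for a, b, d in self._graph.edges(data=True)
            if d["weight"] >= min_weight)
        return WeightedGeneNetwork._from_graph(g)


def load_edge_list(path: str | Path, min_weight: float = 0.0) -> WeightedGeneNetwork:
    """Load a tab-separated ``geneA<TAB>geneB<TAB>weight`` edge list.

    Lines starting with ``#`` are comments. Edges with weight below
    ``min_weight`` are dropped; duplicate unordered pairs are collapsed
    keeping the maximum weight; self-loops are dropped with a warning.

    Raises
    ------
    ValueError
        On a malformed line (fewer than 3 columns or unparseable weight),
        naming the line number, or on a weight outside (0, 1].
    """
    path = Path(path)
    best: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, "
                    f"got {len(parts)}")
            a, b = parts[0], parts[1]
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: weight {parts[2]!r} is not a number"
                ) from exc
            if not (0.0 < w <= 1.0):
                raise ValueError(
                    f"{path}:{lineno}: weight {w} outside (0, 1]")
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                continue
            nodes.update((a, b))
            if w < min_weight:
                continue
            key = (a, b) if a <= b else (b, a)
            if w > best.get(key, 0.0):
                best[key] = w
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_weighted_edges_from((a, b, w) for (a, b), w in best.items())
    # nodes seen only on sub-threshold edges are retained as isolates so
    # the scoring universe does not depend on the threshold
    return WeightedGeneNetwork._from_graph(g)


def threshold_by_quantile(net: WeightedGeneNetwork, keep_fraction: float
                          ) -> tuple[WeightedGeneNetwork, float]:
    """Keep the strongest ``keep_fraction`` of edges by weight quantile.

    The returned network contains the edges with weight >= the
    ``1 - keep_fraction`` quantile of the edge-weight distribution (ties
    at the threshold are kept, so slightly more than the nominal fraction
    may survive). The node set is unchanged: isolated nodes are retained
    so that the scoring universe is stable across parameter sweeps.

    Returns the thresholded network and the threshold weight used.
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError(f"keep_fraction {keep_fraction} outside (0, 1]")
    if net.n_edges == 0:
        raise ValueError("cannot threshold an empty network")
    weights = net.edge_weights()
    if keep_fraction == 1.0:
        thr = float(weights.min())
    else:
        # 'higher' keeps the threshold at an actual edge weight, so the
        # inclusive >= rule keeps close to the nominal fraction
        thr = float(np.quantile(weights, 1.0 - keep_fraction,
                                method="higher"))
    return net.restrict_edges(thr), thr


def neighbors_within(net: WeightedGeneNetwork, seeds: Iterable[str],
                     depth: int) -> set[str]:
    """Non-seed genes reachable from any seed in <= ``depth`` edges.

    ``depth`` must be 1 or 2 (mutated drivers plus first, or first and
    second, nearest neighbors). Seeds absent from the network are
    ignored with a warning.
    """
    if depth not in (1, 2):
        raise ValueError(f"depth must be 1 or 2, got {depth}")
    seeds = set(seeds)
    missing = {s for s in seeds if s not in net}
    if missing:
        logger.warning("%d seed gene(s) absent from the network: %s",
                       len(missing), sorted(missing)[:10])
    present = seeds - missing
    frontier = set(present)
    reached: set[str] = set()
    for _ in range(depth):
        nxt = {n for f in frontier for n in net.graph.neighbors(f)}
        reached |= nxt
        frontier = nxt - seeds
    return reached - seeds
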