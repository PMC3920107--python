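"""Semantic network construction from a pairwise similarity matrix.

The network is an unweighted, undirected simple graph: nodes are documents
(concepts), and an edge joins two nodes whose pairwise score is at least as
similar as a threshold. The threshold is found by an iterative coverage
search: the strictest value at which the largest connected component still
covers the requested fraction of documents (default 90%). Documents outside
that component are discarded. A scrambled control keeps the node and edge
counts but reassigns the edges uniformly at random, destroying the semantic
structure while matching network size and density.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .corpus import Direction, SimilarityMatrix


class NetworkError(ValueError):
    """Raised for invalid network-construction inputs."""


@dataclass
class SemanticNetwork:
    """Undirected simple graph of concept nodes (the search space).

    Wraps a :class:`networkx.Graph`; node insertion order is the canonical
    node ordering. ``provenance`` records how the network came to be:
    ``thresholded`` (from a similarity matrix), ``scrambled`` (randomized
    control), or ``synthetic`` (generator output).
    """

    graph: nx.Graph
    provenance: str = "thresholded"

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise NetworkError(f"self-loops not allowed: {loops[:5]}")

    @property
    def node_ids(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree()], dtype=int)

    def largest_component(self) -> list[str]:
        """Node ids of the largest connected component (ties: first seen)."""
        if self.n_nodes == 0:
            return []
        best = max(nx.connected_components(self.graph), key=len)
        order = {n: i for i, n in enumerate(self.graph.nodes)}
        return sorted(best, key=order.__getitem__)


@dataclass
class ThresholdResult:
    """Outcome of the coverage-threshold search."""

    threshold: float
    coverage_achieved: float
    retained_nodes: list[str]
    discarded_nodes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "threshold": self.threshold,
                "coverage_achieved": self.coverage_achieved,
                "n_retained": len(self.retained_nodes),
                "n_discarded": len(self.discarded_nodes),
                "discarded_ids": self.discarded_nodes,
            },
            indent=2,
        )


def _similar_mask(values: np.ndarray, threshold: float,
                  direction: Direction) -> np.ndarray:
    """Boolean adjacency at a threshold; ties at the threshold are edges."""
    if direction is Direction.LOWER_IS_SIMILAR:
        mask = values <= threshold
    else:
        mask = values >= threshold
    np.fill_diagonal(mask, False)
    return mask

def _largest_component_indices(mask: np.ndarray) -> np.ndarray:
    n_comp, labels = connected_components(csr_matrix(mask), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return np.flatnonzero(labels == int(np.argmax(sizes)))


def find_threshold(matrix: SimilarityMatrix, coverage: float = 0.9) -> ThresholdResult:
    """Find the strictest threshold whose largest component covers ``coverage``.

    The candidate thresholds are the observed off-diagonal values; component
    structure only changes there, and coverage is monotone in threshold
    leniency, so the answer is located by bisection over the sorted unique
    values (strictest to most lenient). Ties at the threshold are included
    as edges.

    Raises
    ------
    NetworkError
        If the coverage is unreachable even with every edge present; the
        message reports the maximum achievable coverage.
    """
    if not (0 < coverage <= 1):
        raise NetworkError("coverage must be in (0, 1]")
    n = matrix.n
    if n < 2:
        raise NetworkError("matrix must have at least 2 nodes")
    need = math.ceil(coverage * n)

    uniq = np.unique(matrix.off_diagonal())
    if matrix.direction is Direction.HIGHER_IS_SIMILAR:
        uniq = uniq[::-1]  # leniency order: strictest candidate first

    def lcc(k: int) -> np.ndarray:
        return _largest_component_indices(
            _similar_mask(matrix.values, float(uniq[k]), matrix.direction)
        )

    last = lcc(len(uniq) - 1)
    if len(last) < need:
        raise NetworkError(
            f"coverage {coverage} unreachable: even the most lenient threshold "
            f"connects {len(last)}/{n} nodes "
            f"(max achievable coverage {len(last) / n:.4f})"
        )

    lo, hi = 0, len(uniq) - 1  # invariant: lcc(hi) satisfies coverage
    while lo < hi:
        mid = (lo + hi) // 2
        if len(lcc(mid)) >= need:
            hi = mid
        else:
            lo = mid + 1
    comp = lcc(hi)
    retained = [matrix.doc_ids[i] for i in comp]
    kept = set(comp.tolist())
    discarded = [d for i, d in enumerate(matrix.doc_ids) if i not in kept]
    return ThresholdResult(float(uniq[hi]), len(comp) / n, retained, discarded)


def build_network(
    matrix: SimilarityMatrix,
    threshold: float,
    retained: list[str] | None = None,
) -> SemanticNetwork:
    """Threshold the matrix into a network on the retained nodes.

    Edge (i, j) exists iff the pair is at least as similar as ``threshold``
    (<= for divergences, >= for similarity scores) and both endpoints are
    retained. No self-loops. The edge set does not depend on the node
    ordering of the input matrix.
    """
    if retained is None:
        retained = list(matrix.doc_ids)
    if not retained:
        raise NetworkError("retained node list is empty")
    idx = [matrix.index(d) for d in retained]
    sub = matrix.values[np.ix_(idx, idx)]
    mask = _similar_mask(sub, threshold, matrix.direction)
    g = nx.Graph()
    g.add_nodes_from(retained)
    ii, jj = np.nonzero(np.triu(mask, k=1))
    g.add_edges_from((retained[i], retained[j]) for i, j in zip(ii, jj))
    return SemanticNetwork(g, provenance="thresholded")


def scramble_network(network: SemanticNetwork, seed: int) -> SemanticNetwork:
    """Size-matched control: same nodes, same edge count, random edges.

    Edges are drawn uniformly at random without replacement from all
    unordered non-self pairs (Erdos-Renyi G(N, M) on the original node set),
    so the control destroys any similarity structure while matching size and
    density. Reproducible for a fixed seed.
    """
    nodes = network.node_ids
    n, m = len(nodes), network.n_edges
    if m > n * (n - 1) // 2:
        raise NetworkError("edge count exceeds simple-graph capacity")
    g = nx.gnm_random_graph(n, m, seed=random.Random(int(seed)))
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))
    g.add_nodes_from(nodes)  # keep isolated nodes and canonical order
    return SemanticNetwork(g, provenance="scrambled")


# ---------------------------------------------------------------------------
# I/O: TSV edge list + node file + meta JSON, lossless round-trip
# ---------------------------------------------------------------------------

def write_network(network: SemanticNetwork, path: str | Path) -> None:
    """Write a network directory: edges.tsv, nodes.txt, meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\n")
        for u, v in network.graph.edges:
            fh.write(f"{u}\t{v}\n")
    with open(path / "nodes.txt", "w", encoding="utf-8") as fh:
        for node in network.node_ids:
            fh.write(f"{node}\n")
    (path / "meta.json").write_text(
        json.dumps({"provenance": network.provenance}), "utf-8"
    )


def read_network(path: str | Path) -> SemanticNetwork:
    path = Path(path)
    if not (path / "edges.tsv").exists():
        raise NetworkError(f"no network found at {path} (missing edges.tsv)")
    g = nx.Graph()
    nodes_file = path / "nodes.txt"
    if nodes_file.exists():
        g.add_nodes_from(
            line.rstrip("\n") for line in nodes_file.read_text("utf-8").splitlines()
            if line.strip()
        )
    with open(path / "edges.tsv", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "source\ttarget":
            raise NetworkError(f"bad edge-list header in {path}: {header!r}")
        for line in fh:
            if line.strip():
                u, v = line.rstrip("\n").split("\t")
                g.add_edge(u, v)
    provenance = "thresholded"
    meta = path / "meta.json"
    if meta.exists():
        provenance = json.loads(meta.read_text("utf-8")).get("provenance", provenance)
    return SemanticNetwork(g, provenance=provenance)
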