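"""Protein-protein interaction graph handling.

Reads STRING-dialect edge lists (``protein1 protein2 combined_score`` with
scores on the integer 0-1000 scale), applies the confidence threshold,
restricts the network to measured genes, and classifies interactor order
(shortest-path distance) from a query node.  Confidence is kept as an edge
attribute but the thresholded network is treated as unweighted topology:
confidence never acts as a path weight.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractorReport",
    "read_string_edges",
    "filter_by_confidence",
    "restrict_to_measured",
    "interaction_order",
    "write_edge_tsv",
]


@dataclass
class InteractorReport:
    """Shortest-path orders from a source gene to a set of targets.

    ``orders`` maps each target to its interactor order (1 = direct,
    2 = second-order, ...) or None when unreachable; ``paths`` holds one
    witness shortest path per reachable target (lexicographically smallest
    among all shortest paths, for reproducibility).
    """

    source: str
    orders: dict
    paths: dict

    def to_json(self, path) -> None:
        payload = {
            "source": self.source,
            "targets": {
                t: {
                    "order": self.orders[t],
                    "path": self.paths.get(t),
                }
                for t in self.orders
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return path.open()


def read_string_edges(path) -> nx.Graph:
    """Parse a STRING links file into an undirected confidence graph.

    Accepts tab- or space-delimited rows with a header naming ``protein1``,
    ``protein2`` and ``combined_score``; scores are divided by 1000.
    Reciprocal/duplicate rows are merged keeping the maximum score and
    self-loops are dropped (count logged).
    """
    g = nx.Graph()
    self_loops = 0
    with _open_text(path) as fh:
        header = fh.readline()
        cols = header.replace("\t", " ").split()
        try:
            i1 = cols.index("protein1")
            i2 = cols.index("protein2")
            isc = cols.index("combined_score")
        except ValueError:
            raise ValueError(
                f"format error in {path}: line 1 must name columns "
                "protein1, protein2, combined_score"
            ) from None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.replace("\t", " ").split()
            if len(parts) <= max(i1, i2, isc):
                raise ValueError(f"format error in {path}: line {lineno} too short")
            a, b = parts[i1], parts[i2]
            try:
                conf = int(parts[isc]) / 1000.0
            except ValueError:
                raise ValueError(
                    f"format error in {path}: line {lineno}: "
                    f"combined_score {parts[isc]!r} is not an integer"
                ) from None
            if a == b:
                self_loops += 1
                continue
            if g.has_edge(a, b):
                conf = max(conf, g.edges[a, b]["confidence"])
            g.add_edge(a, b, confidence=conf)
    if self_loops:
        logger.info("read_string_edges: dropped %d self-loops", self_loops)
    logger.info("read_string_edges: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


def filter_by_confidence(g: nx.Graph, min_score: float = 0.850) -> nx.Graph:
    """Keep only edges with confidence >= min_score; drop isolated nodes.

    The cut is strict on the low side: an edge exactly at ``min_score``
    survives, one at min_score - 1/1000 does not.
    """
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score must lie in [0, 1]")
    out = nx.Graph()
    for u, v, data in g.edges(data=True):
        if data["confidence"] >= min_score:
            out.add_edge(u, v, **data)
    logger.info(
        "filter_by_confidence(%.3f): edges %d -> %d, nodes %d -> %d",
        min_score, g.number_of_edges(), out.number_of_edges(),
        g.number_of_nodes(), out.number_of_nodes(),
    )
    return out


def restrict_to_measured(g: nx.Graph, measured) -> nx.Graph:
    """Induced subgraph on the genes present in the expression data."""
    measured = set(measured)
    keep = set(g.nodes) & measured
    if not keep:
        raise ValueError("no overlap between network and expression data")
    out = g.subgraph(keep).copy()
    logger.info(
        "restrict_to_measured: nodes %d -> %d, edges %d -> %d",
        g.number_of_nodes(), out.number_of_nodes(),
        g.number_of_edges(), out.number_of_edges(),
    )
    return out


def _lex_smallest_shortest_path(g: nx.Graph, source, target) -> list | None:
    """Lexicographically smallest shortest path, by greedy forward walk
    over nodes certified to lie on some shortest path."""
    try:
        dist_from = nx.single_source_shortest_path_length(g, source)
    except nx.NodeNotFound:
        return None
    if target not in dist_from:
        return None
    dist_to = nx.single_source_shortest_path_length(g, target)
    total = dist_from[target]
    path = [source]
    node = source
    for step in range(1, total + 1):
        nxt = min(
            nb for nb in g.neighbors(node)
            if dist_from.get(nb) == step and dist_to.get(nb) == total - step
        )
        path.append(nxt)
        node = nxt
    return path


def interaction_order(g: nx.Graph, source, targets) -> InteractorReport:
    """Classify targets by shortest-path distance from ``source``.

    Order 1 means a direct interactor, order 2 a second-order interactor,
    and so on; the confidence attribute is ignored (the filtered network is
    unweighted topology).  Each reachable target gets one witness shortest
    path, the lexicographically smallest for determinism.
    """
    if source not in g:
        raise ValueError(f"source gene {source!r} not in graph")
    dist = nx.single_source_shortest_path_length(g, source)
    orders: dict = {}
    paths: dict = {}
    for t in targets:
        if t in dist and t != source:
            orders[t] = dist[t]
            paths[t] = _lex_smallest_shortest_path(g, source, t)
        elif t == source:
            orders[t] = 0
            paths[t] = [source]
        else:
            orders[t] = None
    return InteractorReport(source=source, orders=orders, paths=paths)


def write_edge_tsv(g: nx.Graph, path) -> None:
    """Write a confidence graph back out in the STRING-links dialect."""
    from .synthio import write_string_fixture

    write_string_fixture(g, path)
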