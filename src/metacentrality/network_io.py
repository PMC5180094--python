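"""Readers and writers for weighted networks and ranking files.

Edge lists are delimiter-configurable text with columns
``node_a, node_b, weight``; GraphML goes through networkx with a numeric
edge attribute (default ``weight``). Rankings are TSV with columns
``node, score, position`` (1-based, tie-averaged). All readers apply the
:class:`~metacentrality.network.WeightedNetwork` validation contract:
duplicate undirected edges are an error, disconnected inputs are reduced to
their largest component with a logged warning.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx

from .network import NetworkValidationError, WeightedNetwork
from .ranking import Ranking

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "read_ranking",
    "write_ranking",
]


def read_edge_list(
    path: str | Path,
    delimiter: str = "\t",
    has_header: bool = False,
) -> WeightedNetwork:
    """Read a ``node_a, node_b, weight`` edge list into a validated network."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, row in enumerate(reader, start=1):
            if has_header and lineno == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise NetworkValidationError(
                    f"{path}:{lineno}: expected 3 columns (node_a, node_b, weight), "
                    f"got {len(row)}"
                )
            u, v, raw_w = row[0].strip(), row[1].strip(), row[2].strip()
            try:
                w = float(raw_w)
            except ValueError:
                raise NetworkValidationError(
                    f"{path}:{lineno}: non-numeric weight {raw_w!r}"
                ) from None
            edges.append((u, v, w))
    if not edges:
        raise NetworkValidationError(f"{path}: no edges found")
    return WeightedNetwork(edges)


def write_edge_list(
    network: WeightedNetwork,
    path: str | Path,
    delimiter: str = "\t",
    header: bool = True,
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        if header:
            writer.writerow(["node_a", "node_b", "weight"])
        for u, v, w in network.edges():
            writer.writerow([u, v, repr(w)])


def read_graphml(path: str | Path, weight_attr: str = "weight") -> WeightedNetwork:
    """Read a GraphML file whose edges carry a numeric *weight_attr*."""
    g = nx.read_graphml(Path(path))
    if g.is_directed():
        raise NetworkValidationError(f"{path}: directed input is unsupported")
    edges = []
    for u, v, data in g.edges(data=True):
        if weight_attr not in data:
            raise NetworkValidationError(
                f"{path}: edge ({u!r}, {v!r}) is missing the {weight_attr!r} attribute"
            )
        edges.append((str(u), str(v), float(data[weight_attr])))
    return WeightedNetwork(edges)


def write_graphml(network: WeightedNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, Path(path))


_RANKING_HEADER = ["node", "score", "position"]


def write_ranking(ranking: Ranking, path: str | Path) -> None:
    """Write ``node<TAB>score<TAB>position`` rows in ranking order."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_RANKING_HEADER)
        for node in ranking.order:
            writer.writerow([node, repr(ranking.scores[node]), repr(ranking.positions[node])])


def read_ranking(path: str | Path, source: str = "") -> Ranking:
    """Inverse of :func:`write_ranking`; duplicate nodes are an error."""
    path = Path(path)
    order: list[str] = []
    scores: dict[str, float] = {}
    positions: dict[str, float] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [c.strip() for c in header] != _RANKING_HEADER:
            raise ValueError(f"{path}: expected header {_RANKING_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            node = row[0]
            if node in scores:
                raise ValueError(f"{path}:{lineno}: duplicate node {node!r}")
            order.append(node)
            scores[node] = float(row[1])
            positions[node] = float(row[2])
    return Ranking(order=order, scores=scores, positions=positions, source=source)
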