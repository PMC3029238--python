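"""Phospho-PPI graph construction and filtering.

A phospho-PPI is an undirected simple graph of proteins whose nodes carry a
boolean phosphoprotein label (present in the unified phosphosite catalog or
not) plus a category tag naming the assay class the edges came from (ALL,
Y2H, IMM or TAP). Nodes exist only through edges, so degree zero cannot
occur. Degree counts distinct interaction partners: a self-edge contributes
one partner (the protein itself), not two stubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .identifiers_io import CovariateTable, InteractionRecord

CATEGORIES = ("ALL", "Y2H", "IMM", "TAP")


@dataclass
class PhosphoPPI:
    """Undirected simple graph with per-node phospho labels."""

    graph: nx.Graph
    category: str = "ALL"
    filtered: bool = False

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self):
        return self.graph.nodes

    def is_phospho(self, node: str) -> bool:
        return bool(self.graph.nodes[node]["phospho"])

    @property
    def phospho_nodes(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data="phospho") if d]

    @property
    def nonphospho_nodes(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data="phospho") if not d]

    def group_nodes(self, group: str) -> list[str]:
        if group == "phospho":
            return self.phospho_nodes
        if group == "nonphospho":
            return self.nonphospho_nodes
        raise ValueError(f"unknown group {group!r}")

    def degree(self, node: str) -> int:
        """Number of distinct interaction partners (self counted once)."""
        return len(self.graph.adj[node])

    def degrees(self, nodes: Iterable[str] | None = None) -> dict[str, int]:
        it = self.graph.nodes if nodes is None else nodes
        return {v: len(self.graph.adj[v]) for v in it}

    @property
    def self_edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v in self.graph.edges if u == v]

    def summary(self) -> dict:
        n_p = len(self.phospho_nodes)
        return {
            "category": self.category,
            "filtered": self.filtered,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_phospho": n_p,
            "phospho_percent": phospho_percentage(n_p, self.n_nodes),
        }

    def copy(self) -> "PhosphoPPI":
        return PhosphoPPI(self.graph.copy(), self.category, self.filtered)


def phospho_percentage(n_phospho: int, n_nodes: int) -> float:
    """Phosphoprotein share of network nodes, as percent to one decimal."""
    if n_nodes <= 0:
        raise ValueError("n_nodes must be positive")
    return round(100.0 * n_phospho / n_nodes, 1)


def build(
    records: Iterable[InteractionRecord],
    phospho,
    category: str = "ALL",
) -> PhosphoPPI:
    """Build the phospho-PPI of one assay category.

    ``phospho`` is anything supporting ``in`` on accessions (a
    UnifiedPhosphoSet, set, or dict). Records whose method tags do not
    intersect the category are dropped (ALL keeps everything, including
    records with no tags); duplicate pairs merge into one edge.
    """
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}, got {category!r}")
    graph = nx.Graph()
    for rec in records:
        if category != "ALL" and category not in rec.methods:
            continue
        a, b = rec.pair
        graph.add_edge(a, b)
    if graph.number_of_edges() == 0:
        raise ValueError(f"no interactions remain for category {category!r}")
    for v in graph.nodes:
        graph.nodes[v]["phospho"] = v in phospho
    return PhosphoPPI(graph, category=category, filtered=False)


def filter_homologs(net: PhosphoPPI, pairs: CovariateTable | Iterable) -> PhosphoPPI:
    """Drop edges between homologous proteins (and all self-edges).

    The homolog pair set is closed under symmetry here; a self-edge is
    trivially an edge between two "similar" proteins and is always removed.
    Nodes isolated by the removal are dropped.
    """
    pair_set = pairs.pairs if isinstance(pairs, CovariateTable) else set(pairs)
    homolog = {(a, b) if a <= b else (b, a) for a, b in pair_set}
    graph = net.graph.copy()
    to_drop = [
        (u, v)
        for u, v in graph.edges
        if u == v or ((u, v) if u <= v else (v, u)) in homolog
    ]
    graph.remove_edges_from(to_drop)
    graph.remove_nodes_from([v for v in list(graph.nodes) if graph.degree(v) == 0])
    return PhosphoPPI(graph, category=net.category, filtered=True)


def restrict_to_covariate(net: PhosphoPPI, table: CovariateTable) -> PhosphoPPI:
    """Keep only nodes covered by a scalar covariate table.

    Uncovered nodes and their incident edges are deleted; nodes newly
    isolated by those deletions are then dropped as well.
    """
    if table.kind not in ("abundance", "disorder", "length"):
        raise ValueError(f"restriction requires a scalar covariate, got {table.kind!r}")
    graph = net.graph.copy()
    graph.remove_nodes_from([v for v in list(graph.nodes) if v not in table.entries])
    graph.remove_nodes_from([v for v in list(graph.nodes) if graph.degree(v) == 0])
    if graph.number_of_nodes() == 0:
        raise ValueError("covariate restriction emptied the network")
    return PhosphoPPI(graph, category=net.category, filtered=net.filtered)


def export_network(net: PhosphoPPI, edge_path: str | Path, node_path: str | Path) -> None:
    """Edge TSV plus node-attribute TSV (accession, phospho)."""
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("accession\tphospho\n")
        for v in sorted(net.graph.nodes):
            fh.write(f"{v}\t{int(net.is_phospho(v))}\n")


def import_network(
    edge_path: str | Path, node_path: str | Path, category: str = "ALL"
) -> PhosphoPPI:
    from .identifiers_io import _iter_tsv

    graph = nx.Graph()
    for _, parts in _iter_tsv(edge_path):
        if parts[0].lower() == "protein_a":
            continue
        graph.add_edge(parts[0], parts[1])
    for _, parts in _iter_tsv(node_path):
        if parts[0].lower() == "accession":
            continue
        if parts[0] in graph:
            graph.nodes[parts[0]]["phospho"] = bool(int(parts[1]))
    for v in graph.nodes:
        graph.nodes[v].setdefault("phospho", False)
    return PhosphoPPI(graph, category=category)
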