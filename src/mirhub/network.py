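"""Bipartite miRNA-target network, Venn partition and hub selection.

Nodes are differentially expressed miRNAs (annotated up/down) and their
retained target mRNAs; an edge is one retained miRNA-target interaction.
Target *hubs* are mRNAs contacted by at least ``hub_min_degree`` miRNAs
(default 4). Two degree definitions are supported because the literature
uses both: TOTAL counts interactions with any differential miRNA, UP_ONLY
counts only interactions with upregulated miRNAs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx
import pandas as pd

from .ingest import Direction, MirnaExpression
from .scoring import ScoredInteraction, ScoringConfig

__all__ = [
    "BipartiteNetwork",
    "VennCounts",
    "HubMode",
    "build_network",
    "excluded_mirnas",
    "venn_partition",
    "select_hubs",
    "export_graphml",
    "import_graphml",
    "export_edge_list",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeData:
    compound_score: float
    dbs_present: frozenset[str]


@dataclass
class BipartiteNetwork:
    """miRNA and mRNA node sets plus evidence-annotated edges.

    Every miRNA node has degree >= 1: differential miRNAs without any
    retained interaction never enter the network (they are reported by
    :func:`excluded_mirnas`).
    """

    mirna_nodes: dict[str, Direction] = field(default_factory=dict)
    gene_nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], EdgeData] = field(default_factory=dict)
    dropped_edges: int = 0  # edges whose miRNA was not differentially expressed

    def gene_degree(self, gene: str, direction: Direction | None = None) -> int:
        return sum(
            1
            for (m, g) in self.edges
            if g == gene
            and (direction is None or self.mirna_nodes[m] is direction)
        )

    def gene_neighbors(self, gene: str) -> set[str]:
        return {m for (m, g) in self.edges if g == gene}

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class VennCounts:
    """Partition of target genes by the direction of their regulators."""

    up_only: int
    down_only: int
    both: int

    @property
    def union_total(self) -> int:
        return self.up_only + self.down_only + self.both

    @property
    def up_total(self) -> int:
        return self.up_only + self.both

    @property
    def down_total(self) -> int:
        return self.down_only + self.both

    @property
    def naive_sum(self) -> int:
        """up_total + down_total; double-counts shared genes."""
        return self.up_total + self.down_total


class HubMode(str, Enum):
    TOTAL = "total"
    UP_ONLY = "up_only"


def build_network(
    scored: list[ScoredInteraction], expressions: list[MirnaExpression]
) -> BipartiteNetwork:
    """Assemble the network from retained interactions of differential miRNAs.

    Non-retained interactions are ignored. A retained edge whose miRNA is
    absent from the expression table is dropped with a logged count (it is
    not differentially expressed). Genes appear iff they keep >= 1 edge.
    """
    directions = {e.mirna_id: e.direction for e in expressions}
    net = BipartiteNetwork()
    for s in sorted(scored, key=lambda s: (s.mirna_id, s.gene_id)):
        if not s.retained:
            continue
        if s.mirna_id not in directions:
            net.dropped_edges += 1
            continue
        net.mirna_nodes[s.mirna_id] = directions[s.mirna_id]
        net.gene_nodes.add(s.gene_id)
        net.edges[(s.mirna_id, s.gene_id)] = EdgeData(
            s.compound_score,
            frozenset(db.value for db in s.evidence.dbs_present),
        )
    if net.dropped_edges:
        logger.warning(
            "%d retained interactions dropped: miRNA not differentially expressed",
            net.dropped_edges,
        )
    if not net.edges:
        logger.warning("network is empty: no retained interactions")
    return net


def excluded_mirnas(
    expressions: list[MirnaExpression], network: BipartiteNetwork
) -> tuple[list[str], list[str]]:
    """Differential miRNAs absent from the network, split by direction.

    These are the miRNAs with no interaction surviving the evidence rules
    (no support from two predicted databases nor from the validated one).
    """
    up = sorted(
        e.mirna_id
        for e in expressions
        if e.direction is Direction.UP and e.mirna_id not in network.mirna_nodes
    )
    down = sorted(
        e.mirna_id
        for e in expressions
        if e.direction is Direction.DOWN and e.mirna_id not in network.mirna_nodes
    )
    return up, down


def venn_partition(network: BipartiteNetwork) -> VennCounts:
    """Classify every target gene as up-only / down-only / both."""
    up_only = down_only = both = 0
    for gene in network.gene_nodes:
        dirs = {network.mirna_nodes[m] for m in network.gene_neighbors(gene)}
        if dirs == {Direction.UP}:
            up_only += 1
        elif dirs == {Direction.DOWN}:
            down_only += 1
        else:
            both += 1
    return VennCounts(up_only, down_only, both)


def select_hubs(
    network: BipartiteNetwork,
    config: ScoringConfig | None = None,
    mode: HubMode | str = HubMode.TOTAL,
) -> pd.DataFrame:
    """Degree table of all genes with hubs flagged.

    Columns: gene_id, degree_total, degree_up, degree_down, is_hub. A gene
    is a hub when the mode's degree (total, or upregulated-miRNA only)
    reaches ``config.hub_min_degree``. Rows are sorted by the mode's degree
    descending, ties broken by gene_id ascending.
    """
    config = config or ScoringConfig()
    mode = HubMode(mode)
    rows = []
    for gene in sorted(network.gene_nodes):
        d_up = network.gene_degree(gene, Direction.UP)
        d_down = network.gene_degree(gene, Direction.DOWN)
        total = d_up + d_down
        key = total if mode is HubMode.TOTAL else d_up
        rows.append(
            {
                "gene_id": gene,
                "degree_total": total,
                "degree_up": d_up,
                "degree_down": d_down,
                "is_hub": key >= config.hub_min_degree,
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "degree_total", "degree_up", "degree_down", "is_hub"]
    )
    sort_col = "degree_total" if mode is HubMode.TOTAL else "degree_up"
    return df.sort_values(
        [sort_col, "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def _to_networkx(network: BipartiteNetwork) -> nx.Graph:
    g = nx.Graph()
    for mirna in sorted(network.mirna_nodes):
        g.add_node(mirna, type="mirna", direction=network.mirna_nodes[mirna].value)
    for gene in sorted(network.gene_nodes):
        g.add_node(gene, type="gene")
    for (m, gene) in sorted(network.edges):
        data = network.edges[(m, gene)]
        g.add_edge(
            m,
            gene,
            compound_score=data.compound_score,
            dbs_present=";".join(sorted(data.dbs_present)),
        )
    return g


def export_graphml(network: BipartiteNetwork, path: str | Path) -> None:
    """Write the network as GraphML with type/direction/evidence attributes."""
    nx.write_graphml(_to_networkx(network), str(path))


def import_graphml(path: str | Path) -> BipartiteNetwork:
    """Read a network written by :func:`export_graphml` (round-trip inverse)."""
    g = nx.read_graphml(str(path))
    net = BipartiteNetwork()
    for node, attrs in g.nodes(data=True):
        if attrs.get("type") == "mirna":
            net.mirna_nodes[node] = Direction(attrs["direction"])
        else:
            net.gene_nodes.add(node)
    for u, v, attrs in g.edges(data=True):
        m, gene = (u, v) if u in net.mirna_nodes else (v, u)
        net.edges[(m, gene)] = EdgeData(
            float(attrs["compound_score"]),
            frozenset(attrs["dbs_present"].split(";")) if attrs.get("dbs_present") else frozenset(),
        )
    return net


def export_edge_list(network: BipartiteNetwork, path: str | Path) -> None:
    """Deterministic TSV edge list (byte-identical across reruns)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["mirna_id", "direction", "gene_id", "compound_score", "dbs_present"])
        for (m, gene) in sorted(network.edges):
            data = network.edges[(m, gene)]
            writer.writerow(
                [
                    m,
                    network.mirna_nodes[m].value,
                    gene,
                    f"{data.compound_score:g}",
                    ";".join(sorted(data.dbs_present)),
                ]
            )
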