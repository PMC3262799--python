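"""Assembly of the bipartite miRNA->gene regulatory network.

Input edges are replicated, cell-type-specific repression pairs.  Before a
gene's regulators are counted towards the multi-miRNA degree filter, seed-
site redundancy is collapsed: two regulators of the same gene are considered
*seed-similar* when every predicted site of each one overlaps a site of the
other (non-empty half-open intersection on the same coordinate system), in
which case the group is collapsed to a single representative (the lexically
smallest miRNA id) and the collapse is reported.  Partial overlap keeps both
regulators — the gene then has independent evidence from each.

The degree filter (default: genes targeted by more than one distinct miRNA)
is applied after collapse.  miRNA nodes carry their specific cell types and
lineage; genes are ranked as hubs by in-degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .io import CellTypeScheme, TargetPredictionTable
from .specificity import SpecificityCall

__all__ = [
    "RegulatoryNetwork",
    "build_network",
    "collapse_seed_overlaps",
    "rank_hubs",
    "export_network",
    "read_sif",
]

Interval = tuple[str, int, int]


def _intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def _covers(sites_a: list[Interval], sites_b: list[Interval]) -> bool:
    """True when every site in A overlaps at least one site in B."""
    return all(any(_intervals_overlap(sa, sb) for sb in sites_b) for sa in sites_a)


def collapse_seed_overlaps(
    gene: str, regulators: list[tuple[str, list[Interval]]]
) -> tuple[list[str], list[list[str]]]:
    """Collapse seed-similar regulators of one gene.

    Two regulators are seed-similar when each one's every site overlaps a
    site of the other; similarity groups (connected components) collapse to
    their lexically smallest member.  Returns the kept regulator ids and the
    list of collapsed groups (each sorted, only groups of size > 1).
    """
    names = [m for m, _ in regulators]
    sim = nx.Graph()
    sim.add_nodes_from(names)
    for i in range(len(regulators)):
        mi, si = regulators[i]
        for j in range(i + 1, len(regulators)):
            mj, sj = regulators[j]
            if si and sj and _covers(si, sj) and _covers(sj, si):
                sim.add_edge(mi, mj)
    kept: list[str] = []
    groups: list[list[str]] = []
    for comp in nx.connected_components(sim):
        members = sorted(comp)
        kept.append(members[0])
        if len(members) > 1:
            groups.append(members)
    kept.sort()
    groups.sort()
    return kept, groups


@dataclass
class RegulatoryNetwork:
    """Bipartite miRNA->gene graph with collapse and degree annotations."""

    graph: nx.DiGraph
    min_degree: int
    collapse_report: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def mirnas(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "mirna"
        )

    @property
    def genes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene"
        )

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges())


def build_network(
    replicated: list[tuple[str, str, float]],
    specificity_calls: list[SpecificityCall],
    predictions: TargetPredictionTable,
    min_degree: int = 2,
    scheme: CellTypeScheme | None = None,
) -> RegulatoryNetwork:
    """Assemble the regulatory network from replicated (mirna, gene, r) pairs.

    Pairs whose miRNA carries no cell-type specificity call are dropped.  Per
    gene, seed-similar regulators are collapsed, then genes with fewer than
    ``min_degree`` distinct regulators are removed.  An empty network is a
    valid outcome.
    """
    if scheme is None:
        scheme = CellTypeScheme.immune_default()
    call_by_mirna: dict[str, SpecificityCall] = {}
    for c in specificity_calls:
        if c.platform == "mirna":
            call_by_mirna.setdefault(c.transcript, c)

    by_gene: dict[str, dict[str, float]] = {}
    for mirna, gene, r in replicated:
        if mirna in call_by_mirna:
            by_gene.setdefault(gene, {})[mirna] = float(r)

    graph = nx.DiGraph()
    collapse_report: list[tuple[str, list[str]]] = []
    for gene in sorted(by_gene):
        regs = sorted(by_gene[gene])
        sites = [(m, predictions.sites_for(m, gene)) for m in regs]
        kept, groups = collapse_seed_overlaps(gene, sites)
        for grp in groups:
            collapse_report.append((gene, grp))
        if len(kept) < min_degree:
            continue
        graph.add_node(gene, kind="gene")
        for m in kept:
            if m not in graph:
                call = call_by_mirna[m]
                lineages = sorted(
                    {
                        scheme.lineage_map[ct]
                        for ct in call.specific_cell_types
                        if ct in scheme.lineage_map
                    }
                )
                graph.add_node(
                    m,
                    kind="mirna",
                    specific_cell_types=";".join(call.specific_cell_types),
                    lineage=";".join(lineages),
                )
            graph.add_edge(m, gene, r=by_gene[gene][m])
    return RegulatoryNetwork(graph=graph, min_degree=min_degree, collapse_report=collapse_report)


def rank_hubs(network: RegulatoryNetwork) -> list[tuple[str, int]]:
    """Gene nodes ranked by number of distinct regulators, ties lexical."""
    degs = [(g, network.graph.in_degree(g)) for g in network.genes]
    degs.sort(key=lambda t: (-t[1], t[0]))
    return degs


def export_network(network: RegulatoryNetwork, path: str | Path, fmt: str = "sif") -> None:
    """Write the network as SIF (``mirna represses gene``) or GraphML."""
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for m, g in network.edges:
                fh.write(f"{m}\trepresses\t{g}\n")
    elif fmt == "graphml":
        nx.write_graphml(network.graph, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_sif(path: str | Path) -> nx.DiGraph:
    """Read a SIF file written by :func:`export_network` back into a graph."""
    graph = nx.DiGraph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            src, _rel, *targets = parts
            graph.add_node(src, kind="mirna")
            for t in targets:
                graph.add_node(t, kind="gene")
                graph.add_edge(src, t)
    return graph
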