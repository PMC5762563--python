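"""Functional-interaction dissection of one co-expression module.

The module's genes are projected onto a user-supplied undirected
interaction edge list.  Optional *linker* genes — non-module genes adjacent
to at least two module genes — are admitted to increase connectivity.  The
resulting subnetwork is split into sub-modules by greedy modularity
maximization, hub genes are nodes with at least ``min_degree`` neighbors,
and the connected fraction reports how many module genes touch the network
at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms import community

from .io import EdgeList, ValidationError
from .modules import GeneModule

MODULE_GENE = "module_gene"
LINKER_GENE = "linker_gene"
RESIDUAL_LABEL = "unconnected"


@dataclass
class FINetwork:
    graph: nx.Graph  # node attribute "role" in {module_gene, linker_gene}
    module_genes: list[str]
    provenance: str = ""

    def roles(self) -> dict[str, str]:
        return dict(self.graph.nodes(data="role"))


@dataclass
class SubModulePartition:
    labels: dict[str, str]  # node -> "M1".."Mk" or the residual label
    modularity: float
    residual: list[str] = field(default_factory=list)

    def members(self, label: str) -> list[str]:
        return sorted(n for n, l in self.labels.items() if l == label)

    def sub_module_labels(self) -> list[str]:
        return sorted(
            {l for l in self.labels.values() if l != RESIDUAL_LABEL},
            key=lambda s: int(s[1:]),
        )


def build_fi_subnetwork(
    module: GeneModule | list[str],
    edges: EdgeList,
    use_linkers: bool = True,
    min_linker_neighbors: int = 2,
) -> FINetwork:
    """Induced interaction subgraph on the module, optionally with linkers.

    Module genes absent from the edge list stay as isolated nodes (they count
    as unconnected).  A linker is admitted when adjacent to at least
    ``min_linker_neighbors`` module genes; only its edges to module genes are
    kept, so linkers can only add connectivity between module genes.
    """
    genes = list(module.gene_ids) if isinstance(module, GeneModule) else list(module)
    if not genes:
        raise ValidationError("empty module")
    gene_set = set(genes)
    g = nx.Graph()
    g.add_nodes_from(sorted(gene_set), role=MODULE_GENE)
    neighbor_count: dict[str, set[str]] = {}
    for a, b in edges.edges:
        if a in gene_set and b in gene_set:
            g.add_edge(a, b)
        elif use_linkers and a in gene_set:
            neighbor_count.setdefault(b, set()).add(a)
        elif use_linkers and b in gene_set:
            neighbor_count.setdefault(a, set()).add(b)
    if use_linkers:
        for linker, adj in sorted(neighbor_count.items()):
            if len(adj) >= min_linker_neighbors:
                g.add_node(linker, role=LINKER_GENE)
                for target in sorted(adj):
                    g.add_edge(linker, target)
    return FINetwork(graph=g, module_genes=genes, provenance=edges.source)


def connected_fraction(network: FINetwork) -> float:
    """Fraction of module genes with at least one interaction edge."""
    genes = network.module_genes
    connected = sum(1 for g in genes if network.graph.degree(g) > 0)
    return connected / len(genes)


def cluster_network(network: FINetwork, seed: int = 0) -> SubModulePartition:
    """Greedy-modularity sub-modules M1..Mk plus a residual group.

    Each connected component with at least one edge is clustered separately
    (greedy modularity maximization, deterministic given the sorted node
    order); isolated nodes form the residual group — the counterpart of the
    paper-style "module of genes not connected to the network".  Sub-modules
    are numbered by decreasing size, ties by smallest member node.
    """
    g = network.graph
    communities: list[set[str]] = []
    residual: list[str] = []
    for comp_nodes in nx.connected_components(g):
        sub = g.subgraph(comp_nodes)
        if sub.number_of_edges() == 0:
            residual.extend(comp_nodes)
            continue
        # rebuild with sorted nodes/edges so greedy tie-breaks are reproducible
        canon = nx.Graph()
        canon.add_nodes_from(sorted(sub.nodes()))
        canon.add_edges_from(sorted(tuple(sorted(e)) for e in sub.edges()))
        if canon.number_of_nodes() <= 2:
            communities.append(set(canon.nodes()))
            continue
        communities.extend(
            set(c) for c in community.greedy_modularity_communities(canon)
        )
    communities.sort(key=lambda c: (-len(c), min(c)))
    labels: dict[str, str] = {}
    for i, comm in enumerate(communities, start=1):
        for node in comm:
            labels[node] = f"M{i}"
    for node in residual:
        labels[node] = RESIDUAL_LABEL
    clustered = [c for c in communities]
    if clustered and g.number_of_edges() > 0:
        mod = community.modularity(g, clustered + [{n} for n in residual])
    else:
        mod = 0.0
    return SubModulePartition(labels=labels, modularity=float(mod),
                              residual=sorted(residual))


def hub_genes(network: FINetwork, min_degree: int = 10) -> list[tuple[str, int, str]]:
    """Nodes with >= min_degree neighbors, as (gene, degree, role), sorted by
    decreasing degree then name; role retained so hub counts can be split into
    module vs linker hubs."""
    hubs = [
        (node, deg, network.graph.nodes[node]["role"])
        for node, deg in network.graph.degree()
        if deg >= min_degree
    ]
    hubs.sort(key=lambda t: (-t[1], t[0]))
    return hubs


def partition_sizes(partition: SubModulePartition) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for label in partition.labels.values():
        sizes[label] = sizes.get(label, 0) + 1
    return sizes
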