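"""Bipartite miRNA–target networks and convergent hub genes.

Validated miRNA→gene interactions (reporter assay, Western blot, qPCR
grade evidence) form a bipartite graph; genes targeted by many
age-associated miRNAs are points of regulatory convergence. Hub
identification applies a gene-degree threshold (degrees measured on the
unfiltered network), keeps the miRNA neighbors of retained genes, and
prunes nodes left isolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .harmonize import harmonize

__all__ = ["BipartiteNetwork", "build_bipartite", "degree_filter", "hub_genes"]

logger = logging.getLogger(__name__)

#: Evidence categories accepted as strong experimental support.
STRONG_EVIDENCE = {"reporter assay", "western blot", "qpcr"}


@dataclass
class BipartiteNetwork:
    """A miRNA–gene interaction graph with class bookkeeping.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes carry a
    ``kind`` attribute (``"mirna"`` or ``"gene"``); miRNA node names are
    harmonized base ids.
    """

    graph: nx.Graph

    @property
    def mirna_nodes(self) -> set[str]:
        return {n for n, k in self.graph.nodes(data="kind") if k == "mirna"}

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, k in self.graph.nodes(data="kind") if k == "gene"}

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as (mirna base id, gene symbol) pairs."""
        kinds = dict(self.graph.nodes(data="kind"))
        return {
            (u, v) if kinds[u] == "mirna" else (v, u) for u, v in self.graph.edges
        }

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def gene_degrees(self) -> dict[str, int]:
        return {g: self.graph.degree[g] for g in self.gene_nodes}


def build_bipartite(
    edge_list, evidence_filter: set[str] | None = None
) -> BipartiteNetwork:
    """Build the network from (raw miRNA id, gene symbol[, evidence]) rows.

    miRNA ids are harmonized; duplicate edges collapse under set
    semantics; malformed rows (missing id or symbol) are skipped with a
    counted warning. When rows carry an evidence column and
    ``evidence_filter`` is given (e.g. :data:`STRONG_EVIDENCE`), edges
    whose evidence is not in the set are dropped.
    """
    if isinstance(edge_list, pd.DataFrame):
        edge_list = edge_list.itertuples(index=False)
    g = nx.Graph()
    n_skipped = 0
    for row in edge_list:
        row = tuple(row)
        mirna_raw, gene = row[0], row[1]
        evidence = str(row[2]).strip().lower() if len(row) > 2 else None
        if (
            not isinstance(gene, str)
            or not gene.strip()
            or mirna_raw is None
            or not str(mirna_raw).strip()
        ):
            n_skipped += 1
            continue
        if evidence_filter is not None and evidence is not None:
            if evidence not in evidence_filter:
                continue
        try:
            mirna = harmonize(str(mirna_raw))
        except ValueError:
            n_skipped += 1
            continue
        g.add_node(mirna, kind="mirna")
        g.add_node(gene.strip(), kind="gene")
        g.add_edge(mirna, gene.strip())
    if n_skipped:
        logger.warning("skipped %d malformed interaction rows", n_skipped)
    return BipartiteNetwork(g)


def degree_filter(
    net: BipartiteNetwork,
    min_gene_degree: int = 5,
    keep_neighbors: bool = True,
    prune_isolated: bool = True,
) -> BipartiteNetwork:
    """Retain hub genes by degree, their miRNA neighbors, and prune isolates.

    Genes with degree >= ``min_gene_degree`` (degree in the *input*
    network) are retained. With ``keep_neighbors``, every miRNA incident
    to a retained gene is kept along with all its edges to retained
    genes — preserving the local structure around each hub. Nodes with no
    remaining edges are removed when ``prune_isolated``. The operation is
    idempotent at a fixed threshold.
    """
    if min_gene_degree < 1:
        raise ValueError("min_gene_degree must be >= 1")
    kept_genes = {g for g, d in net.gene_degrees().items() if d >= min_gene_degree}
    sub = nx.Graph()
    for gene in kept_genes:
        sub.add_node(gene, kind="gene")
    if keep_neighbors:
        for gene in kept_genes:
            for mirna in net.graph.neighbors(gene):
                sub.add_node(mirna, kind="mirna")
                sub.add_edge(mirna, gene)
    if prune_isolated:
        sub.remove_nodes_from(list(nx.isolates(sub)))
    return BipartiteNetwork(sub)


def hub_genes(net: BipartiteNetwork) -> pd.DataFrame:
    """Genes ranked by degree, descending, ties broken lexicographically."""
    degs = net.gene_degrees()
    out = pd.DataFrame(
        sorted(degs.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "degree"],
    )
    return out
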