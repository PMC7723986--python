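"""Assembly and export of the bipartite lncRNA-gene regulatory network.

Nodes are differentially expressed lncRNAs and genes, each annotated with
its regulation direction (up/down in LP); edges run lncRNA -> gene with an
evidence mode (cis or trans) and a weight (Pearson r for trans edges,
negative genomic distance for cis edges).  A cis and a trans edge between
the same pair are kept as two distinct edges.  Exports are loadable by
Cytoscape: SIF plus node/edge attribute tables, an edge TSV that round-trips,
and GraphML.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .targets import CisTarget, TransTarget

__all__ = ["build_network", "export_network", "read_edge_tsv"]

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["lncrna_id", "gene_id", "mode", "weight",
                "lnc_direction", "gene_direction"]


def build_network(
    cis: list[CisTarget],
    trans: list[TransTarget],
    de_lnc: dict[str, str],
    de_genes: dict[str, str],
    gene_whitelist: set[str] | None = None,
) -> nx.MultiDiGraph:
    """Assemble the regulatory network.

    ``de_lnc`` / ``de_genes`` map feature id -> direction ("up"/"down");
    they define which endpoints are admissible and carry the node
    attributes.  With a ``gene_whitelist`` (e.g. lactation genes) edges are
    restricted to whitelisted genes; whitelist entries absent from the DE
    genes are skipped with a warning.  Node and edge insertion order is
    deterministic.
    """
    g = nx.MultiDiGraph()
    if gene_whitelist is not None:
        missing = sorted(set(gene_whitelist) - set(de_genes))
        if missing:
            logger.warning("whitelist genes absent from DE genes, skipped: %s",
                           ", ".join(missing))
        allowed = set(gene_whitelist) & set(de_genes)
    else:
        allowed = set(de_genes)

    def admissible(lnc: str, gene: str) -> bool:
        return lnc in de_lnc and gene in allowed and lnc != gene

    edges: list[tuple[str, str, str, float]] = []
    for c in cis:
        if admissible(c.lncrna_id, c.gene_id):
            edges.append((c.lncrna_id, c.gene_id, "cis", float(-abs(c.distance))))
    for t in trans:
        if admissible(t.lncrna_id, t.gene_id):
            edges.append((t.lncrna_id, t.gene_id, "trans", float(t.r)))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))

    for lnc, gene, mode, weight in edges:
        if lnc not in g:
            g.add_node(lnc, kind="lncRNA", direction=de_lnc[lnc])
        if gene not in g:
            g.add_node(gene, kind="gene", direction=de_genes[gene])
        g.add_edge(lnc, gene, mode=mode, weight=weight)
    return g


def export_network(network: nx.MultiDiGraph, out_prefix, fmt: str) -> list[str]:
    """Write the network as ``sif``, ``edge_tsv`` or ``graphml``.

    SIF exports also write a node attribute table (kind, direction).
    Returns the list of files written; output is byte-deterministic.
    """
    out_prefix = str(out_prefix)
    edges = sorted(
        network.edges(data=True),
        key=lambda e: (e[0], e[1], e[2]["mode"]),
    )
    nodes = sorted(network.nodes(data=True))
    if fmt == "sif":
        sif_path = out_prefix + ".sif"
        with open(sif_path, "w") as fh:
            for u, v, d in edges:
                fh.write(f"{u}\t{d['mode']}\t{v}\n")
        attr_path = out_prefix + ".node_attrs.tsv"
        with open(attr_path, "w") as fh:
            fh.write("node_id\tkind\tdirection\n")
            for n, d in nodes:
                fh.write(f"{n}\t{d['kind']}\t{d['direction']}\n")
        return [sif_path, attr_path]
    if fmt == "edge_tsv":
        path = out_prefix + ".edges.tsv"
        rows = [
            {
                "lncrna_id": u,
                "gene_id": v,
                "mode": d["mode"],
                "weight": d["weight"],
                "lnc_direction": network.nodes[u]["direction"],
                "gene_direction": network.nodes[v]["direction"],
            }
            for u, v, d in edges
        ]
        pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
        return [path]
    if fmt == "graphml":
        path = out_prefix + ".graphml"
        nx.write_graphml(network, path)
        return [path]
    raise ValueError(f"unknown network format {fmt!r}")


def read_edge_tsv(path) -> nx.MultiDiGraph:
    """Reconstruct a network from an ``edge_tsv`` export (round-trip)."""
    df = pd.read_csv(path, sep="\t")
    g = nx.MultiDiGraph()
    for row in df.itertuples(index=False):
        if row.lncrna_id not in g:
            g.add_node(row.lncrna_id, kind="lncRNA", direction=row.lnc_direction)
        if row.gene_id not in g:
            g.add_node(row.gene_id, kind="gene", direction=row.gene_direction)
        g.add_edge(row.lncrna_id, row.gene_id, mode=row.mode,
                   weight=float(row.weight))
    return g
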