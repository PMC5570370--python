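"""Inverse-correlation target integration and interaction-network expansion.

Because miRNAs are repressors, a predicted miRNA->mRNA edge is credible only
when the mRNA moves opposite to the miRNA under HSF-1 regulation: a miRNA
normally upregulated by HSF-1 should have downregulated targets, and vice
versa.  Integration keeps exactly those predicted edges whose target gene is
significantly regulated with the opposite sign.

The kept target genes are then embedded in a literature-interaction graph:
unaffected genes are pulled in when they are shared neighbors of at least
two affected genes, and "linker" genes/edges connecting the upregulated and
downregulated clusters are reported.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

_UP_CLASSES = {"hs_dep_up", "hs_indep_up"}
_DOWN_CLASSES = {"hs_dep_down", "hs_indep_down"}


def _call_direction(cls: str) -> int:
    if cls in _UP_CLASSES:
        return 1
    if cls in _DOWN_CLASSES:
        return -1
    return 0


def integrate(
    calls: pd.DataFrame,
    predictions: pd.DataFrame,
    regulation: pd.DataFrame,
    contrast: str,
) -> pd.DataFrame:
    """Keep predicted miRNA->gene edges passing the inverse-correlation rule.

    Parameters
    ----------
    calls
        Classification table indexed by miRNA with a ``class`` column (as
        produced by :func:`stressmir.classify.call_classes`), or any frame
        with ``mirna``/``class`` columns.
    predictions
        Target predictions with ``mirna``, ``gene`` columns (unique pairs).
    regulation
        Gene regulation with ``gene``, ``contrast``, ``log2fc``,
        ``significant`` columns; ``log2fc`` signs are on the HSF-1
        regulation scale (positive = induced by HSF-1).
    contrast
        Which contrast label in ``regulation`` to filter on.

    Returns
    -------
    DataFrame of kept edges: mirna, gene, mirna_class, mirna_direction,
    gene_log2fc, grouped into the four class networks via ``mirna_class``.
    """
    if contrast not in set(regulation["contrast"]):
        raise ValueError(f"contrast {contrast!r} absent from regulation table")
    if "mirna" in calls.columns:
        classes = calls.set_index("mirna")["class"]
    else:
        classes = calls["class"]
    reg = regulation[regulation["contrast"] == contrast].set_index("gene")

    rows = []
    for row in predictions.itertuples(index=False):
        direction = _call_direction(classes.get(row.mirna, "unclassified"))
        if direction == 0:
            continue
        if row.gene not in reg.index:
            continue
        g = reg.loc[row.gene]
        if not bool(g["significant"]):
            continue
        lfc = float(g["log2fc"])
        if lfc == 0 or (lfc > 0) == (direction > 0):
            continue  # same sign (or flat): not inversely correlated
        rows.append(
            (
                row.mirna,
                row.gene,
                classes[row.mirna],
                direction,
                lfc,
            )
        )
    kept = pd.DataFrame(
        rows, columns=["mirna", "gene", "mirna_class", "mirna_direction", "gene_log2fc"]
    )
    # hard invariant: every kept edge is sign-opposed
    assert (
        (kept["mirna_direction"] * kept["gene_log2fc"]) < 0
    ).all(), "inverse-sign rule violated"
    return kept


def expand_network(
    affected: dict[str, str] | pd.Series,
    interactions: pd.DataFrame,
    min_shared: int = 2,
) -> nx.Graph:
    """Interaction subgraph of affected genes plus well-connected neighbors.

    ``affected`` maps gene -> "up"/"down" (HSF-1 regulation direction of the
    mRNA).  Unaffected genes enter only when adjacent to at least
    ``min_shared`` affected genes; edges are restricted to the node set.
    Node attribute ``label`` is "up", "down" or "unaffected".
    """
    if isinstance(affected, pd.Series):
        affected = affected.to_dict()
    full = nx.Graph()
    full.add_nodes_from(affected)
    for row in interactions.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        if a != b:
            full.add_edge(a, b)
    keep = set(affected)
    for node in full.nodes:
        if node in affected:
            continue
        shared = sum(1 for nb in full.neighbors(node) if nb in affected)
        if shared >= min_shared:
            keep.add(node)
    g = full.subgraph(keep).copy()
    g.add_nodes_from(affected)  # affected genes stay even if isolated
    nx.set_node_attributes(
        g, {n: affected.get(n, "unaffected") for n in g.nodes}, "label"
    )
    return g


def find_linkers(network: nx.Graph) -> dict:
    """Genes and edges bridging the up- and down-regulated clusters.

    A linker edge directly joins an up- and a down-labeled node; a linker
    node is adjacent to at least one node of each cluster (an up->X->down
    path of length two).  Returns ``{"nodes": set, "edges": list}`` where
    edges include both direct up-down edges and the incident edges of
    linker nodes into either cluster.
    """
    labels = nx.get_node_attributes(network, "label")
    linker_edges = []
    linker_nodes = set()
    for u, v in network.edges:
        if {labels.get(u), labels.get(v)} == {"up", "down"}:
            linker_edges.append(tuple(sorted((u, v))))
    for node in network.nodes:
        nbr_labels = {labels.get(nb) for nb in network.neighbors(node)}
        if "up" in nbr_labels and "down" in nbr_labels:
            linker_nodes.add(node)
            for nb in network.neighbors(node):
                if labels.get(nb) in ("up", "down"):
                    linker_edges.append(tuple(sorted((node, nb))))
    return {"nodes": linker_nodes, "edges": sorted(set(linker_edges))}


def network_tables(network: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables (TSV-ready) for graph viewers."""
    nodes = pd.DataFrame(
        [(n, d.get("label", "unaffected")) for n, d in network.nodes(data=True)],
        columns=["gene", "label"],
    ).sort_values("gene", ignore_index=True)
    edges = pd.DataFrame(
        sorted(tuple(sorted(e)) for e in network.edges),
        columns=["gene_a", "gene_b"],
    )
    return nodes, edges


def write_sif(network: nx.Graph, path, relation: str = "pp") -> None:
    """SIF-style edge list (gene <relation> gene), one line per edge."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for n in sorted(nx.isolates(network)):
            fh.write(f"{n}\n")
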