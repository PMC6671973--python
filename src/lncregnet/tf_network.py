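"""Transcription-factor association and network construction.

A TF is associated with an lncRNA when the overlap between the lncRNA's
co-expressed coding genes and the TF's target set is larger than chance
under the hypergeometric model (single source of truth:
:func:`lncregnet.enrichment.hypergeom_upper_tail`). BH correction is
applied across all (lncRNA, TF) combinations tested; associations with
q at or below the cutoff become edges. Edge scores are -log10(P), capped.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np
import pandas as pd

from .diffexpr import bh_fdr
from .enrichment import hypergeom_upper_tail
from .io_formats import GeneSetCollection, NetworkGraph

logger = logging.getLogger(__name__)

SCORE_CAP = 300.0

ASSOCIATION_COLUMNS = [
    "lncrna", "tf", "k", "K", "n", "N", "p_value", "q_value", "overlap_members",
]


def _edge_score(p: float) -> float:
    if p <= 0.0:
        return SCORE_CAP
    return float(min(SCORE_CAP, -np.log10(p)))


def associate_tfs(coexpressed: dict[str, list[str]], tf_sets: GeneSetCollection,
                  universe: list[str], q_max: float = 0.05) -> pd.DataFrame:
    """Hypergeometric overlap test for every (lncRNA, TF) combination;
    rows with BH q <= q_max are retained.

    `coexpressed` maps lncRNA id -> its co-expressed gene symbols.
    """
    if tf_sets.kind_tag != "tf_targets":
        raise ValueError("tf_sets must have kind_tag='tf_targets'")
    universe_set = set(universe)
    if not universe_set and coexpressed:
        raise ValueError("empty universe")
    records = []
    for lncrna, genes in coexpressed.items():
        query = set(genes) & universe_set
        n = len(query)
        for s in tf_sets:
            targets = set(s.members) & universe_set
            K = len(targets)
            if K == 0:
                continue
            overlap = sorted(query & targets)
            records.append({
                "lncrna": lncrna,
                "tf": s.name,
                "k": len(overlap), "K": K, "n": n, "N": len(universe_set),
                "p_value": hypergeom_upper_tail(len(overlap), K, n, len(universe_set)),
                "overlap_members": ",".join(overlap),
            })
    if not records:
        return pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    table = pd.DataFrame(records)
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    table = table[table["q_value"] <= q_max].reset_index(drop=True)
    return table[ASSOCIATION_COLUMNS]


def build_lncrna_tf_network(associations: pd.DataFrame) -> NetworkGraph:
    """Bipartite lncRNA-TF graph; edge score = -log10(association P)."""
    nodes: dict[str, str] = {}
    edges = []
    for rec in associations.itertuples(index=False):
        nodes.setdefault(rec.lncrna, "lncRNA")
        nodes.setdefault(rec.tf, "TF")
        edges.append((rec.lncrna, rec.tf, "tf_association", _edge_score(rec.p_value)))
    return NetworkGraph(nodes=list(nodes.items()), edges=edges)


def build_lncrna_tf_gene_network(associations: pd.DataFrame,
                                 tf_sets: GeneSetCollection,
                                 coexpressed: dict[str, list[str]]) -> NetworkGraph:
    """Tripartite lncRNA-TF-gene graph.

    lncRNA-TF edges come from the association table; a TF-gene edge is added
    for each target gene that is also co-expressed with the associated
    lncRNA (genes regulated by lncRNA and TF simultaneously).
    """
    nodes: dict[str, str] = {}
    edges: dict[tuple[str, str, str], float] = {}
    for rec in associations.itertuples(index=False):
        nodes.setdefault(rec.lncrna, "lncRNA")
        nodes.setdefault(rec.tf, "TF")
        edges.setdefault((rec.lncrna, rec.tf, "tf_association"),
                         _edge_score(rec.p_value))
        targets = set(tf_sets.members_of(rec.tf))
        shared = targets & set(coexpressed.get(rec.lncrna, []))
        for gene in sorted(shared):
            if gene in nodes and nodes[gene] != "gene":
                continue  # identity collision with an lncRNA/TF node id
            nodes.setdefault(gene, "gene")
            edges.setdefault((rec.tf, gene, "targets"), _edge_score(rec.p_value))
    edge_list = [(s, t, rel, score) for (s, t, rel), score in edges.items()]
    return NetworkGraph(nodes=list(nodes.items()), edges=edge_list)


def network_summary(graph: NetworkGraph) -> dict:
    """Node counts by type, edge count, connected components and degree
    distribution."""
    g = graph.to_networkx()
    import networkx as nx
    type_counts = Counter(t for _, t in graph.nodes)
    degrees = sorted(d for _, d in g.degree())
    return {
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "nodes_by_type": dict(type_counts),
        "n_components": nx.number_connected_components(g) if graph.n_nodes else 0,
        "degree_distribution": dict(Counter(degrees)),
    }
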