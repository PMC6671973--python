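"""Hypergeometric over-representation analysis and lncRNA functional
prediction via co-expressed mRNAs."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import coexpressed_genes
from .io_formats import ExpressionMatrix, GeneSetCollection, ProbeAnnotation
from .diffexpr import bh_fdr

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "set_name", "k", "K", "n", "N", "p_value", "q_value", "overlap_members",
]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n):
    sum_{j=k}^{min(K,n)} C(K,j) C(N-K, n-j) / C(N,n).
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric arguments k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query: list[str], sets: GeneSetCollection, universe: list[str],
           ) -> pd.DataFrame:
    """One-sided over-representation of `query` in each gene set.

    The query is intersected with the universe; sets with no member in the
    universe are dropped before BH correction. Results are sorted by
    ascending P (stable in original set order).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query) & universe_set
    N = len(universe_set)
    n = len(query_set)
    records = []
    for s in sets:
        members = set(s.members) & universe_set
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(query_set & members)
        k = len(overlap)
        records.append({
            "set_name": s.name,
            "k": k, "K": K, "n": n, "N": N,
            "p_value": hypergeom_upper_tail(k, K, n, N),
            "overlap_members": ",".join(overlap),
        })
    if not records:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    out = pd.DataFrame(records)
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out[ENRICHMENT_COLUMNS]


def predict_lncrna_function(lncrna_probe: str, matrix: ExpressionMatrix,
                            annotation: ProbeAnnotation, sets: GeneSetCollection,
                            corr_p_max: float = 0.05) -> pd.DataFrame:
    """Enrichment of one lncRNA's co-expressed mRNA genes (any-sign Pearson
    correlation, P < corr_p_max) against functional gene sets.

    The universe is all mRNA gene symbols present in the matrix.
    """
    in_matrix = set(matrix.probe_ids)
    universe: dict[str, None] = {}
    for p in annotation.probes_of_type("mRNA"):
        if p in in_matrix:
            universe.setdefault(annotation.symbol_of(p), None)
    genes = coexpressed_genes(lncrna_probe, matrix, annotation, p_max=corr_p_max)
    if not genes:
        logger.info("lncRNA %s has no co-expressed mRNAs at P < %g",
                    lncrna_probe, corr_p_max)
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return enrich(genes, sets, list(universe))
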