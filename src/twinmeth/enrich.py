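"""Hypergeometric over-representation analysis of gene lists against GMT sets.

This is a transparent stand-in for GUI/service-based network enrichment:
for each gene set, the one-sided hypergeometric tail probability of the
observed overlap is computed against an explicit gene universe and
Benjamini-Hochberg adjusted across sets.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datamodel import GeneSetCollection, ProbeAnnotation
from .errors import AnalysisError

logger = logging.getLogger(__name__)


def map_probes_to_genes(
    probes: Sequence[str], ann: ProbeAnnotation
) -> list[str]:
    """Sorted, deduplicated union of gene names over the given probes.

    Probes without gene annotation are dropped (count logged).
    """
    genes: set[str] = set()
    n_unmapped = 0
    for probe in probes:
        g = ann.genes_for(probe)
        if g:
            genes.update(g)
        else:
            n_unmapped += 1
    if n_unmapped:
        logger.info("map_probes_to_genes: %d probe(s) without gene annotation", n_unmapped)
    return sorted(genes)


def hypergeometric_enrichment(
    query: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided hypergeometric tail P per gene set, BH-adjusted across sets.

    Query genes outside the universe are dropped (logged); each set is
    intersected with the universe. P = P(X >= k) for X ~
    Hypergeom(N=|universe|, K=|set & universe|, n=|query & universe|).
    Rows are sorted by ascending P (ties by set name).
    """
    uni = set(universe)
    if not uni:
        raise AnalysisError("empty gene universe")
    q = set(query) & uni
    n_dropped = len(set(query)) - len(q)
    if n_dropped:
        logger.info(
            "hypergeometric_enrichment: dropped %d query gene(s) outside universe",
            n_dropped,
        )
    if not q:
        raise AnalysisError("query is empty after intersection with universe")

    N, n = len(uni), len(q)
    rows = []
    for name, members in sets.sets.items():
        in_universe = set(members) & uni
        overlap = sorted(q & in_universe)
        K, k = len(in_universe), len(overlap)
        # upper tail P(X >= k); sf(k-1) == P(X > k-1)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap_count": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p_value": min(p, 1.0),
                "overlapping_genes": ";".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "set_name",
                "overlap_count",
                "set_size",
                "query_size",
                "universe_size",
                "p_value",
                "fdr",
                "overlapping_genes",
            ]
        )
    result = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(result["p_value"], method="fdr_bh")
    result["fdr"] = fdr
    result = result.sort_values(
        by=["p_value", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
    return result[
        [
            "set_name",
            "overlap_count",
            "set_size",
            "query_size",
            "universe_size",
            "p_value",
            "fdr",
            "overlapping_genes",
        ]
    ]
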