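"""Over-representation analysis of gene lists against GMT collections.

One-sided hypergeometric test: for a query of n genes drawn from a
universe of N, a term covering K universe genes, and k hits, the p-value
is P[X >= k] for X ~ Hypergeometric(N, K, n), computed with the survival
function. Benjamini-Hochberg adjusts across retained terms. Pathway (KEGG)
and GO collections are just two GMT files; no live database access.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data import ImmLncError, SignatureSet

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "term_id", "term_name", "k", "n", "K", "N",
    "gene_ratio", "p_value", "p_adjusted", "hit_genes",
]


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    genesets: SignatureSet,
    min_term: int = 3,
    max_term: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the universe are dropped with a warning; term
    genes are intersected with the universe and terms outside
    [min_term, max_term] universe genes are skipped. Results are sorted by
    p ascending, ties broken by term_id.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ImmLncError("empty universe")
    query_list = list(dict.fromkeys(query))
    outside = [g for g in query_list if g not in universe_set]
    if outside:
        logger.warning(
            "dropping %d query gene(s) outside the universe (e.g. %s)",
            len(outside), outside[:5],
        )
    query_set = {g for g in query_list if g in universe_set}
    if not query_set:
        raise ImmLncError("empty query after universe filtering")
    if len(genesets) == 0:
        raise ImmLncError("empty gene-set collection")

    big_n = len(universe_set)
    n = len(query_set)
    rows = []
    for term, genes in genesets.sets.items():
        term_genes = set(genes) & universe_set
        big_k = len(term_genes)
        if big_k < min_term or big_k > max_term:
            continue
        hits = sorted(term_genes & query_set)
        k = len(hits)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "term_id": term,
                "term_name": genesets.descriptions.get(term, term),
                "k": k,
                "n": n,
                "K": big_k,
                "N": big_n,
                "gene_ratio": k / n,
                "p_value": min(p, 1.0),
                "hit_genes": hits,
            }
        )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    return out[RESULT_COLUMNS]


def dotplot_table(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format term x condition table for dot-plot style summaries.

    One row per (term, condition) over the union of terms; conditions in
    which a term was not tested get NA gene_ratio / p_adjusted.
    """
    if not results:
        raise ImmLncError("no result sets given")
    all_terms: list[str] = []
    for cond, tab in results.items():
        for t in tab["term_id"]:
            if t not in all_terms:
                all_terms.append(t)
    rows = []
    for term in all_terms:
        for cond, tab in results.items():
            hit = tab[tab["term_id"] == term]
            if hit.empty:
                rows.append(
                    {"term_id": term, "condition": cond,
                     "gene_ratio": np.nan, "p_adjusted": np.nan}
                )
            else:
                r = hit.iloc[0]
                rows.append(
                    {"term_id": term, "condition": cond,
                     "gene_ratio": r["gene_ratio"], "p_adjusted": r["p_adjusted"]}
                )
    return pd.DataFrame(rows)
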