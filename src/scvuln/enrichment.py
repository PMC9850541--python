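"""Hypergeometric over-representation of a query gene list against GMT sets.

Upper-tail hypergeometric p per term with BH correction across the
collection; fold enrichment is (k/n)/(K/N).  The background defaults to
every gene surviving preprocessing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core_io import GeneSetCollection, ValidationError
from .diffexp import adjust_pvalues

__all__ = ["hypergeom_enrich"]


def hypergeom_enrich(query, collection: GeneSetCollection, background
                     ) -> pd.DataFrame:
    """Over-representation table for ``query`` against every term.

    Gene symbols are matched case-insensitively.  ``query`` is intersected
    with the background; an empty intersection is an error.  Returns one row
    per term with k, K, n, N, fold_enrichment, p and BH-adjusted p, sorted
    by fold enrichment (descending).
    """
    bg = []
    seen: set[str] = set()
    for g in background:
        gu = str(g).upper()
        if gu not in seen:
            seen.add(gu)
            bg.append(gu)
    bg_set = set(bg)
    n_bg = len(bg_set)
    if n_bg == 0:
        raise ValidationError("empty background")
    query_set = {str(g).upper() for g in query} & bg_set
    if not query_set:
        raise ValidationError("query has no gene in the background")
    n_query = len(query_set)

    rows = []
    for term in collection:
        term_genes = {g.upper() for g in term.genes} & bg_set
        big_k = len(term_genes)
        k = len(term_genes & query_set)
        if big_k > 0:
            p = float(hypergeom.sf(k - 1, n_bg, big_k, n_query))
            fold = (k / n_query) / (big_k / n_bg)
        else:
            p, fold = 1.0, np.nan
        rows.append({"term": term.name, "description": term.description,
                     "k": k, "K": big_k, "n": n_query, "N": n_bg,
                     "fold_enrichment": fold, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_pvalues(table["p"], method="bh")
    return (table.sort_values("fold_enrichment", ascending=False,
                              kind="stable", na_position="last")
            .reset_index(drop=True))
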