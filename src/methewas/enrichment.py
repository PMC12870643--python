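"""Gene-set over-representation testing for EWAS-derived gene lists.

One-sided hypergeometric test per gene set against an explicit
background universe, with Bonferroni correction over the number of sets
tested. The background is always supplied by the caller (typically all
genes in the probe annotation) — no implicit genome-wide constant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import map_sites_to_genes


class EnrichmentError(ValueError):
    pass


def enrich(
    query_genes,
    gene_sets: dict[str, list[str]],
    background_genes,
) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    Sets are intersected with the background before testing. The p-value
    is the upper hypergeometric tail P(overlap >= observed); adjusted p
    is ``min(1, p * n_sets_tested)``. Rows are sorted by adjusted p,
    then set name.
    """
    background = sorted(set(background_genes))
    if not background:
        raise EnrichmentError("empty background gene universe")
    bg = set(background)
    query = sorted(set(query_genes))
    outside = [g for g in query if g not in bg]
    if outside:
        raise EnrichmentError(f"query genes absent from background: {outside[:5]}")
    N = len(bg)
    q = set(query)
    n_q = len(q)
    n_sets = len(gene_sets)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & bg
        K = len(members)
        overlap = sorted(q & members)
        k = len(overlap)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n_q))
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": K,
                "query_size": n_q,
                "background_size": N,
                "p": p,
                "p_bonferroni": min(1.0, p * n_sets),
                "overlap_genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["p_bonferroni", "gene_set"], kind="mergesort").reset_index(drop=True)
    return out


def relaxed_gene_set(
    results,
    annotation,
    threshold: float = 5e-05,
    use_adjusted: bool = False,
) -> list[str]:
    """Genes mapped from probes below a relaxed p threshold.

    Complements the strict array-wide gene list by admitting
    sub-threshold association signal for pathway analysis.
    """
    tab = results.table if hasattr(results, "table") else results
    col = "p_bacon" if use_adjusted else "p"
    hits = tab.index[tab[col] < threshold].tolist()
    if not hits:
        warnings.warn(f"no probes below p < {threshold}", stacklevel=2)
        return []
    return map_sites_to_genes(hits, annotation)
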