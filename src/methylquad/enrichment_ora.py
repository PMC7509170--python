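"""Over-representation analysis of gene lists against supplied gene sets.

For a gene list of size n drawn from a universe of N genes, a term with K
members in the universe and k in the list gets the hypergeometric
upper-tail probability of observing at least k overlaps. Raw p-values are
filtered at a strict threshold by default (Benjamini-Hochberg optional).
"""
from __future__ import annotations

from typing import Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection


def ora_test(
    gene_list: Sequence[str],
    gene_sets: GeneSetCollection,
    universe: Sequence[str],
    p_thr: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Hypergeometric over-representation test per gene set.

    Terms are intersected with the universe before testing; the gene
    list must be a subset of the universe. Results are sorted by
    ascending p and filtered at ``p < p_thr`` (on the BH-adjusted p when
    ``correction="BH"``).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    if not genes <= universe_set:
        raise ValueError("gene list must be a subset of the universe")
    N = len(universe_set)
    n = len(genes)
    rows = []
    for term, (desc, members) in gene_sets.items():
        members_in = set(members) & universe_set
        K = len(members_in)
        if K == 0:
            continue
        overlap = sorted(genes & members_in)
        k = len(overlap)
        # upper tail: P(X >= k) for X ~ Hypergeom(N, K, n); k=0 gives 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 5e-324), 1.0)
        rows.append(
            {
                "term_id": term,
                "description": desc,
                "gene_count": k,
                "list_size": n,
                "term_size": K,
                "universe_size": N,
                "percent": 100.0 * k / n,
                "p_value": p,
                "genes": ";".join(overlap),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id", "description", "gene_count", "list_size", "term_size",
            "universe_size", "percent", "p_value", "genes",
        ],
    )
    if out.empty:
        return out
    if correction == "BH":
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
        filter_col = "p_adjusted"
    elif correction == "none":
        filter_col = "p_value"
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out = out.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    return out[out[filter_col] < p_thr].reset_index(drop=True)
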