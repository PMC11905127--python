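"""Over-representation of trait gene lists within trajectory gene sets.

One-sided hypergeometric upper-tail test per set: drawing |query| genes from
the background, the p-value is P(X >= k) where k is the observed overlap and
the set members are the successes. Recall is intersection size over term
(set) size, the x-axis quantity of the original enrichment scatter plots.
Adjustment across sets is Bonferroni by default (BH optional).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection


def hypergeom_upper_tail(k: int, background: int, term: int, query: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(background, term successes, query draws)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, background, term, query))


def enrich_sets(
    query: list[str] | set[str],
    sets: GeneSetCollection,
    background: set[str],
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query and sets are intersected with the background first (the background
    should be the genes actually tested for trajectories). Returns one row
    per set: set_name, intersection_size, term_size, query_size,
    background_size, recall, pvalue, adjusted_p, sorted by (adjusted_p,
    -recall) so the top row is the best hit with ties broken by recall.
    """
    background = {g.upper() for g in background}
    if not background:
        raise ValueError("empty background")
    query_set = {str(g).upper() for g in query} & background
    if not query_set:
        raise ValueError(
            "query is disjoint from the background; likely a gene-identifier "
            "namespace mismatch"
        )
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown adjustment method {method!r}")

    rows = []
    for name in sets.names():
        term = sets[name] & background
        k = len(query_set & term)
        p = hypergeom_upper_tail(k, len(background), len(term), len(query_set))
        rows.append(
            {
                "set_name": name,
                "intersection_size": k,
                "term_size": len(term),
                "query_size": len(query_set),
                "background_size": len(background),
                "recall": k / len(term) if term else 0.0,
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        sm_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
        out["adjusted_p"] = multipletests(out["pvalue"], method=sm_method)[1]
        out = out.sort_values(
            ["adjusted_p", "recall"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    return out
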