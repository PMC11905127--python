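"""Molecular-identity signatures: anchor-gene correlation and module scores.

The anchor ranking orders all detected genes by their correlation with an
anchor gene (Gnrh1 in the original study) on log2(CPM + 1) expression across
every sample of both fractions; significance comes from the t transform of
Pearson's r with BH adjustment. The module score is the mean expression of a
gene set minus the mean of expression-matched control genes sampled per
abundance bin — the ModuleScore / score_genes contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .normalize import cpm, normalization_factors


def log_expression(m: CountMatrix) -> pd.DataFrame:
    """log2(CPM + 1) as a samples x genes DataFrame."""
    vals = cpm(m, normalization_factors(m), log2=True, prior=1.0)
    return pd.DataFrame(vals.T, index=m.samples["sample_id"], columns=m.genes)


def rank_by_anchor_correlation(
    m: CountMatrix,
    anchor: str = "GNRH1",
    top_n: int = 50,
    method: str = "pearson",
) -> pd.DataFrame:
    """Rank every detected gene by its correlation with the anchor gene.

    Works on log2(CPM + 1) across all samples of both fractions. Returns a
    DataFrame (gene, r, pvalue, fdr, rank) sorted by descending r, with the
    anchor itself excluded; ``df.attrs["signature"]`` holds the ``top_n``
    gene symbols. ``method`` is "pearson" or "spearman".
    """
    return correlation_ranking(log_expression(m), anchor, top_n=top_n, method=method)


def correlation_ranking(
    expr: pd.DataFrame,
    anchor: str,
    top_n: int = 50,
    method: str = "pearson",
) -> pd.DataFrame:
    """Anchor-correlation ranking on an explicit samples x genes matrix.

    Pearson r per gene against the anchor column; p from the t transform
    t = r * sqrt((n - 2) / (1 - r^2)), two-sided; BH across genes. Spearman
    rank-transforms every column first and reuses the same t machinery.
    """
    anchor = anchor.upper()
    expr = expr.rename(columns=lambda c: str(c).upper())
    if anchor not in expr.columns:
        raise ValueError(f"anchor gene {anchor!r} not in matrix")
    n = expr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    x = expr[anchor].to_numpy()
    if np.allclose(x, x[0]):
        raise ValueError("anchor gene is constant across samples; r undefined")

    mat = expr.to_numpy()
    if method == "spearman":
        x = stats.rankdata(x)
        mat = np.apply_along_axis(stats.rankdata, 0, mat)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    xc = x - x.mean()
    mc = mat - mat.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (mc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (mc * xc[:, None]).sum(axis=0) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    pvals = 2 * stats.t.sf(np.abs(t), df=n - 2)

    out = pd.DataFrame({"gene": expr.columns, "r": r, "pvalue": pvals})
    out = out[out["gene"] != anchor].copy()
    out["fdr"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    out = out.sort_values("r", ascending=False, kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["signature"] = list(out["gene"].head(top_n))
    return out


def module_score(
    expr: pd.DataFrame,
    gene_set: set[str],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-sample module score for a gene set against bin-matched controls.

    ``expr`` is a normalized samples x genes DataFrame. Genes are ranked by
    average expression and split into ``n_bins`` equal-count bins; for each
    set gene, up to ``n_ctrl`` control genes are sampled without replacement
    from the non-set genes of its bin (expanding to neighbouring bins when a
    bin holds no controls; if no controls exist at all the control mean is
    taken as 0). Score = mean(set genes) - mean(sampled controls), per sample.
    """
    gene_set = {g.upper() for g in gene_set}
    if not gene_set:
        raise ValueError("empty gene set")
    cols = {c.upper() for c in expr.columns}
    missing = gene_set - cols
    if missing:
        raise ValueError(f"gene set members absent from matrix: {sorted(missing)[:5]}")
    expr = expr.rename(columns=str.upper)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = list(expr.columns)
    avg = expr.mean(axis=0).to_numpy()
    order = np.argsort(np.argsort(avg, kind="stable"), kind="stable")  # 0-based ranks
    bin_of = (order * n_bins) // len(genes)

    in_set = np.array([g in gene_set for g in genes])
    bin_pools: dict[int, list[int]] = {}
    for i, b in enumerate(bin_of):
        if not in_set[i]:
            bin_pools.setdefault(int(b), []).append(i)

    control_idx: list[int] = []
    for i in np.flatnonzero(in_set):
        b = int(bin_of[i])
        pool: list[int] = []
        for offset in range(n_bins + 1):
            lo, hi = b - offset, b + offset
            pool = list(bin_pools.get(lo, [])) + (
                list(bin_pools.get(hi, [])) if hi != lo else []
            )
            if pool:
                break
        if not pool:
            continue  # no controls anywhere: contributes nothing
        take = min(n_ctrl, len(pool))
        control_idx.extend(rng.choice(pool, size=take, replace=False).tolist())

    set_mean = expr.loc[:, [g for g in genes if g in gene_set]].mean(axis=1)
    if control_idx:
        ctrl_mean = expr.iloc[:, control_idx].mean(axis=1)
    else:
        ctrl_mean = pd.Series(0.0, index=expr.index)
    score = set_mean - ctrl_mean
    score.name = "module_score"
    return score
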