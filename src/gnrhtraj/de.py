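"""Per-transition negative-binomial differential expression.

The test is an exact-style conditional test: counts are scaled to a common
effective library size, summed within each condition, and the probability of
the observed split of the grand total between the two condition sums is
evaluated under a negative binomial with equal proportions and the gene's
empirical-Bayes-shrunk dispersion. Two-sided p-values double the smaller
conditional tail (capped at 1). Fold changes are log2 ratios of mean CPM
with a prior of 0.5, so they are always finite.

The NB is parameterized by mean mu and dispersion phi with variance
mu + phi * mu^2; the sum of n iid NB(mu, phi) is NB(n * mu, phi / n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .io import TRANSITIONS, TRANSITION_LABELS, CountMatrix
from .normalize import NormalizationFactors, cpm, expression_filter, normalization_factors

DISPERSION_FLOOR = 1e-4


@dataclass
class DispersionEstimate:
    """Raw method-of-moments, trended, and EB-shrunk per-gene dispersions."""

    raw: np.ndarray
    trend: np.ndarray
    shrunk: np.ndarray
    residual_df: float


def _transition_stages(transition: str | tuple[str, str]) -> tuple[str, str]:
    if isinstance(transition, tuple):
        if tuple(transition) not in TRANSITIONS:
            raise ValueError(f"unknown transition {transition!r}")
        return transition
    try:
        idx = TRANSITION_LABELS.index(transition)
    except ValueError:
        raise ValueError(
            f"unknown transition label {transition!r}; expected one of {TRANSITION_LABELS}"
        ) from None
    return TRANSITIONS[idx]


def estimate_dispersion(
    m: CountMatrix,
    groups: np.ndarray | list,
    norm: NormalizationFactors | None = None,
    prior_df: float = 10.0,
    n_bins: int = 20,
) -> DispersionEstimate:
    """Method-of-moments NB dispersion with shrinkage toward a mean trend.

    Counts are scaled to a common library size; within each replicate group
    the moment identity Var = c*mu + phi*mu^2 gives a per-group raw estimate
    which is pooled across groups with residual-df weights. Raw estimates are
    shrunk toward a running-median mean-dispersion trend with weight
    ``prior_df / (prior_df + residual_df)`` on the trend, and floored at 1e-4.
    """
    groups = np.asarray(groups)
    if norm is None:
        norm = normalization_factors(m)
    eff = norm.effective_size
    common = np.exp(np.mean(np.log(eff)))
    scale = common / eff
    z = m.counts * scale[None, :]

    labels = [g for g in pd.unique(groups)]
    sizes = {g: int((groups == g).sum()) for g in labels}
    if all(n < 2 for n in sizes.values()):
        raise ValueError("no group has replication; cannot estimate dispersion")

    n_genes = m.n_genes
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    total_df = 0.0
    for g in labels:
        idx = groups == g
        n_g = sizes[g]
        if n_g < 2:
            continue
        zg = z[:, idx]
        mean_g = zg.mean(axis=1)
        var_g = zg.var(axis=1, ddof=1)
        cbar = float(np.mean(scale[idx]))
        with np.errstate(divide="ignore", invalid="ignore"):
            # denominator m^2 - v/n removes the first-order Jensen bias of E[m^2]
            denom = mean_g**2 - var_g / n_g
            phi_g = (var_g - cbar * mean_g) / denom
        phi_g = np.where((mean_g > 0) & (denom > 0), phi_g, np.nan)
        df_g = n_g - 1
        ok = ~np.isnan(phi_g)
        num[ok] += df_g * phi_g[ok]
        den[ok] += df_g
        total_df += df_g
    with np.errstate(invalid="ignore"):
        raw = np.where(den > 0, num / np.maximum(den, 1), np.nan)

    # running-mean trend over abundance bins (means are ~unbiased; the raw
    # per-gene distribution is right-skewed, so a median trend sits low)
    mean_expr = z.mean(axis=1)
    trend = np.full(n_genes, np.nan)
    ok = ~np.isnan(raw) & (mean_expr > 0)
    if ok.sum() >= 2:
        order = np.argsort(mean_expr[ok])
        idx_ok = np.flatnonzero(ok)[order]
        bins = np.array_split(idx_ok, min(n_bins, max(1, ok.sum() // 10) or 1))
        centers, medians = [], []
        for b in bins:
            if len(b) == 0:
                continue
            centers.append(np.log(mean_expr[b]).mean())
            medians.append(np.mean(raw[b]))
        if len(centers) >= 2:
            trend[ok] = np.interp(np.log(mean_expr[ok]), centers, medians)
        else:
            trend[ok] = medians[0] if medians else np.nan
    global_med = np.nanmedian(raw) if np.isfinite(np.nanmedian(raw)) else 0.0
    trend = np.where(np.isnan(trend), global_med, trend)

    w = prior_df / (prior_df + total_df)
    filled_raw = np.where(np.isnan(raw), trend, raw)
    shrunk = np.maximum(w * trend + (1 - w) * filled_raw, DISPERSION_FLOOR)
    return DispersionEstimate(raw=raw, trend=trend, shrunk=shrunk, residual_df=total_df)


def _exact_nb_pvalue(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Doubled smaller conditional tail of the NB split of ``s1 + s2``."""
    t = s1 + s2
    if t == 0:
        return 1.0
    mu = t / (n1 + n2)
    r1, r2 = n1 / phi, n2 / phi
    m1, m2 = n1 * mu, n2 * mu
    x = np.arange(t + 1)
    logf = stats.nbinom.logpmf(x, r1, r1 / (r1 + m1)) + stats.nbinom.logpmf(
        t - x, r2, r2 / (r2 + m2)
    )
    logz = logsumexp(logf)
    lower = np.exp(logsumexp(logf[: s1 + 1]) - logz)
    upper = np.exp(logsumexp(logf[s1:]) - logz)
    return float(min(1.0, 2.0 * min(lower, upper)))


def de_test(
    m: CountMatrix,
    transition: str | tuple[str, str],
    fraction: str,
    min_cpm: float = 1.0,
    min_samples: int = 2,
    prior_df: float = 10.0,
    dispersion: np.ndarray | None = None,
) -> pd.DataFrame:
    """Differential expression across one ordered stage transition.

    Returns a DataFrame with columns ``gene, transition, log2fc, pvalue,
    fdr, mean_cpm`` for genes surviving the expression filter
    (CPM > ``min_cpm`` in >= ``min_samples`` samples of the fraction;
    all-zero genes always dropped). FDR is Benjamini-Hochberg within the
    transition. ``log2fc`` is positive when the later stage is higher.
    """
    stage_a, stage_b = _transition_stages(transition)
    frac = m.subset_samples(m.fraction_mask(fraction))
    norm = normalization_factors(frac)
    keep = expression_filter(frac, norm, min_cpm=min_cpm, min_samples=min_samples)
    keep &= frac.counts.sum(axis=1) > 0
    genes = [g for g, k in zip(frac.genes, keep) if k]
    counts = frac.counts[keep]

    stage_labels = frac.samples["stage"].astype(str).to_numpy()
    mask_a = stage_labels == stage_a
    mask_b = stage_labels == stage_b
    n1, n2 = int(mask_a.sum()), int(mask_b.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"transition {stage_a}->{stage_b} needs >= 2 replicates per condition "
            f"in fraction {fraction!r} (got {n1} and {n2})"
        )

    if dispersion is None:
        sub = CountMatrix(genes=genes, samples=frac.samples, counts=counts)
        disp = estimate_dispersion(sub, stage_labels, norm, prior_df=prior_df)
        phi = disp.shrunk
    else:
        phi = np.maximum(np.asarray(dispersion)[keep], DISPERSION_FLOOR)

    eff = norm.effective_size
    pair = mask_a | mask_b
    common = np.exp(np.mean(np.log(eff[pair])))
    scale = common / eff
    s1 = np.rint((counts[:, mask_a] * scale[mask_a]).sum(axis=1)).astype(int)
    s2 = np.rint((counts[:, mask_b] * scale[mask_b]).sum(axis=1)).astype(int)

    pvals = np.array(
        [_exact_nb_pvalue(a, b, n1, n2, p) for a, b, p in zip(s1, s2, phi)]
    )

    cpms = cpm(CountMatrix(genes=genes, samples=frac.samples, counts=counts), norm)
    mean_a = cpms[:, mask_a].mean(axis=1)
    mean_b = cpms[:, mask_b].mean(axis=1)
    log2fc = np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    label = (
        transition
        if isinstance(transition, str)
        else TRANSITION_LABELS[TRANSITIONS.index(tuple(transition))]
    )
    return pd.DataFrame(
        {
            "gene": genes,
            "transition": label,
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "mean_cpm": cpms[:, pair].mean(axis=1),
        }
    )


def significant_genes(
    results: pd.DataFrame, fdr_max: float = 0.05, min_fold: float = 2.0
) -> set[str]:
    """Genes with FDR < ``fdr_max`` and |fold change| > ``min_fold``."""
    if len(results) == 0:
        return set()
    mask = (results["fdr"] < fdr_max) & (results["log2fc"].abs() > np.log2(min_fold))
    return set(results.loc[mask, "gene"])
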