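"""Library-size and composition normalization for count matrices.

Composition factors follow the trimmed-mean-of-M-values recipe: per-gene
log-ratios (M) to a reference sample are trimmed (30% of M, 5% of A by
default), averaged with inverse-variance precision weights, and the resulting
per-sample factors are rescaled to geometric mean 1. Effective library size =
column sum x composition factor; CPM are counts per million effective reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountMatrix


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and composition factors (geometric mean 1)."""

    library_size: np.ndarray
    composition: np.ndarray

    @property
    def effective_size(self) -> np.ndarray:
        return self.library_size * self.composition


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference, on the log2 scale."""
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    m = np.log2(p_obs[keep] / p_ref[keep])
    a = 0.5 * np.log2(p_obs[keep] * p_ref[keep])
    # delta-method precision weights for the M-values
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (
        lib_ref * ref[keep]
    )
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    kept = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if kept.sum() == 0:
        return 1.0
    log2f = np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept])
    return float(2.0 ** log2f)


def normalization_factors(
    m: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """Library sizes (column sums) and TMM composition factors.

    The reference sample is the one whose upper-quartile CPM is closest to
    the across-sample mean upper quartile. Requires >= 2 samples and no
    all-zero sample.
    """
    counts = m.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample")
    uq = np.array([np.quantile(counts[:, j][counts[:, j] > 0] / lib[j], 0.75)
                   if (counts[:, j] > 0).any() else 0.0
                   for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_pair(counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
            if j != ref_idx
            else 1.0
            for j in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(library_size=lib, composition=factors)


def cpm(m: CountMatrix, norm: NormalizationFactors | None = None, log2: bool = False,
        prior: float = 0.0) -> np.ndarray:
    """Counts per million effective library reads; optionally log2(CPM + prior)."""
    if norm is None:
        norm = normalization_factors(m)
    vals = m.counts / norm.effective_size[None, :] * 1e6
    if log2:
        return np.log2(vals + prior)
    return vals


def expression_filter(m: CountMatrix, norm: NormalizationFactors | None = None,
                      min_cpm: float = 1.0, min_samples: int = 2) -> np.ndarray:
    """Boolean gene mask: CPM > min_cpm in >= min_samples samples."""
    vals = cpm(m, norm)
    return (vals > min_cpm).sum(axis=1) >= min_samples
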