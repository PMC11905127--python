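"""Trajectory-collapsed rare-variant burden testing.

Candidate protein-truncating variants (PTVs: stop-gain, frameshift,
canonical splice site, or predicted splice-disrupting) and matched
synonymous variants pass a hard QC cascade (population frequency, call
quality, mapping quality, allelic balance, segmental duplications, local
artifact database, pedigree excess, control-database flags, indel length).
Per trajectory gene set, case subjects carrying at least one passing variant
are counted (each distinct subject once); summary-level control allele
counts are assumed to come from distinct individuals, with a ceiling at the
number of controls. A one-sided Fisher exact test (enrichment in cases)
gives the burden p; odds ratios get Woolf (log-scale normal) 95% intervals,
and a z statistic compares the PTV odds ratio with the synonymous one:

    z = (ln OR_ptv - ln OR_syn) / sqrt(SE_ptv^2 + SE_syn^2),
    SE = sqrt(1/a + 1/b + 1/c + 1/d)

with Haldane-Anscombe +0.5 on every cell only when some cell is zero and
only for OR/CI/z (never for the exact test). A trajectory is retained only
if its Bonferroni-corrected Fisher p passes AND the PTV odds ratio
significantly exceeds the synonymous one (one-sided z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection

VARIANT_CLASSES = ("PTV", "synonymous")
PTV_CONSEQUENCES = ("stop_gain", "frameshift", "splice_site", "spliceai_predicted")


@dataclass
class FilterConfig:
    """Hard QC thresholds of the variant filter cascade (defaults = study values)."""

    popmax_max: float = 1e-4          # popmax frequency <= 0.01%
    qual_min: float = 50.0
    mq_min: float = 55.0
    mqrs_min: float = -2.5
    ad_ratio_min: float = 0.20
    exclude_segdup: bool = True
    local_db_max: int = 3             # local healthy-individual database (n=300)
    pedigree_max: int = 5
    exclude_flagged: bool = True
    indel_len_max: int = 3
    spliceai_min: float = 0.5


@dataclass
class ContingencyTable:
    """2x2 carrier table: a/b case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative contingency cell")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class BurdenResult:
    """One trajectory set x variant class burden outcome."""

    set_name: str
    variant_class: str
    table: ContingencyTable
    or_hat: float
    ci_low: float
    ci_high: float
    fisher_p: float
    bonferroni_p: float = np.nan
    z: float = np.nan
    z_p: float = np.nan
    retained: bool = False
    stratum: str = "all"
    log_se: float = field(default=np.nan, repr=False)


def _class_mask(v: pd.DataFrame, variant_class: str, cfg: FilterConfig) -> pd.Series:
    if variant_class == "PTV":
        base = v["consequence"].isin(["stop_gain", "frameshift", "splice_site"])
        splice_pred = (v["consequence"] == "spliceai_predicted") & (
            v["spliceai_score"] >= cfg.spliceai_min
        )
        return base | splice_pred
    if variant_class == "synonymous":
        return v["consequence"] == "synonymous"
    raise ValueError(f"unknown variant class {variant_class!r}")


def filter_variants(
    v: pd.DataFrame, cfg: FilterConfig, variant_class: str
) -> pd.DataFrame:
    """Rows of the requested class passing every QC filter.

    Missing popmax passes (absent from the control database); any other
    missing QC value fails its filter — a variant is never retained on
    unverifiable evidence.
    """
    checks = {
        "popmax": v["popmax_af"].isna() | (v["popmax_af"] <= cfg.popmax_max),
        "qual": v["qual"] >= cfg.qual_min,
        "mq": v["mq"] >= cfg.mq_min,
        "mq_rank_sum": v["mq_rank_sum"] >= cfg.mqrs_min,
        "ad_ratio": v["ad_ratio"] >= cfg.ad_ratio_min,
        "segdup": (v["in_segdup"] == False) if cfg.exclude_segdup else True,  # noqa: E712
        "local_db": v["local_db_count"] <= cfg.local_db_max,
        "pedigree": v["pedigree_count"] <= cfg.pedigree_max,
        "flagged": (v["flagged_control_db"] == False) if cfg.exclude_flagged else True,  # noqa: E712
        "indel_len": v["indel_len"].fillna(0) <= cfg.indel_len_max,
    }
    mask = _class_mask(v, variant_class, cfg)
    for check in checks.values():
        mask = mask & check
    return v[mask.fillna(False)].reset_index(drop=True)


def build_contingency(
    passing: pd.DataFrame, gene_set: set[str], n_cases: int, n_controls: int
) -> ContingencyTable:
    """Carrier counts for one gene set.

    Case carriers = distinct case subject_ids with >= 1 passing variant in a
    set gene. Control carriers = sum of summary allele counts over passing
    set variants, each allele assumed to come from a different individual,
    with a ceiling at ``n_controls``.
    """
    gene_set = {g.upper() for g in gene_set}
    in_set = passing[passing["gene"].isin(gene_set)]
    cases = in_set[in_set["cohort"] == "case"]
    a = int(cases["subject_id"].dropna().nunique())
    if a > n_cases:
        raise ValueError(f"{a} case carriers exceed n_cases={n_cases}")
    ctrl = in_set[in_set["cohort"] == "control"]
    c = int(min(ctrl["allele_count"].sum(), n_controls))
    return ContingencyTable(a=a, b=n_cases - a, c=c, d=n_controls - c)


def one_sided_fisher_p(a, b, c, d):
    """One-sided Fisher exact p (enrichment in cases) on raw counts.

    Conditional on the margins, the case-carrier count follows a
    hypergeometric law; the p-value is its upper tail P(X >= a). Accepts
    scalars or equal-shaped arrays.
    """
    a, b, c, d = (np.asarray(x) for x in (a, b, c, d))
    n1, n2 = a + b, c + d
    m = a + c
    return stats.hypergeom.sf(a - 1, n1 + n2, n1, m)


def _primed(t: ContingencyTable, haldane: bool) -> np.ndarray:
    cells = np.array(t.cells(), dtype=float)
    if haldane and (cells == 0).any():
        cells = cells + 0.5
    return cells


def fisher_or_ci(
    t: ContingencyTable, haldane: bool = True
) -> tuple[float, float, float, float]:
    """Odds ratio, Woolf 95% CI, and one-sided Fisher p (greater in cases).

    The exact test always uses the raw counts; the Haldane-Anscombe +0.5 is
    applied to every cell, only when some cell is zero, and only for the
    OR/CI arithmetic.
    """
    if t.n_cases == 0 or t.n_controls == 0:
        raise ValueError("empty cohort in contingency table")
    fisher_p = float(one_sided_fisher_p(t.a, t.b, t.c, t.d))
    a, b, c, d = _primed(t, haldane)
    or_hat = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(or_hat) - 1.96 * se))
    ci_high = float(np.exp(np.log(or_hat) + 1.96 * se))
    return float(or_hat), ci_low, ci_high, fisher_p


def log_or_se(t: ContingencyTable, haldane: bool = True) -> float:
    """Woolf standard error of ln(OR), with the same zero-cell convention."""
    a, b, c, d = _primed(t, haldane)
    return float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))


def compare_or_z(ptv: BurdenResult, syn: BurdenResult) -> tuple[float, float]:
    """One-sided z comparing the PTV odds ratio against the synonymous one."""
    se_p, se_s = ptv.log_se, syn.log_se
    if not (np.isfinite(se_p) and np.isfinite(se_s)):
        raise ValueError("degenerate standard error in z comparison")
    z = (np.log(ptv.or_hat) - np.log(syn.or_hat)) / np.sqrt(se_p**2 + se_s**2)
    return float(z), float(stats.norm.sf(z))


def _burden_one(
    passing: pd.DataFrame,
    set_name: str,
    genes: set[str],
    variant_class: str,
    n_cases: int,
    n_controls: int,
    stratum: str,
    haldane: bool,
) -> BurdenResult:
    t = build_contingency(passing, genes, n_cases, n_controls)
    or_hat, lo, hi, p = fisher_or_ci(t, haldane)
    return BurdenResult(
        set_name=set_name,
        variant_class=variant_class,
        table=t,
        or_hat=or_hat,
        ci_low=lo,
        ci_high=hi,
        fisher_p=p,
        stratum=stratum,
        log_se=log_or_se(t, haldane),
    )


def run_burden(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    trajectory_sets: GeneSetCollection,
    cfg: FilterConfig | None = None,
    n_cases: int = 425,
    n_controls: int = 54704,
    subphenotypes: dict[str, str] | None = None,
    alpha: float = 0.05,
    haldane: bool = True,
) -> pd.DataFrame:
    """Full trajectory-collapsed burden table.

    For each trajectory set and stratum ("all" plus each subphenotype
    label): filter both cohorts, build PTV and synonymous contingency
    tables, Fisher test with Bonferroni correction over the number of
    trajectory sets in the stratum, and the PTV-vs-synonymous z comparison.
    ``subphenotypes`` maps case subject_id to a label (e.g. KS / nCHH); the
    stratum restricts cases only (controls are shared). A set is retained
    when ``bonferroni_p < alpha`` and ``z_p < alpha``.
    """
    cfg = cfg or FilterConfig()
    variants = pd.concat([cases, controls], ignore_index=True)
    n_sets = len(trajectory_sets)
    if n_sets == 0:
        return pd.DataFrame(
            columns=["set", "class", "stratum", "a", "b", "c", "d", "or", "ci_low",
                     "ci_high", "fisher_p", "bonferroni_p", "z", "z_p", "retained"]
        )

    strata: dict[str, pd.DataFrame] = {"all": variants}
    if subphenotypes:
        labels = sorted(set(subphenotypes.values()))
        for lab in labels:
            keep_subjects = {s for s, v in subphenotypes.items() if v == lab}
            keep = (variants["cohort"] == "control") | variants["subject_id"].isin(
                keep_subjects
            )
            strata[lab] = variants[keep]

    stratum_sizes = {"all": n_cases}
    if subphenotypes:
        for lab in sorted(set(subphenotypes.values())):
            stratum_sizes[lab] = sum(1 for v in subphenotypes.values() if v == lab)

    rows = []
    for stratum, table in strata.items():
        nc = stratum_sizes[stratum]
        passing = {
            vc: filter_variants(table, cfg, vc) for vc in VARIANT_CLASSES
        }
        results: dict[tuple[str, str], BurdenResult] = {}
        for name in trajectory_sets.names():
            for vc in VARIANT_CLASSES:
                results[(name, vc)] = _burden_one(
                    passing[vc], name, trajectory_sets[name], vc,
                    nc, n_controls, stratum, haldane,
                )
        for name in trajectory_sets.names():
            ptv, syn = results[(name, "PTV")], results[(name, "synonymous")]
            z, z_p = compare_or_z(ptv, syn)
            for res in (ptv, syn):
                res.bonferroni_p = float(min(1.0, res.fisher_p * n_sets))
                res.z, res.z_p = z, z_p
            retained = ptv.bonferroni_p < alpha and z_p < alpha
            ptv.retained = retained
            for res in (ptv, syn):
                t = res.table
                rows.append(
                    {
                        "set": name, "class": res.variant_class, "stratum": stratum,
                        "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                        "or": res.or_hat, "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "fisher_p": res.fisher_p, "bonferroni_p": res.bonferroni_p,
                        "z": res.z, "z_p": res.z_p, "retained": res.retained,
                    }
                )
    return pd.DataFrame(rows)
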