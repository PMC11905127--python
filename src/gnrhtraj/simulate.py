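"""Synthetic data with known ground truth, emulating the study design.

The expression generator reproduces the sampling layout of the real
experiment — four (stage, region) spacetime points (E12.5 nose, E14.5 nose,
E14.5 brain, E18.5 brain) x two FACS fractions (GFP+ GnRH neurons, GFP-
environment) x replicates — as negative-binomial counts with log-normal
abundances and library-size factors. A configurable subset of genes is
planted with a trajectory code: across each of the three consecutive
transitions the stage mean is multiplied by ``planted_fold`` to the power of
the code element (+1, 0, -1).

The variant generator emulates the case/control burden design: case carriers
are Bernoulli draws at the rate implied by a planted per-trajectory odds
ratio against a base carrier rate; controls are emitted as summary-level
allele counts only (no subject ids), forcing downstream code to exercise the
distinct-individual assumption and the carrier ceiling. Matched synonymous
variants are generated with OR = 1, and decoy variants each violating
exactly one named QC filter are interleaved.

All randomness derives from one seed through ``numpy`` ``SeedSequence``
stream splitting, so every sub-simulation is independently reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FRACTIONS, STAGES, CountMatrix, GeneSetCollection

#: Canonical trajectory code alphabet; "+00" means up at the first transition only.
CODE_CHARS = {"+": 1, "0": 0, "-": -1}
ALL_CODES = ["".join(c) for c in itertools.product("+0-", repeat=3)]

#: Default planted mix: the six single-step trajectories, 50 genes each.
DEFAULT_TRAJECTORY_MIX = {
    "+00": 50, "-00": 50, "0+0": 50, "0-0": 50, "00+": 50, "00-": 50,
}


def scaled_trajectory_mix(n_genes: int, reference: int = 2000) -> dict[str, int]:
    """The default mix scaled to a smaller/larger gene count (>= 2 per code)."""
    return {
        code: max(2, round(n * n_genes / reference))
        for code, n in DEFAULT_TRAJECTORY_MIX.items()
    }

#: QC filter vocabulary the decoy machinery must cover.
FILTER_NAMES = (
    "popmax", "qual", "mq", "mq_rank_sum", "ad_ratio",
    "segdup", "local_db", "pedigree", "flagged", "indel_len",
)

PTV_CONSEQUENCES = ("stop_gain", "frameshift", "splice_site", "spliceai_predicted")


def code_to_tuple(code: str) -> tuple[int, int, int]:
    if len(code) != 3 or any(c not in CODE_CHARS for c in code):
        raise ValueError(f"invalid trajectory code {code!r}")
    return tuple(CODE_CHARS[c] for c in code)  # type: ignore[return-value]


@dataclass
class SimulationParams:
    """Knobs of the expression generator.

    ``baseline_log_mean``/``baseline_log_sd`` are the natural-log location
    and scale of per-gene expected counts; ``dispersion`` is the NB phi in
    Var = mu + phi mu^2; ``planted_fold`` the per-transition fold step of
    planted genes; ``library_size_cv`` the coefficient of variation of
    log-normal per-sample library factors.
    """

    n_genes: int = 2000
    replicates_per_condition: int = 4
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.1
    planted_fold: float = 2.5
    library_size_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_fold <= 1:
            raise ValueError("planted_fold must be > 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_genes < 1 or self.replicates_per_condition < 1:
            raise ValueError("n_genes and replicates_per_condition must be positive")


@dataclass
class TruthTable:
    """Planted ground truth accompanying each simulated dataset."""

    gene_codes: dict[str, str] = field(default_factory=dict)
    stage_means_pos: pd.DataFrame | None = None   # GFP+ per-stage expected counts
    base_means_neg: pd.Series | None = None       # GFP- baseline expected counts
    lr_pairs: pd.DataFrame | None = None          # ligand, receptor, planted_class
    variant_truth: pd.DataFrame | None = None     # set, class, planted OR, carriers
    set_or: dict[str, float] = field(default_factory=dict)

    def planted_genes(self) -> list[str]:
        return [g for g, c in self.gene_codes.items() if c != "000"]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, phi) with Var = mean + phi*mean^2 via numpy's (n, p) form."""
    mean = np.asarray(mean, dtype=float)
    if phi < 1e-12:
        return rng.poisson(mean)
    n = 1.0 / phi
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _sample_table(replicates: int) -> pd.DataFrame:
    rows = []
    for fraction in FRACTIONS:
        tag = "GFPpos" if fraction == "GFP+" else "GFPneg"
        for stage in STAGES:
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{stage}_{tag}_r{rep}",
                        "stage": stage,
                        "fraction": fraction,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_counts(
    params: SimulationParams,
    trajectory_mix: dict[str, int] | None = None,
) -> tuple[CountMatrix, TruthTable]:
    """Simulate the 4-stage x 2-fraction count matrix with planted trajectories.

    ``trajectory_mix`` maps trajectory codes to gene counts; remaining genes
    are flat ("000"). Planted (non-flat) genes draw their baseline abundance
    from the upper half of the log-normal abundance distribution (see
    docs/methods.md); flat genes span the full distribution. The GFP-
    fraction is flat for every gene until a ligand program is planted via
    :func:`simulate_lr_pairs`.
    """
    if trajectory_mix is None:
        trajectory_mix = DEFAULT_TRAJECTORY_MIX
    for code in trajectory_mix:
        tup = code_to_tuple(code)
        if tup == (0, 0, 0) and trajectory_mix[code] > 0:
            raise ValueError("flat code '000' cannot be planted explicitly")
    n_planted = sum(trajectory_mix.values())
    if n_planted > params.n_genes:
        raise ValueError("trajectory_mix exceeds n_genes")

    ss = np.random.SeedSequence(params.seed)
    rng_means, rng_lib, rng_pos, rng_neg = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    genes = [f"G{i:05d}" for i in range(1, params.n_genes + 1)]
    codes = {}
    i = 0
    for code in sorted(trajectory_mix):
        for _ in range(trajectory_mix[code]):
            codes[genes[i]] = code
            i += 1
    for g in genes[i:]:
        codes[g] = "000"

    # baselines: planted genes from the upper half of the abundance distribution
    planted_mask = np.array([codes[g] != "000" for g in genes])
    z = rng_means.normal(0.0, params.baseline_log_sd, size=params.n_genes)
    z = np.where(planted_mask, np.abs(z), z)
    base_pos = np.exp(params.baseline_log_mean + z)
    base_neg = np.exp(
        params.baseline_log_mean
        + rng_means.normal(0.0, params.baseline_log_sd, size=params.n_genes)
    )

    stage_means = np.empty((params.n_genes, len(STAGES)))
    stage_means[:, 0] = base_pos
    steps = np.array([code_to_tuple(codes[g]) for g in genes])
    for t in range(3):
        stage_means[:, t + 1] = stage_means[:, t] * params.planted_fold ** steps[:, t]

    samples = _sample_table(params.replicates_per_condition)
    sigma = np.sqrt(np.log1p(params.library_size_cv**2))
    lib = (
        np.exp(rng_lib.normal(-0.5 * sigma**2, sigma, size=len(samples)))
        if params.library_size_cv > 0
        else np.ones(len(samples))
    )

    counts = np.zeros((params.n_genes, len(samples)), dtype=np.int64)
    for j, row in samples.iterrows():
        stage_idx = STAGES.index(row["stage"])
        if row["fraction"] == "GFP+":
            mu = stage_means[:, stage_idx] * lib[j]
            counts[:, j] = _nb_draw(rng_pos, mu, params.dispersion)
        else:
            mu = base_neg * lib[j]
            counts[:, j] = _nb_draw(rng_neg, mu, params.dispersion)

    truth = TruthTable(
        gene_codes=codes,
        stage_means_pos=pd.DataFrame(stage_means, index=genes, columns=list(STAGES)),
        base_means_neg=pd.Series(base_neg, index=genes),
    )
    m = CountMatrix(genes=genes, samples=samples, counts=counts)
    return m, truth


def simulate_lr_pairs(
    m: CountMatrix,
    truth: TruthTable,
    params: SimulationParams,
    n_pairs: int = 60,
    parallel_fraction: float = 0.35,
    anti_fraction: float = 0.35,
    ligands_per_receptor: int = 2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, CountMatrix]:
    """Plant ligand-receptor co-dynamics and amend the GFP- counts.

    Receptors are planted (non-flat) GFP+ genes, each serving up to
    ``ligands_per_receptor`` pairs (ligand-receptor databases are hubby);
    ligands are distinct flat genes whose GFP- stage profile is rewritten:
    *parallel* ligands follow the receptor's stage fold-pattern,
    *anti-parallel* ligands the inverted (reciprocal) pattern — i.e. the
    opposing trend — and *independent* ligands stay flat. Returns the pair
    table (ligand, receptor, planted_class) and the amended matrix;
    ``truth.lr_pairs`` is filled in place.
    """
    ss = np.random.SeedSequence(params.seed if seed is None else seed).spawn(2)
    rng_pick, rng_counts = np.random.default_rng(ss[0]), np.random.default_rng(ss[1])

    planted = truth.planted_genes()
    flat = [g for g, c in truth.gene_codes.items() if c == "000"]
    n_receptors = -(-n_pairs // ligands_per_receptor)  # ceil
    if n_receptors > len(planted):
        raise ValueError(
            f"n_pairs={n_pairs} exceeds {len(planted)} planted receptor genes "
            f"at {ligands_per_receptor} ligands per receptor"
        )
    if n_pairs > len(flat):
        raise ValueError("not enough flat genes to serve as ligands")

    distinct = list(rng_pick.choice(planted, size=n_receptors, replace=False))
    receptors = [r for r in distinct for _ in range(ligands_per_receptor)][:n_pairs]
    ligands = list(rng_pick.choice(flat, size=n_pairs, replace=False))
    n_par = int(round(parallel_fraction * n_pairs))
    n_anti = int(round(anti_fraction * n_pairs))
    classes = ["parallel"] * n_par + ["anti-parallel"] * n_anti
    classes += ["independent"] * (n_pairs - len(classes))

    counts = m.counts.copy()
    gene_pos = {g: i for i, g in enumerate(m.genes)}
    stage_idx = np.array([STAGES.index(s) for s in m.samples["stage"].astype(str)])
    neg_cols = np.flatnonzero((m.samples["fraction"] == "GFP-").to_numpy())
    lib = _recover_library_factors(m, truth)

    rows = []
    for lig, rec, cls in zip(ligands, receptors, classes):
        rec_means = truth.stage_means_pos.loc[rec].to_numpy()
        pattern = rec_means / rec_means[0]
        base = float(np.exp(params.baseline_log_mean + abs(
            rng_counts.normal(0.0, params.baseline_log_sd))))
        if cls == "parallel":
            lig_means = base * pattern
        elif cls == "anti-parallel":
            lig_means = base / pattern
        else:
            lig_means = np.full(4, base)
        gi = gene_pos[lig]
        for j in neg_cols:
            mu = lig_means[stage_idx[j]] * lib[j]
            counts[gi, j] = _nb_draw(rng_counts, np.array([mu]), params.dispersion)[0]
        rows.append({"ligand": lig, "receptor": rec, "planted_class": cls})

    pairs = pd.DataFrame(rows)
    truth.lr_pairs = pairs
    amended = CountMatrix(genes=list(m.genes), samples=m.samples.copy(), counts=counts)
    return pairs, amended


def _recover_library_factors(m: CountMatrix, truth: TruthTable) -> np.ndarray:
    """Per-sample depth factors estimated from flat genes (median ratio)."""
    flat = [g for g, c in truth.gene_codes.items() if c == "000"]
    idx = [m.genes.index(g) for g in flat[: min(len(flat), 500)]]
    neg = (m.samples["fraction"] == "GFP-").to_numpy()
    expect = np.where(
        neg[None, :],
        truth.base_means_neg.iloc[idx].to_numpy()[:, None],
        truth.stage_means_pos.iloc[idx, 0].to_numpy()[:, None],
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = m.counts[idx, :] / expect
    return np.nanmedian(np.where(ratios > 0, ratios, np.nan), axis=0)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def _case_rate_for_or(odds_ratio: float, base_rate: float) -> float:
    """Carrier probability in cases implied by an OR against ``base_rate``."""
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base carrier rate must be in (0, 1)")
    odds0 = base_rate / (1.0 - base_rate)
    odds1 = odds_ratio * odds0
    p = odds1 / (1.0 + odds1)
    if p >= 1.0:
        raise ValueError(f"odds ratio {odds_ratio} with base rate {base_rate} implies p >= 1")
    return p


_PASSING_QC = dict(
    qual=99.0, mq=60.0, mq_rank_sum=0.0, ad_ratio=0.5, in_segdup=False,
    local_db_count=0, pedigree_count=0, flagged_control_db=False, indel_len=0,
)

_FILTER_VIOLATIONS: dict[str, dict] = {
    "popmax": {"popmax_af": 2e-4},
    "qual": {"qual": 30.0},
    "mq": {"mq": 40.0},
    "mq_rank_sum": {"mq_rank_sum": -5.0},
    "ad_ratio": {"ad_ratio": 0.10},
    "segdup": {"in_segdup": True},
    "local_db": {"local_db_count": 5},
    "pedigree": {"pedigree_count": 7},
    "flagged": {"flagged_control_db": True},
    "indel_len": {"indel_len": 5, "consequence": "frameshift"},
}


def simulate_variants(
    trajectory_sets: GeneSetCollection,
    planted_or: dict[str, float],
    n_cases: int = 425,
    n_controls: int = 54704,
    base_carrier_rate: float = 0.01,
    qc_fail_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate case and summary-control variant tables with planted ORs.

    Per trajectory set: PTV case carriers ~ Binomial(n_cases, p) with p
    solving the planted OR against ``base_carrier_rate``; control carriers ~
    Binomial(n_controls, base rate), emitted as summary allele counts across
    a handful of variant records without subject ids. Matched synonymous
    variants use OR = 1 for both cohorts. For every passing variant,
    ``qc_fail_fraction`` decoys are emitted, each violating exactly one named
    QC filter, cycling through the filter vocabulary.
    """
    unknown = set(planted_or) - set(trajectory_sets.names())
    if unknown:
        raise ValueError(f"planted_or references unknown sets: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for name in sorted(trajectory_sets.names()):
        genes = sorted(trajectory_sets[name])
        for vclass in ("PTV", "synonymous"):
            orr = float(planted_or.get(name, 1.0)) if vclass == "PTV" else 1.0
            p_case = _case_rate_for_or(orr, base_carrier_rate)
            n_case_carr = int(rng.binomial(n_cases, p_case))
            n_ctrl_carr = int(rng.binomial(n_controls, base_carrier_rate))
            truth_rows.append(
                {"set": name, "class": vclass, "planted_or": orr,
                 "case_carriers": n_case_carr, "control_carriers": n_ctrl_carr}
            )
            carriers = rng.choice(n_cases, size=n_case_carr, replace=False)
            for k, subj in enumerate(sorted(carriers)):
                csq = (
                    str(rng.choice(PTV_CONSEQUENCES)) if vclass == "PTV" else "synonymous"
                )
                rows.append(_passing_row(
                    variant_id=f"{name}_{vclass}_case_{k}",
                    gene=str(rng.choice(genes)), cohort="case",
                    subject_id=f"CASE{subj:05d}", consequence=csq,
                    allele_count=1, rng=rng,
                ))
            if n_ctrl_carr > 0:
                n_records = int(min(5, n_ctrl_carr))
                split = rng.multinomial(n_ctrl_carr - n_records, np.full(n_records, 1 / n_records))
                for k, extra in enumerate(split):
                    csq = (
                        str(rng.choice(PTV_CONSEQUENCES)) if vclass == "PTV" else "synonymous"
                    )
                    rows.append(_passing_row(
                        variant_id=f"{name}_{vclass}_ctrl_{k}",
                        gene=str(rng.choice(genes)), cohort="control",
                        subject_id=None, consequence=csq,
                        allele_count=int(1 + extra), rng=rng,
                    ))

    n_decoys = int(round(qc_fail_fraction * len(rows)))
    passing = list(rows)
    applicable = {
        "PTV": list(FILTER_NAMES),
        "synonymous": [f for f in FILTER_NAMES if f != "indel_len"],
    }
    for k in range(n_decoys):
        base = dict(passing[k % len(passing)])
        vclass = "synonymous" if base["consequence"] == "synonymous" else "PTV"
        filt = applicable[vclass][k % len(applicable[vclass])]
        base.update(_FILTER_VIOLATIONS[filt])
        base["variant_id"] = f"decoy_{k}_{filt}"
        rows.append(base)

    table = pd.DataFrame(rows)
    truth = TruthTable(
        variant_truth=pd.DataFrame(truth_rows),
        set_or={k: float(v) for k, v in planted_or.items()},
    )
    return table, truth


def _passing_row(variant_id, gene, cohort, subject_id, consequence, allele_count, rng):
    row = {
        "variant_id": variant_id, "gene": gene, "cohort": cohort,
        "subject_id": subject_id, "consequence": consequence,
        "popmax_af": float(rng.uniform(0, 1e-4)) if rng.random() < 0.7 else np.nan,
        "allele_count": allele_count,
        "spliceai_score": 0.9 if consequence == "spliceai_predicted" else np.nan,
        **_PASSING_QC,
    }
    if consequence == "frameshift":
        row["indel_len"] = int(rng.integers(1, 4))
    return row


def simulate_trait_list(
    trajectory_sets: GeneSetCollection,
    enriched_set: str,
    overlap_fraction: float = 0.5,
    list_size: int = 50,
    background: set[str] | None = None,
    seed: int = 0,
) -> list[str]:
    """A synthetic GWAS-trait gene list overlapping one trajectory set.

    ``floor(overlap_fraction * list_size)`` genes come from ``enriched_set``;
    the remainder are uniform draws from the background minus every
    trajectory set (so the planted overlap is the only signal).
    """
    if background is None:
        raise ValueError("background gene universe required")
    if enriched_set not in trajectory_sets:
        raise ValueError(f"unknown set {enriched_set!r}")
    if len(background) < list_size:
        raise ValueError("background smaller than list_size")
    k = int(np.floor(overlap_fraction * list_size))
    target = sorted(trajectory_sets[enriched_set])
    if k > len(target):
        raise ValueError("requested overlap exceeds the enriched set size")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = list(rng.choice(target, size=k, replace=False))
    pool = sorted(set(background) - trajectory_sets.all_genes())
    if len(pool) < list_size - k:
        raise ValueError("background (minus trajectory sets) too small")
    chosen += list(rng.choice(pool, size=list_size - k, replace=False))
    return chosen
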