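"""Readers and writers for the formats the pipeline touches.

Count matrices travel as TSV (genes x samples) or MatrixMarket triplets with
row/column sidecar files; gene sets as GMT; variant tables and every result
table as TSV. All readers validate and reject out-of-vocabulary categorical
values instead of coercing them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("gnrhtraj")

#: The four (stage, region) sampling cells of the design, in developmental order.
STAGES = ("E12.5-nose", "E14.5-nose", "E14.5-brain", "E18.5-brain")

#: FACS fractions: GFP+ are GnRH neurons, GFP- the surrounding (environment) cells.
FRACTIONS = ("GFP+", "GFP-")

#: The three consecutive stage transitions, in order.
TRANSITIONS = (
    ("E12.5-nose", "E14.5-nose"),
    ("E14.5-nose", "E14.5-brain"),
    ("E14.5-brain", "E18.5-brain"),
)
TRANSITION_LABELS = ("tau1", "tau2", "tau3")

VARIANT_CONSEQUENCES = (
    "stop_gain",
    "frameshift",
    "splice_site",
    "spliceai_predicted",
    "synonymous",
    "other",
)

COHORTS = ("case", "control")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _normalize_gene(g: str) -> str:
    """Gene symbols are matched case-insensitively (mouse Gnrh1 vs human GNRH1)."""
    return str(g).strip().upper()


# ---------------------------------------------------------------------------
# Count matrix + sample design
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ("sample_id", "stage", "fraction", "replicate")


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample design annotations.

    Attributes
    ----------
    genes
        Uppercased, unique gene symbols (rows).
    samples
        DataFrame with columns ``sample_id, stage, fraction, replicate``,
        one row per count column, in column order.
    counts
        ``(n_genes, n_samples)`` non-negative integer array.
    """

    genes: list[str]
    samples: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [_normalize_gene(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Series(self.genes)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise FormatError(f"duplicate gene symbols after case normalization: {dupes[:5]}")
        if not self.genes:
            raise FormatError("empty gene list")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.asarray(self.counts)
            if not np.allclose(as_int, np.round(as_int)):
                raise FormatError("non-integer counts")
            self.counts = np.round(as_int).astype(np.int64)
        if (self.counts < 0).any():
            raise FormatError("negative counts")
        self.samples = validate_design(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self, gene: str) -> int:
        return self.genes.index(_normalize_gene(gene))

    def subset_samples(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            genes=list(self.genes),
            samples=self.samples.loc[mask].reset_index(drop=True),
            counts=self.counts[:, mask],
        )

    def fraction_mask(self, fraction: str) -> np.ndarray:
        if fraction not in FRACTIONS:
            raise FormatError(f"unknown fraction {fraction!r}")
        return (self.samples["fraction"] == fraction).to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples["sample_id"])


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-design table (sample_id, stage, fraction, replicate)."""
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"design table missing columns {missing}")
    design = design.loc[:, list(DESIGN_COLUMNS)].copy()
    if design["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in design")
    bad_stage = sorted(set(design["stage"]) - set(STAGES))
    if bad_stage:
        raise FormatError(f"unknown stage label: {bad_stage}")
    bad_frac = sorted(set(design["fraction"]) - set(FRACTIONS))
    if bad_frac:
        raise FormatError(f"unknown fraction label: {bad_frac}")
    reps = pd.to_numeric(design["replicate"], errors="raise")
    if (reps < 1).any() or (reps != reps.astype(int)).any():
        raise FormatError("replicate must be a positive integer")
    design["replicate"] = reps.astype(int)
    design["stage"] = pd.Categorical(design["stage"], categories=list(STAGES), ordered=True)
    design["fraction"] = pd.Categorical(design["fraction"], categories=list(FRACTIONS))
    return design.reset_index(drop=True)


def read_counts(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a count matrix (TSV, or MTX triplet with sidecars) plus its design.

    A TSV has genes in rows and samples in columns. An ``.mtx`` file expects
    ``<stem>.rows.txt`` (gene symbols) and ``<stem>.cols.txt`` (sample ids)
    beside it. Samples present in the counts but absent from the design are
    an error; the design's row order is ignored in favour of column order.
    """
    path = Path(path)
    design_path = Path(design_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not design_path.exists():
        raise FileNotFoundError(design_path)

    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        genes = [_normalize_gene(g) for g in path.with_suffix("").with_suffix(".rows.txt").read_text().split()]
        sample_ids = path.with_suffix("").with_suffix(".cols.txt").read_text().split()
        counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        frame = pd.DataFrame(counts, index=genes, columns=sample_ids)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = [_normalize_gene(g) for g in frame.index]

    design = pd.read_csv(design_path, sep="\t")
    design = validate_design(design)
    unknown = [s for s in frame.columns if s not in set(design["sample_id"])]
    if unknown:
        raise FormatError(f"samples in counts but not in design: {unknown[:5]}")
    design = design.set_index("sample_id").loc[list(frame.columns)].reset_index()
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("non-numeric counts")
    return CountMatrix(genes=list(frame.index), samples=design, counts=values)


def write_counts(m: CountMatrix, path: str | Path, design_path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.counts))
        path.with_suffix("").with_suffix(".rows.txt").write_text("\n".join(m.genes) + "\n")
        path.with_suffix("").with_suffix(".cols.txt").write_text(
            "\n".join(m.samples["sample_id"]) + "\n"
        )
    else:
        m.to_frame().to_csv(path, sep="\t", index_label="gene")
    m.samples.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"empty gene set {name!r}")
            self.sets[name] = {_normalize_gene(g) for g in genes}

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return out


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB gene TAB gene ...`` per line.

    Duplicate genes within a line are deduplicated; a duplicate set name or a
    line with fewer than three fields is an error. An empty file yields an
    empty collection with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        warnings.warn(f"empty gene-set file {path}", stacklevel=2)
        logger.warning("empty gene-set file %s", path)
        return GeneSetCollection()
    for lineno, line in enumerate(lines, 1):
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, desc, *genes = fields
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = [g for g in genes if g.strip()]
        if not genes:
            raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
        sets[name] = {_normalize_gene(g) for g in genes}
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = {
    "variant_id": str,
    "gene": str,
    "cohort": str,
    "subject_id": str,          # absent/NA for summary-level controls
    "consequence": str,
    "popmax_af": float,
    "qual": float,
    "mq": float,
    "mq_rank_sum": float,
    "ad_ratio": float,
    "in_segdup": bool,
    "local_db_count": int,
    "pedigree_count": int,
    "flagged_control_db": bool,
    "indel_len": int,
    "allele_count": int,        # summary controls; 1 for per-subject rows
    "spliceai_score": float,    # only meaningful for spliceai_predicted rows
}

#: Columns that may be absent from an input file; they are filled as missing
#: (NaN), never as silently passing values.
OPTIONAL_VARIANT_COLUMNS = (
    "subject_id",
    "popmax_af",
    "qual",
    "mq",
    "mq_rank_sum",
    "ad_ratio",
    "in_segdup",
    "local_db_count",
    "pedigree_count",
    "flagged_control_db",
    "indel_len",
    "spliceai_score",
)


def validate_variants(df: pd.DataFrame) -> pd.DataFrame:
    required = ["variant_id", "gene", "cohort", "consequence", "allele_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"variant table missing required columns {missing}")
    df = df.copy()
    for col in OPTIONAL_VARIANT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    bad_cohort = sorted(set(df["cohort"]) - set(COHORTS))
    if bad_cohort:
        raise FormatError(f"cohort outside {COHORTS}: {bad_cohort}")
    bad_csq = sorted(set(df["consequence"]) - set(VARIANT_CONSEQUENCES))
    if bad_csq:
        raise FormatError(f"unknown consequence: {bad_csq}")
    df["gene"] = df["gene"].map(_normalize_gene)
    df["allele_count"] = pd.to_numeric(df["allele_count"], errors="raise")
    if (df["allele_count"] <= 0).any():
        raise FormatError("allele_count must be positive")
    for col in ("popmax_af", "ad_ratio"):
        vals = pd.to_numeric(df[col], errors="coerce")
        oob = vals.dropna()
        if ((oob < 0) | (oob > 1)).any():
            raise FormatError(f"{col} outside [0, 1]")
        df[col] = vals
    for col in ("qual", "mq", "mq_rank_sum", "spliceai_score"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("local_db_count", "pedigree_count", "indel_len"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() < 0).any():
            raise FormatError(f"{col} must be non-negative")
        df[col] = vals
    snv_mask = ~df["consequence"].isin(["frameshift"])  # SNV-type consequences
    indels = df.loc[snv_mask, "indel_len"].fillna(0)
    if (indels[df.loc[snv_mask, "consequence"] == "synonymous"] != 0).any():
        raise FormatError("indel_len must be 0 for SNVs (synonymous rows)")
    for col in ("in_segdup", "flagged_control_db"):
        df[col] = df[col].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False,
             "true": True, "false": False, np.nan: np.nan}
        )
    return df.reset_index(drop=True)


def read_variants(path: str | Path, cohort_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Read and validate an annotated-variant TSV.

    ``cohort_sizes`` (``{"case": N, "control": N}``) is attached as
    ``df.attrs["cohort_sizes"]`` for downstream carrier counting.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    df = validate_variants(df)
    if cohort_sizes is not None:
        for name, n in cohort_sizes.items():
            if n <= 0:
                raise FormatError(f"cohort size for {name!r} must be positive")
        df.attrs["cohort_sizes"] = dict(cohort_sizes)
    return df


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
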