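"""Spatiotemporal trajectory codes from per-transition DE results.

Each gene gets a triplet over the three consecutive transitions: +1 where
it is significantly up (raw p < 0.01 and fold change > 2 by default), -1
where significantly down, 0 otherwise. Codes are written as three-character
strings over {+, 0, -}; "000" is the flat code. Raw p-values (not FDR) are
used at this step; FDR stays in the DE tables for reporting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import TRANSITION_LABELS, GeneSetCollection

logger = logging.getLogger("gnrhtraj")

_DIGIT = {1: "+", 0: "0", -1: "-"}


def encode_trajectories(
    de_results: dict[str, pd.DataFrame],
    p_max: float = 0.01,
    min_fold: float = 2.0,
    fraction: str | None = None,
) -> pd.DataFrame:
    """Assign one trajectory code per tested gene.

    ``de_results`` maps each transition label (tau1..tau3) to its DE table.
    A gene missing from some transitions (e.g. filtered there) is assigned 0
    at the missing transitions, with a warning. Returns a DataFrame with
    columns ``gene, code, fraction`` (fraction carried through if given).
    """
    missing = [t for t in TRANSITION_LABELS if t not in de_results]
    if missing:
        raise ValueError(f"missing transitions: {missing}")
    log_fold = np.log2(min_fold)

    all_genes: list[str] = []
    seen: set[str] = set()
    for t in TRANSITION_LABELS:
        for g in de_results[t]["gene"]:
            if g not in seen:
                seen.add(g)
                all_genes.append(g)

    digits = pd.DataFrame(0, index=all_genes, columns=list(TRANSITION_LABELS))
    partial = False
    for t in TRANSITION_LABELS:
        df = de_results[t].set_index("gene")
        sig = df["pvalue"] < p_max
        up = sig & (df["log2fc"] > log_fold)
        down = sig & (df["log2fc"] < -log_fold)
        d = pd.Series(0, index=df.index)
        d[up] = 1
        d[down] = -1
        digits.loc[d.index, t] = d
        if len(df) != len(all_genes):
            partial = True
    if partial:
        logger.warning(
            "some genes were not tested in every transition; untested transitions coded 0"
        )

    codes = digits.apply(lambda r: "".join(_DIGIT[int(v)] for v in r), axis=1)
    out = pd.DataFrame({"gene": all_genes, "code": codes.loc[all_genes].to_numpy()})
    if fraction is not None:
        out["fraction"] = fraction
    return out


def build_trajectory_sets(
    assignment: pd.DataFrame,
    min_genes: int = 10,
    aliases: dict[str, str] | None = None,
) -> GeneSetCollection:
    """One gene set per non-flat code with at least ``min_genes`` members.

    The flat code "000" is never a set. ``aliases`` optionally renames codes
    (e.g. {"+00": "T01"}); unlisted codes keep their canonical string.
    """
    if len(assignment) == 0:
        raise ValueError("empty trajectory assignment")
    aliases = aliases or {}
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for code, group in assignment.groupby("code"):
        if code == "000" or len(group) < min_genes:
            continue
        name = aliases.get(code, code)
        if name in sets:
            raise ValueError(f"alias collision: two codes map to {name!r}")
        sets[name] = set(group["gene"])
        descriptions[name] = f"trajectory {code}"
    return GeneSetCollection(sets=sets, descriptions=descriptions)
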