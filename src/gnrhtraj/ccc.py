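"""Dynamic cell-to-cell communication network.

Ligands are expressed by the environment (GFP- fraction), receptors by GnRH
neurons (GFP+). Each gene's stage profile is its mean log2(CPM+1) per
spacetime point, centered and scaled to unit Euclidean norm; the edge
strength of a ligand-receptor pair is the scalar product of the two unit
profiles (a correlation over the four stage means, in [-1, 1]). Edges are
classed parallel (> tau), anti-parallel (< -tau) or neutral, and modules are
connected components of the strong-edge subgraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import STAGES, CountMatrix
from .normalize import cpm, normalization_factors

logger = logging.getLogger("gnrhtraj")


@dataclass
class StageProfiles:
    """Unit-norm centered stage profiles for every gene of one fraction."""

    fraction: str
    profiles: pd.DataFrame      # genes x 4 stages, centered / unit norm (or 0s)
    degenerate: pd.Series       # True where the raw profile was constant
    max_cpm: pd.Series          # max over stages of the raw mean CPM


def stage_profiles(m: CountMatrix, fraction: str) -> StageProfiles:
    """Per-gene centered unit-norm profile of mean log2(CPM+1) across stages."""
    frac = m.subset_samples(m.fraction_mask(fraction))
    stages_present = set(frac.samples["stage"].astype(str))
    missing = [s for s in STAGES if s not in stages_present]
    if missing:
        raise ValueError(f"fraction {fraction!r} is missing stages {missing}")
    norm = normalization_factors(frac)
    log_expr = cpm(frac, norm, log2=True, prior=1.0)
    raw_cpm = cpm(frac, norm)
    stage_labels = frac.samples["stage"].astype(str).to_numpy()
    means = np.column_stack(
        [log_expr[:, stage_labels == s].mean(axis=1) for s in STAGES]
    )
    max_cpm = np.column_stack(
        [raw_cpm[:, stage_labels == s].mean(axis=1) for s in STAGES]
    ).max(axis=1)

    centered = means - means.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms < 1e-12
    unit = np.where(degenerate[:, None], 0.0, centered / np.where(norms == 0, 1, norms)[:, None])
    return StageProfiles(
        fraction=fraction,
        profiles=pd.DataFrame(unit, index=frac.genes, columns=list(STAGES)),
        degenerate=pd.Series(degenerate, index=frac.genes),
        max_cpm=pd.Series(max_cpm, index=frac.genes),
    )


def classify_strength(strength: float, tau: float = 0.5) -> str:
    if strength > tau:
        return "parallel"
    if strength < -tau:
        return "anti-parallel"
    return "neutral"


def build_dynamic_network(
    pairs: pd.DataFrame,
    ligand_profiles: StageProfiles,
    receptor_profiles: StageProfiles,
    assignments: pd.DataFrame | None = None,
    tau: float = 0.5,
    expression_floor: float = 1.0,
) -> pd.DataFrame:
    """Score every ligand-receptor pair by the profile scalar product.

    ``pairs`` needs columns ``ligand`` and ``receptor``. Pairs whose ligand
    (GFP-) or receptor (GFP+) never reaches ``expression_floor`` CPM in any
    stage of its fraction are dropped (the "expressed" gate), as are pairs
    naming unknown genes (with a warning). Degenerate profiles give strength
    0. Returns edges: ligand, receptor, strength, class, and the trajectory
    codes of both genes when ``assignments`` (gene, code, fraction) is given.
    """
    code_map = {}
    if assignments is not None:
        for _, row in assignments.iterrows():
            code_map[(row["gene"], row.get("fraction"))] = row["code"]

    lig_prof = ligand_profiles.profiles
    rec_prof = receptor_profiles.profiles
    edges = []
    for _, row in pairs.iterrows():
        lig, rec = str(row["ligand"]).upper(), str(row["receptor"]).upper()
        if lig not in lig_prof.index or rec not in rec_prof.index:
            logger.warning("dropping pair %s->%s: unknown gene", lig, rec)
            continue
        if (
            ligand_profiles.max_cpm[lig] < expression_floor
            or receptor_profiles.max_cpm[rec] < expression_floor
        ):
            continue
        if ligand_profiles.degenerate[lig] or receptor_profiles.degenerate[rec]:
            strength = 0.0
        else:
            strength = float(lig_prof.loc[lig] @ rec_prof.loc[rec])
        edges.append(
            {
                "ligand": lig,
                "receptor": rec,
                "strength": strength,
                "class": classify_strength(strength, tau),
                "ligand_code": code_map.get((lig, "GFP-"), ""),
                "receptor_code": code_map.get((rec, "GFP+"), ""),
            }
        )
    return pd.DataFrame(
        edges,
        columns=["ligand", "receptor", "strength", "class", "ligand_code", "receptor_code"],
    )


def detect_modules(
    edges: pd.DataFrame, min_abs_strength: float = 0.8, min_edges: int = 2
) -> list[dict]:
    """Modules = connected components of the strong-edge bipartite graph.

    Edges with |strength| >= ``min_abs_strength`` are kept; components with
    at least ``min_edges`` edges become modules, summarized by mean
    |strength|. Ligand and receptor node namespaces are kept distinct so a
    symbol appearing on both sides does not merge components spuriously.
    """
    strong = edges[edges["strength"].abs() >= min_abs_strength]
    g = nx.Graph()
    for _, e in strong.iterrows():
        g.add_edge(("L", e["ligand"]), ("R", e["receptor"]), strength=e["strength"])
    modules = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)):
        sub = g.subgraph(comp)
        if sub.number_of_edges() < min_edges:
            continue
        strengths = [d["strength"] for _, _, d in sub.edges(data=True)]
        modules.append(
            {
                "module_id": f"m{len(modules) + 1}",
                "ligands": sorted(n for kind, n in comp if kind == "L"),
                "receptors": sorted(n for kind, n in comp if kind == "R"),
                "n_edges": sub.number_of_edges(),
                "summary_strength": float(np.mean(np.abs(strengths))),
            }
        )
    return modules


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Write the network as GraphML with strength/class edge attributes."""
    g = nx.DiGraph()
    for _, e in edges.iterrows():
        g.add_node(f"L:{e['ligand']}", kind="ligand", code=e["ligand_code"])
        g.add_node(f"R:{e['receptor']}", kind="receptor", code=e["receptor_code"])
        g.add_edge(
            f"L:{e['ligand']}", f"R:{e['receptor']}",
            strength=float(e["strength"]), **{"class": e["class"]},
        )
    nx.write_graphml(g, path)
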