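"""Independent oracles: brute-force or first-principles re-derivations kept
deliberately separate from the package's code paths."""

from __future__ import annotations

from math import comb

import numpy as np


def hypergeom_upper_tails(population: int, successes: int, draws: int) -> np.ndarray:
    """P(X >= k) for all k in 0..min(successes, draws), by direct enumeration.

    Exact integer combinatorics; one suffix sum per (population, successes,
    draws) triple.
    """
    kmax = min(successes, draws)
    total = comb(population, draws)
    pmf = np.array(
        [
            comb(successes, k) * comb(population - successes, draws - k) / total
            for k in range(kmax + 1)
        ]
    )
    return np.cumsum(pmf[::-1])[::-1]


def fisher_one_sided_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater in cases) Fisher p by hypergeometric enumeration."""
    tails = hypergeom_upper_tails(a + b + c + d, a + b, a + c)
    return float(tails[a])


def bh_step_up(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, textbook step-up."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = n - rank_from_top
        running = min(running, p[idx] * n / rank)
        adj[idx] = running
    return adj


def tmm_factor_direct(obs, ref, trim_m=0.30, trim_a=0.05) -> float:
    """Trimmed weighted mean of M-values, written out step by step."""
    obs = np.asarray(obs, float)
    ref = np.asarray(ref, float)
    n_o, n_r = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    m = np.log2((obs[keep] / n_o) / (ref[keep] / n_r))
    a = 0.5 * np.log2((obs[keep] / n_o) * (ref[keep] / n_r))
    w = (n_o - obs[keep]) / (n_o * obs[keep]) + (n_r - ref[keep]) / (n_r * ref[keep])
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    return float(2 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])))


def module_score_procedural(expr_df, gene_set, n_bins, n_ctrl, seed) -> np.ndarray:
    """Step-by-step re-implementation of the bin/sample/subtract procedure.

    Mirrors the stated contract (rank-based equal-count bins; per set gene,
    n_ctrl non-set controls from its bin, expanding symmetrically to the
    nearest non-empty bins; score = mean(set) - mean(control draws)) using
    plain loops and its own RNG stream construction.
    """
    gene_set = {g.upper() for g in gene_set}
    expr_df = expr_df.rename(columns=str.upper)
    genes = list(expr_df.columns)
    avg = expr_df.mean(axis=0).to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rank_of = np.empty(len(genes), dtype=int)
    rank_of[np.argsort(avg, kind="stable")] = np.arange(len(genes))
    bins = [int(r * n_bins // len(genes)) for r in rank_of]

    pools: dict[int, list[int]] = {}
    for i, g in enumerate(genes):
        if g not in gene_set:
            pools.setdefault(bins[i], []).append(i)

    picked: list[int] = []
    for i, g in enumerate(genes):
        if g not in gene_set:
            continue
        pool: list[int] = []
        for off in range(n_bins + 1):
            pool = list(pools.get(bins[i] - off, []))
            if bins[i] + off != bins[i] - off:
                pool += list(pools.get(bins[i] + off, []))
            if pool:
                break
        if not pool:
            continue
        picked.extend(rng.choice(pool, size=min(n_ctrl, len(pool)), replace=False).tolist())

    set_vals = expr_df[[g for g in genes if g in gene_set]].to_numpy()
    set_mean = set_vals.mean(axis=1)
    if picked:
        ctrl_mean = expr_df.to_numpy()[:, picked].mean(axis=1)
    else:
        ctrl_mean = np.zeros(len(expr_df))
    return set_mean - ctrl_mean


def connected_components_bruteforce(edges: list[tuple]) -> list[set]:
    """Components by repeated closure over an explicit node list."""
    nodes = set()
    for u, v in edges:
        nodes.update((u, v))
    comps = []
    unseen = set(nodes)
    while unseen:
        frontier = {unseen.pop()}
        comp = set(frontier)
        while frontier:
            nxt = set()
            for u, v in edges:
                if u in comp and v not in comp:
                    nxt.add(v)
                if v in comp and u not in comp:
                    nxt.add(u)
            comp |= nxt
            frontier = nxt
        unseen -= comp
        comps.append(comp)
    return comps
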