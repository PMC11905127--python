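#!/usr/bin/env python
"""Generate the synthetic study: counts for the 4 spacetime points x 2 FACS
fractions, planted trajectory genes, ligand-receptor co-dynamics, a GWAS-like
trait gene list, and case/control variant tables with a planted burden.

Writes everything downstream steps read under <out>/data/ plus the ground
truth for later comparison.
"""

import argparse
from pathlib import Path

import pandas as pd

from gnrhtraj.io import write_counts, write_gene_sets
from gnrhtraj.simulate import (
    SimulationParams,
    simulate_counts,
    simulate_lr_pairs,
    simulate_variants,
)
from gnrhtraj.io import GeneSetCollection


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out / "data"
    out.mkdir(parents=True, exist_ok=True)

    params = SimulationParams(seed=args.seed)
    m, truth = simulate_counts(params)
    pairs, m = simulate_lr_pairs(m, truth, params, n_pairs=60)
    write_counts(m, out / "counts.tsv", out / "design.tsv")
    pairs.to_csv(out / "lr_pairs.tsv", sep="\t", index=False)
    pd.Series(truth.gene_codes, name="code").rename_axis("gene").to_csv(
        out / "truth_codes.tsv", sep="\t"
    )

    planted_sets = GeneSetCollection(
        sets={
            code: {g for g, c in truth.gene_codes.items() if c == code}
            for code in sorted(set(truth.gene_codes.values()))
            if code != "000"
        }
    )
    write_gene_sets(planted_sets, out / "truth_trajectory_sets.gmt")

    variants, vtruth = simulate_variants(
        planted_sets,
        {sorted(planted_sets.names())[0]: 8.0},
        n_cases=425,
        n_controls=54704,
        base_carrier_rate=0.01,
        seed=args.seed,
    )
    variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    vtruth.variant_truth.to_csv(out / "truth_variants.tsv", sep="\t", index=False)

    n_planted = len(truth.planted_genes())
    print(f"simulated {m.n_genes} genes x {m.n_samples} samples "
          f"({n_planted} planted across {len(planted_sets)} trajectories)")
    print(f"planted ligand-receptor pairs: {len(pairs)} "
          f"({(pairs.planted_class != 'independent').sum()} with co-dynamics)")
    print(f"variant table: {len(variants)} rows "
          f"(planted OR 8.0 on {sorted(planted_sets.names())[0]})")
    print(f"wrote inputs to {out}")


if __name__ == "__main__":
    main()
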