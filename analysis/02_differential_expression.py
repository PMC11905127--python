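#!/usr/bin/env python
"""Stagewise NB differential expression across the three consecutive
spacetime transitions, separately for the GFP+ (GnRH neuron) and GFP-
(environment) fractions."""

import argparse
from pathlib import Path

import pandas as pd

from gnrhtraj.de import de_test, significant_genes
from gnrhtraj.io import TRANSITION_LABELS, read_counts


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.out / "data"
    m = read_counts(data / "counts.tsv", data / "design.tsv")

    for fraction, tag in (("GFP+", "gfppos"), ("GFP-", "gfpneg")):
        tables = []
        for t in TRANSITION_LABELS:
            res = de_test(m, t, fraction)
            n_sig = len(significant_genes(res))
            print(f"{fraction} {t}: {len(res)} genes tested, "
                  f"{n_sig} significant (FDR<0.05, FC>2)")
            tables.append(res)
        pd.concat(tables).to_csv(args.out / f"de_{tag}.tsv", sep="\t", index=False)
    print(f"wrote DE tables to {args.out}")


if __name__ == "__main__":
    main()
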