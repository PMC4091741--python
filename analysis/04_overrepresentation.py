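#!/usr/bin/env python
"""Functional-category enrichment of the changed genes.

Builds a synthetic gene-set collection for the simulated genome (random
categories plus, for reference, a category holding each line's truly
perturbed genes) and asks which categories are over- or under-represented
among the significantly up-/down-regulated genes of each line
(hypergeometric tails, BH-FDR 0.05 per direction).
"""

import argparse
from pathlib import Path

import numpy as np

from txdist import diffexpr, enrichment, io, simulate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--datadir", type=Path, default=Path("results/data"))
    parser.add_argument("--outdir", type=Path, default=Path("results/ora"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    matrix = io.read_expression(args.datadir / "focal_expression.tsv")
    metadata = io.read_metadata(args.datadir / "focal_metadata.tsv")
    calls = diffexpr.call_de(diffexpr.anova_tukey(matrix, metadata))

    # synthetic categories: 30 random sets + the construction truth, which
    # is recoverable by regenerating the focal study from its seed
    focal = simulate.StudyConfig(
        n_genes=2000,
        groups=[("WT", 3), ("GMa", 3), ("GMb", 3)],
        de_spikes=[("GMa", 1, 4.5, ["G0001"]), ("GMb", 1, 2.5, ["G0002"]),
                   ("GMa", 40, 1.5), ("GMb", 30, -1.5)],
        high_cv_fraction=0.04,
        seed=args.seed,
    )
    _, _, truth = simulate.generate_expression_study(focal)
    rng = np.random.default_rng(args.seed + 10_000)
    collection = enrichment.GeneSetCollection()
    for i in range(30):
        members = sorted(rng.choice(matrix.index, 40, replace=False))
        collection.add(enrichment.GeneSet(f"SET{i + 1:03d}", "random", members))
    for group in ("GMa", "GMb"):
        spiked = truth.de_effects.index[truth.de_effects[group] != 0].tolist()
        collection.add(enrichment.GeneSet(f"PERTURBED_{group}", "construction",
                                          spiked))
    enrichment.write_gmt(collection, args.outdir / "categories.gmt")

    reference = list(matrix.index)
    for (a, b), sets in calls.items():
        if a != "WT":
            continue
        for direction in ("up", "down"):
            if not sets[direction]:
                continue
            table = enrichment.ora(sets[direction], reference, collection, 0.05)
            name = f"{b}_{direction}"
            enrichment.write_ora_tsv(table, args.outdir / f"ora_{name}.tsv")
            over = table.index[table["sig_over"]].tolist()
            under = table.index[table["sig_under"]].tolist()
            print(f"{b} {direction}-regulated ({len(sets[direction])} genes): "
                  f"over-represented {over or 'none'}; "
                  f"under-represented {under or 'none'}")
    print(f"wrote ORA tables -> {args.outdir}")


if __name__ == "__main__":
    main()
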