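#!/usr/bin/env python
"""Generate every dataset the assessment consumes.

Produces, under ``results/data/``:

* a focal study — wild type (WT) plus two independently engineered lines
  (GMa, GMb), three biological replicates each, with spiked transgene-like
  effects (one strong overexpression marker gene per line) plus a handful
  of moderate pleiotropic changes, and 4% highly variable genes;
* two baseline accession-style studies (two accessions each, n = 3) that
  carry their own study-level batch signatures;
* a recombinant-inbred-line (RIL) population of 60 lines with a binary
  marker table, mixing two parental expression profiles block-wise with
  transgressive segregation.

All files are plain TSV; the generator seed fixes everything.
"""

import argparse
from pathlib import Path

from txdist import io, simulate


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    focal = simulate.StudyConfig(
        n_genes=2000,
        groups=[("WT", 3), ("GMa", 3), ("GMb", 3)],
        de_spikes=[
            # the intended transgene effects: one strong marker gene each
            ("GMa", 1, 4.5, ["G0001"]),
            ("GMb", 1, 2.5, ["G0002"]),
            # moderate unintended (pleiotropic) changes
            ("GMa", 40, 1.5),
            ("GMb", 30, -1.5),
        ],
        high_cv_fraction=0.04,
        seed=args.seed,
    )
    matrix, meta, truth = simulate.generate_expression_study(focal)
    io.write_expression(matrix, args.outdir / "focal_expression.tsv")
    io.write_metadata(meta, args.outdir / "focal_metadata.tsv")
    io.write_gene_list(["G0001", "G0002"], args.outdir / "transgene_probes.txt")
    spiked = truth.de_effects.index[(truth.de_effects != 0).any(axis=1)]
    print(f"focal study: {matrix.shape[0]} genes x {matrix.shape[1]} samples, "
          f"{len(spiked)} genes with true effects "
          f"({len(spiked) / matrix.shape[0]:.1%} of genes)")

    for i, names in enumerate((("AccA", "AccB"), ("AccC", "AccD"))):
        config = simulate.StudyConfig(
            n_genes=2000,
            groups=[(names[0], 3), (names[1], 3)],
            # accessions genuinely differ in expression (the natural
            # baseline the GM lines are judged against) and carry their
            # own highly variable genes
            de_spikes=[(names[1], 60, 1.2), (names[1], 60, -1.2)],
            high_cv_fraction=0.04,
            seed=args.seed + 1 + i,
        )
        m, md, _ = simulate.generate_expression_study(config)
        io.write_expression(m, args.outdir / f"baseline{i + 1}_expression.tsv")
        io.write_metadata(md, args.outdir / f"baseline{i + 1}_metadata.tsv")
        print(f"baseline study {i + 1}: accessions {names[0]}/{names[1]}, "
              f"{m.shape[1]} samples")

    ril = simulate.RILConfig(
        n_lines=60, n_genes=2000, n_markers=40,
        polymorphic_fraction=0.25, transgressive_fraction=0.15,
        seed=args.seed + 100,
    )
    matrix, markers, meta, truth = simulate.generate_ril_population(ril)
    io.write_expression(matrix, args.outdir / "ril_expression.tsv")
    io.write_markers(markers, args.outdir / "ril_markers.tsv")
    io.write_metadata(meta, args.outdir / "ril_metadata.tsv")
    print(f"RIL population: {matrix.shape[1]} lines, {markers.shape[0]} markers, "
          f"{len(truth.polymorphic_genes)} parent-polymorphic genes, "
          f"{len(truth.transgressive_genes)} transgressive genes")
    print(f"wrote all inputs -> {args.outdir}")


if __name__ == "__main__":
    main()
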