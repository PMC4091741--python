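"""Over-/under-representation analysis of functional categories.

Hypergeometric enrichment of a test gene set against a fixed reference
universe (all probe IDs on the array), one category at a time, with
Benjamini–Hochberg FDR control applied separately to the over- and
under-representation directions — both directions are of interest (a
category can be depleted in one line and enriched in another).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSet", "GeneSetCollection", "read_gmt", "write_gmt", "ora", "write_ora_tsv"]


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GMT semantics)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValueError(f"duplicate gene-set name {gene_set.name!r}")
        if not gene_set.members:
            raise ValueError(f"gene set {gene_set.name!r} is empty")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line ``name<TAB>description<TAB>member...``.

    Duplicate members within a set are de-duplicated (order preserved);
    malformed lines (fewer than three fields / empty member list /
    duplicate set name) are rejected with the offending line number.
    """
    collection = GeneSetCollection()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, description = fields[0], fields[1]
        members = list(dict.fromkeys(m for m in fields[2:] if m))
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        try:
            collection.add(GeneSet(name, description, members))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def ora(
    test_set: Iterable[str],
    reference_set: Iterable[str],
    collection: GeneSetCollection,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-/under-representation of every category.

    With N = |reference|, K = |category ∩ reference|, n = |test| and
    k = |category ∩ test|: ``p_over = P(X >= k)`` and ``p_under = P(X <= k)``
    for X ~ Hypergeometric(N, K, n). BH q-values are computed separately
    per direction; ``sig_over``/``sig_under`` flag q < fdr.

    Test genes outside the reference are dropped with a warning;
    categories are intersected with the reference universe before testing.
    """
    reference = set(reference_set)
    test = set(test_set)
    outside = test - reference
    if outside:
        warnings.warn(
            f"{len(outside)} test genes outside the reference universe dropped"
        )
        test &= reference
    if not test:
        raise ValueError("test set is empty (after restriction to the reference)")

    N, n = len(reference), len(test)
    rows = []
    for gs in collection:
        members = set(gs.members) & reference
        K = len(members)
        k = len(members & test)
        p_over = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_under = float(stats.hypergeom.cdf(k, N, K, n))
        rows.append((gs.name, k, K, n, N, p_over, p_under))
    table = pd.DataFrame(
        rows, columns=["category", "k", "K", "n", "N", "p_over", "p_under"]
    ).set_index("category")
    for direction in ("over", "under"):
        p = table[f"p_{direction}"].to_numpy()
        reject, q, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
        table[f"q_{direction}"] = q
        table[f"sig_{direction}"] = reject
    return table[
        ["k", "K", "n", "N", "p_over", "q_over", "sig_over",
         "p_under", "q_under", "sig_under"]
    ]


def write_ora_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="category")
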