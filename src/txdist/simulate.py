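"""Synthetic-data generators for every input the pipeline consumes.

Three generators, each fully determined by a config object and its seed:

* :func:`generate_expression_study` — a multi-replicate microarray-style
  study on the log2 scale, with optional per-batch gene-specific offsets,
  a calibrated fraction of highly variable (high-CV) genes and spiked
  differential-expression effects. Emulates RMA-normalized intensity data
  with small replicate groups (typically n = 3).
* :func:`generate_group_geometry` — low-dimensional score-space point
  clouds with known group geometry (separated / overlapping / nested),
  used to exercise the distance statistic's semantics directly.
* :func:`generate_ril_population` — a recombinant-inbred-line population
  mixing two parental expression profiles block-wise, with a binary marker
  table and transgressive (parent-equal but genotype-linked) genes.

Each generator also returns a *truth* record describing exactly what was
injected, so downstream recovery can be asserted against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyConfig",
    "StudyTruth",
    "GeometryConfig",
    "RILConfig",
    "RILTruth",
    "generate_expression_study",
    "generate_group_geometry",
    "generate_ril_population",
]


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Design of one synthetic expression study.

    Parameters
    ----------
    n_genes:
        Number of genes (probe sets).
    groups:
        Ordered ``(group_name, n_replicates)`` pairs; every group needs
        at least two replicates.
    batch_assignments:
        Optional map from sample ID to batch label. Sample IDs are
        ``"{group}_{i}"`` with ``i`` starting at 1. Unlisted samples fall
        into batch ``"batch1"``. When omitted, the study is single-batch
        and no offsets are drawn.
    baseline_mean_log2, baseline_sd_log2:
        Per-gene true means are drawn from this normal law (log2 scale).
        Defaults 8.0 / 2.0 mimic the spread of RMA-summarized intensities.
    replicate_sd_log2:
        Replicate (biological) noise SD for ordinary genes; default 0.15.
    high_cv_fraction:
        Fraction of genes given inflated replicate noise.
    high_cv_range:
        Target coefficient-of-variation percentage range (uniform draw) for
        the high-CV genes. The lower bound defaults to 40% — comfortably
        above the 20% flagging threshold — so that CV estimates from as few
        as three replicates still mark these genes reliably.
    de_spikes:
        ``(group_name, n_genes, log2_effect)`` triples, optionally with a
        fourth element giving explicit gene IDs; the effect is added to the
        named group's true mean for those genes. Without explicit IDs,
        spiked genes are drawn (without replacement per group) from genes
        not already spiked in that group.
    batch_sd_log2:
        SD of the per-(gene, batch) offsets (log2); shared by all samples
        of a batch, which is exactly the structure the mean-shift batch
        correction removes.
    seed:
        Seed for the study's private :class:`numpy.random.Generator`.
    """

    n_genes: int = 1000
    groups: Sequence[tuple[str, int]] = (("WT", 3), ("GM", 3))
    batch_assignments: Mapping[str, str] | None = None
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 2.0
    replicate_sd_log2: float = 0.15
    high_cv_fraction: float = 0.0
    high_cv_range: tuple[float, float] = (40.0, 70.0)
    de_spikes: Sequence[tuple] = ()
    batch_sd_log2: float = 0.3
    seed: int = 0
    gene_prefix: str = "G"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        names = [g for g, _ in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        for g, n in self.groups:
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 replicates, got {n}")
        if not 0.0 <= self.high_cv_fraction <= 1.0:
            raise ValueError("high_cv_fraction must lie in [0, 1]")
        lo, hi = self.high_cv_range
        if not 0 < lo <= hi:
            raise ValueError("high_cv_range must be 0 < low <= high")
        for spike in self.de_spikes:
            if spike[0] not in names:
                raise ValueError(f"de_spike references unknown group {spike[0]!r}")
            if spike[1] < 1:
                raise ValueError("de_spike gene count must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1}" for g, n in self.groups for i in range(n)]

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"{self.gene_prefix}{i + 1:0{width}d}" for i in range(self.n_genes)]


@dataclass
class StudyTruth:
    """What was injected into a synthetic study (the test oracle)."""

    gene_means: pd.Series                      # per-gene baseline true mean
    de_effects: pd.DataFrame                   # genes x groups, true log2 shift
    batch_offsets: pd.DataFrame                # genes x batches, true offset
    high_cv_genes: list[str]
    target_cv: pd.Series                       # target CV% for high-CV genes
    replicate_sd: pd.Series                    # per-gene replicate noise SD


def _resolve_batches(config: StudyConfig) -> pd.Series:
    samples = config.sample_ids
    if config.batch_assignments is None:
        return pd.Series("batch1", index=samples)
    unknown = [s for s in config.batch_assignments if s not in samples]
    if unknown:
        raise ValueError(f"batch_assignments name unknown samples: {unknown[:5]}")
    return pd.Series(
        [config.batch_assignments.get(s, "batch1") for s in samples], index=samples
    )


def generate_expression_study(
    config: StudyConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, StudyTruth]:
    """Simulate one expression study.

    Returns
    -------
    (matrix, metadata, truth)
        ``matrix`` is genes × samples (log2), ``metadata`` carries the
        group and batch label of every sample, and ``truth`` records the
        injected effects for reconstruction-based assertions.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    samples = config.sample_ids
    groups = pd.Series(
        [g for g, n in config.groups for _ in range(n)], index=samples, name="group"
    )
    batches = _resolve_batches(config)

    gene_means = pd.Series(
        rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, config.n_genes),
        index=genes,
        name="true_mean",
    )

    # high-CV genes: replicate noise inflated so sd/mean lands in the target
    # CV band (percent, on the analysis scale)
    n_high = int(round(config.high_cv_fraction * config.n_genes))
    high_idx = rng.choice(config.n_genes, size=n_high, replace=False)
    high_idx.sort()
    high_genes = [genes[i] for i in high_idx]
    target_cv = pd.Series(
        rng.uniform(*config.high_cv_range, size=n_high), index=high_genes
    )
    replicate_sd = pd.Series(config.replicate_sd_log2, index=genes)
    if n_high:
        replicate_sd.loc[high_genes] = (
            np.abs(gene_means.loc[high_genes]) * target_cv.to_numpy() / 100.0
        )

    # DE spikes: per-group log2 shifts on disjoint gene sets
    group_names = [g for g, _ in config.groups]
    de_effects = pd.DataFrame(0.0, index=genes, columns=group_names)
    assigned: dict[str, set[str]] = {g: set() for g in group_names}
    for spike in config.de_spikes:
        group, n_spike, effect = spike[0], int(spike[1]), float(spike[2])
        if len(spike) > 3 and spike[3] is not None:
            chosen = list(spike[3])
            if len(chosen) != n_spike:
                raise ValueError("explicit spike gene list length mismatch")
            missing = [g for g in chosen if g not in de_effects.index]
            if missing:
                raise ValueError(f"spike names unknown genes: {missing[:5]}")
        else:
            pool = [g for g in genes if g not in assigned[group]]
            if n_spike > len(pool):
                raise ValueError("more spiked genes requested than genes available")
            chosen = list(rng.choice(pool, size=n_spike, replace=False))
        overlap = assigned[group].intersection(chosen)
        if overlap:
            raise ValueError(
                f"overlapping spike assignment for group {group!r}: "
                f"{sorted(overlap)[:5]}"
            )
        assigned[group].update(chosen)
        de_effects.loc[chosen, group] += effect

    batch_names = list(dict.fromkeys(batches))
    batch_offsets = pd.DataFrame(0.0, index=genes, columns=batch_names)
    if len(batch_names) > 1:
        batch_offsets.iloc[:, :] = rng.normal(
            0.0, config.batch_sd_log2, size=(config.n_genes, len(batch_names))
        )

    noise = rng.normal(0.0, 1.0, size=(config.n_genes, len(samples)))
    values = (
        gene_means.to_numpy()[:, None]
        + de_effects[groups.to_numpy()].to_numpy()
        + batch_offsets[batches.to_numpy()].to_numpy()
        + noise * replicate_sd.to_numpy()[:, None]
    )
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    metadata = pd.DataFrame({"group": groups, "batch": batches})
    truth = StudyTruth(
        gene_means=gene_means,
        de_effects=de_effects,
        batch_offsets=batch_offsets,
        high_cv_genes=high_genes,
        target_cv=target_cv,
        replicate_sd=replicate_sd,
    )
    return matrix, metadata, truth


# ---------------------------------------------------------------------------
# score-space geometries
# ---------------------------------------------------------------------------

@dataclass
class GeometryConfig:
    """Two-group point configuration in a low-dimensional score space.

    ``separated``: two unit-spread Gaussian clusters whose centroids lie
    ``separation`` apart (in units of within-group SD). ``overlapping``:
    both groups drawn from the identical standard law. ``nested``: shared
    centroid, group A spread 1/100 of group B's.
    """

    layout: Literal["separated", "overlapping", "nested"] = "separated"
    n_per_group: int = 3
    dim: int = 2
    separation: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("separated", "overlapping", "nested"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def generate_group_geometry(config: GeometryConfig) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(scores, labels)``: a (2·n_per_group) × dim array and the
    group label ("A"/"B") of every row."""
    rng = np.random.default_rng(config.seed)
    n, d = config.n_per_group, config.dim
    labels = np.array(["A"] * n + ["B"] * n)
    if config.layout == "separated":
        offset = np.full(d, config.separation / np.sqrt(d))
        a = rng.normal(0.0, 1.0, size=(n, d))
        b = rng.normal(0.0, 1.0, size=(n, d)) + offset
    elif config.layout == "overlapping":
        a = rng.normal(0.0, 1.0, size=(n, d))
        b = rng.normal(0.0, 1.0, size=(n, d))
    else:  # nested: A tightly clustered inside B, same centroid
        a = rng.normal(0.0, 0.01, size=(n, d))
        b = rng.normal(0.0, 1.0, size=(n, d))
    return np.vstack([a, b]), labels


# ---------------------------------------------------------------------------
# RIL populations
# ---------------------------------------------------------------------------

@dataclass
class RILConfig:
    """Recombinant-inbred-line population derived from two parents.

    Genes are partitioned into ``n_markers`` contiguous blocks; each line
    draws an independent Bernoulli(0.5) genotype per block (no genetic
    map — only the group-level transcriptome contrast matters downstream).
    Polymorphic genes differ between the parents by ``parent_effect_log2``;
    a ``transgressive_fraction`` of the parent-equal genes nevertheless
    carry genotype-linked effects in the population, mirroring transgressive
    segregation (default 0.15 of parent-equal genes).
    """

    n_lines: int = 160
    n_genes: int = 1000
    n_markers: int = 50
    parent_effect_log2: float = 1.0
    polymorphic_fraction: float = 0.25
    transgressive_fraction: float = 0.15
    replicate_sd_log2: float = 0.15
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("polymorphic_fraction", "transgressive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_markers > self.n_genes:
            raise ValueError("n_markers must not exceed n_genes")
        if self.n_lines < 2 or self.n_genes < 1 or self.n_markers < 1:
            raise ValueError("n_lines, n_genes, n_markers must be positive (n_lines >= 2)")


@dataclass
class RILTruth:
    """Construction record for a synthetic RIL population."""

    gene_block: pd.Series          # gene -> marker (block) id
    polymorphic_genes: list[str]
    transgressive_genes: list[str]
    gene_effects: pd.Series        # genotype-linked log2 effect per gene
    parent_means: pd.DataFrame     # genes x ["parentA", "parentB"]


def generate_ril_population(
    config: RILConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, RILTruth]:
    """Simulate a RIL population.

    Returns
    -------
    (matrix, markers, metadata, truth)
        ``matrix``: genes × lines log2 expression (one array per line);
        ``markers``: binary markers × lines block-genotype table
        (1 = parent-B allele); ``metadata`` assigns every line to group
        ``"RIL"`` and batch ``"RIL"``.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_genes))
    genes = [f"R{i + 1:0{width}d}" for i in range(config.n_genes)]
    lines = [f"RIL{i + 1:03d}" for i in range(config.n_lines)]
    marker_ids = [f"M{i + 1:03d}" for i in range(config.n_markers)]

    # contiguous gene blocks, one marker per block
    block_of_gene = np.repeat(
        np.arange(config.n_markers),
        np.diff(np.linspace(0, config.n_genes, config.n_markers + 1).astype(int)),
    )
    genotypes = rng.integers(0, 2, size=(config.n_markers, config.n_lines))

    base = rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, config.n_genes)
    n_poly = int(round(config.polymorphic_fraction * config.n_genes))
    poly_idx = rng.choice(config.n_genes, size=n_poly, replace=False)
    poly_mask = np.zeros(config.n_genes, dtype=bool)
    poly_mask[poly_idx] = True
    equal_idx = np.flatnonzero(~poly_mask)
    n_trans = int(round(config.transgressive_fraction * len(equal_idx)))
    trans_idx = rng.choice(equal_idx, size=n_trans, replace=False)

    # genotype-linked effect per gene: parental difference for polymorphic
    # genes, transgressive line-specific effect (random sign) otherwise
    effects = np.zeros(config.n_genes)
    effects[poly_mask] = config.parent_effect_log2
    effects[trans_idx] = config.parent_effect_log2 * rng.choice(
        [-1.0, 1.0], size=n_trans
    )

    gene_geno = genotypes[block_of_gene, :]                       # genes x lines
    poly_contrib = np.where(poly_mask[:, None], gene_geno * effects[:, None], 0.0)
    trans_mask = np.zeros(config.n_genes, dtype=bool)
    trans_mask[trans_idx] = True
    trans_contrib = np.where(trans_mask[:, None], gene_geno * effects[:, None], 0.0)
    noise = rng.normal(0.0, config.replicate_sd_log2, size=gene_geno.shape)
    values = base[:, None] + poly_contrib + trans_contrib + noise

    matrix = pd.DataFrame(values, index=genes, columns=lines)
    markers = pd.DataFrame(genotypes, index=marker_ids, columns=lines)
    metadata = pd.DataFrame({"group": "RIL", "batch": "RIL"}, index=pd.Index(lines, name="sample"))
    parent_means = pd.DataFrame(
        {
            "parentA": base,
            "parentB": base + np.where(poly_mask, effects, 0.0),
        },
        index=genes,
    )
    truth = RILTruth(
        gene_block=pd.Series(block_of_gene, index=genes, name="block"),
        polymorphic_genes=[genes[i] for i in sorted(poly_idx)],
        transgressive_genes=[genes[i] for i in sorted(trans_idx)],
        gene_effects=pd.Series(effects, index=genes, name="effect"),
        parent_means=parent_means,
    )
    return matrix, markers, metadata, truth
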