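"""Transcriptome distance between sample groups in a retained PC subspace.

This is the analytical core of the package. The route is:

1. :func:`pca` — principal components of the meta-data matrix with genes
   as variables and samples as observations, computed through the n × n
   sample-space kernel so that tens of thousands of genes cost nothing.
2. :func:`horns_parallel_analysis` — how many components to retain, by
   comparing the observed eigenvalue spectrum against same-shape
   standard-normal data (95th-percentile criterion by default).
3. :func:`transcriptome_distance` — a bounded, rank-based group-separation
   statistic on the retained scores (optionally variance-weighted via
   :func:`weight_scores`): rank all pairwise Euclidean distances among the
   pooled samples (midranks for ties) and set

       D = (mean rank of between-group pairs − mean rank of within-group
            pairs) / (M / 2),        M = n(n−1)/2.

   D = 1 exactly when every between-group distance exceeds every
   within-group distance (no overlap); the permutation expectation of D is
   exactly 0 for exchangeable (fully overlapping) groups; D < 0 when one
   group nests inside the other. This is the ANOSIM R statistic of Clarke
   (1993) applied to PC scores.
4. :func:`permutation_test` — significance by exhaustive enumeration of
   the distinct balanced relabelings when feasible, Monte Carlo otherwise.
5. :func:`distance_matrix` / :func:`select_extreme_groups` — all-pairs
   group distances (intact above / weighted below the diagonal in the
   rendered table), and extreme-group selection along a leading PC axis
   for recombinant-inbred-line populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import rankdata

__all__ = [
    "PCAModel",
    "PermutationConfig",
    "PermutationResult",
    "DistanceResult",
    "pca",
    "horns_parallel_analysis",
    "weight_scores",
    "transcriptome_distance",
    "permutation_test",
    "distance_matrix",
    "format_distance_table",
    "select_extreme_groups",
]


# ---------------------------------------------------------------------------
# PCA via the sample-space kernel
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Sample scores and the eigenvalue spectrum of a centered matrix.

    ``scores`` (samples × components) reproduce the pairwise Euclidean
    distances of the gene-centered data exactly when all components are
    kept; ``eigenvalues`` are the kernel eigenvalues (component sums of
    squares, so they add up to the total centered sum of squares);
    ``explained_fraction`` is each eigenvalue over their sum.
    ``k_retained`` defaults to all non-trivial components and is narrowed
    by parallel analysis or an explicit override.
    """

    scores: pd.DataFrame
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    k_retained: int
    loadings: pd.DataFrame

    def retained_scores(self) -> pd.DataFrame:
        """Intact (un-weighted) scores on the retained components."""
        return self.scores.iloc[:, : self.k_retained]


def _kernel_eigen(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decompose the centered sample-space kernel.

    Returns (eigenvalues desc, sample eigenvectors, centered matrix).
    """
    centered = values - values.mean(axis=1, keepdims=True)
    kernel = centered.T @ centered
    w, u = np.linalg.eigh(kernel)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    u = u[:, order]
    return w, u, centered


def pca(matrix: pd.DataFrame) -> PCAModel:
    """Principal components of a genes × samples matrix.

    Genes are the variables: each gene is centered across samples and no
    unit-variance scaling is applied (the data are already on a common
    log2 scale). The decomposition runs on the n × n kernel of the
    centered matrix, so the gene dimension only enters through one matrix
    product. The trailing zero component of centering is dropped
    (``n_samples − 1`` components at most).
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    w, u, centered = _kernel_eigen(matrix.to_numpy(float))
    total = w.sum()
    if total <= 0:
        raise ValueError("matrix has no variance after centering")
    k = n - 1
    w = w[:k]
    u = u[:, :k]
    scores = u * np.sqrt(w)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        load = np.where(w > 0, 1.0, np.nan) * (centered @ u) / np.where(
            w > 0, np.sqrt(w), 1.0
        )
    load = np.nan_to_num(load)
    # deterministic sign: largest-|loading| gene positive per component
    for j in range(k):
        col = load[:, j]
        if col.size and col[np.argmax(np.abs(col))] < 0:
            load[:, j] = -col
            scores[:, j] = -scores[:, j]
    names = [f"PC{i + 1}" for i in range(k)]
    return PCAModel(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=names),
        eigenvalues=w,
        explained_fraction=w / total,
        k_retained=k,
        loadings=pd.DataFrame(load, index=matrix.index, columns=names),
    )


def horns_parallel_analysis(
    matrix: pd.DataFrame,
    n_iterations: int = 100,
    criterion: Literal["p95", "mean"] = "p95",
    seed: int | np.random.Generator | None = None,
) -> int:
    """Number of components to retain by Horn's parallel analysis.

    Standard-normal matrices of the observed shape are decomposed exactly
    like the data (gene-centered, sample-space kernel); a component is
    retained while its observed eigenvalue exceeds the criterion statistic
    (95th percentile by default, mean optionally) of the random
    eigenvalues at the same rank, stopping at the first failure.

    Both spectra are normalized to explained-variance fractions before
    comparison, making the decision invariant to the overall scale of the
    data (raw-eigenvalue comparison would retain nothing whenever the
    data's variance is far below 1). For unit-variance data the two
    comparisons coincide for all practical purposes.
    """
    if n_iterations < 10:
        raise ValueError("parallel analysis needs >= 10 iterations")
    if criterion not in ("p95", "mean"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = matrix.to_numpy(float)
    n_genes, n_samples = values.shape
    if n_samples < 3:
        raise ValueError("parallel analysis needs at least 3 samples")
    observed = _kernel_eigen(values)[0][: n_samples - 1]
    total = observed.sum()
    if total <= 0:
        raise ValueError("matrix has no variance after centering")
    observed = observed / total
    random_eigs = np.empty((n_iterations, n_samples - 1))
    for i in range(n_iterations):
        noise = rng.standard_normal((n_genes, n_samples))
        eigs = _kernel_eigen(noise)[0][: n_samples - 1]
        random_eigs[i] = eigs / eigs.sum()
    if criterion == "p95":
        threshold = np.percentile(random_eigs, 95, axis=0)
    else:
        threshold = random_eigs.mean(axis=0)
    exceeds = observed > threshold
    k = 0
    for flag in exceeds:
        if not flag:
            break
        k += 1
    return k


def weight_scores(model: PCAModel) -> pd.DataFrame:
    """Variance-weighted scores: each retained component's scores
    multiplied by the fraction of variance that component explains.

    Because the downstream distance statistic is rank-based, weighting by
    fractions or percentages is equivalent (a uniform ×100 rescale cannot
    change distance ranks).
    """
    if model.k_retained < 1:
        raise ValueError("no retained components to weight")
    k = model.k_retained
    return model.scores.iloc[:, :k] * model.explained_fraction[:k]


# ---------------------------------------------------------------------------
# the distance statistic
# ---------------------------------------------------------------------------

def _as_scores_labels(
    scores, labels
) -> tuple[np.ndarray, np.ndarray, list]:
    values = scores.to_numpy(float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, float)
    if values.ndim == 1:
        values = values[:, None]
    labels = np.asarray(list(labels))
    if len(labels) != values.shape[0]:
        raise ValueError("one label per sample required")
    groups = list(dict.fromkeys(labels))
    return values, labels, groups


def _pair_rank_setup(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Condensed pairwise distances, their midranks, and pair indices."""
    n = values.shape[0]
    dists = pdist(values)
    ranks = rankdata(dists)  # midranks for ties
    iu, ju = np.triu_indices(n, k=1)
    return ranks, iu, ju


def _rank_statistic(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    between = ~within
    return float(
        (ranks[between].mean() - ranks[within].mean()) / (m / 2.0)
    )


def transcriptome_distance(scores, labels) -> float:
    """Rank-based separation D ∈ [−1, 1] of two sample groups.

    All n(n−1)/2 pairwise Euclidean distances among the pooled samples are
    ranked ascending (midranks for ties); D is the difference between the
    mean rank of between-group pairs and the mean rank of within-group
    pairs, normalized by M/2. Both groups need at least two samples (a
    singleton group has no within-group pairs).
    """
    values, labels, groups = _as_scores_labels(scores, labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    sizes = [(labels == g).sum() for g in groups]
    if min(sizes) < 2:
        raise ValueError("each group needs >= 2 samples")
    ranks, iu, ju = _pair_rank_setup(values)
    in_first = labels == groups[0]
    within = in_first[iu] == in_first[ju]
    return _rank_statistic(ranks, within)


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------

@dataclass
class PermutationConfig:
    """Scheme for the label-permutation null of the distance statistic.

    When the number of distinct balanced relabelings (group sizes fixed;
    for equal sizes the two mirror-image labelings count once) does not
    exceed ``exact_enumeration_threshold``, the null is enumerated
    exhaustively and the p-value is exact; otherwise ``n_permutations``
    Monte-Carlo draws are used with the add-one correction. The default
    sidedness tests for separation (``greater``); ``two_sided`` uses |D|.
    """

    n_permutations: int = 999
    exact_enumeration_threshold: int = 10000
    sidedness: Literal["greater", "two_sided"] = "greater"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.sidedness not in ("greater", "two_sided"):
            raise ValueError(f"unknown sidedness {self.sidedness!r}")


@dataclass
class PermutationResult:
    p_value: float
    d_observed: float
    scheme: Literal["exact", "monte_carlo"]
    n_labelings: int               # distinct assignments enumerated, or draws


def n_distinct_labelings(n1: int, n2: int) -> int:
    """Distinct balanced relabelings of n1+n2 samples into groups of the
    observed sizes, collapsing the group-name swap when sizes are equal."""
    total = comb(n1 + n2, n1)
    return total // 2 if n1 == n2 else total


def _null_distances(
    ranks: np.ndarray,
    iu: np.ndarray,
    ju: np.ndarray,
    n: int,
    n1: int,
    exact: bool,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """D under relabeling: all distinct assignments (exact) or MC draws.

    Vectorized over assignments: the within/between pair counts are fixed
    by the group sizes, so D for every assignment reduces to two masked
    rank sums.
    """
    n2 = n - n1
    if exact:
        equal = n1 == n2
        members_iter = (
            m for m in combinations(range(n), n1) if not equal or 0 in m
        )
        member_rows = np.fromiter(
            (i for m in members_iter for i in m), dtype=np.intp
        ).reshape(-1, n1)
        in_first = np.zeros((member_rows.shape[0], n), dtype=bool)
        np.put_along_axis(in_first, member_rows, True, axis=1)
    else:
        in_first = np.zeros((n_draws, n), dtype=bool)
        for row in range(n_draws):
            in_first[row, rng.choice(n, size=n1, replace=False)] = True
    within = in_first[:, iu] == in_first[:, ju]
    m = ranks.size
    m_w = n1 * (n1 - 1) // 2 + n2 * (n2 - 1) // 2
    m_b = m - m_w
    sum_w = within @ ranks
    sum_b = ranks.sum() - sum_w
    return (sum_b / m_b - sum_w / m_w) / (m / 2.0)


def permutation_test(
    scores, labels, config: PermutationConfig | None = None
) -> PermutationResult:
    """Significance of the observed distance under group-label permutation.

    Exact mode: p = (#assignments with D ≥ D_obs) / (#assignments), the
    observed labeling included — so the smallest attainable p is
    1/#assignments (0.1 for two groups of three). Monte-Carlo mode:
    p = (1 + #{D_perm ≥ D_obs}) / (1 + n_permutations). ``two_sided``
    compares |D| instead of D.
    """
    config = config or PermutationConfig()
    values, labels, groups = _as_scores_labels(scores, labels)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    n1 = int((labels == groups[0]).sum())
    n2 = int((labels == groups[1]).sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs >= 2 samples")
    n = n1 + n2
    ranks, iu, ju = _pair_rank_setup(values)
    in_first = labels == groups[0]
    d_obs = _rank_statistic(ranks, in_first[iu] == in_first[ju])

    n_exact = n_distinct_labelings(n1, n2)
    exact = n_exact <= config.exact_enumeration_threshold
    rng = np.random.default_rng(config.seed)
    null = _null_distances(
        ranks, iu, ju, n, n1, exact, config.n_permutations, rng
    )
    if config.sidedness == "two_sided":
        null, ref = np.abs(null), abs(d_obs)
    else:
        ref = d_obs
    hits = int((null >= ref - 1e-12).sum())
    if exact:
        p = hits / n_exact
        return PermutationResult(p, d_obs, "exact", n_exact)
    p = (1 + hits) / (1 + config.n_permutations)
    return PermutationResult(p, d_obs, "monte_carlo", config.n_permutations)


# ---------------------------------------------------------------------------
# group-by-group distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceResult:
    """Distance between one pair of groups, intact and weighted variants."""

    group_a: str
    group_b: str
    d_intact: float
    d_weighted: float
    p_intact: float
    p_weighted: float
    scheme: str
    n_labelings: int
    group_sizes: tuple[int, int]

    def significant(self, alpha: float = 0.05, variant: str = "intact") -> bool:
        p = self.p_intact if variant == "intact" else self.p_weighted
        return p < alpha


def distance_matrix(
    model: PCAModel,
    labels,
    config: PermutationConfig | None = None,
    groups: Sequence[str] | None = None,
) -> dict[tuple[str, str], DistanceResult]:
    """All-pairs group distances on the retained subspace.

    For every unordered group pair, D is computed on the intact retained
    scores and on the variance-weighted scores, each with its own
    permutation p-value. Groups with fewer than two samples are rejected.
    """
    config = config or PermutationConfig()
    labels = pd.Series(list(labels), index=model.scores.index)
    if groups is None:
        groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    intact = model.retained_scores()
    weighted = weight_scores(model)
    results: dict[tuple[str, str], DistanceResult] = {}
    for idx, a in enumerate(groups):
        for b in groups[idx + 1 :]:
            mask = labels.isin([a, b]).to_numpy()
            sub_labels = labels[mask].to_numpy()
            seed = None if config.seed is None else config.seed
            pair_config = PermutationConfig(
                n_permutations=config.n_permutations,
                exact_enumeration_threshold=config.exact_enumeration_threshold,
                sidedness=config.sidedness,
                seed=seed,
            )
            res_i = permutation_test(
                intact.to_numpy()[mask], sub_labels, pair_config
            )
            res_w = permutation_test(
                weighted.to_numpy()[mask], sub_labels, pair_config
            )
            results[(a, b)] = DistanceResult(
                group_a=a,
                group_b=b,
                d_intact=res_i.d_observed,
                d_weighted=res_w.d_observed,
                p_intact=res_i.p_value,
                p_weighted=res_w.p_value,
                scheme=res_i.scheme,
                n_labelings=res_i.n_labelings,
                group_sizes=(
                    int((sub_labels == a).sum()),
                    int((sub_labels == b).sum()),
                ),
            )
    return results


def format_distance_table(
    results: dict[tuple[str, str], DistanceResult],
    groups: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Render the pairwise distances as one square table: intact distances
    above the diagonal, weighted below, significant entries marked '*'."""
    if groups is None:
        seen: list[str] = []
        for a, b in results:
            for g in (a, b):
                if g not in seen:
                    seen.append(g)
        groups = seen
    table = pd.DataFrame("", index=list(groups), columns=list(groups), dtype=object)
    for g in groups:
        table.loc[g, g] = "-"
    for (a, b), res in results.items():
        ia, ib = groups.index(a), groups.index(b)
        upper, lower = ((a, b) if ia < ib else (b, a)), None
        star_i = "*" if res.p_intact < alpha else ""
        star_w = "*" if res.p_weighted < alpha else ""
        row_u, col_u = (a, b) if ia < ib else (b, a)
        table.loc[row_u, col_u] = f"{res.d_intact:.2f}{star_i}"
        table.loc[col_u, row_u] = f"{res.d_weighted:.2f}{star_w}"
    return table


# ---------------------------------------------------------------------------
# extreme-group selection (RIL populations)
# ---------------------------------------------------------------------------

def select_extreme_groups(
    scores,
    n_pcs: int,
    group_size: int,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list, list]:
    """Pick the two most separated groups along a leading PC axis.

    Samples are projected onto the first ``n_pcs`` components and ordered
    along the direction of maximal variance within that subspace (its
    first component); the ``group_size`` lowest- and highest-scoring
    samples form the two groups. Ties are broken by position in the input
    (sample-ID order), so the selection is deterministic.
    """
    if isinstance(scores, pd.DataFrame):
        if sample_ids is None:
            sample_ids = list(scores.index)
        values = scores.to_numpy(float)
    else:
        values = np.asarray(scores, float)
        if values.ndim == 1:
            values = values[:, None]
        if sample_ids is None:
            sample_ids = list(range(values.shape[0]))
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    if values.shape[0] < 2 * group_size:
        raise ValueError("need at least 2 * group_size samples")
    axis = values[:, 0]  # first component of the chosen subspace
    order = np.argsort(axis, kind="stable")
    low = [sample_ids[i] for i in order[:group_size]]
    high = [sample_ids[i] for i in order[-group_size:]]
    return low, high
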