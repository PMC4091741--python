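"""PCA, parallel analysis, the rank-based distance and its permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from txdist import distance, simulate
from txdist.distance import PermutationConfig
from txdist.simulate import GeometryConfig, RILConfig


# ---------------------------------------------------------------------------
# independent oracle: sort-and-average rank statistic, written from scratch
# ---------------------------------------------------------------------------

def _midranks_by_counting(values):
    values = np.asarray(values, float)
    ranks = np.empty(len(values))
    for i, v in enumerate(values):
        ranks[i] = (values < v).sum() + ((values == v).sum() + 1) / 2.0
    return ranks


def _distance_oracle(points, labels):
    points = np.atleast_2d(np.asarray(points, float))
    n = len(points)
    dists, within = [], []
    for i in range(n):
        for j in range(i + 1, n):
            dists.append(float(np.linalg.norm(points[i] - points[j])))
            within.append(labels[i] == labels[j])
    ranks = _midranks_by_counting(dists)
    r_b = np.mean([r for r, w in zip(ranks, within) if not w])
    r_w = np.mean([r for r, w in zip(ranks, within) if w])
    return (r_b - r_w) / (len(dists) / 2.0)


def _random_instance(rng):
    n1, n2 = rng.integers(2, 5, size=2)
    dim = rng.integers(1, 4)
    points = rng.normal(0, 1, (n1 + n2, dim))
    labels = np.array(["A"] * n1 + ["B"] * n2)
    return points, labels


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(rng.normal(8, 1, (40, 5)),
                              columns=[f"s{i}" for i in range(5)])
        matrix["s_dup"] = matrix["s0"]
        model = distance.pca(matrix)
        assert np.allclose(model.scores.loc["s0"], model.scores.loc["s_dup"],
                           atol=1e-8)

    def test_eigenvalues_sum_to_total_centered_variance(self):
        rng = np.random.default_rng(1)
        matrix = pd.DataFrame(rng.normal(8, 2, (60, 7)))
        model = distance.pca(matrix)
        centered = matrix.to_numpy() - matrix.to_numpy().mean(1, keepdims=True)
        assert np.isclose(model.eigenvalues.sum(), (centered**2).sum())
        assert np.isclose(model.explained_fraction.sum(), 1.0, atol=1e-9)

    def test_scores_reproduce_sample_distances(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(rng.normal(0, 1, (30, 6)))
        model = distance.pca(matrix)
        centered = matrix.to_numpy() - matrix.to_numpy().mean(1, keepdims=True)
        assert np.allclose(pdist(model.scores.to_numpy()), pdist(centered.T),
                           atol=1e-8)

    def test_known_principal_axis_at_45_degrees(self):
        rng = np.random.default_rng(3)
        t = rng.normal(0, 2, 50)
        matrix = pd.DataFrame(np.vstack([t, t]), index=["g1", "g2"])
        model = distance.pca(matrix)
        v = model.loadings["PC1"].to_numpy()
        assert np.allclose(np.abs(v), 1 / np.sqrt(2), atol=1e-8)
        assert v[0] * v[1] > 0  # along (1, 1)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            distance.pca(pd.DataFrame(np.ones((5, 2))))


class TestParallelAnalysis:
    def test_pure_noise_retains_nothing(self):
        zeros = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            matrix = pd.DataFrame(rng.standard_normal((300, 10)))
            k = distance.horns_parallel_analysis(matrix, 100, seed=seed + 1000)
            zeros += k == 0
        assert zeros >= 27  # >= 90% of seeds

    def test_three_orthogonal_factors_retained(self):
        """Three mutually orthogonal ±1 sample factors dominating the noise
        are all retained."""
        rng = np.random.default_rng(4)
        factors = np.array([
            [1, 1, 1, 1, -1, -1, -1, -1],
            [1, 1, -1, -1, 1, 1, -1, -1],
            [1, -1, 1, -1, 1, -1, 1, -1],
        ], float)
        values = rng.normal(0, 0.1, (600, 8))
        for f in range(3):
            values[f * 60 : (f + 1) * 60] += 2.0 * factors[f]
        k = distance.horns_parallel_analysis(pd.DataFrame(values), 60, seed=5)
        assert k >= 3

    def test_mean_criterion_never_stricter_than_p95(self):
        rng = np.random.default_rng(6)
        matrix = pd.DataFrame(rng.standard_normal((200, 8)))
        k95 = distance.horns_parallel_analysis(matrix, 60, "p95", seed=7)
        kmean = distance.horns_parallel_analysis(matrix, 60, "mean", seed=7)
        assert kmean >= k95

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError, match="10 iterations"):
            distance.horns_parallel_analysis(pd.DataFrame(np.ones((5, 4))), 5)


class TestWeighting:
    @staticmethod
    def _model_from_geometry(layout="separated", **kwargs):
        scores, labels = simulate.generate_group_geometry(
            GeometryConfig(layout=layout, **kwargs)
        )
        matrix = pd.DataFrame(scores.T)  # dims as genes, samples as columns
        return distance.pca(matrix), labels

    def test_single_component_weighting_preserves_distance(self):
        model, labels = self._model_from_geometry(n_per_group=4, seed=8)
        model.k_retained = 1
        d_intact = distance.transcriptome_distance(model.retained_scores(), labels)
        d_weighted = distance.transcriptome_distance(
            distance.weight_scores(model), labels
        )
        assert d_intact == pytest.approx(d_weighted, abs=1e-12)

    def test_equal_eigenvalue_weighting_preserves_distance(self):
        model, labels = self._model_from_geometry(n_per_group=4, seed=9)
        model.explained_fraction = np.full_like(
            model.explained_fraction, 1 / len(model.explained_fraction)
        )
        d_intact = distance.transcriptome_distance(model.retained_scores(), labels)
        d_weighted = distance.transcriptome_distance(
            distance.weight_scores(model), labels
        )
        assert d_intact == pytest.approx(d_weighted, abs=1e-12)

    def test_fraction_vs_percentage_weighting_identical(self):
        model, labels = self._model_from_geometry(
            layout="overlapping", n_per_group=5, seed=10
        )
        w_frac = distance.weight_scores(model)
        w_pct = w_frac * 100.0
        assert distance.transcriptome_distance(
            w_frac, labels
        ) == pytest.approx(distance.transcriptome_distance(w_pct, labels), abs=1e-12)

    def test_weighting_shrinks_minor_axes(self):
        model, _ = self._model_from_geometry(n_per_group=5, seed=11, dim=3)
        model.k_retained = 3  # the geometry spans exactly three axes
        weighted = distance.weight_scores(model)
        ratio_intact = model.retained_scores().std()
        ratio_weighted = weighted.std()
        # relative spread of later components shrinks by their smaller share
        assert (
            ratio_weighted.iloc[-1] / ratio_weighted.iloc[0]
            < ratio_intact.iloc[-1] / ratio_intact.iloc[0]
        )


# ---------------------------------------------------------------------------
# the distance statistic
# ---------------------------------------------------------------------------

class TestTranscriptomeDistance:
    def test_no_overlap_gives_one(self):
        d = distance.transcriptome_distance(
            np.array([[0.0], [1.0], [10.0], [11.0]]), ["A", "A", "B", "B"]
        )
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_nested_example(self):
        d = distance.transcriptome_distance(
            np.array([[0.0], [1.0], [0.1], [0.2]]), ["A", "A", "B", "B"]
        )
        assert d == pytest.approx(-0.125, abs=1e-12)

    def test_mean_over_balanced_relabelings_is_zero(self):
        """The permutation expectation of D is exactly 0 (the exchangeable,
        fully-overlapping reference point)."""
        from itertools import combinations
        rng = np.random.default_rng(12)
        points = rng.normal(0, 1, (6, 2))
        values = []
        seen = set()
        for members in combinations(range(6), 3):
            key = frozenset(members)
            mirror = frozenset(set(range(6)) - key)
            if mirror in seen:
                continue
            seen.add(key)
            labels = np.where(np.isin(np.arange(6), members), "A", "B")
            values.append(distance.transcriptome_distance(points, labels))
        assert len(values) == 10
        assert abs(np.mean(values)) < 1e-12

    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            points, labels = _random_instance(rng)
            d = distance.transcriptome_distance(points, labels)
            assert abs(d - _distance_oracle(points, labels)) < 1e-12
            assert -1.0 - 1e-12 <= d <= 1.0 + 1e-12

    def test_matches_anosim_r(self):
        """Agreement with scikit-bio's ANOSIM test statistic (independent
        implementation of the same rank statistic)."""
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(14)
        for _ in range(20):
            points, labels = _random_instance(rng)
            dm = skbio_distance.DistanceMatrix(
                squareform(pdist(points)), [str(i) for i in range(len(points))]
            )
            r = skbio_distance.anosim(dm, list(labels), permutations=0)
            assert distance.transcriptome_distance(points, labels) == pytest.approx(
                r["test statistic"], abs=1e-12
            )

    def test_one_iff_complete_separation(self):
        scores, labels = simulate.generate_group_geometry(
            GeometryConfig(layout="separated", separation=100, n_per_group=3, seed=15)
        )
        assert distance.transcriptome_distance(scores, labels) == 1.0
        # breaking complete separation breaks D = 1
        scores2 = scores.copy()
        scores2[0] = scores[labels == "B"].mean(0)
        assert distance.transcriptome_distance(scores2, labels) < 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rank_invariances(self, seed):
        """D is invariant to translation, rotation, uniform scaling and the
        group-name swap; always in [-1, 1]."""
        rng = np.random.default_rng(seed)
        points, labels = _random_instance(rng)
        d = distance.transcriptome_distance(points, labels)
        assert -1.0 - 1e-12 <= d <= 1.0 + 1e-12
        shift = rng.normal(0, 10, points.shape[1])
        q, _ = np.linalg.qr(rng.normal(0, 1, (points.shape[1], points.shape[1])))
        transformed = (points + shift) @ q * 3.7
        assert distance.transcriptome_distance(transformed, labels) == pytest.approx(
            d, abs=1e-9
        )
        swapped = np.where(labels == "A", "B", "A")
        assert distance.transcriptome_distance(points, swapped) == pytest.approx(
            d, abs=1e-12
        )

    def test_errors(self):
        with pytest.raises(ValueError, match="two groups"):
            distance.transcriptome_distance(np.ones((4, 2)), ["A"] * 4)
        with pytest.raises(ValueError, match=">= 2"):
            distance.transcriptome_distance(
                np.ones((3, 2)), ["A", "A", "B"]
            )


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------

class TestPermutationTest:
    def test_three_vs_three_minimum_p(self):
        """With 3 + 3 samples there are 10 distinct labelings, so even the
        maximal distance D = 1 cannot reach p < 0.05."""
        scores, labels = simulate.generate_group_geometry(
            GeometryConfig(layout="separated", separation=100, n_per_group=3, seed=16)
        )
        result = distance.permutation_test(scores, labels)
        assert result.scheme == "exact"
        assert result.n_labelings == 10
        assert result.d_observed == 1.0
        assert result.p_value == pytest.approx(0.1)
        assert result.p_value >= 0.05

    def test_two_vs_two_exact_third(self):
        scores, labels = simulate.generate_group_geometry(
            GeometryConfig(layout="separated", separation=100, n_per_group=2, seed=17)
        )
        result = distance.permutation_test(scores, labels)
        assert result.n_labelings == 3
        assert result.p_value == pytest.approx(1 / 3)

    def test_null_type_one_error(self):
        """Exact p under a true null rejects at ~nominal level (500 sims)."""
        rng = np.random.default_rng(18)
        labels = ["A"] * 5 + ["B"] * 5
        rejections = 0
        for _ in range(500):
            points = rng.normal(0, 1, (10, 3))
            result = distance.permutation_test(points, labels)
            rejections += result.p_value <= 0.05
        rate = rejections / 500
        se = np.sqrt(0.05 * 0.95 / 500)
        assert abs(rate - 0.05) < 3 * se

    def test_exact_matches_monte_carlo(self):
        scores, labels = simulate.generate_group_geometry(
            GeometryConfig(layout="overlapping", n_per_group=5, seed=19)
        )
        exact = distance.permutation_test(scores, labels)
        mc = distance.permutation_test(
            scores, labels,
            PermutationConfig(exact_enumeration_threshold=1,
                              n_permutations=10_000, seed=20),
        )
        assert exact.scheme == "exact" and mc.scheme == "monte_carlo"
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 10_000)
        assert abs(mc.p_value - exact.p_value) < 3 * se + 1e-4

    def test_two_sided_uses_magnitude(self):
        """On a child configuration (negative D) the one-sided-greater p is
        large while the two-sided p counts |D|; both match enumeration."""
        from itertools import combinations
        points = np.array([[0.0], [1.0], [0.1], [0.2]])
        labels = np.array(["A", "A", "B", "B"])
        greater = distance.permutation_test(
            points, labels, PermutationConfig(sidedness="greater")
        )
        two_sided = distance.permutation_test(
            points, labels, PermutationConfig(sidedness="two_sided")
        )
        assert greater.d_observed == pytest.approx(-0.125)
        # manual enumeration of the 3 distinct balanced labelings
        null = []
        for members in combinations(range(4), 2):
            if 0 not in members:
                continue
            lab = np.where(np.isin(np.arange(4), members), "A", "B")
            null.append(distance.transcriptome_distance(points, lab))
        assert greater.p_value == pytest.approx(
            np.mean([d >= -0.125 - 1e-12 for d in null])
        )
        assert two_sided.p_value == pytest.approx(
            np.mean([abs(d) >= 0.125 - 1e-12 for d in null])
        )

    def test_mean_distance_monotone_in_separation(self):
        means = []
        for sep in (0.5, 2.0, 5.0, 20.0):
            ds = []
            for seed in range(20):
                scores, labels = simulate.generate_group_geometry(
                    GeometryConfig(layout="separated", separation=sep,
                                   n_per_group=4, seed=seed)
                )
                ds.append(distance.transcriptome_distance(scores, labels))
            means.append(np.mean(ds))
        assert all(x <= y + 1e-12 for x, y in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# distance matrices and extreme groups
# ---------------------------------------------------------------------------

def _model_from_scores(scores) -> distance.PCAModel:
    matrix = pd.DataFrame(np.asarray(scores, float).T)
    return distance.pca(matrix)


class TestDistanceMatrix:
    def test_three_separated_groups_all_one(self):
        rng = np.random.default_rng(22)
        centers = np.array([[0, 0], [100, 0], [0, 100]], float)
        scores = np.vstack([rng.normal(0, 1, (3, 2)) + c for c in centers])
        labels = ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3
        model = _model_from_scores(scores)
        results = distance.distance_matrix(model, labels,
                                           PermutationConfig(seed=0))
        assert len(results) == 3
        for res in results.values():
            assert res.d_intact == pytest.approx(1.0)
            assert res.scheme == "exact"

    def test_duplicated_group_near_zero(self):
        ds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.normal(0, 1, (10, 3))
            labels = ["X"] * 5 + ["Y"] * 5  # same law, two names
            ds.append(distance.transcriptome_distance(scores, labels))
        assert abs(np.mean(ds)) < 0.1
        assert np.mean(np.abs(ds)) < 0.3

    def test_symmetry_under_group_order(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(0, 1, (9, 2))
        labels_ab = ["A"] * 4 + ["B"] * 5
        labels_ba = ["B"] * 4 + ["A"] * 5
        assert distance.transcriptome_distance(
            scores, labels_ab
        ) == pytest.approx(
            distance.transcriptome_distance(scores, labels_ba), abs=1e-12
        )

    def test_rendered_table_layout(self):
        rng = np.random.default_rng(24)
        scores = np.vstack([rng.normal(0, 1, (3, 2)),
                            rng.normal(50, 1, (3, 2))])
        model = _model_from_scores(scores)
        results = distance.distance_matrix(model, ["A"] * 3 + ["B"] * 3,
                                           PermutationConfig(seed=1))
        table = distance.format_distance_table(results)
        assert table.loc["A", "A"] == "-"
        assert table.loc["A", "B"].startswith("1.00")   # intact above diagonal
        res = results[("A", "B")]
        assert table.loc["B", "A"].startswith(f"{res.d_weighted:.2f}")


class TestSelectExtremeGroups:
    def test_one_dimensional_selection(self):
        scores = np.array([-5.0, -4.0, -3.0, 0.0, 3.0, 4.0, 5.0])[:, None]
        ids = list("abcdefg")
        low, high = distance.select_extreme_groups(scores, 1, 3, ids)
        assert low == ["a", "b", "c"]
        assert high == ["e", "f", "g"]

    def test_ties_broken_by_input_order(self):
        scores = np.array([1.0, 1.0, 0.0, 0.0, 2.0, 2.0])[:, None]
        ids = list("abcdef")
        low, high = distance.select_extreme_groups(scores, 1, 2, ids)
        assert low == ["c", "d"]
        assert high == ["e", "f"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="group_size"):
            distance.select_extreme_groups(np.ones((4, 1)), 1, 3)

    def test_ril_extreme_groups_beat_random_groups(self):
        """Expression-selected extreme groups of a RIL population are more
        separated than random groups of the same size."""
        selected, random_ = [], []
        for seed in range(20):
            config = RILConfig(n_lines=30, n_genes=300, n_markers=10,
                               polymorphic_fraction=0.3, seed=seed)
            matrix, _, _, _ = simulate.generate_ril_population(config)
            model = distance.pca(matrix)
            scores = model.scores.iloc[:, :3]
            low, high = distance.select_extreme_groups(scores, 3, 5)
            sel = scores.loc[list(low) + list(high)]
            selected.append(distance.transcriptome_distance(
                sel, ["L"] * 5 + ["H"] * 5
            ))
            rng = np.random.default_rng(seed + 500)
            pick = rng.choice(scores.index, 10, replace=False)
            random_.append(distance.transcriptome_distance(
                scores.loc[pick], ["L"] * 5 + ["H"] * 5
            ))
        assert np.mean(selected) > np.mean(random_)
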