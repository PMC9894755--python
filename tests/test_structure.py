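import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
import skbio.stats.distance as skbio_distance

from vagmet.structure import (
    DistanceMatrix,
    cluster_robustness,
    compute_distance,
    contingency_association,
    kmedoids_fit,
    mantel,
    match_clusters,
    permanova,
    select_k_gap,
)

from conftest import toy_matrix


def blob_distance(centers, n_per, spread, seed=0, metric="canberra"):
    rng = np.random.default_rng(seed)
    pts = np.vstack([c + rng.normal(0, spread, size=(n_per, len(c))) for c in centers])
    df = pd.DataFrame(pts, index=[f"s{i}" for i in range(len(pts))])
    return df, compute_distance(df, metric)


class TestComputeDistance:
    def test_identical_rows_distance_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert compute_distance(df, "canberra").D[0, 1] == 0.0

    def test_canberra_known_value(self):
        df = pd.DataFrame([[1.0, 2.0, 0.0], [3.0, 2.0, 0.0]], index=["a", "b"])
        # |1-3|/(1+3) = 0.5; equal and 0/0 coordinates contribute 0
        assert compute_distance(df, "canberra").D[0, 1] == pytest.approx(0.5)

    def test_bray_curtis_disjoint_supports(self):
        df = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert compute_distance(df, "bray_curtis").D[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_rejects_negative(self):
        df = pd.DataFrame([[1.0, -0.1], [0.5, 0.2]], index=["a", "b"])
        with pytest.raises(ValueError, match="non-negative"):
            compute_distance(df, "bray_curtis")

    def test_incomplete_matrix_rejected(self):
        m = toy_matrix([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            compute_distance(m)


class TestPermanova:
    def test_two_tight_pairs_exhaustive_p_is_one_third(self):
        df = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]],
            index=list("abcd"),
        )
        D = compute_distance(df, "canberra")
        res = permanova(D, ["x", "x", "y", "y"], n_permutations="exhaustive")
        assert res.p == pytest.approx(1 / 3)

    def test_pseudo_f_matches_skbio(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(12, 4)), index=[f"s{i}" for i in range(12)])
        D = compute_distance(df, "canberra")
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova(D, groups, n_permutations=99, seed=0)
        ref = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(D.D, ids=D.sample_ids), groups, permutations=0
        )
        assert ours.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_random_permutation_p_approaches_exhaustive(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"s{i}" for i in range(6)])
        D = compute_distance(df, "canberra")
        groups = ["a", "a", "a", "b", "b", "b"]
        exact = permanova(D, groups, n_permutations="exhaustive").p
        approx = permanova(D, groups, n_permutations=4999, seed=2).p
        assert abs(approx - exact) < 0.05

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(10, 3)), index=[f"s{i}" for i in range(10)])
        D = compute_distance(df, "canberra")
        groups = np.array(["a", "b"] * 5)
        perm = rng.permutation(10)
        D2 = DistanceMatrix([D.sample_ids[i] for i in perm], D.D[np.ix_(perm, perm)], "canberra")
        r1 = permanova(D, groups, n_permutations=99, seed=3)
        r2 = permanova(D2, groups[perm], n_permutations=99, seed=3)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)

    def test_p_never_zero(self):
        df = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [9.0, 9.0], [9.1, 9.0]], index=list("abcd")
        )
        D = compute_distance(df, "canberra")
        assert permanova(D, ["x", "x", "y", "y"], n_permutations=999, seed=0).p > 0

    def test_degenerate_groups_rejected(self):
        df = pd.DataFrame(np.eye(4), index=list("abcd"))
        D = compute_distance(df, "canberra")
        with pytest.raises(ValueError):
            permanova(D, ["x"] * 4)
        with pytest.raises(ValueError):
            permanova(D, ["x", "x", "x", "y"])


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"s{i}" for i in range(8)])
        D = compute_distance(df, "canberra")
        r, _ = mantel(D, D, n_permutations=99, seed=1)
        assert r == pytest.approx(1.0)

    def test_mismatched_samples_rejected(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(6, 3)), index=[f"s{i}" for i in range(6)])
        D1 = compute_distance(df, "canberra")
        df2 = df.copy()
        df2.index = [f"t{i}" for i in range(6)]
        D2 = compute_distance(df2, "canberra")
        with pytest.raises(ValueError, match="sample"):
            mantel(D1, D2)


class TestKMedoids:
    def test_k_equals_n_zero_dispersion(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(5, 3)), index=[f"s{i}" for i in range(5)])
        D = compute_distance(df, "canberra")
        fit = kmedoids_fit(D, 5, seed=0)
        assert fit.within_dispersion == 0.0
        assert sorted(fit.medoids) == sorted(D.sample_ids)

    def test_recovers_two_planted_blobs(self):
        _, D = blob_distance([np.zeros(4) + 1, np.zeros(4) + 50], 10, 0.1, seed=3)
        fit = kmedoids_fit(D, 2, seed=0)
        labels = fit.labels(D.sample_ids)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 5)), index=[f"s{i}" for i in range(30)])
        D = compute_distance(df, "canberra")
        f1 = kmedoids_fit(D, 3, seed=9)
        f2 = kmedoids_fit(D, 3, seed=9)
        assert f1.assignment == f2.assignment

    def test_k_out_of_range_rejected(self):
        df = pd.DataFrame(np.eye(3), index=list("abc"))
        D = compute_distance(df, "canberra")
        with pytest.raises(ValueError):
            kmedoids_fit(D, 4)


class TestGapStatistic:
    def test_curve_length_and_dispersion_monotone(self):
        df, D = blob_distance([np.zeros(3), np.zeros(3) + 20, np.zeros(3) - 20], 12, 0.5, seed=1)
        gap = select_k_gap(df, D, k_range=range(1, 7), B=10, seed=0, n_init=3)
        assert len(gap.gap) == 6
        assert all(a >= b - 1e-9 for a, b in zip(gap.W_k, gap.W_k[1:]))

    def test_single_blob_chooses_one(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(0, 1, size=(40, 1)), index=[f"s{i}" for i in range(40)])
        D = compute_distance(df, "canberra")
        gap = select_k_gap(df, D, k_range=range(1, 6), B=10, seed=0, n_init=3)
        assert gap.chosen_k == 1

    def test_degenerate_identical_points_rejected(self):
        df = pd.DataFrame(np.ones((5, 2)), index=[f"s{i}" for i in range(5)])
        D = compute_distance(df, "canberra")
        with pytest.raises(ValueError, match="degenerate"):
            select_k_gap(df, D, k_range=range(1, 3), B=10)


class TestMatchClusters:
    def test_label_permutation_invariance(self):
        ref = {f"s{i}": i % 3 for i in range(12)}
        new = {s: (c + 1) % 3 for s, c in ref.items()}
        _, acc = match_clusters(ref, new)
        assert acc == 1.0

    def test_one_moved_sample(self):
        ref = {f"s{i}": i % 2 for i in range(10)}
        new = dict(ref)
        new["s0"] = 1 - new["s0"]
        _, acc = match_clusters(ref, new)
        assert acc == pytest.approx(9 / 10)

    def test_surplus_labels_vs_brute_force(self):
        """3 new labels vs 2 reference labels: optimal injection checked by
        brute force over all label injections on the contingency table."""
        ref = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        new = {"a": 0, "b": 0, "c": 2, "d": 1, "e": 1, "f": 2}
        _, acc = match_clusters(ref, new)
        best = 0
        for mapping in itertools.permutations([0, 1, None], 3):
            matched = sum(
                1 for s in ref if mapping[new[s]] is not None and mapping[new[s]] == ref[s]
            )
            best = max(best, matched)
        assert acc == pytest.approx(best / 6)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            match_clusters({"a": 0}, {"b": 0})


@pytest.fixture(scope="module")
def planted():
    df, D = blob_distance(
        [np.zeros(5), np.zeros(5) + 30, np.zeros(5) - 30], 20, 0.3, seed=8
    )
    return df, D, kmedoids_fit(D, 3, seed=0)


class TestClusterRobustness:

    def test_full_fraction_gives_perfect_accuracy(self, planted):
        df, D, ref = planted
        rep = cluster_robustness(df, D, ref, n_subsamples=5, fraction=1.0, seed=1)
        assert rep.accuracies == [1.0] * 5
        assert rep.n_above_95 == 5

    def test_well_separated_clusters_are_stable(self, planted):
        df, D, ref = planted
        rep = cluster_robustness(df, D, ref, n_subsamples=10, fraction=0.9, seed=2)
        assert rep.mean_accuracy > 0.99

    def test_accuracy_invariant_to_reference_relabeling(self, planted):
        df, D, ref = planted
        relabeled = type(ref)(
            ref.k, ref.medoids, {s: (c + 2) % 3 for s, c in ref.assignment.items()},
            ref.within_dispersion, ref.seed,
        )
        r1 = cluster_robustness(df, D, ref, n_subsamples=5, fraction=0.9, seed=3)
        r2 = cluster_robustness(df, D, relabeled, n_subsamples=5, fraction=0.9, seed=3)
        assert r1.accuracies == r2.accuracies

    def test_bad_fraction_rejected(self, planted):
        df, D, ref = planted
        with pytest.raises(ValueError):
            cluster_robustness(df, D, ref, n_subsamples=2, fraction=1.5)


class TestContingency:
    def test_two_by_two_exact_p_one_third(self):
        """[[2,0],[0,2]]: hypergeometric enumeration gives two-sided p =
        2 * P(X = 2 | margins) = 2/6 = 1/3."""
        res = contingency_association(["x", "x", "y", "y"], ["u", "u", "v", "v"])
        p_xu = next(r.p for r in res if r.level_a == "x" and r.level_b == "u")
        expected = hypergeom.pmf(2, 4, 2, 2) + hypergeom.pmf(0, 4, 2, 2)
        assert p_xu == pytest.approx(expected)
        assert p_xu == pytest.approx(1 / 3)

    def test_row_column_swap_symmetry(self):
        a = ["x", "x", "x", "y", "y", "y", "y", "x"]
        b = ["u", "v", "u", "v", "v", "u", "v", "u"]
        p1 = {(r.level_a, r.level_b): r.p for r in contingency_association(a, b)}
        p2 = {(r.level_b, r.level_a): r.p for r in contingency_association(b, a)}
        assert p1 == pytest.approx(p2)

    def test_q_values_attached(self):
        rng = np.random.default_rng(11)
        a = rng.choice(["x", "y", "z"], 60)
        b = rng.choice(["u", "v"], 60)
        res = contingency_association(a, b)
        assert all(np.isfinite(r.q) and r.q >= 0 for r in res)
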