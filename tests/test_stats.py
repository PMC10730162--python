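"""Inferential layer: distances, PERMANOVA, PLS-DA, scans, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ibdevo import ValidationError
from ibdevo import stats as st


def fm(values, groups, samples=None, features=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    features = features or [f"f{j}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, index=samples, columns=features)
    return st.FeatureMatrix(data, pd.Series(groups, index=samples))


class TestBrayCurtis:
    def test_disjoint_supports_are_maximally_distant(self):
        d = st.bray_curtis(pd.DataFrame([[1.0, 0.0], [0.0, 1.0]]))
        assert d.iloc[0, 1] == 1.0

    def test_identical_samples_have_zero_distance(self):
        d = st.bray_curtis(pd.DataFrame([[2.0, 1.0], [2.0, 1.0]]))
        assert d.iloc[0, 1] == 0.0

    def test_hand_computed_value(self):
        d = st.bray_curtis(pd.DataFrame([[2.0, 1.0], [1.0, 1.0]]))
        assert d.iloc[0, 1] == pytest.approx(0.2)

    def test_two_all_zero_samples_rejected(self):
        with pytest.raises(ValidationError):
            st.bray_curtis(pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))

    def test_symmetric_zero_diagonal_unit_range(self):
        rng = np.random.default_rng(3)
        d = st.bray_curtis(pd.DataFrame(rng.gamma(2, 1, size=(8, 5)))).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert ((d >= 0) & (d <= 1)).all()


class TestPermanova:
    def test_equidistant_points_give_p_one(self):
        # all pairwise distances equal: F is permutation invariant, so p = 1
        n = 6
        d = pd.DataFrame(np.ones((n, n)) - np.eye(n))
        groups = np.array(["A"] * 3 + ["B"] * 3)
        res = st.permanova(d, groups, n_permutations=99, seed=0)
        assert res.p_value == 1.0

    def test_separated_clouds_attain_minimal_p(self):
        # 10+10 samples: the permutation space (C(20,10) ~ 1.8e5) dwarfs the
        # 999 draws, so no permutation re-attains the observed grouping
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, size=(20, 4))
        x[10:] += 50
        d = st.bray_curtis(pd.DataFrame(np.abs(x)))
        groups = np.array(["A"] * 10 + ["B"] * 10)
        res = st.permanova(d, groups, n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_seeded_permutations_reproducible(self):
        rng = np.random.default_rng(5)
        d = st.bray_curtis(pd.DataFrame(rng.gamma(2, 1, size=(10, 6))))
        groups = np.array(["A"] * 5 + ["B"] * 5)
        a = st.permanova(d, groups, 199, seed=11)
        b = st.permanova(d, groups, 199, seed=11)
        assert a.p_value == b.p_value and a.pseudo_F == b.pseudo_F

    def test_invariant_to_sample_reordering(self):
        rng = np.random.default_rng(9)
        x = pd.DataFrame(rng.gamma(2, 1, size=(10, 6)), index=[f"s{i}" for i in range(10)])
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=x.index)
        order = rng.permutation(x.index)
        d1 = st.bray_curtis(x)
        d2 = st.bray_curtis(x.loc[order])
        r1 = st.permanova(d1, groups, 99, seed=2)
        r2 = st.permanova(d2, groups.loc[order].to_numpy(), 99, seed=2)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)

    def test_singleton_group_rejected(self):
        d = pd.DataFrame(np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValidationError):
            st.permanova(d, np.array(["A", "A", "B"]), 99, seed=0)

    def test_pseudo_f_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as skb_permanova

        rng = np.random.default_rng(21)
        x = pd.DataFrame(rng.gamma(2, 1, size=(14, 7)))
        groups = np.array(["A"] * 7 + ["B"] * 7)
        d = st.bray_curtis(x)
        ours = st.permanova(d, groups, 99, seed=0)
        theirs = skb_permanova(DistanceMatrix(d.to_numpy()), groups, permutations=0)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)


class TestPlsda:
    def test_separating_feature_gets_top_loading(self):
        rng = np.random.default_rng(4)
        x = rng.normal(5, 1, size=(20, 6))
        x[10:, 2] += 6  # only feature f2 separates the groups
        matrix = fm(np.abs(x), ["WT"] * 10 + ["KO"] * 10)
        fit = st.plsda_fit(matrix)
        top = fit.loadings.comp1.abs().idxmax()
        assert top == "f2"

    def test_null_separation_indistinguishable_from_permuted_labels(self):
        rng = np.random.default_rng(8)
        x = np.abs(rng.normal(5, 1, size=(20, 6)))

        def separation(labels):
            fit = st.plsda_fit(fm(x, labels))
            centroids = fit.scores.groupby(np.asarray(labels)).mean()
            return float(np.linalg.norm(centroids.iloc[0] - centroids.iloc[1]))

        labels = np.array(["WT"] * 10 + ["KO"] * 10)
        observed = separation(labels)
        null = [separation(rng.permutation(labels)) for _ in range(99)]
        rank = (1 + sum(n >= observed for n in null)) / 100
        assert rank > 0.05  # exchangeable data: observed separation is typical

    def test_single_component_scores_are_linear_map(self):
        rng = np.random.default_rng(2)
        x = np.abs(rng.normal(5, 1, size=(12, 2)))
        matrix = fm(x, ["WT"] * 6 + ["KO"] * 6)
        fit = st.plsda_fit(matrix, n_components=1, scale=False)
        centered = x - x.mean(axis=0)
        w, *_ = np.linalg.lstsq(centered, fit.scores.to_numpy(), rcond=None)
        assert np.allclose(centered @ w, fit.scores.to_numpy(), atol=1e-8)

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        x = np.abs(rng.normal(5, 1, size=(10, 3)))
        x[:, 1] = 2.0
        with pytest.warns(UserWarning):
            fit = st.plsda_fit(fm(x, ["WT"] * 5 + ["KO"] * 5))
        assert fit.dropped_features == ["f1"]


class TestBhAdjust:
    def test_hand_computed_example(self):
        assert np.allclose(st.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_tied_inputs(self):
        assert st.bh_adjust([0.5]) == pytest.approx([0.5])
        assert np.allclose(st.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            st.bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=30))
    def test_never_decreases_and_order_invariant(self, pvals):
        adjusted = st.bh_adjust(pvals)
        assert (adjusted >= np.asarray(pvals) - 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(pvals))
        permuted = st.bh_adjust(np.asarray(pvals)[perm])
        assert np.allclose(np.asarray(adjusted)[perm], permuted)


class TestFeatureScan:
    def test_shifted_feature_detected_with_direction(self):
        rng = np.random.default_rng(1)
        x = np.abs(rng.normal(5, 1, size=(25, 4)))
        x[14:, 0] += 4  # KO block higher in f0
        matrix = fm(x, ["WT"] * 14 + ["KO"] * 11)
        results = {r.feature_id: r for r in st.feature_scan(matrix)}
        assert results["f0"].adjusted_p < 0.05
        assert results["f0"].direction == "higher-in-KO"
        assert all(results[f].adjusted_p > results[f].raw_p - 1e-12 for f in results)

    def test_all_tied_feature_gets_p_one_no_direction(self):
        x = np.ones((10, 2))
        x[:, 1] = np.arange(10)
        results = st.feature_scan(fm(x, ["WT"] * 5 + ["KO"] * 5))
        assert results[0].raw_p == 1.0 and results[0].direction is None

    def test_single_feature_adjusted_equals_raw(self):
        rng = np.random.default_rng(0)
        matrix = fm(np.abs(rng.normal(5, 1, size=(10, 1))), ["WT"] * 5 + ["KO"] * 5)
        (result,) = st.feature_scan(matrix)
        assert result.adjusted_p == result.raw_p

    def test_signed_rank_requires_pairing(self):
        rng = np.random.default_rng(0)
        matrix = fm(np.abs(rng.normal(5, 1, size=(9, 2))), ["WT"] * 5 + ["KO"] * 4)
        with pytest.raises(ValidationError):
            st.feature_scan(matrix, test="signed-rank")


class TestTrajectoryCorrelation:
    @staticmethod
    def series(freqs, markers):
        weeks = list(range(1, len(freqs) + 1))
        freq = pd.DataFrame({"mouse_id": "m1", "week": weeks, "frequency": freqs})
        marker = pd.DataFrame({"mouse_id": "m1", "week": weeks, "marker_per_gram": markers})
        return freq, marker

    def test_comonotone_series_give_rho_one(self):
        freq, marker = self.series([0.1, 0.3, 0.7, 0.9], [10, 20, 30, 40])
        rho, _ = st.trajectory_correlation(freq, marker, scope="all-mice")
        assert rho == pytest.approx(1.0)

    def test_reversed_marker_gives_rho_minus_one(self):
        freq, marker = self.series([0.1, 0.3, 0.7, 0.9], [40, 30, 20, 10])
        rho, _ = st.trajectory_correlation(freq, marker, scope="all-mice")
        assert rho == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        freq, marker = self.series([0.1, 0.2], [1, 2])
        with pytest.raises(ValidationError):
            st.trajectory_correlation(freq, marker, scope="all-mice")


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        h, p = st.kruskal_wallis([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert h == 0.0 and p == 1.0

    def test_fully_separated_groups_maximize_h(self):
        from itertools import combinations

        h_obs, _ = st.kruskal_wallis([1, 2, 3], [10, 11, 12])
        values = [1, 2, 3, 10, 11, 12]
        h_all = []
        for left in combinations(range(6), 3):
            right = [i for i in range(6) if i not in left]
            h, _ = st.kruskal_wallis([values[i] for i in left], [values[i] for i in right])
            h_all.append(h)
        assert h_obs == pytest.approx(max(h_all))

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(0)
        rejections = 0
        for _ in range(500):
            groups = [rng.normal(size=8) for _ in range(3)]
            _, p = st.kruskal_wallis(*groups)
            rejections += p < 0.05
        assert 0.03 <= rejections / 500 <= 0.07
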