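"""SVR mapping machinery: fits, C selection, permutation p-values, FDR,
cluster filtering and covariate control."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest
from sklearn.svm import SVR

from famap import (
    CovariateControl,
    DataError,
    DegenerateInputError,
    MappingConfig,
    ParameterError,
    Volume,
    apply_covariate_control,
    evaluate_c,
    fdr_select,
    filter_clusters,
    fit_svr,
    optimize_c,
    permutation_pmap,
    run_mapping,
)
from famap.mapping import _select_c


def _single_voxel_dataset(n=40, n_voxels=10, seed=0):
    """Features iid noise except voxel 0; scores an exact linear function
    of voxel 0."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.2, 0.8, size=(n, n_voxels))
    y = 10.0 * x[:, 0] + 1.0
    return x, y


class TestFitSVR:
    def test_recovers_linear_relation(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, size=(30, 2))
        y = 2.0 * x[:, 0]
        model = fit_svr(x, y, c=1e4, epsilon=0.0)
        np.testing.assert_allclose(model.weights, [2.0, 0.0], atol=1e-3)
        np.testing.assert_allclose(model.predict(x), y, atol=1e-3)

    def test_constant_scores(self):
        x = np.random.default_rng(0).random((10, 3))
        with pytest.raises(DegenerateInputError):
            fit_svr(x, np.ones(10))

    def test_nonfinite_features(self):
        x = np.full((5, 2), np.nan)
        with pytest.raises(DataError):
            fit_svr(x, np.arange(5.0))

    def test_subject_order_invariance(self):
        x, y = _single_voxel_dataset(seed=2)
        perm = np.random.default_rng(3).permutation(len(y))
        w1 = fit_svr(x, y, c=1.0).weights
        w2 = fit_svr(x[perm], y[perm], c=1.0).weights
        np.testing.assert_allclose(w1, w2, atol=1e-6)

    def test_rbf_has_no_weights(self):
        x, y = _single_voxel_dataset()
        model = fit_svr(x, y, c=1.0, kernel="rbf")
        assert model.weights is None
        assert model.predict(x).shape == y.shape


class TestEvaluateC:
    def test_perfect_signal(self):
        x, y = _single_voxel_dataset(n=50)
        fit_r2, rep = evaluate_c(x, y, c=100.0, seed=0)
        assert fit_r2 >= 0.95
        assert rep >= 0.95

    def test_null_fit_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.random((50, 30))
        y = rng.normal(size=50)
        fit_r2, _ = evaluate_c(x, y, c=1.0, seed=0)
        assert fit_r2 < 0.1

    def test_single_pair_counting(self):
        # 4 subjects, 2 folds, 1 repeat -> exactly one weight-vector pair
        rng = np.random.default_rng(5)
        x = rng.random((4, 3))
        y = rng.normal(size=4)
        _, rep = evaluate_c(x, y, c=1.0, folds=2, repeats=1, seed=0)
        assert np.isfinite(rep)

    def test_fewer_subjects_than_folds(self):
        with pytest.raises(DegenerateInputError):
            evaluate_c(np.random.default_rng(0).random((3, 2)),
                       np.arange(3.0), c=1.0, folds=5)


class TestOptimizeC:
    def test_single_value_grid(self):
        x, y = _single_voxel_dataset()
        trace = optimize_c(x, y, c_grid=[0.5], seed=0)
        assert trace.chosen_c == 0.5

    def test_selection_rule_dominance(self):
        grid = np.array([0.1, 1.0, 10.0])
        fit = np.array([0.2, 0.9, 0.5])
        rep = np.array([0.3, 0.8, 0.4])
        assert _select_c(grid, fit, rep) == 1

    def test_selection_rule_tie_prefers_smaller_c(self):
        grid = np.array([4.0, 1.0, 2.0])
        fit = np.array([0.5, 0.5, 0.5])
        rep = np.array([0.5, 0.5, 0.5])
        assert grid[_select_c(grid, fit, rep)] == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(-1, 1)),
                    min_size=2, max_size=10))
    def test_dominating_c_always_chosen(self, pairs):
        fit = np.array([p[0] for p in pairs])
        rep = np.array([p[1] for p in pairs])
        grid = 2.0 ** np.arange(len(pairs))
        idx = _select_c(grid, fit, rep)
        dominators = [
            i for i in range(len(pairs))
            if all(fit[i] >= fit[j] and rep[i] >= rep[j]
                   for j in range(len(pairs)))
        ]
        if dominators:
            assert idx in dominators

    def test_empty_grid(self):
        x, y = _single_voxel_dataset()
        with pytest.raises(ParameterError):
            optimize_c(x, y, c_grid=[])


class TestPermutationPmap:
    def test_extreme_voxel_floor_p(self):
        x, y = _single_voxel_dataset(n=30, seed=6)
        p = permutation_pmap(x, y, c=1.0, n_permutations=99, seed=0,
                             tail="positive")
        assert p[0] == pytest.approx(1 / 100)
        assert p.min() >= 1 / 100 and p.max() <= 1.0

    def test_exhaustive_matches_bruteforce_oracle(self):
        """n = 4 subjects: all 24 label orderings enumerated; p must equal
        the rank-based p from an independent per-permutation linear-SVR
        refit (no Gram precomputation)."""
        rng = np.random.default_rng(7)
        x = rng.uniform(0.2, 0.8, size=(4, 5))
        y = np.array([1.0, 3.0, 2.0, 5.0])
        c, eps, tail = 1.0, 0.1, "negative"
        p = permutation_pmap(x, y, c=c, epsilon=eps, tail=tail,
                             exhaustive=True)

        def weights(yy):
            est = SVR(kernel="linear", C=c, epsilon=eps).fit(x, yy)
            return est.coef_.ravel()

        obs = weights(y)
        counts = np.zeros(x.shape[1])
        total = 0
        for perm in itertools.permutations(range(4)):
            counts += weights(y[list(perm)]) <= obs
            total += 1
        np.testing.assert_allclose(p, counts / total)

    def test_null_p_values_uniform(self):
        """Under the null, per-voxel p-values are uniform on the achievable
        grid (KS at alpha = 0.01 over 200 voxels, 2000 permutations)."""
        rng = np.random.default_rng(8)
        x = rng.random((50, 200))
        y = rng.normal(size=50)
        p = permutation_pmap(x, y, c=1.0, n_permutations=2000, seed=1,
                             tail="negative")
        assert kstest(p, "uniform").pvalue > 0.01

    def test_column_order_invariance(self):
        x, y = _single_voxel_dataset(n=20, seed=9)
        perm = np.random.default_rng(10).permutation(x.shape[1])
        p1 = permutation_pmap(x, y, c=1.0, n_permutations=200, seed=2)
        p2 = permutation_pmap(x[:, perm], y, c=1.0, n_permutations=200, seed=2)
        np.testing.assert_array_equal(p1[perm], p2)

    def test_degenerate_voxel_reported_as_one(self):
        x, y = _single_voxel_dataset(n=20, seed=11)
        x[:, 3] = 0.0  # all-lesion FA column
        p = permutation_pmap(x, y, c=1.0, n_permutations=50, seed=0)
        assert p[3] == 1.0

    def test_constant_scores(self):
        x = np.random.default_rng(0).random((10, 3))
        with pytest.raises(DegenerateInputError):
            permutation_pmap(x, np.ones(10), c=1.0, n_permutations=10)


def _bh_literal(p, q):
    """Literal Benjamini-Hochberg step-up definition (independent oracle)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ks = np.flatnonzero(sorted_p <= (np.arange(1, m + 1) * q / m))
    if ks.size == 0:
        return 0.0, np.zeros(m, bool)
    threshold = sorted_p[ks[-1]]
    return threshold, p <= threshold


class TestFDR:
    def test_all_small(self):
        thr, flags = fdr_select(np.full(100, 0.001), q=0.05)
        assert flags.all() and thr == 0.001

    def test_all_one(self):
        thr, flags = fdr_select(np.ones(50), q=0.05)
        assert not flags.any() and thr == 0.0

    def test_five_vector_oracle(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.9])
        thr, flags = fdr_select(p, q=0.05)
        thr_o, flags_o = _bh_literal(p, 0.05)
        assert thr == thr_o
        np.testing.assert_array_equal(flags, flags_o)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(1, 1000), st.integers(0, 2**32 - 1))
    def test_random_vectors_match_literal_bh(self, m, seed):
        p = np.random.default_rng(seed).uniform(1e-6, 1.0, size=m)
        thr, flags = fdr_select(p, q=0.05)
        thr_o, flags_o = _bh_literal(p, 0.05)
        assert thr == pytest.approx(thr_o)
        np.testing.assert_array_equal(flags, flags_o)

    def test_empty(self):
        with pytest.raises(DegenerateInputError):
            fdr_select(np.array([]))


def _component_volume(coords, shape=(10, 10, 10)):
    data = np.zeros(shape, dtype=np.int16)
    for c in coords:
        data[c] = 1
    return Volume(data, np.eye(4))


class TestClusterFilter:
    def test_size_boundary(self):
        line19 = [(0, 0, k) for k in range(10)] + [(0, 1, k) for k in range(9)]
        line20 = [(0, 0, k) for k in range(10)] + [(0, 1, k) for k in range(10)]
        assert filter_clusters(_component_volume(line19)).data.sum() == 0
        assert filter_clusters(_component_volume(line20)).data.sum() == 20

    def test_diagonal_connectivity(self):
        diag = _component_volume([(0, 0, 0), (1, 1, 1)])
        kept26 = filter_clusters(diag, min_cluster=2, connectivity=26)
        kept6 = filter_clusters(diag, min_cluster=2, connectivity=6)
        assert kept26.data.sum() == 2  # one 26-connected component
        assert kept6.data.sum() == 0  # two 6-connected singletons

    def test_idempotent_and_subset(self):
        rng = np.random.default_rng(13)
        vol = Volume((rng.random((12, 12, 12)) > 0.6).astype(np.int16), np.eye(4))
        once = filter_clusters(vol, min_cluster=5)
        twice = filter_clusters(once, min_cluster=5)
        np.testing.assert_array_equal(once.data, twice.data)
        assert not ((once.data > 0) & (vol.data == 0)).any()

    def test_bad_connectivity(self):
        with pytest.raises(ParameterError):
            filter_clusters(_component_volume([(0, 0, 0)]), connectivity=10)


class TestCovariateControl:
    def test_orthogonal_covariate_keeps_centered_scores(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        cov = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to centered scores
        adj, _ = apply_covariate_control(
            scores, np.zeros((4, 2)),
            CovariateControl("residualize_behaviour", cov),
        )
        np.testing.assert_allclose(adj, scores - scores.mean(), atol=1e-12)

    def test_covariate_equal_to_score(self):
        scores = np.arange(6.0)
        adj, _ = apply_covariate_control(
            scores, np.zeros((6, 2)),
            CovariateControl("residualize_behaviour", scores.copy()),
        )
        np.testing.assert_allclose(adj, 0.0, atol=1e-10)

    def test_known_residuals(self):
        rng = np.random.default_rng(14)
        cov = rng.normal(size=50)
        e = rng.normal(size=50)
        e -= np.polyval(np.polyfit(cov, e, 1), cov)  # orthogonalize
        scores = 2.0 * cov + e
        adj, _ = apply_covariate_control(
            scores, np.zeros((50, 1)),
            CovariateControl("residualize_behaviour", cov),
        )
        np.testing.assert_allclose(adj, e - e.mean(), atol=1e-10)

    def test_covary_in_model_adjusts_features(self):
        rng = np.random.default_rng(15)
        cov = rng.normal(size=30)
        feats = np.outer(cov, [1.0, 2.0]) + rng.normal(size=(30, 2)) * 0.1
        _, adj = apply_covariate_control(
            rng.normal(size=30), feats, CovariateControl("covary_in_model", cov)
        )
        # residualized features are orthogonal to the covariate
        np.testing.assert_allclose(adj.T @ cov, 0.0, atol=1e-8)

    def test_constant_covariate(self):
        with pytest.raises(DegenerateInputError):
            apply_covariate_control(
                np.arange(5.0), np.zeros((5, 1)),
                CovariateControl("residualize_behaviour", np.ones(5)),
            )


class TestRunMapping:
    def test_zero_permutations_rejected(self, strong_cohort):
        with pytest.raises(ParameterError):
            run_mapping(strong_cohort.fa, strong_cohort.scores,
                        MappingConfig(c=1.0, n_permutations=0))

    def test_invariants_on_phantom(self, strong_cohort, anatomy):
        cfg = MappingConfig(c=0.25, n_permutations=200, tail="positive",
                            perm_seed=3)
        res = run_mapping(strong_cohort.fa, strong_cohort.scores, cfg)
        assert res.p_values.min() >= 1 / 201 and res.p_values.max() <= 1.0
        raw = res.sig_mask_raw.data
        filt = res.sig_mask_filtered.data
        assert not ((filt > 0) & (raw == 0)).any()
        assert not ((raw > 0) & (anatomy.skeleton_mask.data == 0)).any()

    def test_binary_lesion_variant(self, strong_cohort):
        from famap import SkeletonDataset

        lesion_feats = np.stack([
            l.data[strong_cohort.fa.voxel_index.as_tuple_index()]
            for l in strong_cohort.lesions
        ]).astype(float)
        ds = SkeletonDataset(lesion_feats, strong_cohort.fa.subject_ids,
                             strong_cohort.fa.voxel_index)
        cfg = MappingConfig(c=0.25, n_permutations=100, tail="negative",
                            perm_seed=4)
        res = run_mapping(ds, strong_cohort.scores, cfg)
        assert res.p_values.shape == (ds.n_voxels,)
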