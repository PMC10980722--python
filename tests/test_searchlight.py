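"""Searchlight machinery: sphere geometry, folds, SVR, FDR, decoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from traitscan import CohortSpec, simulate_cohort
from traitscan.grid import VolumeGrid
from traitscan.searchlight import (
    SearchlightSpec,
    fdr_threshold,
    kfold_partition,
    searchlight_predict,
    sphere_offsets,
    svr_train_predict,
)


def brute_force_offsets(radius):
    out = []
    for i in range(-radius, radius + 1):
        for j in range(-radius, radius + 1):
            for k in range(-radius, radius + 1):
                if i * i + j * j + k * k <= radius * radius:
                    out.append((i, j, k))
    return set(out)


def qp_svr_predict(train_X, train_y, test_X, C, epsilon):
    """Independent oracle: solve the standard epsilon-SVR primal by SLSQP."""
    X = np.asarray(train_X, float)
    y = np.asarray(train_y, float)
    n, d = X.shape

    def unpack(v):
        return v[:d], v[d], v[d + 1 : d + 1 + n], v[d + 1 + n :]

    def obj(v):
        w, b, xi, xis = unpack(v)
        return 0.5 * w @ w + C * (xi.sum() + xis.sum())

    cons = [
        {"type": "ineq",
         "fun": lambda v: epsilon + unpack(v)[2] - (y - X @ unpack(v)[0] - unpack(v)[1])},
        {"type": "ineq",
         "fun": lambda v: epsilon + unpack(v)[3] - (X @ unpack(v)[0] + unpack(v)[1] - y)},
        {"type": "ineq", "fun": lambda v: unpack(v)[2]},
        {"type": "ineq", "fun": lambda v: unpack(v)[3]},
    ]
    v0 = np.zeros(d + 1 + 2 * n)
    v0[d] = y.mean()
    res = minimize(obj, v0, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    w, b, _, _ = unpack(res.x)
    return np.asarray(test_X, float) @ w + b


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,count", [(0, 1), (1, 7), (2, 33), (3, 123)])
    def test_lattice_ball_sizes(self, radius, count):
        offs = sphere_offsets(radius)
        assert offs.shape == (count, 3)
        assert set(map(tuple, offs)) == brute_force_offsets(radius)

    @given(radius=st.integers(0, 5))
    @settings(max_examples=6, derandomize=True)
    def test_symmetric_under_negation(self, radius):
        offs = set(map(tuple, sphere_offsets(radius)))
        assert offs == {(-i, -j, -k) for i, j, k in offs}
        assert (0, 0, 0) in offs

    def test_deterministic_lexicographic_order(self):
        offs = sphere_offsets(2)
        assert list(map(tuple, offs)) == sorted(map(tuple, offs))

    def test_negative_radius(self):
        with pytest.raises(ValueError):
            sphere_offsets(-1)


class TestKFold:
    def test_study_partition_sizes(self):
        # 229 participants in 10 folds: nine of 23 and one of 22
        fold = kfold_partition(229, 10, seed=4)
        sizes = sorted(np.bincount(fold))
        assert sizes == [22] + [23] * 9

    def test_singleton_folds(self):
        fold = kfold_partition(7, 7, seed=0)
        assert sorted(np.bincount(fold)) == [1] * 7

    @given(n=st.integers(4, 60), k=st.integers(2, 10), seed=st.integers(0, 99))
    @settings(max_examples=40, derandomize=True)
    def test_partition_property(self, n, k, seed):
        if k > n:
            return
        fold = kfold_partition(n, k, seed)
        counts = np.bincount(fold, minlength=k)
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1

    def test_k_exceeds_n(self):
        with pytest.raises(ValueError):
            kfold_partition(5, 6)


class TestSVR:
    def test_constant_target(self, rng):
        X = rng.normal(size=(15, 4))
        preds = svr_train_predict(X, np.full(15, 3.5), rng.normal(size=(6, 4)))
        np.testing.assert_allclose(preds, 3.5, atol=1e-6)

    def test_line_fit_example(self):
        x = np.linspace(0, 19, 20).reshape(-1, 1)
        pred = svr_train_predict(x, 2 * x.ravel(), np.array([[5.0]]),
                                 C=100.0, epsilon=0.01)
        assert pred[0] == pytest.approx(10.0, abs=0.05)

    def test_matches_qp_oracle(self, rng):
        for _ in range(4):
            X = rng.normal(size=(20, 2))
            y = X @ np.array([1.5, -0.8]) + 0.1 * rng.normal(size=20)
            Xt = rng.normal(size=(8, 2))
            ours = svr_train_predict(X, y, Xt, C=1.0, epsilon=0.1, tol=1e-8)
            oracle = qp_svr_predict(X, y, Xt, C=1.0, epsilon=0.1)
            np.testing.assert_allclose(ours, oracle, atol=0.05)

    def test_duplicated_columns_same_prediction(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        Xt = rng.normal(size=(5, 3))
        p1 = svr_train_predict(X, y, Xt, C=100.0, epsilon=0.01, tol=1e-8)
        p2 = svr_train_predict(np.hstack([X, X]), y, np.hstack([Xt, Xt]),
                               C=100.0, epsilon=0.01, tol=1e-8)
        np.testing.assert_allclose(p1, p2, atol=0.05)

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            svr_train_predict(rng.normal(size=(10, 3)), np.ones(10),
                              rng.normal(size=(2, 4)))
        with pytest.raises(ValueError):
            svr_train_predict(np.full((10, 2), np.nan), np.ones(10),
                              np.ones((1, 2)))


class TestFDR:
    def test_step_up_worked_example(self):
        flags, crit = fdr_threshold(np.array([0.001, 0.008, 0.039, 0.041]), 0.05)
        assert flags.all()
        assert crit == pytest.approx(0.041)

    def test_all_ones_nothing_flagged(self):
        flags, crit = fdr_threshold(np.ones(20), 0.05)
        assert not flags.any()
        assert crit == 0.0

    def _bh_oracle(self, p, q):
        # literal Benjamini-Hochberg step-up definition
        m = p.size
        order = np.argsort(p)
        ks = [i + 1 for i in range(m) if p[order[i]] <= (i + 1) / m * q]
        flags = np.zeros(m, bool)
        if ks:
            flags[order[: max(ks)]] = True
        return flags

    @given(seed=st.integers(0, 500))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_literal_step_up(self, seed):
        r = np.random.default_rng(seed)
        p = np.clip(r.beta(0.6, 3.0, size=r.integers(1, 120)), 1e-12, 1.0)
        flags, _ = fdr_threshold(p, 0.05)
        np.testing.assert_array_equal(flags, self._bh_oracle(p, 0.05))

    def test_nan_handling(self):
        p = np.array([0.001, np.nan, 0.9])
        flags, _ = fdr_threshold(p, 0.05)
        assert flags[0] and not flags[1] and not flags[2]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            fdr_threshold(np.array([]), 0.05)


class TestSearchlight:
    def test_degenerate_target(self, small_cohort, small_cohort_contrasts):
        with pytest.raises(ValueError, match="degenerate"):
            searchlight_predict(
                small_cohort_contrasts,
                np.full(small_cohort.spec.n_subjects, 21.0),
                small_cohort.grid,
                SearchlightSpec(n_folds=4),
            )

    def test_fewer_subjects_than_folds(self, small_cohort, small_cohort_contrasts):
        with pytest.raises(ValueError, match="folds"):
            searchlight_predict(
                small_cohort_contrasts, small_cohort.traits, small_cohort.grid,
                SearchlightSpec(n_folds=13),
            )

    def test_output_ranges_and_mask(self, small_cohort, small_cohort_contrasts):
        pm = searchlight_predict(
            small_cohort_contrasts, small_cohort.traits, small_cohort.grid,
            SearchlightSpec(n_folds=4),
        )
        ok = np.isfinite(pm.r)
        assert ok.any()
        assert np.all(np.abs(pm.r[ok]) <= 1.0)
        assert np.all((pm.p[ok] > 0) & (pm.p[ok] <= 1.0))
        assert not pm.significant[~ok].any()

    def test_min_voxels_undefined_centers(self, small_cohort, small_cohort_contrasts):
        spec = SearchlightSpec(radius_vox=1, min_voxels=7, n_folds=4)
        pm = searchlight_predict(
            small_cohort_contrasts, small_cohort.traits, small_cohort.grid, spec
        )
        # boundary voxels with truncated spheres must be NaN
        assert np.isnan(pm.r).any()

    def test_radius_zero_reduces_to_univariate(self):
        spec = CohortSpec(n_subjects=16, grid_shape=(8, 8, 8), rng_seed=3,
                          pattern_region=np.array([[4, 4, 4]]),
                          coupling_seed_region=np.array([[2, 4, 4]]),
                          coupling_target_region=np.array([[6, 4, 4]]))
        sim = simulate_cohort(spec)
        from traitscan import first_level_contrasts
        from traitscan.searchlight import kfold_partition as kf

        maps = first_level_contrasts(sim)
        sl = SearchlightSpec(radius_vox=0, min_voxels=1, n_folds=4,
                             adjust_fold_means=False, svr_tol=1e-6)
        pm = searchlight_predict(maps, sim.traits, sim.grid, sl)
        fold = kf(16, 4, sl.cv_seed)
        # manual per-voxel single-feature CV with the public SVR op
        for v in [0, sim.grid.n_voxels // 2, sim.grid.n_voxels - 1]:
            preds = np.empty(16)
            for f in range(4):
                te = fold == f
                preds[te] = svr_train_predict(
                    maps[~te, v : v + 1], sim.traits[~te], maps[te, v : v + 1],
                    tol=1e-6,
                )
            r_manual = np.corrcoef(preds, sim.traits)[0, 1]
            assert pm.r[v] == pytest.approx(r_manual, abs=1e-3)

    def test_calibrated_p_method_runs(self, small_cohort, small_cohort_contrasts):
        pm = searchlight_predict(
            small_cohort_contrasts, small_cohort.traits, small_cohort.grid,
            SearchlightSpec(n_folds=4, p_method="calibrated", n_calib_perms=5,
                            n_calib_centers=32),
        )
        ok = np.isfinite(pm.p)
        assert ((pm.p[ok] > 0) & (pm.p[ok] <= 1.0)).all()
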