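import numpy as np
import pytest

from pfclust import (
    HyperParams,
    fcm_update_memberships,
    fcm_update_prototypes,
    make_blobs,
    pfcm_objective,
    pfcm_update,
    pfcm_update_prototypes,
    run_fcm,
    run_hpfcm,
    run_pfcm,
)


class TestPFCMUpdates:
    def test_fuzzy_part_bit_equals_fcm_update(self, x12, rng):
        V = rng.normal(size=(3, 2))
        params = HyperParams(m=1.7, eta=2.3, a=2.0, b=0.5)
        U, _ = pfcm_update(x12.X, V, params, gammas=np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(U, fcm_update_memberships(x12.X, V, 1.7))

    @pytest.mark.parametrize(
        "d2, b, gamma, expected", [(1.0, 1.0, 1.0, 0.5), (3.0, 1.0, 1.0, 0.25)]
    )
    def test_typicality_crossovers(self, d2, b, gamma, expected):
        params = HyperParams(eta=2.0, b=b)
        _, T = pfcm_update(
            [[np.sqrt(d2)]], [[0.0]], params, gammas=np.array([gamma])
        )
        assert T[0, 0] == pytest.approx(expected)

    def test_coincident_point_has_unit_typicality_and_membership(self):
        params = HyperParams()
        U, T = pfcm_update(
            [[2.0, 2.0]], [[2.0, 2.0], [5.0, 5.0]], params, gammas=np.array([1.0, 1.0])
        )
        assert T[0, 0] == 1.0 and U[0, 0] == 1.0
        assert T[0, 1] < 1.0

    def test_prototypes_reduce_to_fcm_when_b_zero(self, x12, rng):
        U = fcm_update_memberships(x12.X, rng.normal(size=(2, 2)), 2.0)
        T = rng.uniform(0.1, 1.0, size=(12, 2))
        params = HyperParams(a=1.0, b=0.0)
        np.testing.assert_allclose(
            pfcm_update_prototypes(x12.X, U, T, params),
            fcm_update_prototypes(x12.X, U, 2.0),
        )

    def test_prototypes_hand_weighted_mean(self):
        # two points {0, 1}; cluster-1 blended weights (a u^m + b t^eta)
        # = (1 + 1, 0.25 + 0.25) = (2, 0.5) -> v = 0.5/2.5 = 0.2
        X = np.array([[0.0], [1.0]])
        U = np.array([[1.0], [0.5]])
        T = np.array([[1.0], [0.5]])
        V = pfcm_update_prototypes(X, U, T, HyperParams(a=1.0, b=1.0))
        assert V[0, 0] == pytest.approx(0.2)

    def test_objective_algebraic_limits(self, x12, rng):
        V = rng.normal(size=(2, 2))
        U = fcm_update_memberships(x12.X, V, 2.0)
        T = np.ones((12, 2))
        from pfclust import fcm_objective
        from pfclust.core import squared_distances

        D = squared_distances(x12.X, V)
        g = np.array([3.0, 4.0])
        # T = 1 kills the penalty term; b-weighted distance sum remains
        val = pfcm_objective(x12.X, U, T, V, HyperParams(a=2.0, b=5.0), g)
        expected = 2.0 * fcm_objective(x12.X, U, V, 2.0) + 5.0 * D.sum()
        assert val == pytest.approx(expected)
        val_b0 = pfcm_objective(x12.X, U, T, V, HyperParams(a=2.0, b=0.0), g)
        assert val_b0 == pytest.approx(2.0 * fcm_objective(x12.X, U, V, 2.0))


class TestRunPFCM:
    def test_terminal_objective_matches_definition(self, x12, params):
        res = run_pfcm(x12.X, 2, params)
        assert res.objective == pytest.approx(
            pfcm_objective(x12.X, res.U, res.T, res.V, params, res.scales)
        )

    def test_objective_trace_non_increasing(self, x12, params):
        res = run_pfcm(x12.X, 2, params)
        assert np.all(np.diff(res.objective_trace) <= 1e-8)

    def test_b_to_zero_reduces_to_fcm(self, x12):
        fcm = run_fcm(x12.X, 2, HyperParams(seed=5))
        pfcm = run_pfcm(x12.X, 2, HyperParams(seed=5, b=1e-8))
        order = np.argsort(fcm.V[:, 0]), np.argsort(pfcm.V[:, 0])
        np.testing.assert_allclose(pfcm.V[order[1]], fcm.V[order[0]], atol=1e-4)

    def test_blob_recovery(self):
        ds = make_blobs(K=2, n_per_cluster=80, centers=((-4, 0), (4, 0)), spread=0.3, seed=2)
        res = run_pfcm(ds.X, 2, HyperParams(seed=2))
        V = res.V[np.argsort(res.V[:, 0])]
        np.testing.assert_allclose(V, ds.true_centers, atol=0.15)


class TestRunHPFCM:
    def test_stage_structure(self, x12, params):
        res = run_hpfcm(x12.X, 2, params)
        assert res.stage1 is not None and res.stage1.T is None
        assert res.T is not None and res.U is res.stage1.U
        assert res.converged

    def test_stage2_objective_non_increasing(self, x12, params):
        res = run_hpfcm(x12.X, 2, params)
        assert np.all(np.diff(res.objective_trace) <= 1e-8)

    def test_matches_fcm_on_clean_tight_blobs(self):
        ds = make_blobs(K=2, n_per_cluster=50, centers=((-5, 0), (5, 0)),
                        spread=1e-3, seed=4)
        fcm = run_fcm(ds.X, 2, HyperParams(seed=4))
        hyb = run_hpfcm(ds.X, 2, HyperParams(seed=4))
        np.testing.assert_allclose(
            hyb.V[np.argsort(hyb.V[:, 0])], fcm.V[np.argsort(fcm.V[:, 0])], atol=1e-3
        )

    def test_outlier_moves_hpfcm_centers_less_than_fcm(self):
        # two blobs plus one gross outlier at >= 10x the blob spread:
        # the possibilistic stage should shrug it off, the fuzzy stage not
        clean = make_blobs(K=2, n_per_cluster=40, centers=((-3, 0), (3, 0)),
                           spread=0.4, seed=9)
        outlier = np.array([[0.0, 40.0]])
        noisy = np.vstack([clean.X, outlier])
        f0 = run_fcm(clean.X, 2, HyperParams(seed=9))
        f1 = run_fcm(noisy, 2, HyperParams(seed=9))
        h0 = run_hpfcm(clean.X, 2, HyperParams(seed=9))
        h1 = run_hpfcm(noisy, 2, HyperParams(seed=9))

        def shift(a, b):
            a = a[np.argsort(a[:, 0])]
            b = b[np.argsort(b[:, 0])]
            return np.max(np.abs(a - b))

        assert shift(h0.V, h1.V) < shift(f0.V, f1.V)

    def test_fixed_scale_equals_paper_parameterization(self, x12, params):
        # with the scale pinned at 2 the hybrid lands on the same
        # prototypes as with the core-median estimate (eta ~ 2.03)
        est = run_hpfcm(x12.X, 2, params, n_init=5)
        fixed = run_hpfcm(x12.X, 2, params, n_init=5, fixed_scale=2.0)
        np.testing.assert_allclose(est.V, fixed.V, atol=0.01)

    def test_x12_prototype_error_beats_fcm_and_pfcm(self, x12, params):
        from pfclust import centroid_error

        err_h = centroid_error(run_hpfcm(x12.X, 2, params, n_init=5).V, x12.true_centers)
        err_f = centroid_error(run_fcm(x12.X, 2, params, n_init=5).V, x12.true_centers)
        err_p = centroid_error(run_pfcm(x12.X, 2, params, n_init=5).V, x12.true_centers)
        assert err_h < err_p < err_f
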