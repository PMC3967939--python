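import numpy as np
import pytest
from scipy.optimize import minimize

from chromcode import (
    fit_hierarchical_group_l1,
    fit_independent,
    fit_pairwise_l1,
    lambda_max,
    neg_log_pseudolikelihood,
    random_sparse_model,
    sample_dataset,
    select_lambda,
)
from chromcode.model_core import MaxEntModel
from chromcode.structure_learning import (
    _pl_value_grad,
    all_triples,
    default_lambda_grid,
    pseudolikelihood_value,
)
from chromcode.synthetic import planted_hierarchical_model


class TestPseudolikelihood:
    def test_zero_model_value_is_n_log2(self, small_data):
        m = MaxEntModel(factors=list(small_data.factors))
        value, _ = neg_log_pseudolikelihood(m, small_data)
        assert value == pytest.approx(small_data.n_factors * np.log(2))

    def test_h_gradient_vanishes_at_independence_fit(self, small_data):
        m = fit_independent(small_data, pseudocount=0.0)
        _, grad = neg_log_pseudolikelihood(m, small_data)
        for f in m.factors:
            assert grad[("h", f)] == pytest.approx(0.0, abs=1e-9)

    def test_gradient_matches_finite_differences(self):
        # random third-order model, n=8, N=200: central differences to 1e-6 rel
        model = random_sparse_model(8, pair_density=0.3, triplet_density=0.7,
                                    seed=17)
        assert model.K, "fixture needs at least one triplet"
        data = sample_dataset(model, 200, seed=18, method="exact")
        X = data.calls.astype(float)
        h, Jd, tidx, tval = model.to_dense()
        _, gh, GJ, gK = _pl_value_grad(X, h, Jd, tidx, tval)
        eps = 1e-5

        def f(h_, Jd_, tval_):
            return _pl_value_grad(X, h_, Jd_, tidx, tval_)[0]

        for i in range(model.n):
            hp, hm = h.copy(), h.copy()
            hp[i] += eps
            hm[i] -= eps
            num = (f(hp, Jd, tval) - f(hm, Jd, tval)) / (2 * eps)
            assert gh[i] == pytest.approx(num, rel=1e-6, abs=1e-9)
        for (i, j) in [(0, 1), (2, 5), (6, 7)]:
            Jp, Jm = Jd.copy(), Jd.copy()
            Jp[i, j] = Jp[j, i] = Jd[i, j] + eps
            Jm[i, j] = Jm[j, i] = Jd[i, j] - eps
            num = (f(h, Jp, tval) - f(h, Jm, tval)) / (2 * eps)
            assert GJ[i, j] == pytest.approx(num, rel=1e-6, abs=1e-9)
        for r in range(len(tval)):
            tp, tm = tval.copy(), tval.copy()
            tp[r] += eps
            tm[r] -= eps
            num = (f(h, Jd, tp) - f(h, Jd, tm)) / (2 * eps)
            assert gK[r] == pytest.approx(num, rel=1e-6, abs=1e-9)


class TestFitPairwiseL1:
    def test_huge_lambda_gives_independence(self, small_data):
        m = fit_pairwise_l1(small_data, 1e3)
        assert not m.J
        indep = fit_independent(small_data, pseudocount=0.0)
        for f in small_data.factors:
            assert m.h.get(f, 0.0) == pytest.approx(indep.h.get(f, 0.0),
                                                    abs=1e-4)

    def test_unpenalized_fit_matches_generic_optimizer(self):
        model = random_sparse_model(6, pair_density=0.4, seed=31)
        data = sample_dataset(model, 5000, seed=32, method="exact")
        m = fit_pairwise_l1(data, 0.0)
        opt_val = pseudolikelihood_value(m, data)
        # independent route: L-BFGS on the smooth objective
        n = 6
        X = data.calls.astype(float)
        ut = np.triu_indices(n, 1)
        empty = (np.zeros((0, 3), dtype=np.int64), np.zeros(0))

        def obj(v):
            h = v[:n]
            Jd = np.zeros((n, n))
            Jd[ut] = v[n:]
            Jd += Jd.T
            val, gh, GJ, _ = _pl_value_grad(X, h, Jd, *empty)
            return val, np.concatenate([gh, GJ[ut]])

        res = minimize(obj, np.zeros(n + len(ut[0])), jac=True,
                       method="L-BFGS-B", options={"maxiter": 2000})
        assert opt_val == pytest.approx(res.fun, abs=1e-4)

    def test_optimal_penalized_objective_monotone_in_lambda(self, small_data):
        # min_theta f + lam * pen is non-decreasing in lam
        values = []
        for lam in (0.002, 0.02, 0.2):
            m = fit_pairwise_l1(small_data, lam)
            pen = sum(abs(v) for v in m.J.values())
            values.append(pseudolikelihood_value(m, small_data) + lam * pen)
        assert values[0] <= values[1] + 1e-8 <= values[2] + 2e-8

    def test_planted_support_and_signs_recovered(self):
        model = random_sparse_model(15, pair_density=0.12, seed=1)
        train = sample_dataset(model, 20_000, seed=101, method="exact")
        val = sample_dataset(model, 8_000, seed=201, method="exact")
        grid = default_lambda_grid(train, order=2, n_points=16)
        best, path = select_lambda(train, val, grid, order=2)
        m = path.models[int(np.nonzero(path.lambdas == best)[0][0])]
        tp = set(m.J) & set(model.J)
        prec = len(tp) / max(len(m.J), 1)
        rec = len(tp) / len(model.J)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert f1 >= 0.8
        for p in tp:
            if abs(m.J[p]) > 0.2:
                assert np.sign(m.J[p]) == np.sign(model.J[p])


class TestHierarchicalGroupL1:
    def test_huge_lambda_empties_support(self, small_data):
        m = fit_hierarchical_group_l1(small_data, 1e3, max_admm_iter=50)
        assert not m.J and not m.K
        assert m.hierarchy_flag

    def test_output_support_is_hierarchical(self):
        model = planted_hierarchical_model(9, n_pairs=7, n_triplets=1, seed=6)
        data = sample_dataset(model, 8000, seed=7, method="exact")
        lam = lambda_max(data, order=3) / 25
        m = fit_hierarchical_group_l1(data, lam)
        m.check_hierarchy()  # raises on violation
        assert m.hierarchy_flag

    def test_planted_triplet_recovered(self):
        model = planted_hierarchical_model(9, n_pairs=7, n_triplets=1, seed=6)
        data = sample_dataset(model, 8000, seed=7, method="exact")
        lam = lambda_max(data, order=3) / 25
        m = fit_hierarchical_group_l1(data, lam)
        top = sorted(m.K.items(), key=lambda kv: -abs(kv[1]))[:5]
        assert list(model.K)[0] in {k for k, _ in top}


class TestSelectLambda:
    def test_single_value_grid_returned(self, small_data):
        best, path = select_lambda(small_data, small_data,
                                   np.array([0.05]), order=2)
        assert best == 0.05
        assert len(path.models) == 1

    def test_null_data_keeps_support_near_empty(self):
        null = random_sparse_model(10, pair_density=0.0, seed=41)
        train = sample_dataset(null, 20_000, seed=42, method="exact")
        val = sample_dataset(null, 8_000, seed=43, method="exact")
        grid = default_lambda_grid(train, order=2, n_points=10)
        best, path = select_lambda(train, val, grid, order=2)
        m = path.models[int(np.nonzero(path.lambdas == best)[0][0])]
        assert len(m.J) <= 2

    def test_best_score_not_worse_than_endpoints(self, small_data):
        half = small_data.n_bins // 2
        from chromcode.io_formats import ChromatinCodeMatrix
        train = ChromatinCodeMatrix(bins=small_data.bins[:half],
                                    factors=list(small_data.factors),
                                    calls=small_data.calls[:half])
        val = ChromatinCodeMatrix(bins=small_data.bins[half:],
                                  factors=list(small_data.factors),
                                  calls=small_data.calls[half:])
        grid = default_lambda_grid(train, order=2, n_points=8)
        best, path = select_lambda(train, val, grid, order=2, rule="min")
        i = int(np.nonzero(path.lambdas == best)[0][0])
        assert path.val_scores[i] <= path.val_scores[0] + 1e-12
        assert path.val_scores[i] <= path.val_scores[-1] + 1e-12

    def test_rejects_ascending_grid(self, small_data):
        with pytest.raises(ValueError, match="descending"):
            select_lambda(small_data, small_data, np.array([0.1, 0.2]))
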