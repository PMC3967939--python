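import numpy as np
import pytest

from chromcode import (
    MaxEntModel,
    count_parameters,
    energy,
    exact_log_partition,
    fit_independent,
    gibbs_sample,
    sample_dataset,
)
from chromcode.model_core import (
    enumerate_patterns,
    gibbs_sample_raw,
    log_probabilities,
    pattern_energies,
)


class TestEnergy:
    def test_all_zero_pattern_has_zero_energy(self, small_model):
        assert energy(np.zeros(small_model.n, dtype=int), small_model) == 0.0

    def test_single_active_factor_gives_self_energy(self):
        m = MaxEntModel(factors=["a", "b"], h={"a": -1.5}, J={("a", "b"): 2.0})
        assert energy([1, 0], m) == -1.5
        assert energy([0, 1], m) == 0.0  # b has no stored h

    def test_full_triple_sums_all_terms(self):
        m = MaxEntModel(
            factors=["a", "b", "c"],
            h={"a": 1.0, "b": 2.0, "c": 3.0},
            J={("a", "b"): 0.1, ("a", "c"): 0.2, ("b", "c"): 0.3},
            K={("a", "b", "c"): 0.7},
        )
        assert energy([1, 1, 1], m) == pytest.approx(1 + 2 + 3 + 0.6 + 0.7)


class TestExactPartition:
    @pytest.mark.parametrize(
        "factors,h,J,expected",
        [
            (["a"], {}, {}, np.log(2)),
            (["a", "b"], {}, {}, np.log(4)),
            (["a", "b"], {}, {("a", "b"): np.log(2)}, np.log(5)),
        ],
    )
    def test_closed_forms(self, factors, h, J, expected):
        m = MaxEntModel(factors=factors, h=h, J=J)
        assert exact_log_partition(m) == pytest.approx(expected)

    def test_enumeration_cap(self):
        m = MaxEntModel(factors=[f"f{i}" for i in range(21)])
        with pytest.raises(ValueError, match="capped"):
            exact_log_partition(m)

    def test_probabilities_sum_to_one(self, small_model):
        pats = enumerate_patterns(small_model.n)
        p = np.exp(log_probabilities(pats, small_model))
        assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_z_equals_inverse_probability_of_zero_pattern(self, small_model):
        p0 = np.exp(log_probabilities(np.zeros((1, small_model.n), dtype=np.int8),
                                      small_model))[0]
        assert np.log(1.0 / p0) == pytest.approx(small_model.logZ)

    def test_permuting_factors_preserves_probabilities(self, small_model):
        rng = np.random.default_rng(5)
        perm = rng.permutation(small_model.n)
        permuted = MaxEntModel(
            factors=[small_model.factors[i] for i in perm],
            h=dict(small_model.h), J=dict(small_model.J), K=dict(small_model.K),
        )
        permuted.logZ = exact_log_partition(permuted)
        assert permuted.logZ == pytest.approx(small_model.logZ)
        x = rng.integers(0, 2, small_model.n)
        x_perm = np.array([x[small_model.factors.index(f)]
                           for f in permuted.factors])
        assert energy(x_perm, permuted) == pytest.approx(energy(x, small_model))


class TestGibbs:
    def test_uniform_model_marginals(self):
        m = MaxEntModel(factors=[f"f{i}" for i in range(10)])
        s = gibbs_sample(m, 50_000, burn_in=100, seed=1)
        se = 0.5 / np.sqrt(50_000)
        assert np.all(np.abs(s.calls.mean(axis=0) - 0.5) < 3 * se + 0.005)

    def test_independent_model_matches_logit(self):
        p = 0.2
        h = float(np.log(p / (1 - p)))
        m = MaxEntModel(factors=["a", "b"], h={"a": h, "b": h})
        s = gibbs_sample(m, 50_000, burn_in=100, seed=2)
        assert np.all(np.abs(s.calls.mean(axis=0) - p) < 0.01)

    def test_total_variation_vs_enumeration(self, small_model):
        n = small_model.n
        s = gibbs_sample_raw(small_model, 500_000, burn_in=1000, seed=4)
        codes = (s.astype(np.int64) << 0) @ (1 << np.arange(n))
        emp = np.bincount(codes, minlength=2 ** n) / len(codes)
        exact = np.exp(log_probabilities(enumerate_patterns(n), small_model))
        assert 0.5 * np.abs(emp - exact).sum() < 0.02

    def test_deterministic_given_seed(self, small_model):
        a = gibbs_sample_raw(small_model, 100, burn_in=10, seed=9)
        b = gibbs_sample_raw(small_model, 100, burn_in=10, seed=9)
        np.testing.assert_array_equal(a, b)


class TestFitIndependent:
    def test_half_occupancy_gives_zero_h(self, rng):
        from chromcode.io_formats import ChromatinCodeMatrix
        calls = np.zeros((1000, 1), dtype=int)
        calls[:500] = 1
        data = ChromatinCodeMatrix(
            bins=[("c", i, i + 1) for i in range(1000)],
            factors=["A"], calls=calls,
        )
        m = fit_independent(data)
        assert m.h.get("A", 0.0) == pytest.approx(0.0, abs=1e-9)

    def test_logit_of_marginal(self):
        from chromcode.io_formats import ChromatinCodeMatrix
        # fraction 1/(1+e) -> h = -1 (up to pseudocount smoothing)
        N = 100_000
        k = round(N / (1 + np.e))
        calls = np.zeros((N, 1), dtype=int)
        calls[:k] = 1
        data = ChromatinCodeMatrix(
            bins=[("c", i, i + 1) for i in range(N)], factors=["A"], calls=calls,
        )
        assert fit_independent(data).h["A"] == pytest.approx(-1.0, abs=0.01)

    def test_probabilities_factorize(self, rng):
        from chromcode.io_formats import ChromatinCodeMatrix
        n = 5
        calls = (rng.random((2000, n)) < [0.1, 0.3, 0.5, 0.7, 0.9]).astype(int)
        data = ChromatinCodeMatrix(
            bins=[("c", i, i + 1) for i in range(2000)],
            factors=[f"f{i}" for i in range(n)], calls=calls,
        )
        m = fit_independent(data)
        pats = enumerate_patterns(n)
        p = np.exp(pattern_energies(pats, m) - m.logZ)
        h, _, _, _ = m.to_dense()
        marg = 1 / (1 + np.exp(-h))
        expect = np.prod(np.where(pats == 1, marg, 1 - marg), axis=1)
        np.testing.assert_allclose(p, expect, rtol=1e-10)

    def test_constant_column_clamped_with_warning(self):
        from chromcode.io_formats import ChromatinCodeMatrix
        data = ChromatinCodeMatrix(
            bins=[("c", i, i + 1) for i in range(100)],
            factors=["A"],
            calls=np.zeros((100, 1), dtype=int),
        )
        with pytest.warns(UserWarning, match="clamped"):
            m = fit_independent(data, pseudocount=1e-8)
        assert abs(m.h["A"]) <= 15.0


class TestCountParameters:
    def test_dense_73_factor_pairwise(self):
        m = MaxEntModel(factors=[f"f{i}" for i in range(73)])
        n_self, n_pair, n_trip = count_parameters(m, dense=True)
        assert (n_self, n_pair, n_trip) == (73, 2628, 0)
        assert n_self + n_pair == 2701

    def test_independent_counts(self):
        m = MaxEntModel(factors=[f"f{i}" for i in range(73)])
        assert count_parameters(m, dense=False) == (0, 0, 0)
        assert count_parameters(m, dense=True)[0] == 73

    def test_sparse_counts_stored_nonzeros(self):
        m = MaxEntModel(
            factors=["a", "b", "c", "d"],
            h={"a": 1.0},
            J={("a", "b"): 1, ("a", "c"): 1, ("a", "d"): 1, ("b", "c"): 1,
               ("b", "d"): 1},
        )
        assert count_parameters(m) == (1, 5, 0)


class TestSampleDatasetConsistency:
    def test_exact_and_gibbs_moments_agree(self, small_model):
        n = small_model.n
        a = sample_dataset(small_model, 100_000, seed=21, method="exact")
        b = sample_dataset(small_model, 100_000, seed=22, method="gibbs")
        ma = (a.calls[:, :, None] * a.calls[:, None, :]).mean(axis=0)
        mb = (b.calls[:, :, None] * b.calls[:, None, :]).mean(axis=0)
        se = np.sqrt(0.25 / 100_000) * 2  # both sides carry MC noise
        assert np.abs(ma - mb).max() < 3 * se + 0.01
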