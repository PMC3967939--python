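import numpy as np
import pytest

from chromcode import (
    EvaluationStandard,
    MaxEntModel,
    SignalMatrix,
    baseline_scores,
    fit_pairwise_l1,
    interaction_energy_scores,
    precision_recall_bootstrap,
    random_sparse_model,
    sample_dataset,
)
from chromcode.interactions import InteractionScoreTable, precision_at_k


def _table(pairs_scores):
    import pandas as pd
    rows = [{"factor_a": a, "factor_b": b, "score": s}
            for (a, b), s in pairs_scores]
    df = pd.DataFrame(rows).sort_values("score", ascending=False)
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return InteractionScoreTable(table=df, order=2)


class TestInteractionEnergyScores:
    def test_single_pair_model(self):
        m = MaxEntModel(factors=["a", "b", "c"], J={("a", "b"): 2.0})
        t = interaction_energy_scores(m, order=2)
        assert len(t.table) == 1
        row = t.table.iloc[0]
        assert (row.factor_a, row.factor_b, row.score) == ("a", "b", 2.0)

    def test_relabeling_invariance(self):
        m1 = MaxEntModel(factors=["a", "b"], J={("a", "b"): 1.5})
        m2 = MaxEntModel(factors=["x", "y"], J={("x", "y"): 1.5})
        t1 = interaction_energy_scores(m1).pairs()
        t2 = interaction_energy_scores(m2).pairs()
        assert list(t1.values()) == list(t2.values())

    def test_order3_from_pairwise_model_rejected(self):
        m = MaxEntModel(factors=["a", "b"], J={("a", "b"): 1.0})
        with pytest.raises(ValueError):
            interaction_energy_scores(m, order=3)

    def test_planted_magnitudes_recovered_in_rank(self):
        model = random_sparse_model(15, pair_density=0.12, seed=1)
        data = sample_dataset(model, 20_000, seed=2, method="exact")
        fit = fit_pairwise_l1(data, 0.01)
        est = interaction_energy_scores(fit).pairs()
        from scipy.stats import spearmanr
        truth = sorted(model.J)
        rho = spearmanr(
            [abs(model.J[p]) for p in truth],
            [abs(est.get(p, 0.0)) for p in truth],
        ).statistic
        assert rho > 0.8

    def test_bystander_factor_leaves_scores_stable(self):
        # adding a factor that interacts with nobody moves no planted J much
        model = random_sparse_model(8, pair_density=0.3, seed=33)
        data = sample_dataset(model, 30_000, seed=34, method="exact")
        fit_small = fit_pairwise_l1(data, 0.005)
        grown = MaxEntModel(factors=model.factors + ["bystander"],
                            h=dict(model.h) | {"bystander": -1.0},
                            J=dict(model.J))
        data_big = sample_dataset(grown, 30_000, seed=34, method="exact")
        fit_big = fit_pairwise_l1(data_big, 0.005)
        small = interaction_energy_scores(fit_small).pairs()
        big = interaction_energy_scores(fit_big).pairs()
        for p in model.J:
            assert abs(small.get(p, 0.0) - big.get(p, 0.0)) < 0.1


class TestPrecisionRecallBootstrap:
    def test_perfect_ranking_gives_unit_precision(self):
        pairs = [(f"f{i}", f"g{i}") for i in range(20)]
        scores = _table([(p, 20 - i) for i, p in enumerate(pairs)])
        std = EvaluationStandard(set(pairs[:5]))
        pr = precision_recall_bootstrap(scores, std, n_boot=50, seed=1)
        assert np.all(pr["precision"].to_numpy() == 1.0)

    def test_perfect_ranking_seed_independent(self):
        pairs = [(f"f{i}", f"g{i}") for i in range(10)]
        scores = _table([(p, 10 - i) for i, p in enumerate(pairs)])
        std = EvaluationStandard(set(pairs[:3]))
        a = precision_recall_bootstrap(scores, std, n_boot=20, seed=1)
        b = precision_recall_bootstrap(scores, std, n_boot=20, seed=99)
        np.testing.assert_array_equal(a["precision"], b["precision"])

    def test_random_ranking_recovers_background_precision(self, rng):
        # background precision = positive fraction (0.10); estimated at a
        # size where the small-sample bias of precision-at-recall is gone,
        # averaging over a few independent random rankings
        pairs = [(f"f{i}", f"g{i}") for i in range(500)]
        std = EvaluationStandard(set(pairs[:50]))
        mids = []
        for trial in range(3):
            scores = _table([(p, rng.random()) for p in pairs])
            pr = precision_recall_bootstrap(scores, std, n_boot=150,
                                            seed=trial)
            mid = pr[(pr["recall"] >= 0.2) & (pr["recall"] <= 0.9)]
            mids.append(np.mean(mid["precision"]))
        assert np.mean(mids) == pytest.approx(0.10, abs=0.03)

    def test_single_round_equals_plain_pr_of_resample(self):
        pairs = [(f"f{i}", f"g{i}") for i in range(10)]
        scores = _table([(p, 10 - i) for i, p in enumerate(pairs)])
        std = EvaluationStandard({pairs[0], pairs[4]})
        from chromcode.interactions import _pr_curve
        pr = precision_recall_bootstrap(scores, std, n_boot=1, seed=3)
        rng2 = np.random.default_rng(3)
        positives = sorted(std.pairs)
        idx = rng2.integers(0, len(positives), size=len(positives))
        expect = _pr_curve([(min(a, b), max(a, b)) for a, b in pairs],
                           [positives[i] for i in idx], std.pairs)
        np.testing.assert_allclose(pr["precision"], expect)

    def test_empty_standard_rejected(self):
        scores = _table([(("a", "b"), 1.0)])
        with pytest.raises(ValueError):
            precision_recall_bootstrap(scores, EvaluationStandard(set()))

    def test_precision_at_k(self):
        pairs = [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h")]
        scores = _table([(p, 4 - i) for i, p in enumerate(pairs)])
        std = EvaluationStandard({("a", "b"), ("e", "f")})
        assert precision_at_k(scores, std, 2) == 0.5
        assert precision_at_k(scores, std, 3) == pytest.approx(2 / 3)


class TestBaselines:
    def test_identical_binary_columns_have_mi_equal_marginal_entropy(self):
        from chromcode.io_formats import ChromatinCodeMatrix
        col = np.array([0, 0, 1, 1, 1, 0, 1, 0, 1, 1])
        data = ChromatinCodeMatrix(
            bins=[("c", i, i + 1) for i in range(10)],
            factors=["A", "B"],
            calls=np.column_stack([col, col]),
        )
        t = baseline_scores(data, method="mutual_information")
        p = col.mean()
        entropy = -(p * np.log(p) + (1 - p) * np.log(1 - p))
        assert t.table.iloc[0].score == pytest.approx(entropy)

    def test_independent_columns_have_small_pearson(self, rng):
        n, f = 10_000, 8
        sm = SignalMatrix(
            bins=[("c", i, i + 1) for i in range(n)],
            factors=[f"f{i}" for i in range(f)],
            values=rng.normal(size=(n, f)),
        )
        t = baseline_scores(sm, method="pearson")
        frac_small = (t.table["score"].abs() < 0.05).mean()
        assert frac_small >= 0.95

    def test_partial_correlation_removes_transitive_link(self, rng):
        # chain X -> Y -> Z: pearson(X,Z) > 0 but pcor(X,Z|Y) ~ 0
        n = 20_000
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n) * 0.6
        z = 0.8 * y + rng.normal(size=n) * 0.6
        sm = SignalMatrix(
            bins=[("c", i, i + 1) for i in range(n)],
            factors=["X", "Y", "Z"],
            values=np.column_stack([x, y, z]),
        )
        pear = baseline_scores(sm, method="pearson").pairs()
        pcor = baseline_scores(sm, method="partial_correlation").pairs()
        assert pear[("X", "Z")] > 0.3
        assert abs(pcor[("X", "Z")]) < 0.05

    def test_method_type_mismatch_rejected(self, small_data):
        with pytest.raises(TypeError):
            baseline_scores(small_data, method="pearson")
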