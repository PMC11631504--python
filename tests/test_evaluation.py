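import numpy as np
import pandas as pd
import pytest

from ridgepath import (
    aggregate,
    lambda_ratio_diagnostic,
    nrmse,
    outer_evaluate,
    pearson_cor,
    simulate_genotypes,
    simulate_phenotype,
)
from ridgepath.evaluation import EvaluationReport


class TestPearsonCor:
    def test_affine_invariance(self, rng):
        y = rng.normal(size=20)
        assert pearson_cor(y, 2 * y + 1) == pytest.approx(1.0)
        assert pearson_cor(y, -y) == pytest.approx(-1.0)
        assert pearson_cor(y, 0.1 * y - 5) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert pearson_cor([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_returns_nan(self):
        assert np.isnan(pearson_cor([1, 2, 3], [5, 5, 5]))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pearson_cor([1, 2], [3, 4])


class TestNrmse:
    def test_perfect_prediction_is_zero(self, rng):
        y = rng.normal(size=10) + 5
        assert nrmse(y, y) == 0.0

    def test_unit_error_over_mean_two(self):
        assert nrmse([2, 2, 2, 2], [3, 3, 3, 3]) == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        y = rng.uniform(1, 3, 15)
        p = y + rng.normal(size=15) * 0.2
        assert nrmse(3.7 * y, 3.7 * p) == pytest.approx(nrmse(y, p), rel=1e-12)

    def test_plain_variant_is_unrooted(self):
        # MSE 1, mean 2: plain 0.5, sqrt 0.5 coincide only when MSE = 1
        assert nrmse([2, 2], [3, 3], variant="plain") == pytest.approx(0.5)
        assert nrmse([2, 2], [4, 4], variant="plain") == pytest.approx(2.0)
        assert nrmse([2, 2], [4, 4], variant="sqrt") == pytest.approx(1.0)

    def test_zero_mean_response_raises(self):
        with pytest.raises(ValueError, match="zero-mean"):
            nrmse([-1.0, 1.0], [0.0, 0.0])


@pytest.fixture(scope="module")
def bench_report():
    X = simulate_genotypes(80, 300, ld_rho=0.3, seed=71)
    y, _ = simulate_phenotype(X, 30, 0.5, seed=72)
    return outer_evaluate(
        X, y, methods=("conventional", "variance_ratio", "gblup"),
        k_outer=5, k_inner=5, seed=73,
    )


class TestOuterEvaluate:
    def test_outer_folds_partition_the_sample(self, bench_report):
        a = bench_report.fold_assignment
        assert a.size == 80 and set(a) == set(range(5))

    def test_every_method_scored_on_every_fold(self, bench_report):
        counts = bench_report.per_fold.groupby("method")["fold"].nunique()
        assert (counts == 5).all()
        assert bench_report.per_fold["nrmse"].notna().all()

    def test_rerun_is_identical(self, bench_report):
        X = simulate_genotypes(80, 300, ld_rho=0.3, seed=71)
        y, _ = simulate_phenotype(X, 30, 0.5, seed=72)
        rep2 = outer_evaluate(
            X, y, methods=("conventional", "variance_ratio", "gblup"),
            k_outer=5, k_inner=5, seed=73,
        )
        pd.testing.assert_frame_equal(bench_report.per_fold, rep2.per_fold)

    def test_null_heritability_gives_near_zero_cor(self):
        cors = []
        for seed in range(3):
            X = simulate_genotypes(60, 150, seed=81 + seed)
            y, _ = simulate_phenotype(X, 20, 0.0, seed=91 + seed)
            rep = outer_evaluate(X, y, methods=("variance_ratio",),
                                 k_outer=5, k_inner=5, seed=seed)
            cors.append(rep.per_fold["cor"].mean())
        # mean fold Cor across replicates within 2 SE of zero
        se = np.std(cors, ddof=1) / np.sqrt(len(cors))
        assert abs(np.mean(cors)) < max(2 * se, 0.15)

    def test_unknown_method_rejected(self, small_dataset):
        X, y, _ = small_dataset
        with pytest.raises(ValueError, match="unknown method"):
            outer_evaluate(X, y, methods=("bogus",))


class TestLambdaRatio:
    def test_log_ratio_definition(self):
        pf = pd.DataFrame({
            "method": ["conventional", "variance_ratio"] * 2,
            "dataset": "d", "trait": "t",
            "fold": [0, 0, 1, 1],
            "cor": 0.5, "nrmse": 0.1,
            "lambda_opt": [10.0, 1.0, 2.0, 2.0],
        })
        rep = EvaluationReport(per_fold=pf, fold_assignment=np.zeros(4, int), seed=0)
        out = lambda_ratio_diagnostic(rep)
        assert out["log_ratio"].tolist() == pytest.approx([np.log(10.0), 0.0])
        assert out.attrs["n_positive"] == 1

    def test_requires_both_grid_methods(self, bench_report):
        only = bench_report.per_fold[bench_report.per_fold.method == "gblup"]
        rep = EvaluationReport(per_fold=only, fold_assignment=np.zeros(1, int),
                               seed=0)
        with pytest.raises(ValueError):
            lambda_ratio_diagnostic(rep)

    def test_majority_positive_in_p_much_greater_than_n_regime(self, bench_report):
        out = lambda_ratio_diagnostic(bench_report)
        assert out.attrs["n_positive"] > out.attrs["n_folds"] / 2


class TestAggregate:
    def _report(self, trait, cors, dataset="d"):
        pf = pd.DataFrame({
            "method": "variance_ratio", "dataset": dataset, "trait": trait,
            "fold": range(len(cors)), "cor": cors, "nrmse": 0.1,
            "lambda_opt": 1.0,
        })
        return EvaluationReport(per_fold=pf, fold_assignment=np.zeros(1, int),
                                seed=0, dataset=dataset, trait=trait)

    def test_mean_and_sample_sd_hand_computed(self):
        tables = aggregate([self._report("t1", [0.1, 0.2, 0.3])])
        row = tables["per_trait"].iloc[0]
        assert row["cor"] == pytest.approx(0.2)
        assert row["cor_sd"] == pytest.approx(0.1)

    def test_single_trait_dataset_has_zero_sd(self):
        tables = aggregate([self._report("t1", [0.1, 0.3])])
        assert tables["per_dataset"].iloc[0]["cor_sd"] == 0.0

    def test_identical_reports_give_zero_across_dataset_sd(self):
        r1 = self._report("t", [0.2, 0.4], dataset="d1")
        r2 = self._report("t", [0.2, 0.4], dataset="d2")
        tables = aggregate([r1, r2])
        assert tables["across_datasets"].iloc[0]["cor_sd"] == 0.0

    def test_per_trait_means_recompute_from_per_fold(self, bench_report):
        tables = aggregate([bench_report])
        pf = bench_report.per_fold
        for _, row in tables["per_trait"].iterrows():
            sel = pf[pf.method == row["method"]]
            assert row["cor"] == pytest.approx(sel["cor"].mean())
            assert row["nrmse"] == pytest.approx(sel["nrmse"].mean())

    def test_gain_column_matches_definition(self, bench_report):
        tables = aggregate([bench_report])
        pt = tables["per_trait"].set_index("method")
        expected = 100 * (pt.loc["variance_ratio", "cor"]
                          - pt.loc["conventional", "cor"]) / pt.loc["conventional", "cor"]
        assert tables["gain"].iloc[0]["cor_gain_pct"] == pytest.approx(expected)

    def test_inconsistent_method_sets_rejected(self, bench_report):
        with pytest.raises(ValueError, match="inconsistent"):
            aggregate([bench_report, self._report("t9", [0.1, 0.2])])
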