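import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radbench import CohortConfig, generate_cohort
from radbench.evaluation import concordance_index
from radbench.predictors import (
    MODEL_NAMES,
    ModelSpec,
    PredictorModel,
    aggregate_mrmr_signature,
    fit_elastic_net,
    fit_mrmr,
    fit_rank_ensemble,
    fit_rank_multivariate,
    fit_single_gene,
    mrmr_select,
    predict,
    variance_filter,
)


def toy_matrix(rng, n_genes=20, n_samples=50, prefix="g"):
    data = rng.normal(size=(n_genes, n_samples))
    return pd.DataFrame(
        data,
        index=[f"{prefix}{i:03d}" for i in range(n_genes)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )


@pytest.fixture(scope="module")
def recovery_cohort():
    """30 planted genes, strong effect, low noise: signature recovery case."""
    cfg = CohortConfig(
        n_samples=500,
        n_tissues=1,
        tissue_effect_sd=0.0,
        n_genes=150,
        n_signal_genes=30,
        signal_effect=4.0,
        expression_noise_sd=0.0,
        latent_noise_sd=0.1,
        survival_noise_sd=0.0,
        seed=31,
    )
    return generate_cohort(cfg)


class TestVarianceFilter:
    def test_keep_all_is_identity(self, rng):
        expr = toy_matrix(rng)
        assert set(variance_filter(expr, 20)) == set(expr.index)

    def test_constant_gene_dropped(self, rng):
        expr = toy_matrix(rng, n_genes=10)
        expr.loc["g000"] = 3.14
        kept = variance_filter(expr, 9)
        assert "g000" not in kept

    def test_matches_brute_force_sort(self, rng):
        expr = toy_matrix(rng, n_genes=10, n_samples=15)
        expected = sorted(
            expr.index, key=lambda g: (-np.var(expr.loc[g], ddof=1), g)
        )[:6]
        assert variance_filter(expr, 6) == expected

    def test_invalid_n_keep(self, rng):
        expr = toy_matrix(rng, n_genes=5)
        with pytest.raises(ValueError):
            variance_filter(expr, 0)
        with pytest.raises(ValueError):
            variance_filter(expr, 6)


class TestSingleGene:
    def test_exact_linear_case(self, rng):
        expr = toy_matrix(rng, n_genes=5)
        y = 2.0 * expr.loc["g002"].to_numpy() + 3.0
        model = fit_single_gene(expr, y)
        assert model.selected_genes == ["g002"]
        assert model.coefficients["g002"] == pytest.approx(2.0, abs=1e-10)
        assert model.intercept == pytest.approx(3.0, abs=1e-10)

    def test_planted_gene_selected(self, rng):
        expr = toy_matrix(rng, n_genes=30)
        y = expr.loc["g017"].to_numpy() + 0.05 * rng.normal(size=50)
        model = fit_single_gene(expr, y)
        assert model.selected_genes == ["g017"]

    def test_training_ci_beats_every_other_gene(self, rng):
        expr = toy_matrix(rng, n_genes=25, n_samples=60)
        y = expr.loc["g010"].to_numpy() * 1.5 + 0.3 * rng.normal(size=60)
        model = fit_single_gene(expr, y)
        best_ci = concordance_index(predict(model, expr).to_numpy(), y)
        for g in expr.index:
            slope, icpt = np.polyfit(expr.loc[g], y, 1)
            ci = concordance_index(slope * expr.loc[g].to_numpy() + icpt, y)
            assert best_ci >= ci - 1e-12

    def test_all_constant_rejected(self):
        expr = pd.DataFrame(np.ones((3, 10)), index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            fit_single_gene(expr, np.arange(10.0))


class TestRankEnsemble:
    def test_size_one_equals_single_gene(self, rng):
        expr = toy_matrix(rng, n_genes=15)
        y = expr.loc["g003"].to_numpy() + 0.2 * rng.normal(size=50)
        single = fit_single_gene(expr, y)
        ens = fit_rank_ensemble(expr, y, signature_size=1)
        np.testing.assert_allclose(
            predict(ens, expr).to_numpy(), predict(single, expr).to_numpy(), atol=1e-12
        )

    def test_prediction_is_mean_of_univariate_members(self, rng):
        expr = toy_matrix(rng, n_genes=12)
        y = expr.iloc[0].to_numpy() - expr.iloc[1].to_numpy() + 0.1 * rng.normal(size=50)
        model = fit_rank_ensemble(expr, y, signature_size=4)
        members = model.hyperparameters["univariate"]
        manual = np.mean(
            [
                slope * expr.loc[g].to_numpy() + icpt
                for g, (slope, icpt) in members.items()
            ],
            axis=0,
        )
        np.testing.assert_allclose(predict(model, expr).to_numpy(), manual, atol=1e-12)

    def test_duplicated_gene_selected_twice_prediction_unchanged(self, rng):
        expr = toy_matrix(rng, n_genes=6)
        y = expr.loc["g001"].to_numpy() + 0.05 * rng.normal(size=50)
        dup = expr.loc[["g001"]].rename(index={"g001": "g001dup"})
        expr_dup = pd.concat([expr, dup])
        model = fit_rank_ensemble(expr_dup, y, signature_size=2)
        assert set(model.selected_genes) == {"g001", "g001dup"}
        single = fit_single_gene(expr, y)
        np.testing.assert_allclose(
            predict(model, expr_dup).to_numpy(),
            predict(single, expr).to_numpy(),
            atol=1e-10,
        )

    def test_planted_signature_recovery(self, recovery_cohort):
        cohort = recovery_cohort
        model = fit_rank_ensemble(
            cohort.expression, cohort.truth.true_sf2, signature_size=30
        )
        recovered = set(model.selected_genes) & set(cohort.truth.signal_gene_ids)
        assert len(recovered) >= 0.8 * 30

    def test_invalid_size(self, rng):
        expr = toy_matrix(rng)
        with pytest.raises(ValueError):
            fit_rank_ensemble(expr, np.arange(50.0), signature_size=0)


class TestRankMultivariate:
    def test_orthogonal_signal_recovered(self):
        rng = np.random.default_rng(5)
        expr = toy_matrix(rng, n_genes=6, n_samples=80)
        y = expr.loc["g000"].to_numpy() - expr.loc["g001"].to_numpy()
        model = fit_rank_multivariate(expr, y, signature_size=2)
        assert set(model.selected_genes) == {"g000", "g001"}
        assert model.coefficients["g000"] == pytest.approx(1.0, abs=1e-8)
        assert model.coefficients["g001"] == pytest.approx(-1.0, abs=1e-8)

    def test_collinear_duplicates_finite(self, rng):
        expr = toy_matrix(rng, n_genes=4)
        expr.loc["g003"] = expr.loc["g000"]  # exact duplicate
        y = expr.loc["g000"].to_numpy() + 0.1 * rng.normal(size=50)
        model = fit_rank_multivariate(expr, y, signature_size=4)
        assert all(np.isfinite(list(model.coefficients.values())))
        assert np.all(np.isfinite(predict(model, expr)))

    def test_training_mse_not_worse_than_ensemble(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            expr = toy_matrix(r, n_genes=40, n_samples=60)
            y = (
                expr.iloc[0].to_numpy()
                + 0.5 * expr.iloc[1].to_numpy()
                + 0.3 * r.normal(size=60)
            )
            multi = fit_rank_multivariate(expr, y, signature_size=8)
            ens = fit_rank_ensemble(expr, y, signature_size=8)
            assert multi.selected_genes == ens.selected_genes
            mse_multi = np.mean((predict(multi, expr).to_numpy() - y) ** 2)
            mse_ens = np.mean((predict(ens, expr).to_numpy() - y) ** 2)
            assert mse_multi <= mse_ens + 1e-10


def mrmr_oracle_mi(a, b):
    rho = stats.spearmanr(a, b).statistic
    r2 = min(rho * rho, 1 - 1e-12)
    return -0.5 * np.log(1 - r2)


class TestMrmr:
    def test_greedy_steps_match_exhaustive_enumeration(self, rng):
        # per-step oracle: at every step the chosen gene maximizes the
        # relevance - mean-redundancy criterion over remaining candidates
        expr = toy_matrix(rng, n_genes=20, n_samples=40)
        y = expr.iloc[0].to_numpy() + 0.5 * expr.iloc[3].to_numpy()
        y = y + 0.3 * rng.normal(size=40)
        sols = mrmr_select(expr, y, signature_size=6, method="exhaustive", K=1)
        solution = sols.solutions[0]
        genes = list(expr.index)
        relevance = {g: mrmr_oracle_mi(expr.loc[g], y) for g in genes}
        mi = {
            (a, b): mrmr_oracle_mi(expr.loc[a], expr.loc[b])
            for a in genes
            for b in genes
        }
        assert solution[0] == max(genes, key=lambda g: (relevance[g], g))
        selected = [solution[0]]
        for step in range(1, 6):
            crits = {
                g: relevance[g] - np.mean([mi[(g, s)] for s in selected])
                for g in genes
                if g not in selected
            }
            best_value = max(crits.values())
            assert crits[solution[step]] == pytest.approx(best_value, abs=1e-9)
            selected.append(solution[step])

    def test_exhaustive_first_features_distinct(self, rng):
        expr = toy_matrix(rng, n_genes=25, n_samples=40)
        y = expr.iloc[0].to_numpy() + 0.5 * rng.normal(size=40)
        sols = mrmr_select(expr, y, signature_size=5, method="exhaustive", K=6)
        firsts = [s[0] for s in sols.solutions]
        assert len(set(firsts)) == 6

    def test_duplicated_gene_penalized_by_redundancy(self, rng):
        expr = toy_matrix(rng, n_genes=10, n_samples=60)
        y = expr.loc["g000"].to_numpy() + 0.2 * rng.normal(size=60)
        expr.loc["g009"] = expr.loc["g000"]  # perfect duplicate of the top gene
        sols = mrmr_select(expr, y, signature_size=5, method="exhaustive", K=1)
        solution = sols.solutions[0]
        # one copy leads; the redundant copy cannot appear among the early picks
        assert solution[0] == "g000"
        assert "g009" not in solution[1:4]

    def test_bootstrap_reproducible(self, rng):
        expr = toy_matrix(rng, n_genes=30, n_samples=50)
        y = expr.iloc[0].to_numpy() + 0.5 * rng.normal(size=50)
        a = mrmr_select(expr, y, 5, "bootstrap", K=4, seed=7)
        b = mrmr_select(expr, y, 5, "bootstrap", K=4, seed=7)
        assert a.solutions == b.solutions

    def test_methods_agree_on_easy_instance(self, recovery_cohort):
        cohort = recovery_cohort
        y = cohort.truth.true_sf2
        ex = fit_mrmr(cohort.expression, y, 20, "exhaustive", K=5, seed=0)
        bo = fit_mrmr(cohort.expression, y, 20, "bootstrap", K=5, seed=0)
        a, b = set(ex.selected_genes), set(bo.selected_genes)
        jaccard = len(a & b) / len(a | b)
        assert jaccard >= 0.5

    def test_signature_size_one_is_most_relevant_gene(self, rng):
        expr = toy_matrix(rng, n_genes=15, n_samples=40)
        y = expr.loc["g007"].to_numpy() + 0.1 * rng.normal(size=40)
        sols = mrmr_select(expr, y, 1, "exhaustive", K=1)
        assert sols.solutions[0] == ["g007"]

    def test_aggregation_by_frequency(self):
        from radbench.predictors import MRMRSolutionSet

        sols = MRMRSolutionSet(
            solutions=[["a", "b", "c"], ["b", "a", "d"], ["e", "b", "a"]],
            method="bootstrap",
            K=3,
            criterion_trace=[[0.0] * 3] * 3,
        )
        # freq: a=3,b=3 with mean positions 1 vs 2/3 -> b first; among the
        # freq-1 genes e has the smallest mean position (0)
        assert aggregate_mrmr_signature(sols, 3) == ["b", "a", "e"]

    def test_invalid_method(self, rng):
        expr = toy_matrix(rng)
        with pytest.raises(ValueError):
            mrmr_select(expr, np.arange(50.0), 5, "magic", K=1)


class TestElasticNet:
    def test_full_shrinkage_predicts_mean(self, rng):
        expr = toy_matrix(rng, n_genes=10)
        y = expr.iloc[0].to_numpy() + rng.normal(size=50)
        model = fit_elastic_net(expr, y, fixed_lambda=np.exp(5))
        assert model.coefficients == {}
        np.testing.assert_allclose(
            predict(model, expr).to_numpy(), np.full(50, y.mean()), atol=1e-8
        )

    def test_tiny_penalty_approaches_ols(self, rng):
        expr = toy_matrix(rng, n_genes=5, n_samples=100)
        beta_true = np.array([1.0, -0.5, 0.8, 0.0, 0.3])
        y = beta_true @ expr.to_numpy() + 0.05 * rng.normal(size=100)
        model = fit_elastic_net(expr, y, fixed_lambda=np.exp(-6))
        design = np.column_stack([np.ones(100), expr.to_numpy().T])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        fitted = np.array([model.coefficients.get(g, 0.0) for g in expr.index])
        assert np.linalg.norm(fitted - ols[1:]) < 0.05

    def test_sparse_support_recovery(self):
        rng = np.random.default_rng(12)
        expr = toy_matrix(rng, n_genes=1000, n_samples=150)
        true_genes = ["g010", "g200", "g400", "g600", "g800"]
        y = sum(expr.loc[g].to_numpy() for g in true_genes)
        y = y + 0.3 * rng.normal(size=150)
        model = fit_elastic_net(expr, y, n_lambda=50, seed=0)
        recovered = set(model.selected_genes) & set(true_genes)
        assert len(recovered) >= 4

    def test_sparsity_monotone_in_lambda(self, rng):
        expr = toy_matrix(rng, n_genes=30, n_samples=60)
        y = expr.iloc[0].to_numpy() + 0.5 * expr.iloc[1].to_numpy()
        y = y + 0.2 * rng.normal(size=60)
        counts = []
        for gamma in np.linspace(-6, 5, 12):
            model = fit_elastic_net(expr, y, fixed_lambda=np.exp(gamma))
            counts.append(len(model.selected_genes))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_constant_outcome_intercept_only(self, rng):
        expr = toy_matrix(rng, n_genes=5)
        model = fit_elastic_net(expr, np.full(50, 0.7))
        assert model.coefficients == {}
        assert model.intercept == pytest.approx(0.7)

    def test_deterministic_given_seed(self, rng):
        expr = toy_matrix(rng, n_genes=50)
        y = expr.iloc[0].to_numpy() + 0.3 * rng.normal(size=50)
        a = fit_elastic_net(expr, y, n_lambda=20, seed=3)
        b = fit_elastic_net(expr, y, n_lambda=20, seed=3)
        assert a.coefficients == b.coefficients
        assert a.hyperparameters["lambda"] == b.hyperparameters["lambda"]


class TestPredictContract:
    def test_training_predictions_reproduced(self, rng):
        expr = toy_matrix(rng, n_genes=10)
        y = expr.iloc[0].to_numpy() + 0.2 * rng.normal(size=50)
        model = fit_rank_multivariate(expr, y, 3)
        p1 = predict(model, expr)
        p2 = predict(model, expr)
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())

    def test_column_permutation_permutes_predictions(self, rng):
        expr = toy_matrix(rng, n_genes=8)
        y = expr.iloc[0].to_numpy()
        model = fit_rank_ensemble(expr, y, 3)
        perm = rng.permutation(expr.columns)
        p_orig = predict(model, expr)
        p_perm = predict(model, expr[perm])
        np.testing.assert_allclose(
            p_perm.to_numpy(), p_orig.loc[perm].to_numpy(), atol=1e-14
        )

    def test_missing_genes_error_lists_them(self, rng):
        expr = toy_matrix(rng, n_genes=6)
        y = expr.iloc[0].to_numpy()
        model = fit_rank_multivariate(expr, y, 3)
        reduced = expr.drop(index=model.selected_genes[:2])
        with pytest.raises(ValueError) as err:
            predict(model, reduced)
        for g in model.selected_genes[:2]:
            assert g in str(err.value)

    def test_unfitted_model_rejected(self):
        model = PredictorModel("single_gene", [], {}, 0.0, fitted=False)
        with pytest.raises(ValueError, match="not fitted"):
            predict(model, pd.DataFrame(np.ones((2, 3)), index=["a", "b"]))

    def test_json_roundtrip(self, rng):
        expr = toy_matrix(rng, n_genes=10)
        y = expr.iloc[0].to_numpy() + 0.1 * rng.normal(size=50)
        model = fit_rank_multivariate(expr, y, 4)
        back = PredictorModel.from_json(model.to_json())
        assert back == model
        np.testing.assert_array_equal(
            predict(back, expr).to_numpy(), predict(model, expr).to_numpy()
        )


class TestModelSpec:
    def test_all_six_families_fit_and_predict(self, rng):
        expr = toy_matrix(rng, n_genes=60, n_samples=60)
        y = expr.iloc[0].to_numpy() + 0.3 * rng.normal(size=60)
        for name in MODEL_NAMES:
            spec = ModelSpec(name=name, signature_size=5, n_keep=40, K=3, n_lambda=10)
            model = spec.fit(expr, y, seed=1)
            assert model.fitted
            pred = predict(model, expr)
            assert len(pred) == 60
            assert np.all(np.isfinite(pred))

    def test_determinism_across_families(self, rng):
        expr = toy_matrix(rng, n_genes=50, n_samples=50)
        y = expr.iloc[0].to_numpy() + 0.3 * rng.normal(size=50)
        for name in MODEL_NAMES:
            spec = ModelSpec(name=name, signature_size=5, n_keep=40, K=3, n_lambda=10)
            a = spec.fit(expr, y, seed=9)
            b = spec.fit(expr, y, seed=9)
            assert a == b, name

    def test_selection_invariant_to_monotone_gene_transform(self, rng):
        expr = toy_matrix(rng, n_genes=20, n_samples=50)
        y = expr.loc["g004"].to_numpy() + 0.2 * rng.normal(size=50)
        base = fit_rank_ensemble(expr, y, 5).selected_genes
        warped = expr.copy()
        warped.loc["g004"] = np.exp(warped.loc["g004"])  # strictly increasing
        assert fit_rank_ensemble(warped, y, 5).selected_genes == base

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec(name="random_forest")

    def test_prefilter_cap_respected(self, rng):
        expr = toy_matrix(rng, n_genes=50, n_samples=40)
        y = expr.iloc[0].to_numpy() + 0.2 * rng.normal(size=40)
        spec = ModelSpec(name="rank_multivariate", signature_size=5, n_keep=10)
        model = spec.fit(expr, y)
        prefiltered = set(variance_filter(expr, 10))
        assert set(model.selected_genes) <= prefiltered
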