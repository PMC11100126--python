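"""Tests for variant QC, GWAS, trainers, scoring and the final model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from prseval.prs import (
    DEFAULT_P_GRID,
    PolygenicModel,
    PredictionModel,
    WeightVector,
    filter_variants,
    fit_final_model,
    fit_pc_basis,
    marginal_gwas,
    predict,
    prune_and_threshold,
    ridge_trainer,
    score,
)
from prseval.synth import GenotypeMatrix


def make_geno(dosages, ids=None, ea=None, oa=None, pops=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=np.array(ids if ids is not None else [f"v{j}" for j in range(m)]),
        effect_alleles=np.array(ea if ea is not None else ["A"] * m),
        other_alleles=np.array(oa if oa is not None else ["G"] * m),
        sample_ids=np.array([f"s{i}" for i in range(n)]),
        population_labels=np.array(pops if pops is not None else ["train"] * n),
    )


class TestFilterVariants:
    def test_zero_thresholds_keep_everything(self, filter_fixture):
        g, _, _ = filter_fixture
        out, report = filter_variants(g, 0.0, 0.0)
        assert out.n_variants == g.n_variants
        assert report["kept"].all()

    def test_primary_filter_matches_hand_count(self, filter_fixture):
        g, expected_primary, _ = filter_fixture
        out, report = filter_variants(g, 0.90, 0.001)
        assert set(out.variant_ids) == expected_primary
        removed = report.loc[~report["kept"]]
        assert (removed["reason"] != "").all()

    def test_stringent_filter_matches_hand_count(self, filter_fixture):
        g, _, expected_stringent = filter_fixture
        out, _ = filter_variants(g, 0.99, 0.01)
        assert set(out.variant_ids) == expected_stringent

    def test_stricter_thresholds_give_subset(self, filter_fixture, rng):
        g, _, _ = filter_fixture
        loose, _ = filter_variants(g, 0.85, 0.0005)
        strict, _ = filter_variants(g, 0.99, 0.01)
        assert set(strict.variant_ids) <= set(loose.variant_ids)

    def test_everything_removed_raises(self, filter_fixture):
        g, _, _ = filter_fixture
        with pytest.raises(ValueError, match="all .* removed"):
            filter_variants(g, 1.0, 0.49)

    def test_statistics_computed_on_supplied_individuals(self, filter_fixture):
        g, _, _ = filter_fixture
        # restrict to the first 1000 individuals: v6's missing entries all sit
        # in the tail, so its call rate becomes 1.0 there
        sub = np.arange(1000)
        _, report = filter_variants(g, 0.0, 0.0, individuals=sub)
        assert report.loc[report["variant_id"] == "v6", "call_rate"].item() == 1.0


class TestMarginalGwas:
    def test_noise_free_signal_recovered_exactly(self, rng):
        d = rng.binomial(2, 0.4, size=(60, 5)).astype(float)
        g = make_geno(d)
        y = 3.0 * d[:, 2]
        res = marginal_gwas(g, y)
        assert res.loc[2, "beta"] == pytest.approx(3.0, abs=1e-10)
        assert res.loc[2, "p"] == pytest.approx(0.0, abs=1e-300)

    def test_agreement_with_per_variant_statsmodels_fit(self, rng):
        n, m = 40, 3
        d = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        g = make_geno(d)
        y = rng.normal(size=n)
        covar = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        res = marginal_gwas(g, y, covariates=covar)
        for j in range(m):
            X = sm.add_constant(
                np.column_stack([d[:, j], covar.to_numpy()])
            )
            fit = sm.OLS(y, X).fit()
            assert res.loc[j, "beta"] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.loc[j, "se"] == pytest.approx(fit.bse[1], abs=1e-10)
            assert res.loc[j, "p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_null_p_values_are_uniform(self, rng):
        from scipy import stats

        n, m = 300, 2000
        d = rng.binomial(2, rng.uniform(0.1, 0.5, size=m), size=(n, m)).astype(float)
        g = make_geno(d)
        y = rng.normal(size=n)  # independent of genotype
        res = marginal_gwas(g, y)
        p = res["p"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_monomorphic_variant_gets_absent_result_with_reason(self, rng):
        d = rng.binomial(2, 0.4, size=(30, 3)).astype(float)
        d[:, 1] = 2.0
        g = make_geno(d)
        res = marginal_gwas(g, rng.normal(size=30))
        assert np.isnan(res.loc[1, "beta"]) and res.loc[1, "note"] == "monomorphic"
        assert res.loc[0, "note"] == ""

    def test_missing_dosages_mean_imputed(self, rng):
        d = rng.binomial(2, 0.4, size=(50, 2)).astype(float)
        g = make_geno(d)
        y = rng.normal(size=50)
        d_missing = d.copy()
        d_missing[3, 0] = np.nan
        g_miss = make_geno(d_missing)
        res = marginal_gwas(g_miss, y)
        x = d.copy()[:, 0]
        x[3] = np.nanmean(d_missing[:, 0])  # mean-imputed dosage
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.loc[0, "beta"] == pytest.approx(ref.params[1], abs=1e-12)


class TestPruneAndThreshold:
    def _split(self, rng, n, frac=0.7):
        perm = rng.permutation(n)
        cut = int(frac * n)
        return perm[:cut], perm[cut:]

    def test_permissive_settings_keep_all_variants_with_gwas_betas(self, rng):
        d = rng.binomial(2, 0.4, size=(80, 6)).astype(float)
        g = make_geno(d)
        y = d @ rng.normal(size=6) + rng.normal(size=80)
        tr, va = self._split(rng, 80)
        gwas = marginal_gwas(g.subset(individuals=tr), y[tr])
        w, report = prune_and_threshold(
            gwas, g.subset(individuals=tr), y[tr],
            g.subset(individuals=va), y[va],
            r2_prune=1.0, p_grid=(1.0,),
        )
        assert set(w.variant_ids) == set(g.variant_ids)
        merged = dict(zip(gwas["variant_id"], gwas["beta"]))
        for vid, weight in zip(w.variant_ids, w.weights):
            assert weight == pytest.approx(merged[vid], abs=1e-12)

    def test_duplicated_variant_pruned_lexicographically(self, rng):
        base = rng.binomial(2, 0.4, size=(100, 1)).astype(float)
        other = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        d = np.hstack([base, base, other])  # vB duplicates vA exactly
        g = make_geno(d, ids=["vB", "vA", "vC"])
        y = base[:, 0] * 2.0 + rng.normal(scale=0.5, size=100)
        tr, va = self._split(rng, 100)
        gwas = marginal_gwas(g.subset(individuals=tr), y[tr])
        w, _ = prune_and_threshold(
            gwas, g.subset(individuals=tr), y[tr],
            g.subset(individuals=va), y[va],
            r2_prune=0.9, p_grid=(1.0,),
        )
        assert "vA" in w.variant_ids and "vB" not in w.variant_ids

    def test_oligogenic_causal_recall(self):
        """Selected threshold retains >= 80% of causal variants."""
        from prseval.synth import ArchitectureSpec, PopulationSpec, simulate_cohort

        g, tab = simulate_cohort(
            [PopulationSpec("train_pop", 2000)],
            ArchitectureSpec(m=5000, causal_fraction=0.002, heritability=0.6,
                             seed=13),
        )
        y = tab["phenotype"].to_numpy()
        rng = np.random.default_rng(0)
        tr, va = self._split(rng, 2000)
        gwas = marginal_gwas(g.subset(individuals=tr), y[tr])
        w, _ = prune_and_threshold(
            gwas, g.subset(individuals=tr), y[tr],
            g.subset(individuals=va), y[va],
        )
        causal = set(g.true_betas.index[g.true_betas["train_pop"] != 0])
        recall = len(causal & set(w.variant_ids)) / len(causal)
        assert recall >= 0.8

    def test_empty_grid_and_hopeless_grid_raise(self, rng):
        d = rng.binomial(2, 0.4, size=(40, 3)).astype(float)
        g = make_geno(d)
        y = rng.normal(size=40)
        tr, va = self._split(rng, 40)
        gwas = marginal_gwas(g.subset(individuals=tr), y[tr])
        with pytest.raises(ValueError, match="p_grid"):
            prune_and_threshold(gwas, g.subset(individuals=tr), y[tr],
                                g.subset(individuals=va), y[va], p_grid=())
        with pytest.raises(ValueError, match="no variant passes"):
            prune_and_threshold(gwas, g.subset(individuals=tr), y[tr],
                                g.subset(individuals=va), y[va],
                                p_grid=(1e-300,))


class TestRidgeTrainer:
    def test_huge_penalty_shrinks_weights_to_zero(self, rng):
        d = rng.binomial(2, 0.4, size=(60, 4)).astype(float)
        g = make_geno(d)
        y = d @ np.ones(4) + rng.normal(size=60)
        w, _ = ridge_trainer(g, y, g, y, lambda_grid=(1e12,))
        assert np.max(np.abs(w.weights)) < 1e-6

    def test_zero_penalty_full_rank_equals_ols(self, rng):
        n, m = 50, 5
        d = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        g = make_geno(d)
        y = d @ rng.normal(size=m) + rng.normal(size=n)
        w, report = ridge_trainer(g, y, g, y, lambda_grid=(0.0,))
        X = sm.add_constant(d)
        ols = np.linalg.lstsq(X, y, rcond=None)[0][1:]
        np.testing.assert_allclose(w.weights, ols, atol=1e-8)
        assert report["singular_lambdas"] == []

    def test_two_orthogonal_variants_closed_form(self):
        d = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=float)
        g = make_geno(d)
        y = np.array([0.0, 1.0, 2.0, 3.5])
        lam = 2.0
        w, _ = ridge_trainer(g, y, g, y, lambda_grid=(lam,))
        yc = y - y.mean()
        Z = (d - 1.0)  # centered, unit sd columns
        expected_std = (Z.T @ yc) / (4.0 + lam)
        np.testing.assert_allclose(w.weights, expected_std, atol=1e-10)

    def test_singular_zero_penalty_reported(self, rng):
        n, m = 10, 30  # more variants than individuals
        d = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        g = make_geno(d)
        y = rng.normal(size=n)
        with pytest.raises(ValueError, match="singular"):
            ridge_trainer(g, y, g, y, lambda_grid=(0.0,))
        _, report = ridge_trainer(g, y, g, y, lambda_grid=(0.0, 10.0))
        assert report["singular_lambdas"] == [0.0]
        assert report["selected_lambda"] == 10.0


class TestScore:
    def test_zero_weights_give_zero_scores(self, rng):
        d = rng.binomial(2, 0.4, size=(10, 3)).astype(float)
        g = make_geno(d)
        w = WeightVector(g.variant_ids, g.effect_alleles, np.zeros(3))
        np.testing.assert_array_equal(score(g, w), np.zeros(10))

    def test_single_variant_dosage_scaling(self):
        g = make_geno([[0.0], [1.0], [2.0]])
        w = WeightVector(np.array(["v0"]), np.array(["A"]), np.array([1.5]))
        np.testing.assert_allclose(score(g, w), [0.0, 1.5, 3.0])

    def test_missing_dosage_imputed_at_cohort_frequency(self):
        # effect-allele frequency among non-missing = 2/(2*4) = 0.25,
        # so the missing dosage contributes weight * 2 * 0.25 = weight * 0.5
        g = make_geno([[1.0], [1.0], [0.0], [0.0], [np.nan]])
        w = WeightVector(np.array(["v0"]), np.array(["A"]), np.array([2.0]))
        np.testing.assert_allclose(score(g, w), [2.0, 2.0, 0.0, 0.0, 1.0])

    def test_opposite_allele_orientation_flips_dosage(self):
        g = make_geno([[0.0], [1.0], [2.0]], ea=["A"], oa=["G"])
        w = WeightVector(np.array(["v0"]), np.array(["G"]), np.array([1.0]))
        np.testing.assert_allclose(score(g, w), [2.0, 1.0, 0.0])

    def test_unknown_variant_and_incompatible_allele_raise(self):
        g = make_geno([[0.0], [1.0]], ea=["A"], oa=["G"])
        with pytest.raises(ValueError, match="absent"):
            score(g, WeightVector(np.array(["vX"]), np.array(["A"]),
                                  np.array([1.0])))
        with pytest.raises(ValueError, match="neither"):
            score(g, WeightVector(np.array(["v0"]), np.array(["T"]),
                                  np.array([1.0])))

    def test_scoring_is_linear_in_weights(self, rng):
        d = rng.binomial(2, 0.4, size=(20, 4)).astype(float)
        g = make_geno(d)
        w1 = rng.normal(size=4)
        w2 = rng.normal(size=4)
        s1 = score(g, WeightVector(g.variant_ids, g.effect_alleles, w1))
        s2 = score(g, WeightVector(g.variant_ids, g.effect_alleles, w2))
        s12 = score(g, WeightVector(g.variant_ids, g.effect_alleles, w1 + w2))
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-10)

    def test_allele_flip_with_negated_weight_shifts_by_constant(self, rng):
        d = rng.binomial(2, 0.4, size=(15, 1)).astype(float)
        g = make_geno(d, ea=["A"], oa=["G"])
        w = WeightVector(np.array(["v0"]), np.array(["A"]), np.array([0.7]))
        w_flip = WeightVector(np.array(["v0"]), np.array(["G"]), np.array([-0.7]))
        np.testing.assert_allclose(score(g, w_flip), score(g, w) - 1.4,
                                   atol=1e-12)


class TestFinalModel:
    def _covars(self, rng, n, k=3):
        c = pd.DataFrame(rng.normal(size=(n, k)),
                         columns=[f"PC{i+1}" for i in range(k)])
        c.insert(0, "sex", rng.integers(0, 2, n).astype(float))
        c.insert(1, "age", rng.uniform(40, 70, n))
        return c

    def _weights(self):
        return WeightVector(np.array(["v0"]), np.array(["A"]), np.array([1.0]))

    def test_exact_linear_relationship_recovered(self, rng):
        n = 50
        prs = rng.normal(size=n)
        covars = self._covars(rng, n)
        y = 2.0 * prs + 3.0
        model, _ = fit_final_model(prs, covars, y, self._weights())
        assert model.intercept == pytest.approx(3.0, abs=1e-8)
        assert model.prs_coefficient == pytest.approx(2.0, abs=1e-8)
        for coef in model.covariate_coefficients.values():
            assert coef == pytest.approx(0.0, abs=1e-8)
        assert model.train_mean == pytest.approx(float(y.mean()))

    def test_coefficients_match_normal_equations(self, rng):
        n = 20
        prs = rng.normal(size=n)
        covars = pd.DataFrame(
            rng.normal(size=(n, 10)), columns=[f"PC{i+1}" for i in range(10)]
        )
        y = rng.normal(size=n)
        model, res = fit_final_model(prs, covars, y, self._weights())
        X = np.column_stack([np.ones(n), prs, covars.to_numpy()])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        assert model.prs_coefficient == pytest.approx(beta[1], abs=1e-8)
        np.testing.assert_allclose(
            list(model.covariate_coefficients.values()), beta[2:], atol=1e-8
        )

    def test_row_permutation_leaves_coefficients_unchanged(self, rng):
        n = 30
        prs = rng.normal(size=n)
        covars = self._covars(rng, n)
        y = prs + rng.normal(size=n)
        m1, _ = fit_final_model(prs, covars, y, self._weights())
        perm = rng.permutation(n)
        m2, _ = fit_final_model(
            prs[perm], covars.iloc[perm].reset_index(drop=True), y[perm],
            self._weights(),
        )
        assert m1.prs_coefficient == pytest.approx(m2.prs_coefficient, abs=1e-10)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-10)

    def test_rank_deficiency_names_offending_column(self, rng):
        n = 25
        prs = rng.normal(size=n)
        covars = self._covars(rng, n)
        covars["PC3"] = covars["PC1"]  # exact collinearity
        with pytest.raises(ValueError, match="PC3"):
            fit_final_model(prs, covars, rng.normal(size=n), self._weights())


class TestPredict:
    def test_intercept_only_model_predicts_constant(self, rng):
        d = rng.binomial(2, 0.4, size=(8, 1)).astype(float)
        g = make_geno(d)
        model = PredictionModel(
            weights=WeightVector(g.variant_ids, g.effect_alleles, np.zeros(1)),
            intercept=5.5,
            prs_coefficient=0.0,
            covariate_coefficients={"sex": 0.0, "age": 0.0},
            train_mean=5.5,
        )
        covars = pd.DataFrame({"sex": np.zeros(8), "age": np.full(8, 50.0)})
        np.testing.assert_allclose(predict(model, g, covars), np.full(8, 5.5))

    def test_componentwise_equality_with_hand_computation(self):
        g = make_geno([[0.0], [1.0], [2.0], [1.0], [0.0]])
        covars = pd.DataFrame(
            {"sex": [0.0, 1.0, 0.0, 1.0, 0.0], "age": [40, 50, 60, 45, 55.0]}
        )
        model = PredictionModel(
            weights=WeightVector(g.variant_ids, g.effect_alleles,
                                 np.array([0.5])),
            intercept=1.0,
            prs_coefficient=2.0,
            covariate_coefficients={"sex": 0.3, "age": 0.01},
            train_mean=0.0,
        )
        prs = np.array([0.0, 0.5, 1.0, 0.5, 0.0])
        expected = 1.0 + 2.0 * prs + 0.3 * covars["sex"] + 0.01 * covars["age"]
        np.testing.assert_allclose(predict(model, g, covars), expected)

    def test_missing_covariates_rejected(self, rng):
        g = make_geno([[0.0], [1.0]])
        model = PredictionModel(
            weights=WeightVector(g.variant_ids, g.effect_alleles, np.zeros(1)),
            intercept=0.0, prs_coefficient=0.0,
            covariate_coefficients={"sex": 0.1, "age": 0.1}, train_mean=0.0,
        )
        with pytest.raises(ValueError, match="age"):
            predict(model, g, pd.DataFrame({"sex": [0.0, 1.0]}))


class TestPolygenicModelEndToEnd:
    def test_ols_residuals_vanish_on_fitting_data(self, small_cohort):
        g, tab = small_cohort
        rng = np.random.default_rng(1)
        is_train_pop = g.population_labels == "train_pop"
        idx = np.where(is_train_pop)[0]
        perm = rng.permutation(idx)
        res = PolygenicModel(
            g, tab, train_idx=perm[:400], val_idx=perm[400:600],
            method="pt", n_pcs=4, seed=1,
        ).fit()
        fit_idx = np.concatenate([perm[:400], perm[400:600]])
        yhat = res.predict(g.subset(individuals=fit_idx),
                           tab.iloc[fit_idx].reset_index(drop=True))
        resid = tab["phenotype"].to_numpy()[fit_idx] - yhat
        assert abs(resid.sum()) < 1e-6
        assert res.train_mean == pytest.approx(
            float(tab["phenotype"].iloc[fit_idx].mean())
        )

    def test_in_target_accuracy_approaches_heritability(self):
        """With no divergence the three definitions agree and r^2 nears h^2."""
        from prseval.pipeline import StudyConfig, run_study
        from prseval.synth import ArchitectureSpec, PopulationSpec

        cfg = StudyConfig(
            populations=(PopulationSpec("train_pop", 2000),),
            architecture=ArchitectureSpec(
                m=500, causal_fraction=0.02, heritability=0.6, seed=31
            ),
            methods=("pt",),
            assign_ancestry=False,
        )
        result = run_study(cfg)
        r = result.get("train_pop", "pt")
        mset = r.metrics.as_dict()
        assert 0.3 <= mset["r_squared"] <= 0.65
        assert abs(mset["r_squared"] - mset["r2_1a"]) < 0.05
        assert abs(mset["r_squared"] - mset["r2_1b"]) < 0.05
        assert abs(mset["r2_1a"] - mset["r2_1b"]) < 0.05

    def test_summary_mentions_method_and_train_mean(self, small_cohort):
        g, tab = small_cohort
        idx = np.where(g.population_labels == "train_pop")[0]
        res = PolygenicModel(
            g, tab, train_idx=idx[:300], val_idx=idx[300:450],
            method="ridge", n_pcs=3, seed=0,
        ).fit()
        text = res.summary().as_text()
        assert "ridge" in text and "R2_1A" in text
        assert "PRS" in text
        assert len(res.params) == len(res.bse) == 2 + 2 + 3  # const+PRS+sex/age+PCs


class TestPCBasis:
    def test_projection_reproduces_training_coordinates(self, small_cohort):
        g, _ = small_cohort
        idx = np.where(g.population_labels == "train_pop")[0][:200]
        basis = fit_pc_basis(g, individuals=idx, n_components=3, random_state=0)
        coords = basis.project(g.subset(individuals=idx))
        assert coords.shape == (200, 3)
        # deterministic across repeat fits
        basis2 = fit_pc_basis(g, individuals=idx, n_components=3, random_state=0)
        np.testing.assert_allclose(basis.components, basis2.components)

    def test_variant_mismatch_rejected(self, small_cohort):
        g, _ = small_cohort
        basis = fit_pc_basis(g, n_components=2)
        with pytest.raises(ValueError, match="variants"):
            basis.project(g.subset(variants=np.arange(10)))
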