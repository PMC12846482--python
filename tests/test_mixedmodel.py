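"""GRM, REML variance components, phenotype adjustment, GWAS, merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from growmark.examples import per_model_loci
from growmark.mixedmodel import (
    adjust_phenotypes,
    build_design_matrix,
    compute_grm,
    fit_lmm_reml,
    gwas_mlm,
    merge_model_results,
)
from growmark.simdata import SimulationConfig, simulate_genotypes, simulate_phenotypes
from growmark.variants import VariantTable


def _table(dosage, chrom="chr1"):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    loci = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * 10,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return VariantTable(loci=loci, dosage=dosage, samples=[f"s{i}" for i in range(n)])


class TestGrm:
    def test_single_locus_hand_arithmetic(self):
        # p = 0.5, dosages (0, 2): W = (-1, 1), denom = 0.5
        G = compute_grm(_table([[0.0], [2.0]]))
        np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_identical_rows_have_self_relationship(self):
        G = compute_grm(_table([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]]))
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_mean_diagonal_near_one_for_unstructured_hwe_population(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 2000)
        dosage = rng.binomial(2, p, size=(500, 2000))
        G = compute_grm(_table(dosage.astype(float)))
        assert abs(np.mean(np.diag(G)) - 1.0) < 0.05

    def test_all_monomorphic_is_an_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(_table([[0, 2], [0, 2]]))


class TestDesignMatrix:
    def test_aliased_covariates_dropped_and_reported(self):
        ph = pd.DataFrame(
            {
                "population": ["A", "A", "B", "B"],
                "location": ["north", "north", "south", "south"],
                "age": [6.0, 6.0, 9.0, 9.0],
            }
        )
        X, kept, dropped = build_design_matrix(ph, ["population", "location", "age"])
        assert X.shape == (4, 2)  # intercept + one independent contrast
        assert "location_south" in dropped and "age" in dropped
        assert np.linalg.matrix_rank(X) == 2


class TestReml:
    def test_matches_standard_variance_components_oracle(self):
        # random-intercept model: G = ZZ' for a group-incidence Z is the
        # identifiable analogue of an arbitrary-kinship fit
        from statsmodels.regression.mixed_linear_model import MixedLM

        rng = np.random.default_rng(7)
        n_groups, per = 10, 12
        n = n_groups * per
        g = np.repeat(np.arange(n_groups), per)
        Z = np.zeros((n, n_groups))
        Z[np.arange(n), g] = 1
        G = Z @ Z.T
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([2.0, 0.5]) + rng.normal(0, 1.5, n_groups)[g] + rng.normal(0, 1.0, n)
        fit = fit_lmm_reml(y, X, G)
        oracle = MixedLM(y, X, groups=g).fit(reml=True, method="lbfgs")
        assert fit.sigma2_a == pytest.approx(np.asarray(oracle.cov_re)[0, 0], rel=1e-4)
        assert fit.sigma2_e == pytest.approx(oracle.scale, rel=1e-4)
        np.testing.assert_allclose(fit.beta, oracle.fe_params, rtol=1e-5)

    def test_perfect_fixed_effect_fit_gives_zero_variances(self):
        rng = np.random.default_rng(1)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([3.0, -1.0])
        A = rng.normal(size=(n, n))
        G = A @ A.T / n
        fit = fit_lmm_reml(y, X, G)
        assert fit.sigma2_a == pytest.approx(0.0, abs=1e-8)
        assert fit.sigma2_e == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-7)

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        A = rng.normal(size=(n, 30))
        G = A @ A.T / 30
        y = rng.normal(size=n)
        fit = fit_lmm_reml(y, X, G)
        np.testing.assert_allclose(
            fit.X @ fit.beta + fit.breeding_values + fit.residuals, y, atol=1e-10
        )

    def test_rank_deficient_design_names_aliased_columns(self):
        n = 20
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="aliased"):
            fit_lmm_reml(np.zeros(n), X, np.eye(n), column_names=["intercept", "dup"])

    def test_heritability_recovery_on_simulated_data(self):
        # h2 = 0.5, n = 500; homogeneous within-population scale
        estimates = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_per_population=(125, 125, 125, 125),
                n_chromosomes=2,
                loci_per_chromosome=500,
                heritability=0.5,
                population_means=(50.0, 50.0, 50.0, 50.0),
                population_sds=(1.0, 1.0, 1.0, 1.0),
                missing_rate=0.0,
                seed=seed,
            )
            t = simulate_genotypes(cfg)
            ph = simulate_phenotypes(t, cfg)
            G = compute_grm(t)
            X, _, _ = build_design_matrix(ph, ["population"])
            fit = fit_lmm_reml(ph["weight_g"].to_numpy(), X, G, column_names=None)
            estimates.append(fit.heritability)
        assert abs(np.mean(estimates) - 0.5) < 0.15

    def test_optimum_invariant_to_refinement_start(self):
        # profiled likelihood unimodality: perturbing the grid start must
        # not change the optimum
        from growmark.mixedmodel import _LOG_RATIO_BOUNDS, _profiled_reml

        rng = np.random.default_rng(9)
        n = 80
        g = np.repeat(np.arange(8), 10)
        Z = np.zeros((n, 8))
        Z[np.arange(n), g] = 1
        G = Z @ Z.T
        X = np.ones((n, 1))
        y = rng.normal(0, 1.2, 8)[g] + rng.normal(size=n)
        fit = fit_lmm_reml(y, X, G)
        eigvals, U = np.linalg.eigh(G)
        eigvals = np.clip(eigvals, 0, None)
        yt, Xt = U.T @ y, U.T @ X
        lo, hi = _LOG_RATIO_BOUNDS
        from scipy import optimize

        for lo_shift in (0.0, 2.0, 4.0, 6.0, 8.0):
            res = optimize.minimize_scalar(
                lambda v: -_profiled_reml(v, eigvals, yt, Xt)[0],
                bounds=(lo + lo_shift, hi),
                method="bounded",
                options={"xatol": 1e-9},
            )
            assert np.exp(res.x) * _profiled_reml(res.x, eigvals, yt, Xt)[2] == pytest.approx(
                fit.sigma2_a, rel=1e-5, abs=1e-8
            )


class TestAdjustment:
    def test_intercept_only_fixed_adjustment_centres_y(self):
        rng = np.random.default_rng(4)
        n = 50
        y = rng.normal(10, 2, n)
        fit = fit_lmm_reml(y, np.ones((n, 1)), np.eye(n) * 0.0 + np.diag(np.ones(n)))
        adj = adjust_phenotypes(fit, mode="fixed_only")
        # with V ∝ I the GLS intercept is the arithmetic mean
        np.testing.assert_allclose(adj, y - y.mean(), atol=1e-8)

    def test_full_residual_attenuates_causal_slope(self):
        cfg = SimulationConfig(
            n_per_population=(100, 100, 100, 100),
            n_chromosomes=1,
            loci_per_chromosome=300,
            causal_spec=((150, 0.8),),
            heritability=0.4,
            population_means=(30.0, 30.0, 30.0, 30.0),
            population_sds=(2.0, 2.0, 2.0, 2.0),
            missing_rate=0.0,
            seed=15,
        )
        t = simulate_genotypes(cfg)
        ph = simulate_phenotypes(t, cfg)
        G = compute_grm(t)
        X, _, _ = build_design_matrix(ph, ["population"])
        fit = fit_lmm_reml(ph["weight_g"].to_numpy(), X, G)
        x = t.dosage[:, 150]
        slope = lambda y: np.polyfit(x, y, 1)[0]  # noqa: E731
        assert abs(slope(adjust_phenotypes(fit, "full_residual"))) < abs(
            slope(adjust_phenotypes(fit, "fixed_only"))
        )

    def test_unknown_mode_rejected(self):
        fit = fit_lmm_reml(np.zeros(10) + np.arange(10), np.ones((10, 1)), np.eye(10))
        with pytest.raises(ValueError, match="mode"):
            adjust_phenotypes(fit, mode="bogus")


class TestGwas:
    def test_identity_kinship_degenerates_to_ols(self):
        rng = np.random.default_rng(6)
        n, m = 120, 150
        p = rng.uniform(0.1, 0.9, m)
        dosage = rng.binomial(2, p, size=(n, m)).astype(float)
        y = rng.normal(size=n) + 0.5 * dosage[:, 0]
        res = gwas_mlm(y, _table(dosage), np.eye(n))
        for j in rng.choice(m, 20, replace=False):
            x = dosage[:, j]
            if x.std() == 0:
                continue
            ols_p = stats.linregress(x, y).pvalue
            assert res["p"].iloc[j] == pytest.approx(ols_p, abs=1e-6, rel=1e-6)

    def test_pvalues_invariant_under_affine_phenotype_rescaling(self):
        rng = np.random.default_rng(8)
        n, m = 100, 60
        dosage = rng.integers(0, 3, (n, m)).astype(float)
        t = _table(dosage)
        A = rng.normal(size=(n, n))
        G = A @ A.T / n
        y = rng.normal(size=n)
        p1 = gwas_mlm(y, t, G)["p"]
        p2 = gwas_mlm(7.0 * y + 100.0, t, G)["p"]
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_monomorphic_loci_skipped(self):
        rng = np.random.default_rng(10)
        n = 50
        dosage = rng.integers(0, 3, (n, 5)).astype(float)
        dosage[:, 2] = 0.0
        res = gwas_mlm(rng.normal(size=n), _table(dosage), np.eye(n))
        assert np.isnan(res["p"].iloc[2]) and not res["significant"].iloc[2]
        assert res.attrs["n_tested"] == 4


class TestMergeModelResults:
    def test_published_marker_table_merges_to_26(self):
        models = per_model_loci()
        assert {k: len(v) for k, v in models.items()} == {
            "MLM": 22,
            "FarmCPU": 4,
            "BLINK": 3,
        }
        merged = merge_model_results(list(models.values()))
        assert len(merged) == 26
        row = merged[merged["snp"] == "Chr10_3129797_A_T"].iloc[0]
        assert row["method"] == "BLINK, FarmCPU, MLM"
        row2 = merged[merged["snp"] == "Chr20_21148254_A_G"].iloc[0]
        assert row2["method"] == "BLINK, MLM"

    def test_disjoint_lists_concatenate(self):
        a = pd.DataFrame({"snp": ["chr1_10_A_G", "chr1_20_C_T"], "method": "m1"})
        b = pd.DataFrame(
            {"snp": ["chr2_10_A_G", "chr2_20_C_T", "chr2_30_G_A"], "method": "m2"}
        )
        assert len(merge_model_results([a, b])) == 5

    def test_idempotent_and_commutative(self):
        a = pd.DataFrame({"snp": ["chr1_10_A_G", "chr1_20_C_T"], "method": "m1"})
        b = pd.DataFrame({"snp": ["chr1_10_A_G"], "method": "m2"})
        ab = merge_model_results([a, b])
        ba = merge_model_results([b, a])
        pd.testing.assert_frame_equal(ab, ba)
        again = merge_model_results([ab])
        pd.testing.assert_frame_equal(ab, again)
        assert len(merge_model_results([a, a])) == len(a)

    def test_malformed_identifier_rejected(self):
        bad = pd.DataFrame({"snp": ["chr1-10"], "method": "m"})
        with pytest.raises(ValueError, match="malformed"):
            merge_model_results([bad])

    def test_sorted_by_chromosome_then_position(self):
        a = pd.DataFrame(
            {"snp": ["Chr10_5_A_G", "Chr2_9_C_T", "Chr2_3_G_A"], "method": "m"}
        )
        merged = merge_model_results([a])
        assert list(merged["snp"]) == ["Chr2_3_G_A", "Chr2_9_C_T", "Chr10_5_A_G"]
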