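"""Mixed-model equations, REML and corrected phenotypes.

The central correctness oracle is the GBLUP / SNP-BLUP equivalence: with a
full-rank unblended G = lambda M M', the animal-model GEBV must equal M u_hat
from the equivalent ridge system.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import wgblup as w
from wgblup.lmm import ModelError


def toy_phenos(n=6):
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "animal": [f"a{i}" for i in range(n)],
            "herd": ["H1", "H2"] * (n // 2),
            "sex": ["M", "F"] * (n // 2),
            "age": rng.normal(900, 20, n),
            "y": rng.normal(10, 2, n),
        }
    )


class TestBuildDesign:
    def test_column_count_one_factor_one_covariate(self):
        df = toy_phenos(4)
        model = w.ModelSpec(response="y", fixed_factors=["herd"], covariates=["age"])
        design = w.build_design(df, model, df["animal"].tolist())
        assert design.X.shape == (4, 3)  # intercept, herd[H2], age
        assert design.x_labels == ["intercept", "herd[H2]", "age"]

    def test_Z_identity_when_records_match_kernel_order(self):
        df = toy_phenos(4)
        model = w.ModelSpec(response="y", fixed_factors=[], covariates=[])
        design = w.build_design(df, model, df["animal"].tolist())
        assert np.array_equal(design.Z, np.eye(4))

    def test_record_for_unknown_animal_rejected(self):
        df = toy_phenos(4)
        model = w.ModelSpec(response="y", fixed_factors=[], covariates=[])
        with pytest.raises(ModelError, match="absent from the kernel"):
            w.build_design(df, model, ["a0", "a1"])

    def test_single_level_factor_dropped_with_warning(self):
        df = toy_phenos(4)
        df["herd"] = "H1"
        model = w.ModelSpec(response="y", fixed_factors=["herd"], covariates=[])
        with pytest.warns(UserWarning, match="single level"):
            design = w.build_design(df, model, df["animal"].tolist())
        assert design.X.shape[1] == 1

    def test_missing_response_rows_dropped(self):
        df = toy_phenos(6)
        df.loc[2, "y"] = np.nan
        model = w.ModelSpec(response="y", fixed_factors=[], covariates=[])
        design = w.build_design(df, model, df["animal"].tolist())
        assert design.y.size == 5 and design.n_dropped == 1


class TestSolveMME:
    def test_extreme_shrinkage_gives_fixed_effect_mean(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        X = np.ones((4, 1))
        Z = np.eye(4)
        vc = w.VarianceComponents(sigma_a2=1e-10, sigma_e2=1.0)
        b, a, _ = w.solve_mme(X, Z, y, np.eye(4), vc)
        assert b[0] == pytest.approx(y.mean(), rel=1e-6)
        assert np.abs(a).max() < 1e-6

    def test_matches_gls_blup_oracle_on_pedigree_kernel(self):
        """MME solutions equal the direct V-inverse GLS/BLUP formulas."""
        ped = w.Pedigree(
            pd.DataFrame(
                {
                    "animal": ["s", "d", "x", "y", "z"],
                    "sire": [None, None, "s", "s", "x"],
                    "dam": [None, None, "d", "d", None],
                }
            )
        )
        A = w.build_A(ped).values
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(5), rng.normal(size=5)])
        Z = np.eye(5)
        y = rng.normal(size=5)
        sa2, se2 = 2.0, 3.0
        vc = w.VarianceComponents(sa2, se2)
        b, a, _ = w.solve_mme(X, Z, y, A, vc)
        V = sa2 * Z @ A @ Z.T + se2 * np.eye(5)
        Vi = np.linalg.inv(V)
        b_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        a_blup = sa2 * A @ Z.T @ Vi @ (y - X @ b_gls)
        assert np.allclose(b, b_gls, atol=1e-10)
        assert np.allclose(a, a_blup, atol=1e-10)

    def test_duplicated_records_with_doubled_residual_variance(self):
        """Duplicating every record while doubling sigma_e^2 scales the MME by
        two on both sides, leaving all solutions unchanged."""
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(4), rng.normal(size=4)])
        Z = np.eye(4)
        y = rng.normal(size=4)
        K = np.eye(4)
        b1, a1, _ = w.solve_mme(X, Z, y, K, w.VarianceComponents(1.0, 1.0))
        b2, a2, _ = w.solve_mme(
            np.vstack([X, X]),
            np.vstack([Z, Z]),
            np.concatenate([y, y]),
            K,
            w.VarianceComponents(1.0, 2.0),
        )
        assert np.allclose(b1, b2) and np.allclose(a1, a2)

    def test_pcg_matches_direct(self):
        rng = np.random.default_rng(3)
        n = 30
        M = rng.integers(0, 3, size=(n, 60)).astype(float)
        K = 0.95 * np.corrcoef(M) + 0.05 * np.eye(n)
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        vc = w.VarianceComponents(1.0, 1.5)
        b1, a1, _ = w.solve_mme(X, np.eye(n), y, K, vc, method="direct")
        b2, a2, diag = w.solve_mme(X, np.eye(n), y, K, vc, method="pcg", tol=1e-13)
        assert diag["relative_residual"] <= 1e-13
        assert np.allclose(a1, a2, atol=1e-9)

    def test_reordering_animals_permutes_solutions(self):
        rng = np.random.default_rng(4)
        n = 8
        A = np.eye(n) + 0.2
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        vc = w.VarianceComponents(1.0, 1.0)
        _, a1, _ = w.solve_mme(X, np.eye(n), y, A, vc)
        perm = rng.permutation(n)
        # solving the permuted system recovers the permuted solutions
        _, a2, _ = w.solve_mme(X, np.eye(n), y[perm], A[np.ix_(perm, perm)], vc)
        assert np.allclose(a1[perm], a2, atol=1e-10)


class TestREML:
    def test_balanced_one_way_closed_form(self):
        """REML on a balanced one-way random-effects layout equals the
        ANOVA-based closed form: sigma_e2 = MSW, sigma_a2 = (MSB - MSW)/k."""
        rng = np.random.default_rng(5)
        q, k = 8, 5  # groups, replicates
        effects = rng.normal(0, 1.5, q)
        y = np.repeat(effects, k) + rng.normal(0, 1.0, q * k)
        Z = np.kron(np.eye(q), np.ones((k, 1)))
        X = np.ones((q * k, 1))
        vc = w.reml_variance(X, Z, y, np.eye(q))
        ybar_g = y.reshape(q, k).mean(axis=1)
        msb = k * np.var(ybar_g, ddof=1)
        msw = np.sum((y.reshape(q, k) - ybar_g[:, None]) ** 2) / (q * (k - 1))
        assert vc.sigma_e2 == pytest.approx(msw, rel=1e-5)
        assert vc.sigma_a2 == pytest.approx((msb - msw) / k, rel=1e-4)

    def test_null_trait_gives_near_zero_h2(self, small_sim):
        cg = w.center_genotypes(small_sim.genotypes)
        G = w.condition_G(w.build_G(cg), blend=0.05)
        n = G.n
        rng = np.random.default_rng(6)
        y = rng.normal(size=n)
        vc = w.reml_variance(np.ones((n, 1)), np.eye(n), y, G)
        assert vc.h2 < 0.15

    def test_optimum_is_local_maximum(self, small_sim):
        cg = w.center_genotypes(small_sim.genotypes)
        G = w.condition_G(w.build_G(cg), blend=0.05)
        phenos = small_sim.phenotypes
        model = w.ModelSpec()
        design = w.build_design(phenos, model, list(G.ids))
        vc = w.reml_variance(design.X, design.Z, design.y, G)
        l_opt = w.lmm.reml_loglik(vc.sigma_a2, vc.sigma_e2, design.X, design.Z, design.y, G)
        for f in (0.8, 1.25):
            l_pert = w.lmm.reml_loglik(
                vc.sigma_a2 * f, vc.sigma_e2, design.X, design.Z, design.y, G
            )
            assert l_opt >= l_pert - 1e-9

    def test_heritability_recovered_on_one_simulation(self, small_sim):
        cg = w.center_genotypes(small_sim.genotypes)
        G = w.condition_G(w.build_G(cg), blend=0.05)
        design = w.build_design(small_sim.phenotypes, w.ModelSpec(), list(G.ids))
        vc = w.reml_variance(design.X, design.Z, design.y, G)
        # single small replicate: generous band around the generative value
        assert 0.1 < vc.h2 < 0.75
        assert np.isfinite(vc.se_h2)


class TestSNPBlupEquivalence:
    def test_gebv_equals_M_times_ridge_solution(self):
        """GBLUP with full-rank unblended G reproduces SNP-BLUP exactly."""
        cfg = w.SimConfig(n_founders=60, n_generations=1, n_snps=120, n_qtl=5, seed=9)
        ped = w.simulate_pedigree(cfg, cfg.rng())
        g = w.gene_drop_genotypes(ped, cfg, np.random.default_rng(9))
        out = w.simulate_phenotypes(g, ped, cfg, np.random.default_rng(10))
        cg = w.center_genotypes(g, freqs=g.founder_freqs)  # full-rank G
        G = w.build_G(cg)
        y = out.phenotypes["y"].to_numpy()
        X = np.ones((60, 1))
        Z = np.eye(60)
        sa2, se2 = 0.5, 0.8
        vc = w.VarianceComponents(sa2, se2)
        b, a_gblup, _ = w.solve_mme(X, Z, y, G, vc)

        # equivalent ridge (SNP-BLUP) system with sigma_u2 = lambda sigma_a2
        M = cg.M
        k_u = se2 / (sa2 * cg.scale)
        p, m = X.shape[1], M.shape[1]
        C = np.block([[X.T @ X, X.T @ M], [M.T @ X, M.T @ M + k_u * np.eye(m)]])
        sol = linalg.solve(C, np.concatenate([X.T @ y, M.T @ y]), assume_a="sym")
        u_ridge = sol[p:]
        assert np.abs(a_gblup - M @ u_ridge).max() < 1e-8
        # backsolve with D = I recovers the ridge solutions
        G_inv = np.linalg.inv(G.values)
        u_back = w.backsolve_snp_effects(cg, np.ones(m), G_inv, a_gblup)
        assert np.abs(u_back - u_ridge).max() < 1e-8


class TestCorrectPhenotypes:
    def fit(self, phenos):
        n = len(phenos)
        K = w.RelationshipMatrix(np.eye(n), "A", phenos["animal"].tolist())
        model = w.ModelSpec(response="y", fixed_factors=["herd"], covariates=["age"])
        vc = w.VarianceComponents(1.0, 1.0)
        return w.fit_blup(phenos, model, K, vc=vc)

    def test_zero_solutions_give_yc_equal_y(self):
        df = toy_phenos(6)
        res = self.fit(df)
        res.b_hat[:] = 0.0
        yc = w.correct_phenotypes(res, df)
        assert np.allclose(yc["yc"], df["y"])

    def test_shifted_phenotypes_give_identical_yc(self):
        df = toy_phenos(6)
        res1 = self.fit(df)
        df2 = df.copy()
        df2["y"] = df["y"] + 100.0
        res2 = self.fit(df2)
        yc1 = w.correct_phenotypes(res1, df)["yc"]
        yc2 = w.correct_phenotypes(res2, df2)["yc"]
        assert np.allclose(yc1, yc2, atol=1e-8)

    def test_validation_animals_receive_yc(self, small_sim):
        phenos = small_sim.phenotypes
        n = len(phenos)
        train = phenos.iloc[: n - 20]
        A = w.build_A(small_sim.pedigree)
        K = w.RelationshipMatrix(A.values, "A", A.ids)
        model = w.ModelSpec()
        res = w.fit_blup(train, model, K, vc=w.VarianceComponents(0.5, 0.75))
        yc = w.correct_phenotypes(res, phenos)
        assert len(yc) == n
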