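"""SNP-weight update rules, normalization, backsolving and the iteration loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import wgblup as w
from wgblup.weighting import WeightingError


class TestLinearWeight:
    def test_closed_forms(self):
        u = np.array([0.0, 0.5, -0.5, 2.0])
        d = w.linear_weight(u)
        assert np.allclose(d, [0.0, 0.25, 0.25, 4.0])

    def test_sign_invariance(self):
        u = np.array([0.3, -1.2, 0.7])
        assert np.array_equal(w.linear_weight(u), w.linear_weight(-u))


class TestNonlinearAWeight:
    def test_zero_effect_floor_ct_squared_inverse(self):
        scheme = w.WeightScheme(kind="nonlinearA", ct=1.25, exponent_limit=20)
        u = np.array([0.0, 1.0, -1.0, 3.0])  # sd > 0
        d = w.nonlinearA_weight(u, scheme)
        assert d[0] == pytest.approx(1.25**-2)
        assert d[0] == pytest.approx(0.64)

    def test_effect_at_two_sd_gets_unit_weight(self):
        scheme = w.WeightScheme(kind="nonlinearA", ct=1.25, exponent_limit=20)
        u = np.array([1.0, -1.0, 1.0, -1.0, 2.0])
        sd = np.std(u, ddof=1)
        u2 = np.array([2 * sd, *u])
        d = w.nonlinearA_weight(u2, scheme)
        sd2 = np.std(u2, ddof=1)
        expected = 1.25 ** (2 * sd / sd2 - 2)
        assert d[0] == pytest.approx(expected)

    def test_exponent_cap_applies(self):
        scheme = w.WeightScheme(kind="nonlinearA", ct=1.25, exponent_limit=20)
        # construct u with one huge outlier: |u|/sd - 2 > 20
        u = np.array([1e6] + [1.0] * 1000 + [-1.0] * 1000)
        d = w.nonlinearA_weight(u, scheme)
        assert (np.abs(u[0]) / np.std(u, ddof=1) - 2) > 20
        assert d[0] == pytest.approx(1.25**20)
        assert d[0] == pytest.approx(86.7361737988, rel=1e-9)

    def test_constant_effects_rejected(self):
        scheme = w.WeightScheme(kind="nonlinearA")
        with pytest.raises(WeightingError, match="sd"):
            w.nonlinearA_weight(np.full(10, 0.3), scheme)

    def test_bounds(self):
        scheme = w.WeightScheme(kind="nonlinearA", ct=1.125, exponent_limit=5)
        rng = np.random.default_rng(0)
        d = w.nonlinearA_weight(rng.standard_t(df=3, size=500), scheme)
        assert (d >= 1.125**-2 - 1e-12).all()
        assert (d <= 1.125**5 + 1e-12).all()

    def test_invalid_scheme_parameters_rejected(self):
        with pytest.raises(WeightingError):
            w.WeightScheme(kind="nonlinearA", ct=0.9)
        with pytest.raises(WeightingError):
            w.WeightScheme(kind="nonlinearA", exponent_limit=0)
        with pytest.raises(WeightingError):
            w.WeightScheme(kind="quadratic")


class TestNormalizeWeights:
    def test_examples(self):
        assert np.allclose(w.normalize_weights(np.array([8.0, 0, 0, 0])).d, [4, 0, 0, 0])
        already = np.array([1.5, 0.75, 0.75])  # sums to m = 3
        assert np.allclose(w.normalize_weights(already).d, already)
        assert np.allclose(w.normalize_weights(np.full(7, 3.3)).d, np.ones(7))

    def test_all_zero_rejected(self):
        with pytest.raises(WeightingError, match="all-zero"):
            w.normalize_weights(np.zeros(4))

    @given(
        hnp.arrays(
            float,
            st.integers(2, 50),
            elements=st.floats(0, 1e6, allow_nan=False, allow_subnormal=False),
        ).filter(lambda a: a.sum() > 1e-6)
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_trace_always_m(self, raw):
        d = w.normalize_weights(raw).d
        m = len(raw)
        assert abs(d.sum() - m) / m < 1e-12


class TestWeightOrdering:
    @given(
        hnp.arrays(
            float,
            st.integers(3, 40),
            elements=st.floats(-50, 50, allow_nan=False),
        ).filter(lambda a: np.std(a, ddof=1) > 1e-9)
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_larger_effects_never_get_smaller_weights(self, u):
        """Both update rules are monotone in |u|."""
        scheme = w.WeightScheme(kind="nonlinearA", ct=1.25, exponent_limit=20)
        for d in (w.linear_weight(u), w.nonlinearA_weight(u, scheme)):
            order = np.argsort(np.abs(u))
            assert (np.diff(d[order]) >= -1e-12).all()

    def test_nonlinearA_concentrates_less_than_linear_on_heavy_tails(self):
        rng = np.random.default_rng(1)
        u = rng.standard_t(df=2, size=400)
        scheme = w.WeightScheme(kind="nonlinearA", ct=1.25, exponent_limit=20)
        d_lin = w.normalize_weights(w.linear_weight(u)).d
        d_nla = w.normalize_weights(w.nonlinearA_weight(u, scheme)).d
        assert d_nla.max() <= d_lin.max()


@pytest.fixture(scope="module")
def toy_system():
    cfg = w.SimConfig(n_founders=40, n_generations=1, n_snps=80, n_qtl=4, seed=21)
    ped = w.simulate_pedigree(cfg, cfg.rng())
    g = w.gene_drop_genotypes(ped, cfg, np.random.default_rng(21))
    out = w.simulate_phenotypes(g, ped, cfg, np.random.default_rng(22))
    cg = w.center_genotypes(g, freqs=g.founder_freqs)  # full-rank G
    return cg, out


class TestBacksolve:
    def test_zero_gebv_gives_zero_effects(self, toy_system):
        cg, _ = toy_system
        G_inv = np.linalg.inv(w.build_G(cg).values)
        u = w.backsolve_snp_effects(cg, np.ones(cg.n_snps), G_inv, np.zeros(cg.n_animals))
        assert np.all(u == 0.0)

    def test_reconstruction_identity_in_column_space(self):
        """lambda M D M' G*^-1 acts as the identity on the column space when
        G* is unblended and full rank: M u_hat == g_hat."""
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, size=(5, 8)).astype(float)
        cg = w.center_genotypes(
            w.GenotypeMatrix(d, list("abcde")), freqs=np.full(8, 0.35)
        )
        wts = rng.uniform(0.2, 2.0, 8)
        Gs = w.build_weighted_G(cg, wts)
        G_inv = np.linalg.inv(Gs.values)
        ghat = Gs.values @ rng.normal(size=5)  # anything in the column space
        u = w.backsolve_snp_effects(cg, wts, G_inv, ghat)
        assert np.allclose(cg.M @ u, ghat, atol=1e-8)


@pytest.fixture(scope="module")
def yc_and_cg(small_sim):
    cg = w.center_genotypes(small_sim.genotypes)
    phenos = small_sim.phenotypes
    yc = pd.Series(
        phenos["y"].to_numpy() - phenos["y"].mean(),
        index=phenos["animal"].astype(str),
    )
    train = yc.iloc[: len(yc) - 20]
    return cg, train


class TestRunWGBLUP:

    def test_single_iteration_equals_gblup_bitwise_any_scheme(self, yc_and_cg):
        cg, yc_train = yc_and_cg
        vc = w.VarianceComponents(0.5, 0.75)
        base = w.run_gblup(cg, yc_train, vc)
        for scheme in (
            w.WeightScheme(kind="linear"),
            w.WeightScheme(kind="nonlinearA", ct=1.125, exponent_limit=5),
            w.WeightScheme(kind="nonlinearA", ct=1.25, exponent_limit=20),
        ):
            trace = w.run_wgblup(cg, yc_train, vc, scheme, n_iterations=2)
            assert np.array_equal(
                trace.gebv(1).to_numpy(), base.gebv(1).to_numpy()
            )
            assert np.array_equal(trace.snp_effects(1), base.snp_effects(1))
            assert np.all(trace.iterations[0].weights == 1.0)

    def test_trace_conservation_over_ten_iterations(self, yc_and_cg):
        cg, yc_train = yc_and_cg
        vc = w.VarianceComponents(0.5, 0.75)
        m = cg.n_snps
        for kind in ("linear", "nonlinearA"):
            trace = w.run_wgblup(
                cg, yc_train, vc, w.WeightScheme(kind=kind), n_iterations=10
            )
            assert len(trace.iterations) == 10
            for rec in trace.iterations:
                assert abs(rec.weights.sum() - m) / m < 1e-12

    def test_tidy_trace_output(self, yc_and_cg):
        cg, yc_train = yc_and_cg
        vc = w.VarianceComponents(0.5, 0.75)
        trace = w.run_wgblup(cg, yc_train, vc, w.WeightScheme(), n_iterations=3)
        tidy = trace.to_frame(cg.freqs)
        assert set(tidy.columns) == {"iteration", "snp_id", "effect", "weight", "pct_variance"}
        assert len(tidy) == 3 * cg.n_snps
        sums = tidy.groupby("iteration")["pct_variance"].sum()
        assert np.allclose(sums, 100.0)

    def test_training_animal_without_genotype_rejected(self, yc_and_cg):
        cg, yc_train = yc_and_cg
        bad = pd.concat([yc_train, pd.Series([1.0], index=["ghost"])])
        with pytest.raises(WeightingError, match="without genotypes"):
            w.run_wgblup(cg, bad, w.VarianceComponents(1.0, 1.0), w.WeightScheme())
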