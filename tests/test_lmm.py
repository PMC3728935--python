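"""Sampler bookkeeping, parameter recovery, REML oracle, diagnostics, heritability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qstream as q
from qstream.lmm import MCMC_PRESETS


def _one_factor_table(n_fam, n_off, s2f, s2e, seed, mu=10.0):
    d = q.build_design([q.PopulationSpec("A", n_pairs=n_fam)], 1)
    plan = q.build_stocking(d, {"S": n_off})
    params = q.SimulationParams(mu=mu, sigma2_family=s2f, sigma2_resid=s2e, seed=seed)
    return q.simulate_phenotypes(d, plan, params, n_survivors=n_off)


class TestBookkeeping:
    def test_full_regime_retains_9000(self):
        spec = MCMC_PRESETS["full"]
        assert spec.n_chains == 6
        assert spec.retained_per_chain == 1500
        assert spec.retained_total == 9000

    @given(
        n_chains=st.integers(1, 8),
        n_burnin=st.integers(0, 500),
        extra=st.integers(1, 2000),
        thin=st.integers(1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_retained_arithmetic(self, n_chains, n_burnin, extra, thin):
        spec = q.McmcSpec(n_chains, n_burnin + extra, n_burnin, thin, seed=0)
        assert spec.retained_total == n_chains * (extra // thin)

    def test_retained_matches_actual_draws(self):
        tab = _one_factor_table(10, 5, 1.0, 1.0, seed=0)
        spec = q.McmcSpec(n_chains=2, n_iter=203, n_burnin=50, thin=7, seed=1)
        chains = q.gibbs_fit(tab, q.ModelSpec(random=("family",)), spec)
        assert chains.draws.shape[:2] == (2, (203 - 50) // 7)

    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            q.McmcSpec(n_chains=2, n_iter=100, n_burnin=100, thin=1, seed=0)


class TestGibbsFit:
    def test_group_means_recovered_with_tiny_residual(self):
        # near-degenerate residual: posterior fixed-effect cell means must
        # match the sample group means
        d = q.build_design(
            [q.PopulationSpec("A", n_pairs=2), q.PopulationSpec("B", n_pairs=2)], 1
        )
        plan = q.build_stocking(d, {"S": 200})
        params = q.SimulationParams(
            mu=50.0, pop_effects={"A": 0.0, "B": 7.0}, sigma2_resid=1e-4, seed=2
        )
        tab = q.simulate_phenotypes(d, plan, params, n_survivors=200)
        chains = q.gibbs_fit(
            tab,
            q.ModelSpec(fixed=("population",), random=("family",)),
            q.McmcSpec(2, 2000, 500, 2, seed=3),
        )
        gmeans = tab.groupby("population")["length"].mean()
        mu_a = chains.posterior_mean("(Intercept)")
        mu_b = mu_a + chains.posterior_mean("population[B]")
        assert mu_a == pytest.approx(gmeans["A"], rel=0.01)
        assert mu_b == pytest.approx(gmeans["B"], rel=0.01)

    def test_variance_recovery(self):
        # 200 families x 20 offspring at sigma2_family = sigma2_resid = 1
        tab = _one_factor_table(200, 20, 1.0, 1.0, seed=4)
        chains = q.gibbs_fit(
            tab, q.ModelSpec(random=("family",)), q.McmcSpec(2, 3000, 1000, 2, seed=5)
        )
        assert 0.8 <= chains.posterior_median("sigma2_family") <= 1.25
        assert 0.8 <= chains.posterior_median("sigma2_resid") <= 1.25

    def test_null_family_variance_shrinks_to_zero(self):
        tab = _one_factor_table(50, 20, 0.0, 1.0, seed=6)
        chains = q.gibbs_fit(
            tab, q.ModelSpec(random=("family",)), q.McmcSpec(2, 3000, 1000, 2, seed=7)
        )
        lower = np.quantile(chains.flat("sigma2_family"), 0.025)
        assert lower < 0.01 * chains.posterior_median("sigma2_resid")

    def test_variance_draws_strictly_positive(self, balanced_fit):
        for name in balanced_fit.variance_names:
            assert np.all(balanced_fit.flat(name) > 0)

    def test_empty_table_rejected(self):
        tab = _one_factor_table(2, 3, 0.0, 1.0, seed=0).iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            q.gibbs_fit(tab, q.ModelSpec(random=("family",)), q.McmcSpec(2, 100, 10, 1, 0))

    def test_confounded_fixed_design_rejected(self):
        # stream identical to population -> confounded two-factor design
        d = q.build_design(
            [q.PopulationSpec("A", n_pairs=2), q.PopulationSpec("B", n_pairs=2)], 1
        )
        plan = q.build_stocking(d, {"S1": 5, "S2": 5})
        params = q.SimulationParams(sigma2_resid=1.0, seed=0)
        tab = q.simulate_phenotypes(d, plan, params, n_survivors=5)
        tab["stream"] = tab["population"]
        with pytest.raises(ValueError, match="singular"):
            q.gibbs_fit(
                tab,
                q.ModelSpec(fixed=("population", "stream"), random=("family",)),
                q.McmcSpec(2, 100, 10, 1, 0),
            )

    def test_seed_reproducibility(self):
        tab = _one_factor_table(10, 5, 1.0, 1.0, seed=1)
        spec = q.McmcSpec(2, 500, 100, 2, seed=42)
        a = q.gibbs_fit(tab, q.ModelSpec(random=("family",)), spec)
        b = q.gibbs_fit(tab, q.ModelSpec(random=("family",)), spec)
        assert np.array_equal(a.draws, b.draws)


class TestReml:
    def test_no_family_signal_hits_boundary(self):
        rng = np.random.default_rng(0)
        tab = _one_factor_table(30, 10, 0.0, 1.0, seed=8)
        res = q.reml_fit(tab, q.ModelSpec(random=("family",)))
        assert res.variances["sigma2_family"] <= 1e-6
        assert res.variances["sigma2_resid"] == pytest.approx(
            np.var(tab["length"], ddof=1), rel=0.05
        )

    def test_balanced_two_group_fixed_effects_exact(self):
        d = q.build_design(
            [q.PopulationSpec("A", n_pairs=3), q.PopulationSpec("B", n_pairs=3)], 1
        )
        plan = q.build_stocking(d, {"S": 10})
        params = q.SimulationParams(
            mu=10.0, pop_effects={"A": 0.0, "B": 4.0},
            sigma2_family=0.5, sigma2_resid=1.0, seed=9,
        )
        tab = q.simulate_phenotypes(d, plan, params, n_survivors=10)
        res = q.reml_fit(tab, q.ModelSpec(fixed=("population",), random=("family",)))
        gmeans = tab.groupby("population")["length"].mean()
        # balanced design: GLS fixed effects coincide with group means
        assert res.fixed["(Intercept)"] == pytest.approx(gmeans["A"], abs=1e-8)
        assert res.fixed["(Intercept)"] + res.fixed["population[B]"] == pytest.approx(
            gmeans["B"], abs=1e-8
        )

    def test_agreement_with_statsmodels(self):
        # independent implementation check on a single-factor model
        statsmodels = pytest.importorskip("statsmodels.api")
        tab = _one_factor_table(40, 8, 1.5, 2.0, seed=10)
        res = q.reml_fit(tab, q.ModelSpec(random=("family",)))
        sm_fit = statsmodels.MixedLM.from_formula(
            "length ~ 1", groups="cross_id", data=tab
        ).fit(reml=True)
        assert res.variances["sigma2_family"] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3
        )
        assert res.variances["sigma2_resid"] == pytest.approx(
            float(sm_fit.scale), rel=1e-3
        )
        assert res.fixed["(Intercept)"] == pytest.approx(
            float(sm_fit.params["Intercept"]), rel=1e-5
        )

    def test_gibbs_posterior_means_near_reml(self, balanced_table, balanced_fit):
        reml = q.reml_fit(balanced_table, q.MODEL_PRESETS["M1"])
        for name in ("sigma2_family", "sigma2_resid"):
            assert balanced_fit.posterior_mean(name) == pytest.approx(
                reml.variances[name], rel=0.10
            )


class TestDiagnostics:
    def test_identical_chains_psrf_at_most_one(self):
        rng = np.random.default_rng(1)
        seq = rng.standard_normal(500)
        x = np.stack([seq, seq, seq])
        assert q.gelman_rubin(x) <= 1.0 + 1e-6

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        x = np.stack([rng.normal(0, 1, 400), rng.normal(10, 1, 400)])
        assert q.gelman_rubin(x) > 1.2

    def test_well_mixed_fit_converged(self, balanced_fit):
        assert q.gelman_rubin_quantile(balanced_fit) < 1.2

    def test_autocorr_alternating_sequence(self):
        x = np.tile([1.0, -1.0], 50)
        assert q.autocorr(x, 1) == pytest.approx(-1.0)

    def test_autocorr_independent_draws_small(self):
        x = np.random.default_rng(3).standard_normal(10_000)
        assert abs(q.autocorr(x, 1)) < 0.05

    def test_autocorr_constant_chain_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            q.autocorr(np.ones(100), 1)


class TestHeritability:
    def _chains(self, values: dict):
        names = list(values)
        draws = np.stack([np.column_stack([np.full(4, v) for v in values.values()])])
        return q.PosteriorChains(param_names=names, draws=draws)

    def test_fullsib_formula(self):
        ch = self._chains({"sigma2_family": 1.0, "sigma2_resid": 3.0})
        h2 = q.estimate_h2(ch, mode="fullsib")
        assert np.all(h2.draws == 0.5)  # 2*1/(1+3)
        assert h2.n_clipped == 0

    def test_fullsib_zero_family_variance(self):
        ch = self._chains({"sigma2_family": 0.0, "sigma2_resid": 3.0})
        assert np.all(q.estimate_h2(ch, mode="fullsib").draws == 0.0)

    def test_diallel_formula(self):
        ch = self._chains(
            {"sigma2_sire": 0.25, "sigma2_dam": 0.25, "sigma2_resid": 1.0}
        )
        h2 = q.estimate_h2(ch, mode="diallel")
        assert np.allclose(h2.draws, 2.0 / 3.0)  # 2*(0.5)/1.5

    def test_clipping_reported(self):
        ch = self._chains({"sigma2_family": 3.0, "sigma2_resid": 1.0})
        h2 = q.estimate_h2(ch, mode="fullsib")  # raw value 1.5 -> clipped
        assert np.all(h2.draws == 1.0)
        assert h2.n_clipped == ch.draws.shape[0] * ch.draws.shape[1]

    def test_population_variance_excluded(self):
        ch = self._chains(
            {"sigma2_population": 9.0, "sigma2_family": 1.0, "sigma2_resid": 3.0}
        )
        assert np.all(q.estimate_h2(ch, mode="fullsib").draws == 0.5)

    def test_wrong_mode_rejected(self):
        ch = self._chains({"sigma2_family": 1.0, "sigma2_resid": 3.0})
        with pytest.raises(ValueError, match="diallel"):
            q.estimate_h2(ch, mode="diallel")
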