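"""P_ST arithmetic and posteriors, F_ST verdicts, ICC normalization, reaction norms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qstream as q
from qstream.divergence import pst_from_components
from qstream.lmm import PosteriorChains


def _const_chains(values: dict, n=100, meta=None):
    draws = np.stack([np.column_stack([np.full(n, v) for v in values.values()])])
    return PosteriorChains(param_names=list(values), draws=draws, meta=meta or {})


class TestPstFromComponents:
    @pytest.mark.parametrize(
        "s2b,s2w,c,h2,expected",
        [
            (2.0, 1.0, 1.0, 1.0, 0.5),
            (0.0, 5.0, 1.0, 1.0, 0.0),
            (0.0, 5.0, 0.3, 0.2, 0.0),
            (2.0, 1.0, 1.0, 0.5, 2.0 / 3.0),
            (2.0, 1.0, 0.5, 1.0, 1.0 / 3.0),
        ],
    )
    def test_known_values(self, s2b, s2w, c, h2, expected):
        assert pst_from_components(s2b, s2w, c, h2) == pytest.approx(expected)

    def test_both_variances_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            pst_from_components(0.0, 0.0, 1.0, 1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pst_from_components(-1.0, 1.0)
        with pytest.raises(ValueError):
            pst_from_components(1.0, 1.0, c=0.0)

    @given(
        s2b=st.floats(0.0, 100.0),
        s2w=st.floats(0.001, 100.0),
        c=st.floats(0.01, 1.0),
        h2=st.floats(0.01, 1.0),
        ds2b=st.floats(0.001, 10.0),
        dc=st.floats(0.5, 0.999),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_monotonicity(self, s2b, s2w, c, h2, ds2b, dc):
        v = pst_from_components(s2b, s2w, c, h2)
        assert 0.0 <= v <= 1.0
        # increasing in sigma2_B and c; decreasing in h2 and sigma2_W
        assert pst_from_components(s2b + ds2b, s2w, c, h2) >= v
        assert pst_from_components(s2b, s2w, c * dc, h2) <= v
        assert pst_from_components(s2b, s2w * 2.0, c, h2) <= v
        assert pst_from_components(s2b, s2w, c, min(1.0, h2 * 1.5)) <= v

    def test_qst_pst_identity_at_c_one(self):
        # with c = 1 and additive components, the proxy is exactly Q_ST
        s2ab, s2aw = 3.0, 1.5
        qst = s2ab / (s2ab + 2 * s2aw)
        assert pst_from_components(s2ab, s2aw, c=1.0, h2=1.0) == pytest.approx(qst)


class TestPstPosterior:
    def test_degenerate_draws(self):
        ch = _const_chains(
            {"sigma2_population": 2.0, "sigma2_family": 0.4, "sigma2_resid": 0.6}
        )
        pst = q.pst_posterior(ch, h2=1.0, config=q.PstConfig(fst_upper=0.1), stream="S")
        assert np.all(pst.draws == 0.5)
        assert pst.median == 0.5
        assert pst.verdict == "divergent"

    def test_median_matches_per_draw_brute_force(self):
        rng = np.random.default_rng(4)
        n = 500
        s2p, s2f, s2e = rng.gamma(2, 1, n), rng.gamma(2, 0.5, n), rng.gamma(2, 0.5, n)
        h2 = rng.uniform(0.1, 0.9, n)
        ch = PosteriorChains(
            param_names=["sigma2_population", "sigma2_family", "sigma2_resid"],
            draws=np.stack([np.column_stack([s2p, s2f, s2e])]),
        )
        h2post = q.HeritabilityPosterior(draws=h2[None, :], mode="fullsib", n_clipped=0)
        pst = q.pst_posterior(ch, h2post, q.PstConfig(c=0.8))
        brute = [
            0.8 * s2p[i] / (0.8 * s2p[i] + 2 * h2[i] * (s2f[i] + s2e[i]))
            for i in range(n)
        ]
        assert pst.median == pytest.approx(np.median(brute), rel=1e-12)
        assert np.allclose(pst.draws, brute)

    def test_halving_c_weakly_decreases_every_draw(self):
        rng = np.random.default_rng(5)
        n = 200
        ch = PosteriorChains(
            param_names=["sigma2_population", "sigma2_family", "sigma2_resid"],
            draws=np.stack(
                [np.column_stack([rng.gamma(2, 1, n), rng.gamma(2, 1, n), rng.gamma(2, 1, n)])]
            ),
        )
        full = q.pst_posterior(ch, 0.5, q.PstConfig(c=1.0))
        half = q.pst_posterior(ch, 0.5, q.PstConfig(c=0.5))
        assert np.all(half.draws <= full.draws)

    def test_draw_count_mismatch_rejected(self):
        ch = _const_chains(
            {"sigma2_population": 1.0, "sigma2_family": 1.0, "sigma2_resid": 1.0}, n=50
        )
        h2post = q.HeritabilityPosterior(draws=np.full((1, 40), 0.5), mode="fullsib",
                                         n_clipped=0)
        with pytest.raises(ValueError, match="mismatch"):
            q.pst_posterior(ch, h2post)

    def test_residual_only_within_switch(self):
        ch = _const_chains(
            {"sigma2_population": 2.0, "sigma2_family": 0.5, "sigma2_resid": 0.5}
        )
        total = q.pst_posterior(ch, 1.0, q.PstConfig(within="total"))
        resid = q.pst_posterior(ch, 1.0, q.PstConfig(within="residual"))
        assert total.median == pytest.approx(0.5)
        assert resid.median == pytest.approx(2.0 / 3.0)


class TestVerdicts:
    def test_divergent(self):
        assert q.compare_to_fst(np.full(100, 0.6), 0.1) == "divergent"

    def test_stabilizing(self):
        assert q.compare_to_fst(np.full(100, 0.05), 0.1) == "stabilizing"

    def test_neutral_straddle(self):
        draws = np.concatenate([np.full(50, 0.05), np.full(50, 0.6)])
        assert q.compare_to_fst(draws, 0.1) == "neutral"


class TestIcc:
    def test_known_components(self):
        ch = _const_chains(
            {
                "sigma2_population": 1.0,
                "sigma2_stream": 1.0,
                "sigma2_family": 0.0,
                "sigma2_resid": 2.0,
            }
        )
        res = q.icc(ch)
        assert res.medians["population"] == pytest.approx(0.25)
        assert res.medians["stream"] == pytest.approx(0.25)
        assert res.medians["family"] == pytest.approx(0.0)
        assert res.medians["resid"] == pytest.approx(0.5)

    def test_single_nonzero_component(self):
        ch = _const_chains({"sigma2_population": 3.0, "sigma2_resid": 0.0})
        assert q.icc(ch).medians["population"] == pytest.approx(1.0)

    def test_normalization_every_draw(self):
        rng = np.random.default_rng(6)
        n = 9000
        ch = PosteriorChains(
            param_names=["sigma2_population", "sigma2_stream", "sigma2_family",
                         "sigma2_resid"],
            draws=np.stack([rng.gamma(2.0, 1.0, size=(n, 4))]),
        )
        res = q.icc(ch)
        total = np.sum(list(res.components.values()), axis=0)
        assert np.allclose(total, 1.0, atol=1e-12)


class TestReactionNorms:
    def _meta(self, pops, streams):
        return {"factors": {"population": pops, "stream": streams}}

    def test_pure_additive_shift(self):
        # population B shifted +10 with no interaction: every B cell mean +10
        ch = _const_chains(
            {"(Intercept)": 50.0, "population[B]": 10.0, "stream[S2]": 3.0},
            meta=self._meta(["A", "B"], ["S1", "S2"]),
        )
        table, ratio = q.reaction_norm_summary(ch)
        wide = table.pivot(index="population", columns="stream", values="mean")
        assert np.allclose(wide.loc["B"] - wide.loc["A"], 10.0)
        assert ratio["median"] == pytest.approx(0.0, abs=1e-12)

    def test_cell_means_match_sample_means_noise_free(self, balanced_design):
        plan = q.build_stocking(balanced_design, {"S1": 5, "S2": 5})
        params = q.SimulationParams(
            mu=10.0,
            pop_effects=dict(zip("ABCDE", [0.0, 1.0, 2.0, 3.0, 4.0])),
            stream_effects={"S1": 0.0, "S2": -1.0},
            interaction_effects={("B", "S2"): 2.0},
            sigma2_resid=1e-8,
            seed=11,
        )
        tab = q.simulate_phenotypes(balanced_design, plan, params, n_survivors=5)
        chains = q.gibbs_fit(
            tab, q.MODEL_PRESETS["M1"], q.McmcSpec(2, 1500, 500, 2, seed=12)
        )
        table, _ = q.reaction_norm_summary(chains)
        direct = tab.groupby(["population", "stream"])["length"].mean()
        for _, row in table.iterrows():
            assert row["mean"] == pytest.approx(
                direct[(row["population"], row["stream"])], abs=1e-3
            )

    def test_zero_interaction_gives_small_ratio(self, balanced_fit):
        # the balanced fixture was simulated with no interaction
        _, ratio = q.reaction_norm_summary(balanced_fit)
        assert ratio["median"] < 0.2
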