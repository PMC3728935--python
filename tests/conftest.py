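import numpy as np
import pytest

import qstream as q


@pytest.fixture(scope="session")
def exp1_design():
    """The five-population unique-pair design (57 families)."""
    return q.build_design(q.experiment1_populations(), experiment=1)


@pytest.fixture(scope="session")
def exp2_design():
    """The four-population incomplete diallel (90 families)."""
    return q.build_design(q.experiment2_populations(), experiment=2)


@pytest.fixture(scope="session")
def balanced_design():
    """Small balanced design: 5 populations x 12 unique-pair families."""
    pops = [q.PopulationSpec(n, n_pairs=12) for n in "ABCDE"]
    return q.build_design(pops, experiment=1)


@pytest.fixture(scope="session")
def balanced_table(balanced_design):
    """~3600 records over two streams with known variance components.

    sigma2_family = 1, sigma2_resid = 2, population shifts -2..2, 30
    offspring per family per stream; survivor counts fixed so the table is
    free of binomial noise.
    """
    plan = q.build_stocking(balanced_design, {"S1": 30, "S2": 30})
    params = q.SimulationParams(
        mu=70.0,
        pop_effects=dict(zip("ABCDE", [-2.0, -1.0, 0.0, 1.0, 2.0])),
        stream_effects={"S1": 0.0, "S2": 3.0},
        sigma2_family=1.0,
        sigma2_resid=2.0,
        seed=5,
    )
    return q.simulate_phenotypes(balanced_design, plan, params, n_survivors=30)


@pytest.fixture(scope="session")
def balanced_fit(balanced_table):
    """A quick but well-mixed Gibbs fit of the reaction-norm model."""
    mcmc = q.McmcSpec(n_chains=3, n_iter=4000, n_burnin=1000, thin=3, seed=11)
    return q.gibbs_fit(balanced_table, q.MODEL_PRESETS["M1"], mcmc)
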