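"""Shared fixtures: priors, synthetic scenarios, and reusable posterior fits.

Expensive MCMC fits are session-scoped so many tests can interrogate the
same converged posterior.  All randomness is seeded; nothing here touches
the network or the filesystem outside pytest's tmp_path.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import cmcbed as cb


@pytest.fixture(scope="session")
def noise():
    return cb.NoiseModel(sigma=0.001)


@pytest.fixture(scope="session")
def otg_prior():
    return cb.PriorSpec(cmc_bounds=(0.0, 30.0), cmc_prior_kind="uniform")


@pytest.fixture(scope="session")
def triton_prior():
    return cb.PriorSpec(cmc_bounds=(0.001, 10.0), cmc_prior_kind="log_uniform")


@pytest.fixture(scope="session")
def otg_scenario():
    return cb.preset_scenario("otg")


@pytest.fixture(scope="session")
def triton_scenario():
    return cb.preset_scenario("triton")


@pytest.fixture(scope="session")
def otg_data5(otg_scenario):
    """Five well-spread measurements from the OTG-like truth."""
    return cb.generate_synthetic_dataset(otg_scenario, [0.0, 3.0, 7.5, 12.0, 30.0], seed=1)


@pytest.fixture(scope="session")
def otg_fit5(otg_data5, otg_prior, noise):
    """Converged posterior on the informative five-point OTG-like dataset."""
    return cb.sample_posterior(
        otg_data5, otg_prior, noise, cb.SamplerSettings(n_chains=32, n_warmup=1000, n_draws=400, seed=42)
    )


def reduced_campaign_config(
    prior,
    noise,
    seed,
    *,
    budget=9,
    n_cand=7,
    n_outer=8,
    inner=(8, 40, 60, 3),
    outer=(16, 400, 200),
):
    """Campaign configuration at the reduced problem sizes the suite runs.

    ``inner`` is (walkers, warmup, draws, thin) for the nested-MC re-fits;
    ``outer`` is (walkers, warmup, draws) for the per-iteration posterior
    fits.  Defaults favour speed (adequate for calibration-style checks);
    design-quality checks pass a finer grid and larger budgets.
    """
    w_i, wa_i, nd_i, th_i = inner
    w_o, wa_o, nd_o = outer
    return cb.CampaignConfig(
        prior=prior,
        noise=noise,
        sampler=cb.SamplerSettings(n_chains=w_o, n_warmup=wa_o, n_draws=nd_o),
        eig=cb.EIGSettings(
            n_outer=n_outer,
            inner_sampler=cb.SamplerSettings(
                n_chains=w_i, n_warmup=wa_i, n_draws=nd_i, thin=th_i, init_strategy="warm_start"
            ),
        ),
        grid=cb.DesignGrid.from_prior(prior, n_points=n_cand, refinement_rounds=0),
        budget=budget,
        seed=seed,
    )


@pytest.fixture()
def quiet_inner_warnings():
    """Silence the diffuse-posterior inner-refit warnings in campaign loops."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


def deterministic_truth_oracle(truth, noise, seed):
    """Measurement source whose output depends only on (seed, concentration),
    so replaying any prefix of a campaign reproduces it exactly."""

    def measure(c: float) -> cb.Measurement:
        sub = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(int(round(c * 1e6)) % (2**31),)).generate_state(1)[0]
            % (2**31 - 1)
        )
        o = cb.OracleSpec(kind="truth", truth=truth, noise=noise, seed=sub)
        return cb.oracle_measure(o, c)

    return measure
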