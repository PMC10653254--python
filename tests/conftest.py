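import numpy as np
import pandas as pd
import pytest

from outsel.model import MCMCConfig, ModelSpec, NormalPrior, LogNormalPrior, SpikeSpec
from outsel.panel import OutcomePanel


def make_long(n, K, rng, q=1, missing=()):
    """Random complete long panel with q z-covariates; drop cells in `missing`
    (list of (individual_id, outcome_id) 1-based pairs)."""
    exposure = rng.normal(0.5, 1.0, size=n)
    z = rng.normal(size=(n, q))
    rows = []
    for j in range(1, n + 1):
        for p in range(1, K + 1):
            if (j, p) in missing:
                continue
            row = {
                "individual_id": j,
                "outcome_id": p,
                "y": rng.normal(),
                "exposure": exposure[j - 1],
            }
            for a in range(q):
                row[f"z{a + 1}"] = z[j - 1, a]
            rows.append(row)
    return OutcomePanel(pd.DataFrame(rows), n=n, K=K)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def tiny_panel(rng):
    """Complete 6-individual, 3-outcome panel with one z covariate."""
    return make_long(6, 3, rng)


@pytest.fixture
def tight_spec():
    """Moderately informative priors: stable moments for validation runs."""
    return ModelSpec(
        variant="ssvs_mean",
        spike=SpikeSpec(kind="scaled", c=25.0),
        pi=0.5,
        mu_prior=NormalPrior(0.0, 1.0),
        tau_prior=LogNormalPrior(0.0, 0.25),
        sigma_k_prior=LogNormalPrior(0.0, 0.25),
        sigma_r_prior=LogNormalPrior(0.0, 0.25),
        nu_prior=NormalPrior(0.0, 1.0),
        gamma_prior=NormalPrior(0.0, 1.0),
    )


@pytest.fixture
def short_mcmc():
    return MCMCConfig(chains=2, burn_in=200, iterations=400, thin=1, seed=11)
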