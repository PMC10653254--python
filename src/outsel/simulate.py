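"""Synthetic multiple-outcome panels with a confounded exposure.

The generator emulates the simulation design used to benchmark the
selection model: K outcomes on n individuals, of which the first K1 are
truly exposure-sensitive with coefficients clustered tightly around a
common mean mu (SD = 0.1 |mu|, i.e. coefficient of variation 0.1), and the
rest unaffected.  The exposure is deliberately confounded with the
covariate z: individuals with z < 0 draw exposure from N(0, 0.5^2) and the
rest from N(1, 1), so exposure and z are positively correlated and naive
marginal associations are biased.  A shared random intercept alpha_j
induces equal within-individual correlation across outcomes.

Defaults: n = 100, K = 20, nu_k ~ N(0, 1), residual variances
sigma_k^2 ~ N(1.5, 0.3^2) truncated below at 0.05.  The design leaves the
random-intercept scale and the z-coefficients unspecified; we default to
sigma_r = 1 and gamma_k ~ N(0, 1), both exposed as scenario fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import OutcomePanel


@dataclass(frozen=True)
class SimScenario:
    """One cell of the simulation design."""

    n: int = 100
    K: int = 20
    K1: int = 5
    mu_true: float = -3.0
    seed: int = 0
    sigma_r_true: float = 1.0
    gamma_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.K1 <= self.K):
            raise ValueError("K1 must lie in [0, K]")
        if self.n < 2:
            raise ValueError("need at least 2 individuals")
        if self.sigma_r_true <= 0 or self.gamma_sd < 0:
            raise ValueError("sigma_r_true must be > 0 and gamma_sd >= 0")


@dataclass
class SimTruth:
    """The generated parameter values behind one synthetic panel."""

    beta_true: np.ndarray
    relevant: np.ndarray
    nu_true: np.ndarray
    sigma_true: np.ndarray      # residual SDs per outcome
    gamma_true: np.ndarray
    sigma_r_true: float
    alpha_true: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "outcome_id": np.arange(1, len(self.beta_true) + 1),
                "beta_true": self.beta_true,
                "relevant": self.relevant.astype(int),
                "nu_true": self.nu_true,
                "sigma_true": self.sigma_true,
                "gamma_true": self.gamma_true,
            }
        )


def draw_parameters(scenario: SimScenario, rng: np.random.Generator) -> SimTruth:
    """Draw the per-outcome "true" parameters for one replicate.

    The first K1 outcome ids form the sensitive set (a deterministic layout;
    selection is label-equivariant so no generality is lost): their
    coefficients are N(mu, 0.01 mu^2) so they scatter closely around the
    common mean.  Residual variances are N(1.5, 0.3^2) truncated at 0.05.
    """
    K, K1 = scenario.K, scenario.K1
    nu = rng.normal(0.0, 1.0, size=K)
    var = rng.normal(1.5, 0.3, size=K)
    while np.any(var <= 0.05):  # truncation keeps variances positive
        bad = var <= 0.05
        var[bad] = rng.normal(1.5, 0.3, size=bad.sum())
    sigma = np.sqrt(var)
    beta = np.zeros(K)
    relevant = np.zeros(K, dtype=bool)
    relevant[:K1] = True
    if K1:
        beta[:K1] = rng.normal(scenario.mu_true, 0.1 * abs(scenario.mu_true), size=K1)
    gamma = rng.normal(0.0, scenario.gamma_sd, size=K) if scenario.gamma_sd > 0 else np.zeros(K)
    return SimTruth(
        beta_true=beta,
        relevant=relevant,
        nu_true=nu,
        sigma_true=sigma,
        gamma_true=gamma,
        sigma_r_true=scenario.sigma_r_true,
    )


def draw_panel(scenario: SimScenario, truth: SimTruth, rng: np.random.Generator) -> OutcomePanel:
    """Generate one complete n x K panel given the true parameters.

    Per individual: z ~ N(0, 1); exposure ~ N(0, 0.5^2) when z < 0, else
    N(1, 1); alpha ~ N(0, sigma_r^2).  Per cell: y = nu_k + alpha_j +
    beta_k * exposure_j + gamma_k * z_j + N(0, sigma_k^2).
    """
    n, K = scenario.n, scenario.K
    if len(truth.beta_true) != K:
        raise ValueError("truth dimensions do not match scenario")
    z = rng.normal(0.0, 1.0, size=n)
    exposure = np.where(
        z < 0,
        rng.normal(0.0, 0.5, size=n),
        rng.normal(1.0, 1.0, size=n),
    )
    alpha = rng.normal(0.0, truth.sigma_r_true, size=n)
    truth.alpha_true = alpha
    mean = (
        truth.nu_true[None, :]
        + alpha[:, None]
        + exposure[:, None] * truth.beta_true[None, :]
        + z[:, None] * truth.gamma_true[None, :]
    )
    Y = mean + truth.sigma_true[None, :] * rng.standard_normal((n, K))
    df = pd.DataFrame(
        {
            "individual_id": np.repeat(np.arange(1, n + 1), K),
            "outcome_id": np.tile(np.arange(1, K + 1), n),
            "y": Y.ravel(),
            "exposure": np.repeat(exposure, K),
            "z1": np.repeat(z, K),
        }
    )
    return OutcomePanel(df, n=n, K=K)


def simulate_dataset(scenario: SimScenario) -> tuple[OutcomePanel, SimTruth]:
    """Draw parameters then a panel, fully determined by ``scenario.seed``."""
    rng = np.random.default_rng(scenario.seed)
    truth = draw_parameters(scenario, rng)
    panel = draw_panel(scenario, truth, rng)
    return panel, truth
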