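"""Model and prior specification for the outcome-selection mixed model.

The observation model for stacked row i (individual j[i], outcome p[i]) is

    y_i = nu_{p[i]} + alpha_{j[i]} + beta_{p[i]} * exposure_{j[i]}
          + gamma_{p[i]}' z_{j[i]} + eps_i,

with eps_i ~ N(0, sigma_{p[i]}^2) independent and a per-individual random
intercept alpha_j ~ N(0, sigma_r^2) carrying the within-individual
correlation across outcomes.

Five prior variants on the exposure effects beta_k are supported:

``ssvs_mean``
    The headline model.  Latent inclusion indicators I_k ~ Bernoulli(pi_k)
    and the two-component mixture prior

        beta_k | I_k  ~  (1 - I_k) N(0, g_spike) + I_k N(mu, tau^2),

    with the slab centred at an *unknown* common mean mu, so the model
    simultaneously selects sensitive outcomes and estimates the mean effect
    on them.  The spike variance is either tied to the slab, g_spike =
    tau^2 / c (scaled spike, tuning constant c), or a fixed constant g1.
``ssvs_null``
    Standard SSVS: the same mixture with the slab fixed at mean 0.
``hierarchical``
    No selection: beta_k ~ N(mu, tau^2) for every outcome.
``subset``
    The hierarchical model fit only to a declared subset of outcomes; the
    benchmark that uses the correct sensitive set when it is known.
``laplace``
    A shrinkage comparator: beta_k ~ Laplace(0, 1), no indicators; selection
    is reported through 95% credible-interval exclusion of zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VARIANTS = ("ssvs_mean", "ssvs_null", "hierarchical", "subset", "laplace")

#: Variance floor inside density evaluations, preventing -inf log-densities.
VAR_FLOOR = 1e-10


@dataclass(frozen=True)
class SpikeSpec:
    """Spike component of the mixture prior.

    ``kind='scaled'`` sets the spike variance to tau^2 / c so spike and slab
    separate by the factor c; ``kind='fixed'`` uses a constant variance g1.
    """

    kind: str = "scaled"
    c: float = 100.0
    g1: float = 0.04

    def __post_init__(self) -> None:
        if self.kind not in ("scaled", "fixed"):
            raise ValueError(f"spike kind must be 'scaled' or 'fixed', got {self.kind!r}")
        if self.kind == "scaled" and self.c <= 0:
            raise ValueError("spike scale c must be positive")
        if self.kind == "fixed" and self.g1 <= 0:
            raise ValueError("fixed spike variance g1 must be positive")

    def variance(self, tau: float) -> float:
        return self.g1 if self.kind == "fixed" else tau * tau / self.c


@dataclass(frozen=True)
class NormalPrior:
    mean: float = 0.0
    var: float = 100.0

    def __post_init__(self) -> None:
        if self.var <= 0:
            raise ValueError("prior variance must be positive")


@dataclass(frozen=True)
class LogNormalPrior:
    """Log-normal prior on a scale parameter: log x ~ N(loc, scale_var)."""

    loc: float = 0.0
    var: float = 10.0

    def __post_init__(self) -> None:
        if self.var <= 0:
            raise ValueError("log-scale variance must be positive")

    def logpdf_of_log(self, logx: float) -> float:
        # density of log x plus the Jacobian term for x, as a function of log x:
        # lognormal pdf in x is N(logx; loc, var)/x, so in logx it is N(logx; loc, var)
        return -0.5 * (logx - self.loc) ** 2 / self.var - 0.5 * np.log(2 * np.pi * self.var)


@dataclass(frozen=True)
class ModelSpec:
    """Prior variant plus every hyperparameter of the sampler.

    Defaults reproduce the simulation-study configuration: scaled spike with
    c = 100, pi_k = 0.5, mu ~ N(0, 100), tau ~ LogNormal(0, 1),
    sigma_k, sigma_r ~ LogNormal(0, 10), nu_k, gamma_k ~ N(0, 100).
    Normal(a, b) is read as mean a and VARIANCE b; LogNormal(a, b) as
    log-scale mean a and log-scale VARIANCE b.
    """

    variant: str = "ssvs_mean"
    spike: SpikeSpec = field(default_factory=SpikeSpec)
    pi: float | np.ndarray = 0.5
    mu_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 100.0))
    tau_prior: LogNormalPrior = field(default_factory=lambda: LogNormalPrior(0.0, 1.0))
    sigma_k_prior: LogNormalPrior = field(default_factory=lambda: LogNormalPrior(0.0, 10.0))
    sigma_r_prior: LogNormalPrior = field(default_factory=lambda: LogNormalPrior(0.0, 10.0))
    nu_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 100.0))
    gamma_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 100.0))
    laplace_scale: float = 1.0
    subset_outcomes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.variant == "subset" and len(self.subset_outcomes) == 0:
            raise ValueError("subset variant requires a non-empty subset_outcomes")
        pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        if np.any(pi < 0) or np.any(pi > 1):
            raise ValueError("prior inclusion probabilities must lie in [0, 1]")

    def pi_vector(self, K: int) -> np.ndarray:
        """Prior inclusion probabilities broadcast to length K."""
        pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        if pi.size == 1:
            return np.full(K, pi[0])
        if pi.size != K:
            raise ValueError(f"pi has length {pi.size}, expected {K}")
        return pi.copy()

    @property
    def has_indicators(self) -> bool:
        return self.variant in ("ssvs_mean", "ssvs_null")

    @property
    def has_mu(self) -> bool:
        return self.variant in ("ssvs_mean", "hierarchical", "subset")

    @property
    def has_tau(self) -> bool:
        return self.variant != "laplace"


@dataclass
class ModelState:
    """One point in parameter space visited by the sampler.

    Arrays: beta, indicators, nu, sigma have length K; gamma is (q, K) for q
    covariate columns; alpha has length n.  ``laplace_latent`` holds the
    exponential mixing scales of the Laplace prior's scale-mixture
    representation (unused by other variants).
    """

    beta: np.ndarray
    indicators: np.ndarray
    mu: float
    tau: float
    nu: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray
    sigma: np.ndarray
    sigma_r: float
    laplace_latent: np.ndarray | None = None

    def copy(self) -> "ModelState":
        return ModelState(
            beta=self.beta.copy(),
            indicators=self.indicators.copy(),
            mu=float(self.mu),
            tau=float(self.tau),
            nu=self.nu.copy(),
            gamma=self.gamma.copy(),
            alpha=self.alpha.copy(),
            sigma=self.sigma.copy(),
            sigma_r=float(self.sigma_r),
            laplace_latent=None if self.laplace_latent is None else self.laplace_latent.copy(),
        )

    def validate(self) -> None:
        if np.any(self.sigma <= 0) or self.sigma_r <= 0 or self.tau <= 0:
            raise ValueError("scale parameters must be strictly positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout: ``iterations`` post-burn-in sweeps per chain, retaining
    every ``thin``-th state, so floor(iterations / thin) draws per chain."""

    chains: int = 3
    burn_in: int = 5000
    iterations: int = 5000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.burn_in < 0 or self.iterations < 1 or self.thin < 1:
            raise ValueError("invalid MCMC configuration")

    @property
    def retained(self) -> int:
        return self.iterations // self.thin


@dataclass
class ChainDraws:
    """Retained posterior draws, stacked as (chains, draws, ...) arrays."""

    beta: np.ndarray        # (C, D, K)
    indicators: np.ndarray  # (C, D, K)
    mu: np.ndarray          # (C, D)
    tau: np.ndarray         # (C, D)
    nu: np.ndarray          # (C, D, K)
    gamma: np.ndarray       # (C, D, q, K)
    alpha: np.ndarray       # (C, D, n)
    sigma: np.ndarray       # (C, D, K)
    sigma_r: np.ndarray     # (C, D)
    config: MCMCConfig
    variant: str
    outcome_ids: np.ndarray  # 1-based ids of the modeled outcomes, length K
    slice_evals: int = 0     # total density evaluations spent in slice updates

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    @property
    def K(self) -> int:
        return self.beta.shape[2]

    def pooled(self, name: str) -> np.ndarray:
        """All chains' draws of a parameter merged along the draw axis."""
        arr = getattr(self, name)
        return arr.reshape(-1, *arr.shape[2:])

    def to_dataframe(self):
        """Flatten to one row per retained draw with conventional column
        names (beta.1..K, I.1..K, mu, tau, ..., chain, iter)."""
        import pandas as pd

        C, D, K = self.beta.shape
        n = self.alpha.shape[2]
        q = self.gamma.shape[2]
        cols = {}
        ids = self.outcome_ids
        for k in range(K):
            cols[f"beta.{ids[k]}"] = self.beta[:, :, k].ravel()
        for k in range(K):
            cols[f"I.{ids[k]}"] = self.indicators[:, :, k].ravel()
        cols["mu"] = self.mu.ravel()
        cols["tau"] = self.tau.ravel()
        for k in range(K):
            cols[f"nu.{ids[k]}"] = self.nu[:, :, k].ravel()
        for a in range(q):
            for k in range(K):
                cols[f"gamma{a + 1}.{ids[k]}"] = self.gamma[:, :, a, k].ravel()
        for j in range(n):
            cols[f"alpha.{j + 1}"] = self.alpha[:, :, j].ravel()
        for k in range(K):
            cols[f"sigma.{ids[k]}"] = self.sigma[:, :, k].ravel()
        cols["sigma_r"] = self.sigma_r.ravel()
        cols["chain"] = np.repeat(np.arange(1, C + 1), D)
        cols["iter"] = np.tile(np.arange(1, D + 1), C)
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df, variant: str = "ssvs_mean", config: "MCMCConfig | None" = None) -> "ChainDraws":
        """Rebuild ChainDraws from the flat per-draw table written by
        :meth:`to_dataframe` (column layout beta.k / I.k / ... / chain)."""
        import re

        chains = np.sort(df["chain"].unique())
        C = len(chains)
        D = int((df["chain"] == chains[0]).sum())

        def block(prefix: str) -> tuple[np.ndarray, np.ndarray]:
            pat = re.compile(rf"^{prefix}\.(\d+)$")
            pairs = sorted(
                ((int(m.group(1)), c) for c in df.columns if (m := pat.match(c))),
            )
            ids = np.array([i for i, _ in pairs])
            arr = np.stack([df[c].to_numpy().reshape(C, D) for _, c in pairs], axis=2)
            return ids, arr

        ids, beta = block("beta")
        _, ind = block("I")
        _, nu = block("nu")
        _, alpha = block("alpha")
        _, sigma = block("sigma")
        gamma_ids = sorted(
            {int(m.group(1)) for c in df.columns if (m := re.match(r"^gamma(\d+)\.\d+$", c))}
        )
        if gamma_ids:
            gamma = np.stack([block(f"gamma{a}")[1] for a in gamma_ids], axis=2)
        else:
            gamma = np.empty((C, D, 0, beta.shape[2]))
        return cls(
            beta=beta,
            indicators=ind.astype(np.int8),
            mu=df["mu"].to_numpy().reshape(C, D),
            tau=df["tau"].to_numpy().reshape(C, D),
            nu=nu,
            gamma=gamma,
            alpha=alpha,
            sigma=sigma,
            sigma_r=df["sigma_r"].to_numpy().reshape(C, D),
            config=config or MCMCConfig(chains=C, burn_in=0, iterations=D, thin=1, seed=0),
            variant=variant,
            outcome_ids=ids,
        )


def spec_with(spec: ModelSpec, **kw) -> ModelSpec:
    """Convenience: a copy of ``spec`` with fields replaced."""
    return replace(spec, **kw)
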