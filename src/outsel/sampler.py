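"""Metropolis-within-Gibbs sampler for the outcome-selection mixed model.

Every full conditional that is normal is drawn exactly (beta_k, mu, nu_k,
gamma_k, alpha_j, and the Bernoulli indicators I_k); the scale parameters
tau, sigma_k and sigma_r, whose log-normal priors are non-conjugate, move by
slice sampling on the log scale.  The Laplace comparator uses the
exponential scale-mixture-of-normals augmentation, which restores a
conjugate normal draw for beta_k given a latent per-coefficient scale.

The panel's sparse interaction structure keeps every sweep O(nK): the model
matrix is never materialised, and all per-outcome and per-individual sums
are computed on dense (n, K) masked arrays.

A sweep updates, in fixed order: beta (all k), indicators (SSVS variants),
mu (when the slab mean is free), nu and gamma (all k), alpha (all j), tau,
sigma_k (all k), sigma_r.
"""

from __future__ import annotations

import math

import numpy as np

from ._slice import SliceStats, slice_sample
from .model import (
    VAR_FLOOR,
    ChainDraws,
    MCMCConfig,
    ModelSpec,
    ModelState,
)
from .panel import OutcomePanel, PanelArrays

LOG2PI = math.log(2.0 * math.pi)


def _as_arrays(panel: OutcomePanel | PanelArrays) -> PanelArrays:
    return panel if isinstance(panel, PanelArrays) else panel.to_arrays()


# ---------------------------------------------------------------------------
# linear predictor pieces
# ---------------------------------------------------------------------------

def _linpred(state: ModelState, arr: PanelArrays) -> np.ndarray:
    """Fitted mean for every (individual, outcome) cell, shape (n, K)."""
    F = state.nu[None, :] + state.alpha[:, None] + arr.exposure[:, None] * state.beta[None, :]
    if arr.q:
        F = F + arr.Z @ state.gamma
    return F


def log_likelihood(state: ModelState, panel: OutcomePanel | PanelArrays) -> float:
    """Gaussian log likelihood of the observed cells under ``state``."""
    arr = _as_arrays(panel)
    if np.any(state.sigma <= 0) or state.sigma_r <= 0:
        raise ValueError("scale parameters must be strictly positive")
    R = arr.Y - _linpred(state, arr)
    var = np.maximum(state.sigma[None, :] ** 2, VAR_FLOOR)
    ll = -0.5 * (LOG2PI + np.log(var) + R * R / var)
    return float(ll[arr.mask].sum())


# ---------------------------------------------------------------------------
# exact normal full conditionals (moments exposed for testing/diagnostics)
# ---------------------------------------------------------------------------

def beta_full_conditional(
    state: ModelState, arr: PanelArrays, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (mean, variance) of every beta_k given the rest.

    With rows R_k of outcome k, residual r = y - nu_k - alpha_j - gamma_k'z
    and prior N(m, v) (slab N(mu, tau^2) when I_k = 1, spike N(0, g_spike)
    when I_k = 0, or the hierarchical slab for no-selection variants):

        V = 1 / (sum e^2/sigma_k^2 + 1/v),   E = V (sum e r/sigma_k^2 + m/v).

    Outcomes with no rows fall back to the prior.
    """
    R = arr.Y - state.nu[None, :] - state.alpha[:, None]
    if arr.q:
        R = R - arr.Z @ state.gamma
    e = arr.exposure[:, None]
    s2 = np.maximum(state.sigma**2, VAR_FLOOR)
    A = (arr.mask * e * e).sum(axis=0) / s2
    B = (arr.mask * e * R).sum(axis=0) / s2
    g_spike = max(spec.spike.variance(state.tau), VAR_FLOOR)
    slab_var = max(state.tau**2, VAR_FLOOR)
    sel = state.indicators.astype(bool)
    prior_mean = np.where(sel, state.mu, 0.0)
    prior_var = np.where(sel, slab_var, g_spike)
    post_var = 1.0 / (A + 1.0 / prior_var)
    post_mean = post_var * (B + prior_mean / prior_var)
    return post_mean, post_var


def update_beta(state: ModelState, arr: PanelArrays, spec: ModelSpec, rng: np.random.Generator) -> None:
    mean, var = beta_full_conditional(state, arr, spec)
    state.beta = mean + np.sqrt(var) * rng.standard_normal(arr.K)


def indicator_probability(
    beta: np.ndarray, mu: float, tau: float, pi: np.ndarray, g_spike: float
) -> np.ndarray:
    """P(I_k = 1 | beta_k, mu, tau): the slab responsibility

        pi_k N(beta_k; mu, tau^2) / [pi_k N(beta_k; mu, tau^2)
                                     + (1 - pi_k) N(beta_k; 0, g_spike)],

    evaluated in log space.  At beta = mu = 0 and a scaled spike tau^2/c
    this reduces to 1 / (1 + sqrt(c)).
    """
    pi = np.asarray(pi, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("pi must lie in [0, 1]")
    slab_var = max(tau * tau, VAR_FLOOR)
    g_spike = max(g_spike, VAR_FLOOR)
    log_slab = -0.5 * ((beta - mu) ** 2 / slab_var + math.log(slab_var))
    log_spike = -0.5 * (beta**2 / g_spike + math.log(g_spike))
    with np.errstate(divide="ignore"):
        logit = np.log(pi) - np.log1p(-pi) + log_slab - log_spike
    p = np.empty_like(logit)
    np.clip(logit, -700, 700, out=logit)
    p = 1.0 / (1.0 + np.exp(-logit))
    p[pi == 0.0] = 0.0
    p[pi == 1.0] = 1.0
    return p


def update_indicators(state: ModelState, spec: ModelSpec, K: int, rng: np.random.Generator) -> None:
    pi = spec.pi_vector(K)
    g_spike = spec.spike.variance(state.tau)
    p = indicator_probability(state.beta, state.mu, state.tau, pi, g_spike)
    state.indicators = (rng.random(K) < p).astype(np.int8)


def mu_full_conditional(state: ModelState, spec: ModelSpec) -> tuple[float, float]:
    """Posterior (mean, variance) of the slab mean mu.

    Only slab members (I_k = 1) inform mu — the spike component does not
    involve it.  With S = {k : I_k = 1}:

        precision = |S| / tau^2 + 1 / s0^2,
        mean = (sum_S beta_k / tau^2 + m0 / s0^2) / precision.

    An empty S returns the prior.
    """
    if not spec.has_mu:
        raise ValueError(f"variant {spec.variant!r} has no free slab mean mu")
    sel = state.indicators.astype(bool)
    tau2 = max(state.tau**2, VAR_FLOOR)
    m0, s02 = spec.mu_prior.mean, spec.mu_prior.var
    prec = sel.sum() / tau2 + 1.0 / s02
    mean = (state.beta[sel].sum() / tau2 + m0 / s02) / prec
    return float(mean), float(1.0 / prec)


def update_mu(state: ModelState, spec: ModelSpec, rng: np.random.Generator) -> None:
    mean, var = mu_full_conditional(state, spec)
    state.mu = mean + math.sqrt(var) * rng.standard_normal()


def nu_full_conditional(
    state: ModelState, arr: PanelArrays, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (mean, variance) of every intercept nu_k given the rest."""
    R = arr.Y - state.alpha[:, None] - arr.exposure[:, None] * state.beta[None, :]
    if arr.q:
        R = R - arr.Z @ state.gamma
    s2 = np.maximum(state.sigma**2, VAR_FLOOR)
    n_k = arr.mask.sum(axis=0)
    prec = n_k / s2 + 1.0 / spec.nu_prior.var
    mean = ((arr.mask * R).sum(axis=0) / s2 + spec.nu_prior.mean / spec.nu_prior.var) / prec
    return mean, 1.0 / prec


def gamma_full_conditional(
    a: int, state: ModelState, arr: PanelArrays, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (mean, variance) of gamma_{a,k} for all k, conditioning on
    the other covariates' coefficients (sequential scalar Gibbs)."""
    R = (
        arr.Y
        - state.nu[None, :]
        - state.alpha[:, None]
        - arr.exposure[:, None] * state.beta[None, :]
    )
    if arr.q:
        R = R - arr.Z @ state.gamma
    za = arr.Z[:, a][:, None]
    R = R + za * state.gamma[a][None, :]  # add own term back
    s2 = np.maximum(state.sigma**2, VAR_FLOOR)
    A = (arr.mask * za * za).sum(axis=0) / s2
    B = (arr.mask * za * R).sum(axis=0) / s2
    prec = A + 1.0 / spec.gamma_prior.var
    mean = (B + spec.gamma_prior.mean / spec.gamma_prior.var) / prec
    return mean, 1.0 / prec


def update_nu_gamma(state: ModelState, arr: PanelArrays, spec: ModelSpec, rng: np.random.Generator) -> None:
    mean, var = nu_full_conditional(state, arr, spec)
    state.nu = mean + np.sqrt(var) * rng.standard_normal(arr.K)
    for a in range(arr.q):
        mean, var = gamma_full_conditional(a, state, arr, spec)
        state.gamma[a] = mean + np.sqrt(var) * rng.standard_normal(arr.K)


def alpha_full_conditional(state: ModelState, arr: PanelArrays) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (mean, variance) of every random intercept alpha_j.

    Conjugate normal with N(0, sigma_r^2) prior; individuals with no rows
    fall back to the prior, and sigma_r -> 0 pins alpha at 0.
    """
    R = arr.Y - state.nu[None, :] - arr.exposure[:, None] * state.beta[None, :]
    if arr.q:
        R = R - arr.Z @ state.gamma
    s2 = np.maximum(state.sigma**2, VAR_FLOOR)
    prec = (arr.mask / s2[None, :]).sum(axis=1) + 1.0 / max(state.sigma_r**2, VAR_FLOOR)
    mean = (arr.mask * R / s2[None, :]).sum(axis=1) / prec
    return mean, 1.0 / prec


def update_alpha(state: ModelState, arr: PanelArrays, rng: np.random.Generator) -> None:
    mean, var = alpha_full_conditional(state, arr)
    state.alpha = mean + np.sqrt(var) * rng.standard_normal(arr.n)


# ---------------------------------------------------------------------------
# non-conjugate scale updates (slice sampling on the log scale)
# ---------------------------------------------------------------------------

def tau_log_density(logtau: float, state: ModelState, spec: ModelSpec) -> float:
    """Log full conditional of log tau.

    Slab members contribute N(beta_k; mu, tau^2); with a scaled spike the
    non-members also contribute N(beta_k; 0, tau^2/c) since the spike width
    is tied to tau.  With a fixed spike the non-members drop out entirely.
    """
    tau = math.exp(logtau)
    tau2 = max(tau * tau, VAR_FLOOR)
    sel = state.indicators.astype(bool)
    mu = state.mu if spec.has_mu else 0.0
    b1 = state.beta[sel]
    out = -0.5 * (((b1 - mu) ** 2).sum() / tau2) - b1.size * logtau
    if spec.spike.kind == "scaled" and spec.has_indicators:
        b0 = state.beta[~sel]
        spike_var = max(tau2 / spec.spike.c, VAR_FLOOR)
        out += -0.5 * ((b0**2).sum() / spike_var) - b0.size * 0.5 * math.log(spike_var)
    return out + spec.tau_prior.logpdf_of_log(logtau)


def update_tau(state: ModelState, spec: ModelSpec, rng: np.random.Generator, stats: SliceStats | None = None) -> None:
    logtau = slice_sample(
        math.log(state.tau),
        lambda lt: tau_log_density(lt, state, spec),
        rng,
        stats=stats,
    )
    state.tau = math.exp(logtau)


def update_sigma(
    state: ModelState, arr: PanelArrays, spec: ModelSpec, rng: np.random.Generator, stats: SliceStats | None = None
) -> None:
    """Slice-update every residual scale sigma_k.

    The likelihood factor for sigma_k is -n_k log sigma - SSE_k / (2 sigma^2)
    with SSE_k the squared residuals of outcome k's rows; with a diffuse
    prior the full-conditional mode sits near the residual RMS.
    """
    R = arr.Y - _linpred(state, arr)
    sse = (arr.mask * R * R).sum(axis=0)
    n_k = arr.mask.sum(axis=0)
    prior = spec.sigma_k_prior
    for k in range(arr.K):
        sse_k, nk = float(sse[k]), float(n_k[k])

        def logf(ls: float, sse_k=sse_k, nk=nk) -> float:
            return -nk * ls - 0.5 * sse_k * math.exp(-2.0 * ls) + prior.logpdf_of_log(ls)

        state.sigma[k] = math.exp(slice_sample(math.log(state.sigma[k]), logf, rng, stats=stats))


def update_sigma_r(
    state: ModelState, spec: ModelSpec, rng: np.random.Generator, stats: SliceStats | None = None
) -> None:
    ssa = float((state.alpha**2).sum())
    n = state.alpha.size
    prior = spec.sigma_r_prior

    def logf(ls: float) -> float:
        return -n * ls - 0.5 * ssa * math.exp(-2.0 * ls) + prior.logpdf_of_log(ls)

    state.sigma_r = math.exp(slice_sample(math.log(state.sigma_r), logf, rng, stats=stats))


# ---------------------------------------------------------------------------
# Laplace comparator: scale-mixture-of-normals augmentation
# ---------------------------------------------------------------------------

def update_beta_laplace(state: ModelState, arr: PanelArrays, spec: ModelSpec, rng: np.random.Generator) -> None:
    """Draw beta under a Laplace(0, b) prior via its Gaussian scale mixture.

    beta_k | s_k ~ N(0, s_k) with s_k ~ Exp(rate 1/(2 b^2)) marginalises to
    Laplace(0, b).  Given s_k the beta draw is conjugate normal; given
    beta_k, 1/s_k is inverse-Gaussian with mean 1/(b |beta_k|) and shape
    1/b^2.
    """
    b = spec.laplace_scale
    lam = 1.0 / b
    if state.laplace_latent is None:
        state.laplace_latent = np.full(arr.K, b * b)
    # latent scales given current beta
    absb = np.maximum(np.abs(state.beta), 1e-8)
    inv_s = rng.wald(lam / absb, lam * lam)
    state.laplace_latent = 1.0 / np.maximum(inv_s, 1e-12)

    # conjugate beta given latent scales
    R = arr.Y - state.nu[None, :] - state.alpha[:, None]
    if arr.q:
        R = R - arr.Z @ state.gamma
    e = arr.exposure[:, None]
    s2 = np.maximum(state.sigma**2, VAR_FLOOR)
    A = (arr.mask * e * e).sum(axis=0) / s2
    B = (arr.mask * e * R).sum(axis=0) / s2
    post_var = 1.0 / (A + 1.0 / state.laplace_latent)
    post_mean = post_var * B
    state.beta = post_mean + np.sqrt(post_var) * rng.standard_normal(arr.K)


# ---------------------------------------------------------------------------
# sweep, initialization, driver
# ---------------------------------------------------------------------------

def gibbs_sweep(
    state: ModelState,
    arr: PanelArrays,
    spec: ModelSpec,
    rng: np.random.Generator,
    stats: SliceStats | None = None,
) -> None:
    """One full update sweep over all parameters, in the fixed order."""
    if spec.variant == "laplace":
        update_beta_laplace(state, arr, spec, rng)
    else:
        update_beta(state, arr, spec, rng)
    if spec.has_indicators:
        update_indicators(state, spec, arr.K, rng)
    if spec.has_mu:
        update_mu(state, spec, rng)
    update_nu_gamma(state, arr, spec, rng)
    update_alpha(state, arr, rng)
    if spec.has_tau:
        update_tau(state, spec, rng, stats)
    update_sigma(state, arr, spec, rng, stats)
    update_sigma_r(state, spec, rng, stats)


def initialize_state(arr: PanelArrays, spec: ModelSpec) -> ModelState:
    """Data-informed deterministic starting point.

    Per-outcome least squares of y on (1, exposure, z) seeds nu, beta and
    gamma; sigma_k starts at the residual SD (floored); mu and tau at the
    mean and SD of the initial beta.  Indicators start all-in.
    """
    K, q = arr.K, arr.q
    beta = np.zeros(K)
    nu = np.zeros(K)
    gamma = np.zeros((q, K))
    sigma = np.ones(K)
    for k in range(K):
        m = arr.mask[:, k]
        y = arr.Y[m, k]
        if y.size == 0:
            continue
        X = np.column_stack([np.ones(m.sum()), arr.exposure[m]] + [arr.Z[m, a] for a in range(q)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        if np.all(np.isfinite(coef)):
            nu[k], beta[k] = coef[0], coef[1]
            gamma[:, k] = coef[2:]
        resid = y - X @ coef
        dof = max(y.size - X.shape[1], 1)
        sigma[k] = max(math.sqrt(float(resid @ resid) / dof), 1e-3)
    if spec.variant == "laplace":
        mu = 0.0
    elif spec.variant == "ssvs_null":
        mu = 0.0
    else:
        mu = float(beta.mean()) if K else 0.0
    tau = max(float(beta.std()), 0.1)
    state = ModelState(
        beta=beta,
        indicators=np.ones(K, dtype=np.int8),
        mu=mu,
        tau=tau,
        nu=nu,
        gamma=gamma,
        alpha=np.zeros(arr.n),
        sigma=sigma,
        sigma_r=0.5,
        laplace_latent=np.full(K, spec.laplace_scale**2) if spec.variant == "laplace" else None,
    )
    return state


def _check_finite(state: ModelState, sweep: int) -> None:
    for name in ("beta", "nu", "gamma", "alpha", "sigma"):
        if not np.all(np.isfinite(getattr(state, name))):
            raise FloatingPointError(f"non-finite {name} at sweep {sweep}")
    for name in ("mu", "tau", "sigma_r"):
        if not math.isfinite(getattr(state, name)):
            raise FloatingPointError(f"non-finite {name} at sweep {sweep}")


def run_mcmc(
    panel: OutcomePanel | PanelArrays,
    spec: ModelSpec,
    mcmc: MCMCConfig | None = None,
) -> ChainDraws:
    """Run the Gibbs sampler and return retained post-burn-in draws.

    The subset variant first restricts the panel to ``spec.subset_outcomes``
    and then runs the hierarchical (no-selection) sampler on the reduced
    panel; the returned draws carry the subset's 1-based outcome ids.
    Identical inputs and seed give bit-identical draws.
    """
    mcmc = mcmc or MCMCConfig()
    arr = _as_arrays(panel)
    outcome_ids = np.arange(1, arr.K + 1)
    run_spec = spec
    if spec.variant == "subset":
        outcome_ids = np.asarray(sorted(spec.subset_outcomes), dtype=int)
        arr = arr.restrict(list(outcome_ids))
        from .model import spec_with

        run_spec = spec_with(spec, variant="hierarchical", subset_outcomes=())
    K, n, q = arr.K, arr.n, arr.q
    C, D = mcmc.chains, mcmc.retained
    draws = ChainDraws(
        beta=np.empty((C, D, K)),
        indicators=np.empty((C, D, K), dtype=np.int8),
        mu=np.empty((C, D)),
        tau=np.empty((C, D)),
        nu=np.empty((C, D, K)),
        gamma=np.empty((C, D, q, K)),
        alpha=np.empty((C, D, n)),
        sigma=np.empty((C, D, K)),
        sigma_r=np.empty((C, D)),
        config=mcmc,
        variant=spec.variant,
        outcome_ids=outcome_ids,
    )
    stats = SliceStats()
    seeds = np.random.SeedSequence(mcmc.seed).spawn(C)
    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        state = initialize_state(arr, run_spec)
        d = 0
        for sweep in range(mcmc.burn_in + mcmc.iterations):
            gibbs_sweep(state, arr, run_spec, rng, stats)
            if sweep >= mcmc.burn_in:
                it = sweep - mcmc.burn_in
                if (it + 1) % mcmc.thin == 0 and d < D:
                    _check_finite(state, sweep)
                    draws.beta[c, d] = state.beta
                    draws.indicators[c, d] = state.indicators
                    draws.mu[c, d] = state.mu
                    draws.tau[c, d] = state.tau
                    draws.nu[c, d] = state.nu
                    draws.gamma[c, d] = state.gamma
                    draws.alpha[c, d] = state.alpha
                    draws.sigma[c, d] = state.sigma
                    draws.sigma_r[c, d] = state.sigma_r
                    d += 1
    draws.slice_evals = stats.evals
    return draws


# ---------------------------------------------------------------------------
# forward simulation from the model (prior draws, posterior predictive)
# ---------------------------------------------------------------------------

def draw_prior_state(
    spec: ModelSpec, n: int, K: int, q: int, rng: np.random.Generator
) -> ModelState:
    """Draw a full parameter state from the prior (used for prior-predictive
    checks and joint-distribution validation of the sampler)."""
    tau = math.exp(spec.tau_prior.loc + math.sqrt(spec.tau_prior.var) * rng.standard_normal())
    mu = 0.0
    if spec.has_mu:
        mu = spec.mu_prior.mean + math.sqrt(spec.mu_prior.var) * rng.standard_normal()
    if spec.has_indicators:
        indicators = (rng.random(K) < spec.pi_vector(K)).astype(np.int8)
    else:
        indicators = np.ones(K, dtype=np.int8)
    laplace_latent = None
    if spec.variant == "laplace":
        b = spec.laplace_scale
        laplace_latent = rng.exponential(scale=2.0 * b * b, size=K)
        beta = np.sqrt(laplace_latent) * rng.standard_normal(K)
    else:
        g_spike = spec.spike.variance(tau)
        sel = indicators.astype(bool)
        sd = np.where(sel, tau, math.sqrt(max(g_spike, VAR_FLOOR)))
        mean = np.where(sel, mu, 0.0)
        beta = mean + sd * rng.standard_normal(K)
    sigma = np.exp(
        spec.sigma_k_prior.loc + math.sqrt(spec.sigma_k_prior.var) * rng.standard_normal(K)
    )
    sigma_r = math.exp(
        spec.sigma_r_prior.loc + math.sqrt(spec.sigma_r_prior.var) * rng.standard_normal()
    )
    nu = spec.nu_prior.mean + math.sqrt(spec.nu_prior.var) * rng.standard_normal(K)
    gamma = spec.gamma_prior.mean + math.sqrt(spec.gamma_prior.var) * rng.standard_normal((q, K))
    alpha = sigma_r * rng.standard_normal(n)
    return ModelState(
        beta=beta,
        indicators=indicators,
        mu=mu,
        tau=tau,
        nu=nu,
        gamma=gamma,
        alpha=alpha,
        sigma=sigma,
        sigma_r=sigma_r,
        laplace_latent=laplace_latent,
    )


def sample_outcomes(state: ModelState, arr: PanelArrays, rng: np.random.Generator) -> None:
    """Replace the observed outcome values with a draw from the model given
    ``state`` (the individual intercepts alpha are part of the state, not
    re-drawn).  Mutates ``arr.Y`` on the observed cells only."""
    F = _linpred(state, arr)
    noise = state.sigma[None, :] * rng.standard_normal(arr.Y.shape)
    arr.Y = np.where(arr.mask, F + noise, arr.Y)
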