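"""Joint-distribution ("getting it right") validation harness.

Two ways to sample the joint distribution p(theta, y) must agree when the
transition operator is correct:

* marginal-conditional — draw theta from the prior, iid;
* successive-conditional — alternate one Gibbs sweep theta | y with a fresh
  data draw y | theta.

Comparing first and second moments of monitored scalars between the two
samplers (with an autocorrelation-adjusted standard error for the Markov
chain) detects errors in any full conditional.
"""

import arviz as az
import numpy as np

from outsel.panel import PanelArrays
from outsel.sampler import draw_prior_state, gibbs_sweep, sample_outcomes


def monitor(state, spec, q):
    """Monitored scalar functionals of the state."""
    vals = {"beta.1": state.beta[0], "beta.2": state.beta[-1],
            "nu.1": state.nu[0],
            "log_sigma.1": np.log(state.sigma[0]),
            "log_sigma_r": np.log(state.sigma_r),
            "alpha.1": state.alpha[0]}
    if q:
        vals["gamma.1"] = state.gamma[0, 0]
    if spec.has_mu:
        vals["mu"] = state.mu
    if spec.has_tau:
        vals["log_tau"] = np.log(state.tau)
    if spec.has_indicators:
        vals["I.1"] = float(state.indicators[0])
    return vals


def marginal_conditional(spec, n, K, q, draws, seed):
    rng = np.random.default_rng(seed)
    recs = [monitor(draw_prior_state(spec, n, K, q, rng), spec, q) for _ in range(draws)]
    names = list(recs[0])
    return names, np.array([[r[k] for k in names] for r in recs])


def successive_conditional(spec, template: PanelArrays, sweeps, seed):
    rng = np.random.default_rng(seed)
    arr = PanelArrays(Y=template.Y.copy(), mask=template.mask.copy(),
                      exposure=template.exposure, Z=template.Z,
                      n=template.n, K=template.K, z_cols=template.z_cols)
    state = draw_prior_state(spec, arr.n, arr.K, arr.q, rng)
    sample_outcomes(state, arr, rng)
    recs = []
    for _ in range(sweeps):
        gibbs_sweep(state, arr, spec, rng)
        sample_outcomes(state, arr, rng)
        recs.append(monitor(state, spec, arr.q))
    names = list(recs[0])
    return names, np.array([[r[k] for k in names] for r in recs])


def moment_zscores(mc: np.ndarray, sc: np.ndarray):
    """z-scores comparing first and second moments column-wise.

    The iid sampler uses var/N; the Markov chain's standard error is scaled
    by its effective sample size.
    """
    out = []
    for power in (1, 2):
        a, b = mc**power, sc**power
        for col in range(a.shape[1]):
            va = a[:, col].var(ddof=1) / a.shape[0]
            ess = float(az.ess(b[:, col].reshape(1, -1), method="mean"))
            ess = max(ess, 10.0)
            vb = b[:, col].var(ddof=1) / ess
            denom = np.sqrt(va + vb)
            z = 0.0 if denom == 0 else (a[:, col].mean() - b[:, col].mean()) / denom
            out.append(z)
    return np.array(out)
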