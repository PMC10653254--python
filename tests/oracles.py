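"""Independent numerical oracles used across the test suite.

These deliberately avoid the package's own closed-form code paths: posterior
moments are recovered by brute-force quadrature of likelihood x prior on a
grid, and log likelihoods by naive per-row loops.
"""

import numpy as np
from scipy import stats


def grid_moments(logpost, lo, hi, num=20001):
    """Mean and variance of a univariate density known up to a constant."""
    x = np.linspace(lo, hi, num)
    lp = np.array([logpost(v) for v in x])
    lp -= lp.max()
    w = np.exp(lp)
    w /= np.trapezoid(w, x)
    mean = np.trapezoid(w * x, x)
    var = np.trapezoid(w * (x - mean) ** 2, x)
    return mean, var


def normal_lik_times_normal_prior(yvals, coefs, sigma, prior_mean, prior_var):
    """log p(coef) for y_i ~ N(coef * c_i, sigma^2), coef ~ N(m, v)."""

    def logpost(b):
        ll = stats.norm.logpdf(yvals, loc=b * coefs, scale=sigma).sum()
        return ll + stats.norm.logpdf(b, loc=prior_mean, scale=np.sqrt(prior_var))

    return logpost


def loglik_loop(state, panel):
    """Row-by-row Gaussian log likelihood of an OutcomePanel."""
    total = 0.0
    for _, row in panel.data.iterrows():
        j = int(row["individual_id"]) - 1
        p = int(row["outcome_id"]) - 1
        mean = state.nu[p] + state.alpha[j] + state.beta[p] * row["exposure"]
        for a, col in enumerate(panel.z_cols):
            mean += state.gamma[a, p] * row[col]
        total += stats.norm.logpdf(row["y"], loc=mean, scale=state.sigma[p])
    return total
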