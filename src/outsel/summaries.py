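"""Posterior summaries: inclusion probabilities, selection, effect estimates.

The selection rule is the standard one for indicator-based variable
selection: outcome k is declared sensitive when its posterior inclusion
probability (the posterior mean of I_k, pooled over chains) strictly
exceeds a threshold, 0.5 by default.  The coefficient estimate for a
selected outcome is the conditional posterior mean of beta_k over the draws
with I_k = 1; unselected outcomes are reported as exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ChainDraws


@dataclass
class SelectionSummary:
    pip: np.ndarray            # posterior inclusion probability per outcome
    selected: np.ndarray       # pip > threshold (strict)
    beta_hat: np.ndarray       # conditional posterior mean, 0 if unselected
    beta_sd: np.ndarray        # conditional posterior SD (NaN if unselected)
    mu_hat: float
    mu_sd: float
    tau_hat: float
    threshold: float
    outcome_ids: np.ndarray
    variant: str
    top_subsets: list[tuple[tuple[int, ...], float]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        """Table mirroring the usual report layout: one row per outcome with
        pip, selected flag and beta_hat; trailing rows for mu and tau."""
        rows = [
            {
                "outcome_id": int(self.outcome_ids[k]),
                "pip": self.pip[k],
                "selected": bool(self.selected[k]),
                "beta_hat": self.beta_hat[k],
                "beta_sd": self.beta_sd[k],
            }
            for k in range(len(self.pip))
        ]
        rows.append({"outcome_id": "mu", "pip": np.nan, "selected": "", "beta_hat": self.mu_hat, "beta_sd": self.mu_sd})
        rows.append({"outcome_id": "tau", "pip": np.nan, "selected": "", "beta_hat": self.tau_hat, "beta_sd": np.nan})
        return pd.DataFrame(rows)


def summarize_selection(draws: ChainDraws, threshold: float = 0.5) -> SelectionSummary:
    """Pool all chains and summarise selection and effect estimates.

    For SSVS variants, pip_k is the pooled mean of the I_k draws and
    beta_hat_k the mean of beta_k over exactly the pooled draws with
    I_k = 1 (zero when unselected; ties at the threshold are not selected).
    For the no-selection variants (hierarchical, subset) pip is 1 on every
    modeled outcome and beta_hat is the plain posterior mean.  For the
    Laplace comparator, "selection" is 95% credible-interval exclusion of
    zero and beta_hat is again the plain posterior mean.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    beta = draws.pooled("beta")         # (N, K)
    ind = draws.pooled("indicators")    # (N, K)
    K = beta.shape[1]
    mu_all = draws.pooled("mu")
    tau_all = draws.pooled("tau")
    is_ssvs = draws.variant in ("ssvs_mean", "ssvs_null")

    if is_ssvs:
        pip = ind.mean(axis=0)
        selected = pip > threshold
        beta_hat = np.zeros(K)
        beta_sd = np.full(K, np.nan)
        for k in np.nonzero(selected)[0]:
            inc = ind[:, k] == 1
            if not inc.any():
                raise RuntimeError(f"outcome {k + 1} selected but no draw has I=1")
            beta_hat[k] = beta[inc, k].mean()
            beta_sd[k] = beta[inc, k].std(ddof=1) if inc.sum() > 1 else np.nan
        top = _top_subsets(ind)
    elif draws.variant == "laplace":
        lo, hi = np.quantile(beta, [0.025, 0.975], axis=0)
        pip = np.ones(K)
        selected = (lo > 0) | (hi < 0)
        beta_hat = beta.mean(axis=0)
        beta_sd = beta.std(axis=0, ddof=1)
        top = []
    else:  # hierarchical / subset: every modeled outcome is in
        pip = np.ones(K)
        selected = np.ones(K, dtype=bool)
        beta_hat = beta.mean(axis=0)
        beta_sd = beta.std(axis=0, ddof=1)
        top = []

    return SelectionSummary(
        pip=pip,
        selected=selected,
        beta_hat=beta_hat,
        beta_sd=beta_sd,
        mu_hat=float(mu_all.mean()),
        mu_sd=float(mu_all.std(ddof=1)),
        tau_hat=float(tau_all.mean()),
        threshold=threshold,
        outcome_ids=draws.outcome_ids.copy(),
        variant=draws.variant,
        top_subsets=top,
    )


def _top_subsets(ind: np.ndarray, top: int = 5) -> list[tuple[tuple[int, ...], float]]:
    """Most frequently sampled indicator vectors, as (selected ids, freq)."""
    rows = [tuple(np.nonzero(r)[0] + 1) for r in ind.astype(bool)]
    counts: dict[tuple[int, ...], int] = {}
    for r in rows:
        counts[r] = counts.get(r, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    total = len(rows)
    return [(subset, cnt / total) for subset, cnt in ranked]


def coefficient_mse(beta_hat: np.ndarray, beta_true: np.ndarray) -> float:
    """Mean squared error (1/K) sum_k (beta_hat_k - beta_true_k)^2."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    if beta_hat.shape != beta_true.shape:
        raise ValueError("beta_hat and beta_true must have equal length")
    return float(np.mean((beta_hat - beta_true) ** 2))


def detection_counts(selected: np.ndarray, truth: np.ndarray) -> tuple[int, int, int]:
    """(n_selected, n_correct, n_false_positive) for a selection decision
    against the true sensitivity pattern."""
    selected = np.asarray(selected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if selected.shape != truth.shape:
        raise ValueError("selected and truth must have equal length")
    n_selected = int(selected.sum())
    n_correct = int((selected & truth).sum())
    return n_selected, n_correct, n_selected - n_correct


def convergence_report(draws: ChainDraws, rhat_warn: float = 1.01) -> pd.DataFrame:
    """Rank-normalised split-R-hat and effective sample size per scalar.

    With a single chain R-hat is undefined (NaN) and only ESS is reported.
    The ``flagged`` column marks parameters with R-hat above ``rhat_warn``.
    """
    import arviz as az

    data = {
        "beta": draws.beta,
        "mu": draws.mu[:, :, None],
        "tau": draws.tau[:, :, None],
        "nu": draws.nu,
        "sigma": draws.sigma,
        "sigma_r": draws.sigma_r[:, :, None],
    }
    scalar_params = {"mu", "tau", "sigma_r"}
    rows = []
    multi = draws.n_chains >= 2
    for name, arr in data.items():
        for k in range(arr.shape[2]):
            chains = arr[:, :, k]
            label = name if name in scalar_params else f"{name}.{draws.outcome_ids[k]}"
            if chains.std() == 0:
                rhat, ess = np.nan, np.nan
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    rhat = float(az.rhat(chains)) if multi else np.nan
                    ess = float(az.ess(chains))
            rows.append({"parameter": label, "rhat": rhat, "ess": ess})
    rep = pd.DataFrame(rows)
    rep["flagged"] = rep["rhat"] > rhat_warn
    return rep
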