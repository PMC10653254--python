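"""Simulation-study orchestration: the replicate grid and its report tables.

A *cell* of the study is a (mu_true, K1) setting: ``replicates`` synthetic
panels are generated with seeds base_seed + 1 .. base_seed + replicates,
each model variant is fit to each panel, and the selection / estimation
metrics are averaged across replicates.  Three report tables mirror the
standard presentation:

* detection — average number of outcomes selected, correctly selected and
  falsely selected (SSVS variants only; the others do not select),
* mse — average mean squared error of the coefficient estimates, using the
  thresholded conditional estimator for SSVS variants and the plain
  posterior mean for the no-selection fit,
* mu — average posterior mean of the common effect mu with its standard
  error across replicates.

The subset variant is fit to the *true* sensitive set, serving as the
oracle benchmark; the no-selection hierarchical fit on all outcomes shows
how including null outcomes attenuates mu.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MCMCConfig, ModelSpec, SpikeSpec
from .sampler import run_mcmc
from .simulate import SimScenario, simulate_dataset
from .summaries import coefficient_mse, detection_counts, summarize_selection

DEFAULT_VARIANTS = ("ssvs_mean", "ssvs_null", "hierarchical", "subset")

_VARIANT_OFFSET = {v: i for i, v in enumerate(("ssvs_mean", "ssvs_null", "hierarchical", "subset", "laplace"))}


def make_spec(variant: str, subset_outcomes: tuple[int, ...] = (), c: float = 100.0, pi: float = 0.5) -> ModelSpec:
    """Study-default ModelSpec for a variant: scaled spike with the given c,
    scalar prior inclusion probability pi, and the flat default priors."""
    return ModelSpec(
        variant=variant,
        spike=SpikeSpec(kind="scaled", c=c),
        pi=pi,
        subset_outcomes=tuple(subset_outcomes),
    )


@dataclass
class SimCellResult:
    scenario: SimScenario
    replicates: int
    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    failures: list[dict] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return len(self.failures) > 0


def _fit_one(panel_arrays, truth, variant: str, mcmc: MCMCConfig, threshold: float):
    """Fit one variant to one replicate and extract the metric row."""
    subset = tuple(np.nonzero(truth.relevant)[0] + 1) if variant == "subset" else ()
    if variant == "subset" and not subset:
        return {  # nothing to fit when no outcome is truly sensitive
            "n_selected": np.nan, "n_correct": np.nan, "n_false_positive": np.nan,
            "mse": np.nan, "mu_hat": np.nan,
        }
    spec = make_spec(variant, subset_outcomes=subset)
    draws = run_mcmc(panel_arrays, spec, mcmc)
    summ = summarize_selection(draws, threshold=threshold)
    K = len(truth.beta_true)
    row: dict[str, float] = {}
    if variant in ("ssvs_mean", "ssvs_null", "laplace"):
        n_sel, n_cor, n_fp = detection_counts(summ.selected, truth.relevant)
        row.update(n_selected=n_sel, n_correct=n_cor, n_false_positive=n_fp)
    else:
        row.update(n_selected=np.nan, n_correct=np.nan, n_false_positive=np.nan)
    if variant == "subset":
        # MSE over the modeled (truly sensitive) outcomes only
        row["mse"] = coefficient_mse(summ.beta_hat, truth.beta_true[truth.relevant])
    else:
        row["mse"] = coefficient_mse(summ.beta_hat, truth.beta_true)
    row["mu_hat"] = summ.mu_hat if spec.has_mu else np.nan
    row["mu_sd"] = summ.mu_sd if spec.has_mu else np.nan
    row["tau_hat"] = summ.tau_hat if spec.has_tau else np.nan
    return row


def run_cell(
    scenario: SimScenario,
    variants: tuple[str, ...] = DEFAULT_VARIANTS,
    replicates: int = 10,
    mcmc: MCMCConfig | None = None,
    threshold: float = 0.5,
    outdir: str | Path | None = None,
) -> SimCellResult:
    """Run one (mu_true, K1) cell of the study.

    Replicate r uses data seed ``scenario.seed + r`` (r = 1..replicates) and
    a per-fit sampler seed derived from the data seed and the variant, so
    any single replicate can be rerun in isolation.  Per-replicate rows are
    recorded before averaging; a failing fit marks the cell failed but the
    remaining fits still run.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    mcmc = mcmc or MCMCConfig()
    rows = []
    failures: list[dict] = []
    for r in range(1, replicates + 1):
        data_seed = scenario.seed + r
        rep_scenario = SimScenario(
            n=scenario.n, K=scenario.K, K1=scenario.K1, mu_true=scenario.mu_true,
            seed=data_seed, sigma_r_true=scenario.sigma_r_true, gamma_sd=scenario.gamma_sd,
        )
        panel, truth = simulate_dataset(rep_scenario)
        arr = panel.to_arrays()
        for variant in variants:
            fit_seed = (mcmc.seed + 101 * data_seed + _VARIANT_OFFSET[variant]) % (2**31)
            fit_mcmc = MCMCConfig(
                chains=mcmc.chains, burn_in=mcmc.burn_in, iterations=mcmc.iterations,
                thin=mcmc.thin, seed=fit_seed,
            )
            try:
                row = _fit_one(arr, truth, variant, fit_mcmc, threshold)
            except (FloatingPointError, ValueError) as exc:
                failures.append({"replicate": r, "variant": variant, "error": str(exc)})
                continue
            rows.append({"replicate": r, "data_seed": data_seed, "variant": variant, **row})
    per_rep = pd.DataFrame(rows)
    summary = _summarize_cell(per_rep, scenario, replicates)
    result = SimCellResult(
        scenario=scenario, replicates=replicates, per_replicate=per_rep,
        summary=summary, failures=failures,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = f"mu{scenario.mu_true}_K1{scenario.K1}"
        per_rep.to_csv(outdir / f"cell_{tag}_replicates.csv", index=False)
        summary.to_csv(outdir / f"cell_{tag}_summary.csv", index=False)
    return result


def _summarize_cell(per_rep: pd.DataFrame, scenario: SimScenario, replicates: int) -> pd.DataFrame:
    if per_rep.empty:
        return pd.DataFrame()
    metrics = ["n_selected", "n_correct", "n_false_positive", "mse", "mu_hat"]
    out = []
    for variant, grp in per_rep.groupby("variant", sort=False):
        row = {"mu_true": scenario.mu_true, "K1": scenario.K1, "variant": variant,
               "replicates": len(grp)}
        for m in metrics:
            vals = grp[m].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            row[m] = vals.mean() if vals.size else np.nan
            # SE across replicates is undefined for a single replicate
            row[f"{m}_se"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            )
        out.append(row)
    return pd.DataFrame(out)


def run_grid(
    mu_values: tuple[float, ...] = (-0.1, -3.0),
    K1_values: tuple[int, ...] = (5, 10, 15),
    variants: tuple[str, ...] = DEFAULT_VARIANTS,
    replicates: int = 10,
    mcmc: MCMCConfig | None = None,
    n: int = 100,
    K: int = 20,
    base_seed: int = 0,
    sigma_r_true: float = 1.0,
    gamma_sd: float = 1.0,
    threshold: float = 0.5,
    outdir: str | Path | None = None,
) -> tuple[list[SimCellResult], dict[str, pd.DataFrame]]:
    """Run the full Cartesian grid and assemble the three report tables.

    Cell failures are recorded on the cell result and do not halt the grid.
    With an ``outdir``, per-replicate artifacts, the three tables and a JSON
    manifest (every per-replicate seed included) are written there.
    """
    results = []
    for mu in mu_values:
        for K1 in K1_values:
            scenario = SimScenario(
                n=n, K=K, K1=K1, mu_true=mu, seed=base_seed,
                sigma_r_true=sigma_r_true, gamma_sd=gamma_sd,
            )
            results.append(
                run_cell(scenario, variants, replicates, mcmc, threshold, outdir=outdir)
            )
    tables = assemble_tables(results)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(outdir / f"{name}.csv", index=False)
        manifest = {
            "mu_values": list(mu_values),
            "K1_values": list(K1_values),
            "variants": list(variants),
            "replicates": replicates,
            "n": n,
            "K": K,
            "base_seed": base_seed,
            "sigma_r_true": sigma_r_true,
            "gamma_sd": gamma_sd,
            "threshold": threshold,
            "mcmc": vars(mcmc) if mcmc else vars(MCMCConfig()),
            "data_seeds": [base_seed + r for r in range(1, replicates + 1)],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results, tables


def assemble_tables(results: list[SimCellResult]) -> dict[str, pd.DataFrame]:
    """Pivot cell summaries into detection / MSE / mu-estimate tables."""
    summ = pd.concat([r.summary for r in results if not r.summary.empty], ignore_index=True)
    det_variants = [v for v in summ["variant"].unique() if v in ("ssvs_mean", "ssvs_null", "laplace")]
    detection = summ[summ["variant"].isin(det_variants)][
        ["mu_true", "K1", "variant", "n_selected", "n_correct", "n_false_positive"]
    ].reset_index(drop=True)
    mse_variants = [v for v in summ["variant"].unique() if v != "subset"]
    mse = summ[summ["variant"].isin(mse_variants)][
        ["mu_true", "K1", "variant", "mse", "mse_se"]
    ].reset_index(drop=True)
    mu_variants = [v for v in summ["variant"].unique() if v in ("ssvs_mean", "hierarchical", "subset")]
    mu_tab = summ[summ["variant"].isin(mu_variants)][
        ["mu_true", "K1", "variant", "mu_hat", "mu_hat_se"]
    ].reset_index(drop=True)
    return {"table_detection": detection, "table_mse": mse, "table_mu": mu_tab}
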