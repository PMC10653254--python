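"""Stacked (long-format) representation of multiple-outcome data.

A study measuring K outcomes on n individuals is stored as one row per
(individual, outcome) pair: ``individual_id`` j in 1..n, ``outcome_id`` p in
1..K, the outcome value ``y``, the individual's ``exposure`` and any
per-individual covariates ``z_*``.  Stacking turns a multivariate-outcome
problem into a univariate mixed-model problem: the exposure effect on outcome
k acts through the implicit interaction covariate

    x_k[i] = exposure_{j[i]} * 1(p[i] = k),

which is never materialised as a dense matrix — each row activates exactly
one x_k, so the beta-term of the model reduces to
``beta_{p[i]} * exposure_{j[i]}`` per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LONG_COLUMNS = ["individual_id", "outcome_id", "y", "exposure"]


@dataclass
class OutcomePanel:
    """Long-format panel of multiple-outcome observations.

    Parameters
    ----------
    data
        DataFrame with columns ``individual_id`` (integers 1..n),
        ``outcome_id`` (integers 1..K), ``y``, ``exposure`` and zero or more
        ``z_*`` covariate columns.  At most one row per (individual, outcome);
        exposure and covariates must be constant within an individual.
    n, K
        Number of distinct individuals / outcomes the panel is defined over.
        Defaults to the maxima of the id columns; may exceed them when some
        individuals or outcomes are entirely unobserved.
    outcome_names
        Optional labels for outcomes 1..K, preserved through stacking so that
        reports keep a stable, user-declared ordering.
    """

    data: pd.DataFrame
    n: int = 0
    K: int = 0
    outcome_names: list[str] | None = None

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel missing required columns: {missing}")
        df = df.copy()
        df["individual_id"] = df["individual_id"].astype(int)
        df["outcome_id"] = df["outcome_id"].astype(int)
        if len(df) and (df["individual_id"].min() < 1 or df["outcome_id"].min() < 1):
            raise ValueError("individual_id and outcome_id must be 1-based positive integers")
        if df.duplicated(["individual_id", "outcome_id"]).any():
            raise ValueError("duplicate (individual_id, outcome_id) rows")
        self.n = int(self.n) or (int(df["individual_id"].max()) if len(df) else 0)
        self.K = int(self.K) or (int(df["outcome_id"].max()) if len(df) else 0)
        if len(df):
            if df["individual_id"].max() > self.n:
                raise ValueError("individual_id exceeds declared n")
            if df["outcome_id"].max() > self.K:
                raise ValueError("outcome_id exceeds declared K")
        # exposure and z must not vary within an individual
        for col in ["exposure", *self.z_columns(df)]:
            per = df.groupby("individual_id")[col].nunique(dropna=False)
            if (per > 1).any():
                bad = per[per > 1].index.tolist()
                raise ValueError(f"column {col!r} varies within individuals {bad}")
        self.data = df.sort_values(["individual_id", "outcome_id"], ignore_index=True)
        if self.outcome_names is not None and len(self.outcome_names) != self.K:
            raise ValueError("outcome_names length must equal K")

    @staticmethod
    def z_columns(df: pd.DataFrame) -> list[str]:
        return [c for c in df.columns if c.startswith("z")]

    @property
    def z_cols(self) -> list[str]:
        return self.z_columns(self.data)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def interaction_row(self, i: int) -> tuple[int, float]:
        """Sparse row i of the implicit interaction design: the single active
        outcome index p[i] and the exposure value (all other x_k are zero)."""
        row = self.data.iloc[i]
        return int(row["outcome_id"]), float(row["exposure"])

    def to_arrays(self) -> "PanelArrays":
        return PanelArrays.from_panel(self)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "OutcomePanel":
        df = pd.read_csv(path)
        rename = {"outcome": "outcome_id"}
        df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
        return cls(df, **kwargs)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class PanelArrays:
    """Dense (n, K) view of a panel used by the samplers.

    ``mask[j, k]`` flags whether individual j+1 has outcome k+1 observed;
    ``Y`` holds the outcome values (zero where unobserved), ``exposure`` is
    length n and ``Z`` is (n, q).  The sparse interaction structure means the
    linear predictor is assembled with O(nK) work and no K-wide design matrix.
    """

    Y: np.ndarray
    mask: np.ndarray
    exposure: np.ndarray
    Z: np.ndarray
    n: int
    K: int
    z_cols: list[str] = field(default_factory=list)

    @classmethod
    def from_panel(cls, panel: OutcomePanel) -> "PanelArrays":
        n, K = panel.n, panel.K
        df = panel.data
        j = df["individual_id"].to_numpy() - 1
        p = df["outcome_id"].to_numpy() - 1
        Y = np.zeros((n, K))
        mask = np.zeros((n, K), dtype=bool)
        Y[j, p] = df["y"].to_numpy(dtype=float)
        mask[j, p] = True
        exposure = np.zeros(n)
        z_cols = panel.z_cols
        Z = np.zeros((n, len(z_cols)))
        exposure[j] = df["exposure"].to_numpy(dtype=float)
        for a, col in enumerate(z_cols):
            Z[j, a] = df[col].to_numpy(dtype=float)
        return cls(Y=Y, mask=mask, exposure=exposure, Z=Z, n=n, K=K, z_cols=z_cols)

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def restrict(self, outcome_ids: list[int]) -> "PanelArrays":
        """Keep only the given 1-based outcome ids (order preserved)."""
        idx = np.asarray(outcome_ids, dtype=int) - 1
        if len(idx) == 0:
            raise ValueError("outcome subset must be non-empty")
        if idx.min() < 0 or idx.max() >= self.K:
            raise ValueError("outcome subset out of range")
        return PanelArrays(
            Y=self.Y[:, idx].copy(),
            mask=self.mask[:, idx].copy(),
            exposure=self.exposure,
            Z=self.Z,
            n=self.n,
            K=len(idx),
            z_cols=self.z_cols,
        )


def stack_outcomes(
    wide: pd.DataFrame,
    outcome_cols: list[str],
    exposure_col: str = "exposure",
    z_cols: list[str] | None = None,
    id_col: str | None = None,
) -> OutcomePanel:
    """Stack a wide table (one row per individual) into an OutcomePanel.

    ``outcome_cols`` is an ordered list: outcome k is assigned by position, so
    the caller controls the 1..K labelling.  The exposure and covariates are
    replicated across each individual's K rows; missing outcome cells simply
    contribute no row.
    """
    if len(outcome_cols) == 0:
        raise ValueError("at least one outcome column required")
    for c in [*outcome_cols, exposure_col]:
        if c not in wide.columns:
            raise ValueError(f"column {c!r} not in wide table")
    z_cols = list(z_cols) if z_cols is not None else []
    if id_col is not None:
        ids = wide[id_col].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate individual ids in wide table")
    n = len(wide)
    K = len(outcome_cols)
    frames = []
    for k, col in enumerate(outcome_cols, start=1):
        block = pd.DataFrame(
            {
                "individual_id": np.arange(1, n + 1),
                "outcome_id": k,
                "y": wide[col].to_numpy(dtype=float),
                "exposure": wide[exposure_col].to_numpy(dtype=float),
            }
        )
        for a, zc in enumerate(z_cols, start=1):
            block[f"z{a}"] = wide[zc].to_numpy(dtype=float)
        frames.append(block)
    long = pd.concat(frames, ignore_index=True)
    long = long[long["y"].notna()].reset_index(drop=True)
    return OutcomePanel(long, n=n, K=K, outcome_names=list(outcome_cols))


def unstack_outcomes(panel: OutcomePanel) -> pd.DataFrame:
    """Inverse of :func:`stack_outcomes`: one row per individual, one column
    per outcome.  Missing (individual, outcome) combinations become NaN."""
    df = panel.data
    names = panel.outcome_names or [f"y{k}" for k in range(1, panel.K + 1)]
    wide = df.pivot(index="individual_id", columns="outcome_id", values="y")
    wide = wide.reindex(index=np.arange(1, panel.n + 1), columns=np.arange(1, panel.K + 1))
    wide.columns = names
    wide.index.name = "individual_id"
    # exposure and z: take per-individual first value
    extras = df.groupby("individual_id")[["exposure", *panel.z_cols]].first()
    out = wide.join(extras).reset_index()
    return out


def standardize_outcomes(panel: OutcomePanel) -> tuple[OutcomePanel, pd.DataFrame]:
    """Rescale every outcome to sample mean 0 and sample variance 1.

    Returns the rescaled panel together with a per-outcome table of the
    (mean, sd) constants used, for back-transforming coefficient estimates.
    Standardisation is an explicit opt-in step — simulation-style analyses on
    a common scale do not need it, observational batteries mixing test scales
    typically do.
    """
    df = panel.data.copy()
    stats = []
    for k, grp in df.groupby("outcome_id"):
        vals = grp["y"].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"outcome {k}: need >= 2 observations to standardize")
        m, s = vals.mean(), vals.std(ddof=1)
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"outcome {k} is constant; cannot standardize")
        df.loc[grp.index, "y"] = (vals - m) / s
        stats.append({"outcome_id": k, "mean": m, "sd": s})
    out = OutcomePanel(df, n=panel.n, K=panel.K, outcome_names=panel.outcome_names)
    return out, pd.DataFrame(stats)
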