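"""Multiple imputation by chained equations (MICE) and Rubin pooling.

Continuous variables are imputed by predictive mean matching (PMM, five
donors) by default, which respects the skew and non-negativity of cost
data; a Bayesian normal-regression draw ('norm') and a logistic model for
binaries are also available.  Each of the m completed datasets runs from
an independent sub-seed, so between-imputation variability is genuine and
the whole set is reproducible from one master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def choose_m(fraction_incomplete: float) -> int:
    """Number of imputed datasets: the percentage of incomplete cases.

    Follows the rule of thumb that m should match the percentage of
    incomplete information (30% incomplete -> m = 30), rounding half-up
    and never dropping below 2 so that between-imputation variance is
    always estimable.
    """
    if not (0.0 <= fraction_incomplete < 1.0):
        raise ValueError("fraction_incomplete must lie in [0, 1)")
    return max(2, int(math.floor(100.0 * fraction_incomplete + 0.5)))


@dataclass(frozen=True)
class ImputationSpec:
    """Configuration for one MICE run.

    ``variables`` maps incomplete column names to a model type ('pmm',
    'norm' or 'logistic'); columns left out are auto-assigned ('logistic'
    for 0/1 columns, else 'pmm').  ``predictors`` restricts the predictor
    set; by default every other analysis column is used.
    """

    m: int
    seed: int = 0
    n_cycles: int = 10
    variables: Mapping[str, str] = field(default_factory=dict)
    predictors: Sequence[str] | None = None
    pmm_donors: int = 5

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        for var, model in self.variables.items():
            if model not in ("pmm", "norm", "logistic"):
                raise ValueError(f"unknown imputation model {model!r} for {var!r}")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be at least 1")


@dataclass
class ImputationSet:
    """m completed copies of the analysis table plus provenance."""

    datasets: list[pd.DataFrame]
    spec: ImputationSpec
    sub_seeds: list[int]

    @property
    def m(self) -> int:
        return len(self.datasets)


def _design_matrix(table: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = table[cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(table)), X])


def _draw_posterior_beta(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Approximate Bayesian draw of regression coefficients and sigma."""
    n, k = X.shape
    # ridge jitter keeps near-collinear chained models estimable
    xtx = X.T @ X + 1e-8 * np.eye(k)
    xty = X.T @ y
    beta_hat = np.linalg.solve(xtx, xty)
    resid = y - X @ beta_hat
    dof = max(n - k, 1)
    rss = float(resid @ resid)
    sigma2_star = rss / max(rng.chisquare(dof), 1e-12)
    cov = np.linalg.inv(xtx)
    chol = np.linalg.cholesky((cov + cov.T) / 2.0 + 1e-12 * np.eye(k))
    beta_star = beta_hat + math.sqrt(sigma2_star) * (chol @ rng.standard_normal(k))
    return beta_hat, beta_star, math.sqrt(sigma2_star)


def _impute_one_variable(
    work: pd.DataFrame,
    var: str,
    model: str,
    predictors: list[str],
    miss_mask: np.ndarray,
    donors: int,
    rng: np.random.Generator,
) -> None:
    obs = ~miss_mask
    X = _design_matrix(work, predictors)
    y = work[var].to_numpy(dtype=float)
    X_obs, y_obs = X[obs], y[obs]
    X_mis = X[miss_mask]
    if model == "logistic":
        # simple Bayesian-ish logistic via IRLS point fit + normal draw
        from statsmodels.api import GLM, families

        fit = GLM(y_obs, X_obs, family=families.Binomial()).fit()
        beta_star = rng.multivariate_normal(fit.params, fit.cov_params())
        p = 1.0 / (1.0 + np.exp(-(X_mis @ beta_star)))
        work.loc[miss_mask, var] = (rng.random(len(p)) < p).astype(float)
        return
    beta_hat, beta_star, sigma_star = _draw_posterior_beta(X_obs, y_obs, rng)
    pred_mis = X_mis @ beta_star
    if model == "norm":
        work.loc[miss_mask, var] = pred_mis + sigma_star * rng.standard_normal(
            len(pred_mis)
        )
        return
    # PMM type-1: observed units predicted with beta_hat, missing with the
    # posterior draw; each missing value copies a random one of the k
    # nearest observed donors.
    pred_obs = X_obs @ beta_hat
    k = min(donors, len(pred_obs))
    dist = np.abs(pred_mis[:, None] - pred_obs[None, :])
    nearest = np.argpartition(dist, kth=k - 1, axis=1)[:, :k]
    pick = nearest[np.arange(len(pred_mis)), rng.integers(0, k, size=len(pred_mis))]
    work.loc[miss_mask, var] = y_obs[pick]


def mice_impute(table: pd.DataFrame, spec: ImputationSpec) -> ImputationSet:
    """Run chained-equation imputation, returning m completed datasets.

    Observed cells are never altered.  A variable that is entirely missing
    is inestimable and raises.  With no missing cells the result is m
    identical copies, keeping the downstream interface uniform.
    """
    incomplete = [c for c in table.columns if table[c].isna().any()]
    fully_missing = [c for c in incomplete if table[c].isna().all()]
    if fully_missing:
        raise ValueError(
            f"variables with no observed values cannot be imputed: {fully_missing}"
        )
    unknown = set(spec.variables) - set(table.columns)
    if unknown:
        raise ValueError(f"imputation models declared for absent columns: {sorted(unknown)}")

    models: dict[str, str] = {}
    for var in incomplete:
        declared = spec.variables.get(var)
        if declared is not None:
            models[var] = declared
        else:
            vals = table[var].dropna().unique()
            models[var] = "logistic" if set(np.unique(vals)) <= {0.0, 1.0} else "pmm"

    # visit order: least missing first, so early conditionals are best supported
    order = sorted(incomplete, key=lambda c: table[c].isna().sum())
    seed_seq = np.random.SeedSequence(spec.seed)
    children = seed_seq.spawn(spec.m)
    sub_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    complete_cols = [
        c
        for c in table.columns
        if c not in incomplete and np.issubdtype(table[c].dtype, np.number)
    ]
    if spec.predictors is not None:
        complete_cols = [c for c in complete_cols if c in spec.predictors]

    datasets: list[pd.DataFrame] = []
    for child in children:
        rng = np.random.default_rng(child)
        work = table.copy()
        masks = {v: table[v].isna().to_numpy() for v in incomplete}
        # initial fill: random draws from each variable's observed values
        for var in incomplete:
            obs_vals = table[var].dropna().to_numpy(dtype=float)
            work.loc[masks[var], var] = rng.choice(
                obs_vals, size=int(masks[var].sum()), replace=True
            )
        for _ in range(spec.n_cycles if incomplete else 0):
            for var in order:
                predictors = complete_cols + [v for v in incomplete if v != var]
                if spec.predictors is not None:
                    predictors = [
                        p
                        for p in predictors
                        if p in spec.predictors or p in incomplete
                    ]
                _impute_one_variable(
                    work,
                    var,
                    models[var],
                    predictors,
                    masks[var],
                    spec.pmm_donors,
                    rng,
                )
        datasets.append(work)
    return ImputationSet(datasets=datasets, spec=spec, sub_seeds=sub_seeds)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of per-dataset estimates."""

    estimate: float
    variance: float
    within: float
    between: float
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def rubin_pool(
    estimates: Sequence[float], variances: Sequence[float] | None = None
) -> PooledEstimate:
    """Pool m point estimates (and optional within variances).

    Pooled mean is the average; total variance is the within-imputation
    average plus ``(1 + 1/m)`` times the between-imputation variance.
    """
    est = np.asarray(estimates, dtype=float)
    m = len(est)
    if m < 2:
        raise ValueError("Rubin pooling needs at least two imputed datasets")
    if variances is None:
        var = np.zeros(m)
    else:
        var = np.asarray(variances, dtype=float)
        if len(var) != m:
            raise ValueError("estimates and variances must have equal length")
    qbar = float(est.mean())
    within = float(var.mean())
    between = float(est.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    return PooledEstimate(
        estimate=qbar, variance=total, within=within, between=between, m=m
    )
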