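"""Incremental cost-effectiveness estimation.

Adjusted mean differences in costs and effects come from least-squares
regressions of each outcome on treatment arm plus pre-specified baseline
covariates.  Uncertainty is propagated by non-parametric bootstrap nested
within multiple imputation: B resamples (stratified by arm, arm sizes
fixed) of each of the m completed datasets, refitting both regressions in
every resample, pooled into one cloud of m x B incremental (cost, effect)
pairs.  The cloud yields percentile confidence intervals, the
cost-effectiveness plane quadrant shares, and the cost-effectiveness
acceptability curve: for each willingness-to-pay lambda, the fraction of
replicates with positive net monetary benefit lambda*dE - dC.  Point
estimates and variances are pooled across imputations by Rubin's rules.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .eq5d import qaly_from_waves
from .impute import (
    ImputationSet,
    ImputationSpec,
    PooledEstimate,
    choose_m,
    mice_impute,
    rubin_pool,
)

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "female", "hrsd_0", "u_0", "cost_base")
DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.arange(0.0, 50_001.0, 500.0))


@dataclass(frozen=True)
class AdjustmentSpec:
    """Covariate-adjusted mean-difference regression for one outcome.

    The treatment-arm indicator is always included; covariates are
    baseline-only fields (pre-specified clinical predictors plus the
    baseline value of the outcome's counterpart: costs, utility or
    depression score).
    """

    outcome: str
    covariates: tuple[str, ...] = DEFAULT_COVARIATES


def _design(dataset: pd.DataFrame, spec: AdjustmentSpec) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in (spec.outcome, *spec.covariates) if c not in dataset.columns]
    if missing:
        raise KeyError(f"analysis table lacks columns {missing}")
    for c in spec.covariates:
        vals = dataset[c].to_numpy(dtype=float)
        if np.nanstd(vals) == 0.0:
            raise ValueError(f"covariate {c!r} is constant and cannot be adjusted for")
    X = np.column_stack(
        [
            np.ones(len(dataset)),
            dataset["arm"].to_numpy(dtype=float),
            *(dataset[c].to_numpy(dtype=float) for c in spec.covariates),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"collinear design for outcome {spec.outcome!r} with covariates {list(spec.covariates)}"
        )
    y = dataset[spec.outcome].to_numpy(dtype=float)
    return X, y


def adjusted_difference(dataset: pd.DataFrame, spec: AdjustmentSpec):
    """Adjusted between-arm mean difference on one complete dataset.

    Returns ``(arm_coefficient, fitted_model)`` from an OLS fit of the
    outcome on arm plus covariates; the arm coefficient is the adjusted
    incremental mean.
    """
    X, y = _design(dataset, spec)
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), fit


@dataclass
class BootstrapCloud:
    """Pooled bootstrap draws of (incremental cost, incremental effect)."""

    delta_cost: np.ndarray
    delta_effect: np.ndarray
    B_per_dataset: int
    m: int

    def __post_init__(self) -> None:
        if len(self.delta_cost) != len(self.delta_effect):
            raise ValueError("cost and effect replicate arrays differ in length")
        if len(self.delta_cost) != self.B_per_dataset * self.m:
            raise ValueError("cloud size must equal B_per_dataset * m")
        if not (np.isfinite(self.delta_cost).all() and np.isfinite(self.delta_effect).all()):
            raise ValueError("bootstrap cloud contains non-finite replicates")

    def __len__(self) -> int:
        return len(self.delta_cost)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "imputation_id": np.repeat(np.arange(self.m), self.B_per_dataset),
                "replicate_id": np.tile(np.arange(self.B_per_dataset), self.m),
                "delta_cost": self.delta_cost,
                "delta_effect": self.delta_effect,
            }
        )


def _batched_arm_coefs(
    X: np.ndarray, Y: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Arm coefficients for each resample and each outcome column of Y."""
    Xb = X[idx]  # (B, n, k)
    Yb = Y[idx]  # (B, n, q)
    G = np.einsum("bnk,bnl->bkl", Xb, Xb)
    R = np.einsum("bnk,bnq->bkq", Xb, Yb)
    beta = np.linalg.solve(G, R)
    return beta[:, 1, :]  # (B, q)


def _stratified_indices(
    arm: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Resample participants with replacement within arm, arm sizes fixed."""
    idx = np.empty((B, len(arm)), dtype=np.intp)
    for value in np.unique(arm):
        pos = np.nonzero(arm == value)[0]
        idx[:, pos] = rng.choice(pos, size=(B, len(pos)), replace=True)
    return idx


def bootstrap_cloud(
    imputations: ImputationSet | Sequence[pd.DataFrame],
    cost_spec: AdjustmentSpec,
    effect_spec: AdjustmentSpec,
    B: int = 1000,
    seed: int = 0,
    resample: bool = True,
    max_redraws: int = 100,
) -> BootstrapCloud:
    """Nested bootstrap: B stratified resamples of each imputed dataset.

    Both adjustment regressions are refit within every resample so that
    covariate-adjustment uncertainty propagates into the cloud.  Setting
    ``resample=False`` replaces every draw by the identity resample (a
    test hook: the cloud then collapses onto the per-dataset point
    estimates).  Singular resampled designs are redrawn, up to
    ``max_redraws`` per dataset.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    datasets = imputations.datasets if isinstance(imputations, ImputationSet) else list(imputations)
    m = len(datasets)
    dc_parts, de_parts = [], []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(m)
    for d, (dataset, child) in enumerate(zip(datasets, children)):
        rng = np.random.default_rng(child)
        Xc, yc = _design(dataset, cost_spec)
        Xe, ye = _design(dataset, effect_spec)
        arm = dataset["arm"].to_numpy(dtype=int)
        n = len(arm)
        if resample:
            idx = _stratified_indices(arm, B, rng)
        else:
            idx = np.tile(np.arange(n), (B, 1))
        # chunk so the expanded designs stay modest in memory
        chunk = max(1, int(3e7 // max(n * Xc.shape[1], 1)))
        dc = np.empty(B)
        de = np.empty(B)
        for start in range(0, B, chunk):
            block = idx[start : start + chunk]
            redraws = 0
            while True:
                try:
                    dc_block = _batched_arm_coefs(Xc, yc[:, None], block)[:, 0]
                    de_block = _batched_arm_coefs(Xe, ye[:, None], block)[:, 0]
                    if not (
                        np.isfinite(dc_block).all() and np.isfinite(de_block).all()
                    ):
                        raise np.linalg.LinAlgError("non-finite fit")
                    break
                except np.linalg.LinAlgError:
                    redraws += 1
                    if not resample or redraws > max_redraws:
                        raise
                    logger.warning(
                        "singular bootstrap resample in dataset %d; redrawing (%d)",
                        d,
                        redraws,
                    )
                    block = _stratified_indices(arm, len(block), rng)
            dc[start : start + len(dc_block)] = dc_block
            de[start : start + len(de_block)] = de_block
        dc_parts.append(dc)
        de_parts.append(de)
    return BootstrapCloud(
        delta_cost=np.concatenate(dc_parts),
        delta_effect=np.concatenate(de_parts),
        B_per_dataset=B,
        m=m,
    )


def icer(delta_cost: float, delta_effect: float) -> float:
    """Incremental cost-effectiveness ratio, cost difference per unit effect."""
    if delta_effect == 0.0:
        raise ValueError("ICER undefined when the effect difference is zero")
    return delta_cost / delta_effect


def quadrant_label(delta_cost: float, delta_effect: float) -> str:
    """Cost-effectiveness-plane interpretation of a (dC, dE) point."""
    if delta_effect == 0.0:
        return "undefined"
    if delta_effect > 0 and delta_cost > 0:
        return "north-east (more effective, more costly)"
    if delta_effect > 0:
        return "dominant (south-east: more effective, less costly)"
    if delta_cost > 0:
        return "dominated (north-west: less effective, more costly)"
    return "south-west (less effective, less costly)"


def ceac(
    cloud: BootstrapCloud, lambdas: Sequence[float]
) -> dict[float, float]:
    """Probability of positive net monetary benefit at each threshold."""
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("lambda grid must be non-empty")
    if len(cloud) == 0:
        raise ValueError("bootstrap cloud is empty")
    out = {}
    for lam in lambdas:
        nmb = lam * cloud.delta_effect - cloud.delta_cost
        out[float(lam)] = float(np.mean(nmb > 0))
    return out


def quadrant_shares(cloud: BootstrapCloud) -> dict[str, float]:
    """Cloud proportions per CE-plane quadrant.

    Exact zeros follow the half-open convention (> 0 versus <= 0), so the
    four shares always sum to one.
    """
    if len(cloud) == 0:
        raise ValueError("bootstrap cloud is empty")
    de, dc = cloud.delta_effect, cloud.delta_cost
    n = len(cloud)
    return {
        "NE": float(np.sum((de > 0) & (dc > 0)) / n),
        "NW": float(np.sum((de <= 0) & (dc > 0)) / n),
        "SE": float(np.sum((de > 0) & (dc <= 0)) / n),
        "SW": float(np.sum((de <= 0) & (dc <= 0)) / n),
    }


@dataclass
class CEAResult:
    """One analysis run: pooled estimates, cloud and derived summaries."""

    scenario: str
    horizon_months: float
    effect_label: str
    delta_cost: PooledEstimate
    delta_effect: PooledEstimate
    icer: float | None
    icer_quadrant: str
    cloud: BootstrapCloud
    ceac: dict[float, float]
    quadrant_shares: dict[str, float]
    ci_cost: tuple[float, float]
    ci_effect: tuple[float, float]
    n_participants: int
    m: int
    B: int

    def summary(self) -> dict:
        return {
            "scenario": self.scenario,
            "horizon_months": self.horizon_months,
            "effect": self.effect_label,
            "n": self.n_participants,
            "m": self.m,
            "B": self.B,
            "replicates": len(self.cloud),
            "delta_cost": self.delta_cost.estimate,
            "delta_cost_se": self.delta_cost.se,
            "delta_cost_ci": list(self.ci_cost),
            "delta_effect": self.delta_effect.estimate,
            "delta_effect_se": self.delta_effect.se,
            "delta_effect_ci": list(self.ci_effect),
            "icer": self.icer,
            "icer_quadrant": self.icer_quadrant,
            "quadrant_shares": self.quadrant_shares,
        }


@dataclass(frozen=True)
class AnalysisConfig:
    """End-to-end settings for one cost-effectiveness run."""

    horizon_months: float = 12.0
    effect: str = "qaly"  # or "hrsd" (improvement in depression score)
    impute: bool = True
    m: int | None = None  # None: match the percentage of incomplete cases
    n_cycles: int = 10
    B: int = 1000
    lambdas: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    seed: int = 0
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    include_absenteeism: bool = False
    group_cost_substitute: float | None = None
    waves: tuple[float, ...] = (0.0, 7.0, 12.0, 18.0)

    def __post_init__(self) -> None:
        if self.effect not in ("qaly", "hrsd"):
            raise ValueError("effect must be 'qaly' or 'hrsd'")
        if self.horizon_months not in self.waves:
            raise ValueError("horizon must coincide with an assessment wave")


_IMPUTABLE = (
    "cost_other_1",
    "cost_other_2",
    "cost_other_3",
    "u_1",
    "u_2",
    "u_3",
    "hrsd_1",
    "hrsd_2",
    "hrsd_3",
    "absenteeism_1",
    "absenteeism_2",
    "absenteeism_3",
    "presenteeism_1",
    "presenteeism_2",
    "presenteeism_3",
)
_MI_PREDICTORS = (
    "arm",
    "age",
    "female",
    "employed",
    "hrsd_0",
    "u_0",
    "cost_base",
    "cost_intervention",
)


def _needed_columns(table: pd.DataFrame, config: AnalysisConfig) -> list[str]:
    k_max = list(config.waves).index(config.horizon_months)  # wave index of horizon
    cols = [f"cost_other_{k}" for k in range(1, k_max + 1)]
    cols += [f"u_{w}" for w in range(1, k_max + 1)]
    if config.effect == "hrsd":
        cols += [f"hrsd_{k_max}"]
    if config.include_absenteeism:
        cols += [f"absenteeism_{k}" for k in range(1, k_max + 1)]
    return [c for c in cols if c in table.columns]


def _derive_outcomes(
    dataset: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    k_max = list(config.waves).index(config.horizon_months)
    out = dataset.copy()
    if config.group_cost_substitute is not None:
        out["cost_intervention"] = (
            out["cost_intervention_individual"]
            + config.group_cost_substitute * out["group_sessions_attended"]
        )
    total = out["cost_intervention"].to_numpy(dtype=float).copy()
    for k in range(1, k_max + 1):
        total = total + out[f"cost_other_{k}"].to_numpy(dtype=float)
    if config.include_absenteeism:
        for k in range(1, k_max + 1):
            total = total + out[f"absenteeism_{k}"].to_numpy(dtype=float)
    out["total_cost"] = total
    u = out[[f"u_{w}" if w else "u_0" for w in range(k_max + 1)]].to_numpy(dtype=float)
    out["qaly"] = qaly_from_waves(u, config.waves[: k_max + 1], config.horizon_months)
    if config.effect == "hrsd":
        out["hrsd_improvement"] = out["hrsd_0"] - out[f"hrsd_{k_max}"]
    return out


def run_analysis(table: pd.DataFrame, config: AnalysisConfig) -> CEAResult:
    """Full covariate-adjusted, imputed, bootstrapped analysis of one table.

    ``table`` is the aggregate analysis table from
    :func:`ceatk.pipeline.build_analysis_table` (possibly with missing
    aggregate cells).  Imputation happens at the aggregate level; derived
    outcomes (total cost, QALYs, score improvement) are recomputed within
    each completed dataset before adjustment and bootstrapping.
    """
    work = table.drop(columns=[c for c in ("pid",) if c in table.columns])
    needed = _needed_columns(work, config)
    frac_incomplete = float(work[needed].isna().any(axis=1).mean()) if needed else 0.0
    ss = np.random.SeedSequence(config.seed)
    s_impute, s_boot = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    if config.impute:
        m = config.m if config.m is not None else choose_m(frac_incomplete)
        spec = ImputationSpec(
            m=m,
            seed=s_impute,
            n_cycles=config.n_cycles,
            variables={c: "pmm" for c in _IMPUTABLE if c in work.columns},
            predictors=tuple(c for c in _MI_PREDICTORS if c in work.columns),
        )
        imputed = mice_impute(work, spec)
        datasets = [_derive_outcomes(d, config) for d in imputed.datasets]
    else:
        complete = work.dropna(subset=needed) if needed else work
        if not len(complete):
            raise ValueError("no complete cases available")
        datasets = [_derive_outcomes(complete, config)]
        m = 1

    effect_col = "qaly" if config.effect == "qaly" else "hrsd_improvement"
    cost_spec = AdjustmentSpec("total_cost", config.covariates)
    effect_spec = AdjustmentSpec(effect_col, config.covariates)

    cost_fits = [adjusted_difference(d, cost_spec) for d in datasets]
    eff_fits = [adjusted_difference(d, effect_spec) for d in datasets]
    if m >= 2:
        pooled_cost = rubin_pool(
            [c for c, _ in cost_fits], [float(f.bse[1] ** 2) for _, f in cost_fits]
        )
        pooled_eff = rubin_pool(
            [c for c, _ in eff_fits], [float(f.bse[1] ** 2) for _, f in eff_fits]
        )
    else:
        c, f = cost_fits[0]
        pooled_cost = PooledEstimate(c, float(f.bse[1] ** 2), float(f.bse[1] ** 2), 0.0, 1)
        c, f = eff_fits[0]
        pooled_eff = PooledEstimate(c, float(f.bse[1] ** 2), float(f.bse[1] ** 2), 0.0, 1)

    cloud = bootstrap_cloud(datasets, cost_spec, effect_spec, B=config.B, seed=s_boot)
    curve = ceac(cloud, config.lambdas)
    shares = quadrant_shares(cloud)
    dE = pooled_eff.estimate
    ratio = icer(pooled_cost.estimate, dE) if dE != 0.0 else None
    return CEAResult(
        scenario="",
        horizon_months=config.horizon_months,
        effect_label="QALY" if config.effect == "qaly" else "HRSD point improvement",
        delta_cost=pooled_cost,
        delta_effect=pooled_eff,
        icer=ratio,
        icer_quadrant=quadrant_label(pooled_cost.estimate, dE),
        cloud=cloud,
        ceac=curve,
        quadrant_shares=shares,
        ci_cost=tuple(np.percentile(cloud.delta_cost, [2.5, 97.5])),
        ci_effect=tuple(np.percentile(cloud.delta_effect, [2.5, 97.5])),
        n_participants=len(datasets[0]),
        m=m,
        B=config.B,
    )


SCENARIOS = (
    "base_case",
    "complete_case",
    "with_absenteeism",
    "group_cost_substitute",
    "horizon_18m",
    "hrsd_effect",
)


def run_scenarios(
    table: pd.DataFrame,
    base_config: AnalysisConfig,
    group_substitute_rate: float = 14.0,
) -> dict[str, CEAResult]:
    """The base case and the five pre-specified sensitivity scenarios.

    1. complete-case analysis (no imputation); 2. broader perspective
    adding absenteeism costs; 3. national per-attendance unit cost for
    group sessions in place of the micro-costed programme; 4. the
    18-month horizon; 5. depression-score improvement as the effect
    measure.  A scenario whose required columns are absent is skipped
    with a logged reason.
    """
    ss = np.random.SeedSequence(base_config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(SCENARIOS))]
    variants: dict[str, AnalysisConfig] = {
        "base_case": base_config,
        "complete_case": replace(base_config, impute=False),
        "with_absenteeism": replace(base_config, include_absenteeism=True),
        "group_cost_substitute": replace(
            base_config, group_cost_substitute=group_substitute_rate
        ),
        "horizon_18m": replace(base_config, horizon_months=18.0),
        "hrsd_effect": replace(base_config, effect="hrsd"),
    }
    results: dict[str, CEAResult] = {}
    for (name, cfg), seed in zip(variants.items(), seeds):
        cfg = replace(cfg, seed=seed)
        needed = _needed_columns(table, cfg)
        k_max = list(cfg.waves).index(cfg.horizon_months)
        if cfg.effect == "hrsd" and f"hrsd_{k_max}" not in table.columns:
            logger.warning("skipping scenario %s: depression scores absent", name)
            continue
        if any(f"u_{w}" not in table.columns for w in range(1, k_max + 1)):
            logger.warning("skipping scenario %s: utility waves absent", name)
            continue
        result = run_analysis(table, cfg)
        result.scenario = name
        results[name] = result
    return results
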