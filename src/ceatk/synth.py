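"""Synthetic two-arm trial generator.

Emulates the data structure of a pragmatic psychotherapy trial in
refractory depression: 162 intervention vs 88 control participants,
assessments at 0/7/12/18 months, EQ-5D-3L profiles and depression scores
per wave, right-skewed service-use counts per follow-up interval,
medication spells, work-absence hours, an intervention attendance log
(29 individual sessions, 27 group sessions in closed groups), and
missing-at-random loss of whole follow-up blocks driven by baseline
severity.

Everything is driven by a single seed through per-participant substreams
keyed by (arm, within-arm index), so enlarging or shrinking one arm never
reshuffles the draws of other participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .costing import (
    DEFAULT_UNIT_COSTS,
    TherapistCostParams,
    cost_attendance_log,
)
from .eq5d import UK_TARIFF, UtilityTariff, score_state

MISSING_MECHANISMS = ("MCAR", "MAR-on-baseline")

# Noiseless utility targets are real EQ-5D-3L profiles under the UK
# tariff, chosen so the 12-month QALY difference is exactly 0.032 under
# trapezoidal integration over waves (0, 7, 12):
#   (6 x 0.034 + 2.5 x 0.072) / 12 = 0.032.
# The 18-month profiles put the control arm 0.001 ahead, mirroring the
# small late reversal seen in this population.
_CONTROL_STATES = ("11311", "22221", "21222", "12122")
_INTERVENTION_STATES = ("11311", "12122", "12121", "21222")
_DEFAULT_DELTA_QALY = 0.032

# Annual service-use cost shares for the control arm (non-intervention
# health and social care).  The intervention arm uses the same profile
# except markedly less other talking therapy while in the programme.
_SERVICE_SHARES: Mapping[str, float] = {
    "inpatient_day": 0.38,
    "day_hospital": 0.08,
    "ae_attendance": 0.03,
    "psychiatrist": 0.12,
    "psychologist": 0.05,
    "cmht_contact": 0.10,
    "gp_visit": 0.08,
    "practice_nurse": 0.01,
    "social_worker": 0.03,
    "talking_therapy": 0.12,
}
_TALKING_THERAPY_FACTOR = 0.35  # intervention-arm down-weight before renormalising

_MED_PARAMS = {
    # category: (probability of an active spell, daily cost GBP)
    "antidepressant": (0.85, 0.35),
    "antipsychotic": (0.20, 1.50),
    "sleeping_tablet": (0.25, 0.20),
    "painkiller": (0.30, 0.15),
}

# Attendance model: per-participant attendance propensity p ~ Beta with
# mean 22.8/29; 80% are invited to all 27 group sessions, the rest drop
# out uniformly, giving a mean of ~24.4 invitations and ~19.2 attended.
_ATT_BETA_A = 3.55
_ATT_MEAN = 22.8 / 29.0
_ATT_BETA_B = _ATT_BETA_A * (1.0 - _ATT_MEAN) / _ATT_MEAN
_COMPLETER_RATE = 0.80
_N_INDIVIDUAL = 29
_N_GROUP = 27

_HRSD_MIN, _HRSD_MAX = 15.0, 45.0
_HRSD_LOC, _HRSD_SCALE = 21.0, 4.0
_HRSD_CONTROL_FOLLOWUP = (18.0, 17.5, 17.0)
_HRSD_DELTA_PROFILE = (0.8, 1.0, 0.9)  # scaled by truth.delta_hrsd_12m
_HRSD_TRACKING = 0.4
_HRSD_NOISE_SD = 5.0

_DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class SimTruth:
    """True effects and nuisance parameters injected into the generator."""

    delta_qaly_12m: float = _DEFAULT_DELTA_QALY
    delta_cost_other_12m: float = -909.0
    intervention_cost_mean: float = 5000.0
    delta_hrsd_12m: float = 1.0
    control_cost_other_12m: float = 3300.0
    missing_fraction: float = 0.30
    missing_mechanism: str = "MAR-on-baseline"
    utility_noise_sd: float = 0.22
    participant_effect_sd: float = 0.10
    cost_dispersion: float = 0.15
    cost_family: str = "negbin"
    cost_propensity_sd: float = 0.5
    normal_cost_cv: float = 0.35
    outcome_joint_rate: float = 1.0
    mar_slope: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.missing_mechanism not in MISSING_MECHANISMS:
            raise ValueError(
                f"missing_mechanism must be one of {MISSING_MECHANISMS}, "
                f"got {self.missing_mechanism!r}"
            )
        if self.cost_dispersion <= 0:
            raise ValueError("cost_dispersion must be positive")
        if self.cost_family not in ("negbin", "normal"):
            raise ValueError("cost_family must be 'negbin' or 'normal'")
        if self.control_cost_other_12m + self.delta_cost_other_12m < 0:
            raise ValueError("intervention-arm other-care cost target is negative")
        if not (0.0 <= self.outcome_joint_rate <= 1.0):
            raise ValueError("outcome_joint_rate must lie in [0, 1]")


@dataclass(frozen=True)
class TrialDesign:
    """Sample sizes, assessment schedule and truth for one simulated trial."""

    n_intervention: int = 162
    n_control: int = 88
    waves: tuple[float, ...] = (0.0, 7.0, 12.0, 18.0)
    seed: int = 0
    true_effects: SimTruth = field(default_factory=SimTruth)
    group_size: int = 7

    def __post_init__(self) -> None:
        if self.n_intervention + self.n_control < 4:
            raise ValueError("n_intervention + n_control must be at least 4")
        if self.n_intervention < 1 or self.n_control < 1:
            raise ValueError("both arms need at least one participant")
        if len(self.waves) != 4:
            raise ValueError("waves must list four assessment times (months)")
        if self.waves[0] != 0:
            raise ValueError("first wave must be month 0 (baseline)")
        if any(b <= a for a, b in zip(self.waves, self.waves[1:])):
            raise ValueError("waves must be strictly increasing")
        if self.group_size < 1:
            raise ValueError("group_size must be at least 1")


@dataclass
class TrialData:
    """Generated trial: participant table, attendance log, provenance."""

    participants: pd.DataFrame
    attendance: pd.DataFrame
    design: TrialDesign
    therapist_params: TherapistCostParams


def _truncnorm_severity():
    a = (_HRSD_MIN - _HRSD_LOC) / _HRSD_SCALE
    b = (_HRSD_MAX - _HRSD_LOC) / _HRSD_SCALE
    dist = stats.truncnorm(a, b, loc=_HRSD_LOC, scale=_HRSD_SCALE)
    return dist, float(dist.mean()), float(dist.std())


_SEV_DIST, _SEV_MEAN, _SEV_SD = _truncnorm_severity()

_SEV_PHI_A = stats.norm.cdf((_HRSD_MIN - _HRSD_LOC) / _HRSD_SCALE)
_SEV_PHI_B = stats.norm.cdf((_HRSD_MAX - _HRSD_LOC) / _HRSD_SCALE)


def _severity_ppf(u: float) -> float:
    """Inverse CDF of the truncated-normal baseline severity score."""
    from scipy.special import ndtri

    return float(_HRSD_LOC + _HRSD_SCALE * ndtri(_SEV_PHI_A + u * (_SEV_PHI_B - _SEV_PHI_A)))


def _wave_targets(
    truth: SimTruth, tariff: UtilityTariff
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless utility targets per wave for control and intervention."""
    uc = np.array([score_state(s, tariff) for s in _CONTROL_STATES])
    ui_default = np.array([score_state(s, tariff) for s in _INTERVENTION_STATES])
    factor = truth.delta_qaly_12m / _DEFAULT_DELTA_QALY
    ui = uc + (ui_default - uc) * factor
    return uc, ui


def _service_means(truth: SimTruth) -> tuple[dict[str, float], dict[str, float]]:
    """Annual mean counts per service for (control, intervention)."""
    ctrl_target = truth.control_cost_other_12m
    int_target = truth.control_cost_other_12m + truth.delta_cost_other_12m
    ctrl = {s: sh * ctrl_target / DEFAULT_UNIT_COSTS[s] for s, sh in _SERVICE_SHARES.items()}
    shares_int = dict(_SERVICE_SHARES)
    shares_int["talking_therapy"] *= _TALKING_THERAPY_FACTOR
    norm = sum(shares_int.values())
    interv = {
        s: (sh / norm) * int_target / DEFAULT_UNIT_COSTS[s]
        for s, sh in shares_int.items()
    }
    return ctrl, interv


_CALIBRATION_CACHE: dict[tuple, float] = {}


def _mean_intervention_cost_unit_rate(
    params: TherapistCostParams, group_size: int
) -> float:
    """Expected micro-cost per intervention participant at a £1/h rate.

    Monte-Carlo expectation over the attendance model (large fixed-seed
    sample), so scaling the hourly employment cost reproduces any target
    mean intervention cost.
    """
    key = (
        group_size,
        params.nondirect_ratio,
        params.individual_session_minutes,
        params.group_session_minutes,
        params.therapists_small_group,
        params.therapists_large_group,
        params.small_group_max,
    )
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    rng = np.random.default_rng(np.random.SeedSequence([424242]))
    n = 200_000 - (200_000 % group_size)
    p = rng.beta(_ATT_BETA_A, _ATT_BETA_B, size=n)
    ind_attended = rng.binomial(_N_INDIVIDUAL, p)
    completes = rng.random(n) < _COMPLETER_RATE
    invited = np.where(completes, _N_GROUP, rng.integers(1, _N_GROUP + 1, size=n))
    inv = invited.reshape(-1, group_size)
    sessions = np.arange(1, _N_GROUP + 1)
    mask = inv[:, :, None] >= sessions[None, None, :]  # (groups, members, 27)
    counts = mask.sum(axis=1)  # invitees per group-session
    hours = params.group_session_minutes / 60.0
    ther = np.where(
        counts > params.small_group_max,
        params.therapists_large_group,
        params.therapists_small_group,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        per_invitee = np.where(
            counts > 0, ther * (1.0 + params.nondirect_ratio) * hours / counts, 0.0
        )
    group_cost = (mask * per_invitee[:, None, :]).sum(axis=2).ravel()
    ind_hours = params.individual_session_minutes / 60.0
    ind_cost = ind_attended * (1.0 + params.nondirect_ratio) * ind_hours
    mean_cost = float(np.mean(ind_cost + group_cost))
    _CALIBRATION_CACHE[key] = mean_cost
    return mean_cost


def calibrated_therapist_params(
    truth: SimTruth,
    group_size: int = 7,
    base: TherapistCostParams | None = None,
) -> TherapistCostParams:
    """Therapist cost parameters whose expected per-participant micro-cost
    under the attendance model equals ``truth.intervention_cost_mean``."""
    base = base or TherapistCostParams(hourly_employment_cost=1.0)
    unit = _mean_intervention_cost_unit_rate(base, group_size)
    return replace(base, hourly_employment_cost=truth.intervention_cost_mean / unit)


def _mar_intercept(truth: SimTruth) -> float:
    """Intercept of the MAR logistic model giving the target marginal rate."""
    f = truth.missing_fraction
    if f == 0.0:
        return -np.inf
    beta = truth.mar_slope

    def marginal(alpha: float) -> float:
        def integrand(x: float) -> float:
            z = (x - _SEV_MEAN) / _SEV_SD
            return _SEV_DIST.pdf(x) / (1.0 + np.exp(-(alpha + beta * z)))

        val, _ = integrate.quad(integrand, _HRSD_MIN, _HRSD_MAX)
        return val - f

    return float(optimize.brentq(marginal, -20.0, 20.0, xtol=1e-10))


def _participant_rng(seed: int, arm: int, idx: int, stream: int = 0):
    return np.random.default_rng(np.random.SeedSequence([seed, stream, arm, idx]))


def service_columns() -> list[str]:
    cols = []
    for code in _SERVICE_SHARES:
        cols.extend(f"{code}_i{k}" for k in range(4))
    return cols


def generate_trial(design: TrialDesign) -> TrialData:
    """Generate one synthetic trial, including its masked (missing) blocks.

    Returns the participant table (one row per participant, wave/interval
    suffixed columns), the intervention attendance log, and therapist cost
    parameters calibrated to the configured mean intervention cost.
    """
    truth = design.true_effects
    tariff = UK_TARIFF
    uc_targets, ui_targets = _wave_targets(truth, tariff)
    ctrl_means, int_means = _service_means(truth)
    waves = np.asarray(design.waves, dtype=float)
    lengths = np.diff(waves)  # months per follow-up interval
    # interval means: per-arm annual rates scaled to interval lengths for
    # the first two intervals; control rates for both arms in the third
    # (no further divergence after the primary end-point) and at baseline
    # (randomisation balances pre-trial use).
    codes = list(_SERVICE_SHARES)
    unit_costs = np.array([DEFAULT_UNIT_COSTS[c] for c in codes])

    def interval_means(arm: int) -> np.ndarray:
        own = int_means if arm == 1 else ctrl_means
        base = np.array([ctrl_means[c] for c in codes])
        ownv = np.array([own[c] for c in codes])
        m = np.empty((4, len(codes)))
        m[0] = base * 6.0 / 12.0  # baseline window: 6 months pre-trial
        m[1] = ownv * lengths[0] / 12.0
        m[2] = ownv * lengths[1] / 12.0
        m[3] = base * lengths[2] / 12.0
        return m

    means_by_arm = {0: interval_means(0), 1: interval_means(1)}
    normal_targets = {
        arm: (means_by_arm[arm] * unit_costs).sum(axis=1) for arm in (0, 1)
    }
    hrsd_deltas = np.array(_HRSD_DELTA_PROFILE) * truth.delta_hrsd_12m
    day_bounds = np.concatenate([[-6 * _DAYS_PER_MONTH], waves * _DAYS_PER_MONTH])

    rows: list[dict] = []
    att_pid: list[np.ndarray] = []
    att_type: list[str] = []
    att_index: list[np.ndarray] = []
    att_group: list[np.ndarray] = []
    att_invited: list[np.ndarray] = []
    att_attended: list[np.ndarray] = []
    arms = [(1, design.n_intervention), (0, design.n_control)]
    pid = 0
    for arm, n_arm in arms:
        for idx in range(n_arm):
            rng = _participant_rng(design.seed, arm, idx)
            row: dict = {"pid": pid, "arm": arm}
            sev = _severity_ppf(rng.random())
            row["hrsd_0"] = sev
            row["sev_z"] = (sev - _SEV_MEAN) / _SEV_SD
            row["age"] = float(np.clip(rng.normal(45.0, 11.0), 18.0, 78.0))
            row["female"] = int(rng.random() < 0.66)

            # utilities: arm target + participant effect + wave noise,
            # snapped to the nearest attainable EQ-5D-3L profile
            b_i = rng.normal(0.0, 1.0) * truth.participant_effect_sd
            noise = rng.normal(0.0, 1.0, size=4) * truth.utility_noise_sd
            targets = ui_targets if arm == 1 else uc_targets
            u_raw = targets + b_i + noise
            states = tariff.nearest_states(u_raw)
            for w, s in enumerate(states):
                row[f"eq5d_w{w}"] = s

            # depression scores at follow-up waves
            hn = rng.normal(0.0, 1.0, size=3) * _HRSD_NOISE_SD
            for k in range(3):
                mean_k = (
                    _HRSD_CONTROL_FOLLOWUP[k]
                    + _HRSD_TRACKING * (sev - _HRSD_LOC)
                    - (hrsd_deltas[k] if arm == 1 else 0.0)
                )
                row[f"hrsd_w{k + 1}"] = float(np.clip(mean_k + hn[k], 0.0, 52.0))

            # service-use counts per interval
            m = means_by_arm[arm]
            if truth.cost_family == "negbin":
                g_i = rng.gamma(
                    1.0 / truth.cost_propensity_sd**2,
                    truth.cost_propensity_sd**2,
                )
                for k in range(4):
                    mu = np.maximum(m[k] * g_i, 1e-12)
                    r = truth.cost_dispersion
                    counts = rng.negative_binomial(r, r / (r + mu))
                    for c, cnt in zip(codes, counts):
                        row[f"{c}_i{k}"] = int(cnt)
            else:  # normal family: draw aggregate other-care cost directly
                for k in range(4):
                    target = normal_targets[arm][k]
                    draw = rng.normal(target, truth.normal_cost_cv * target)
                    row[f"other_care_i{k}"] = float(max(draw, 0.0))

            # medication spells (identical distribution in both arms)
            if truth.cost_family == "negbin":
                for cat, (p_on, daily) in _MED_PARAMS.items():
                    active = rng.random() < p_on
                    start = -float(rng.integers(0, 180))
                    duration = float(rng.exponential(365.0)) + 30.0
                    row[f"med_{cat}_active"] = int(active)
                    row[f"med_{cat}_start"] = start if active else np.nan
                    row[f"med_{cat}_finish"] = start + duration if active else np.nan
                    row[f"med_{cat}_daily_cost"] = daily if active else np.nan

            # employment and lost work time (similar in both arms)
            employed = int(rng.random() < 0.45)
            row["employed"] = employed
            for k in range(3):
                scale_k = lengths[k] / 6.0
                absent = 0.0
                unproductive = 0.0
                z1, z2, g1, g2 = (
                    rng.random(),
                    rng.random(),
                    rng.gamma(1.2, 40.0 / 1.2),
                    rng.gamma(1.2, 30.0 / 1.2),
                )
                if employed:
                    if z1 < 0.35:
                        absent = g1 * scale_k
                    if z2 < 0.40:
                        unproductive = g2 * scale_k
                row[f"absent_hours_i{k + 1}"] = absent
                row[f"unproductive_hours_i{k + 1}"] = unproductive

            # intervention attendance
            if arm == 1:
                p_att = rng.beta(_ATT_BETA_A, _ATT_BETA_B)
                ind_attended = (rng.random(_N_INDIVIDUAL) < p_att).astype(int)
                completes = rng.random() < _COMPLETER_RATE
                invited_n = (
                    _N_GROUP if completes else int(rng.integers(1, _N_GROUP + 1))
                )
                grp_attended = (rng.random(_N_GROUP) < p_att).astype(int)
                group_id = idx // design.group_size
                grp_range = np.arange(1, _N_GROUP + 1)
                att_pid.append(np.full(_N_INDIVIDUAL + _N_GROUP, pid))
                att_type.extend(
                    ["individual"] * _N_INDIVIDUAL + ["group"] * _N_GROUP
                )
                att_index.append(np.arange(1, _N_INDIVIDUAL + 1))
                att_index.append(grp_range)
                att_group.append(np.full(_N_INDIVIDUAL, np.nan))
                att_group.append(np.full(_N_GROUP, float(group_id)))
                att_invited.append(np.ones(_N_INDIVIDUAL, dtype=int))
                att_invited.append((grp_range <= invited_n).astype(int))
                att_attended.append(ind_attended)
                att_attended.append(grp_attended * (grp_range <= invited_n))
            pid += 1
            rows.append(row)

    participants = pd.DataFrame(rows)
    if att_pid:
        attendance = pd.DataFrame(
            {
                "pid": np.concatenate(att_pid),
                "session_type": att_type,
                "session_index": np.concatenate(att_index),
                "group_id": np.concatenate(att_group),
                "invited": np.concatenate(att_invited),
                "attended": np.concatenate(att_attended),
            }
        )
    else:
        attendance = pd.DataFrame(
            columns=[
                "pid",
                "session_type",
                "session_index",
                "group_id",
                "invited",
                "attended",
            ]
        )
    participants = apply_missingness(participants, truth, seed=design.seed)
    params = calibrated_therapist_params(truth, design.group_size)
    return TrialData(participants, attendance, design, params)


def masked_columns(participants: pd.DataFrame) -> tuple[list[str], list[str]]:
    """(service-use block columns, outcome columns) eligible for masking."""
    cost_cols = [
        c
        for c in participants.columns
        if any(c.endswith(f"_i{k}") for k in (1, 2, 3))
        and not c.startswith(("absent_", "unproductive_"))
    ]
    cost_cols += [
        c
        for c in participants.columns
        if c.startswith(("absent_hours", "unproductive_hours", "med_"))
    ]
    outcome_cols = [
        c for c in participants.columns if c in ("eq5d_w1", "eq5d_w2", "eq5d_w3", "hrsd_w1", "hrsd_w2", "hrsd_w3")
    ]
    return cost_cols, outcome_cols


def apply_missingness(
    participants: pd.DataFrame, truth: SimTruth, seed: int
) -> pd.DataFrame:
    """Mask whole follow-up blocks per participant.

    A single latent draw per participant decides whether their follow-up
    service-use record is lost; the probability is constant (MCAR) or a
    logistic function of baseline severity (MAR-on-baseline), calibrated
    so the marginal masked fraction equals ``truth.missing_fraction``.
    Outcome values (EQ-5D profiles, depression scores) are masked jointly
    with the cost block at rate ``truth.outcome_joint_rate``.  Baseline
    fields and the therapy-record attendance log are never masked.
    """
    out = participants.copy()
    if truth.missing_fraction == 0.0:
        return out
    cost_cols, outcome_cols = masked_columns(out)
    if truth.missing_mechanism == "MAR-on-baseline":
        alpha = _mar_intercept(truth)
        p = 1.0 / (
            1.0
            + np.exp(-(alpha + truth.mar_slope * out["sev_z"].to_numpy(dtype=float)))
        )
    else:
        p = np.full(len(out), truth.missing_fraction)
    arms = out["arm"].to_numpy(dtype=int)
    u = np.empty(len(out))
    v = np.empty(len(out))
    arm_idx: dict[int, int] = {}
    for pos, arm in enumerate(arms):
        idx = arm_idx.get(arm, 0)
        arm_idx[arm] = idx + 1
        rng = _participant_rng(seed, arm, idx, stream=977)
        u[pos], v[pos] = rng.random(), rng.random()
    mask_cost = u < p
    mask_outcome = mask_cost & (v < truth.outcome_joint_rate)
    cost_block = out[cost_cols].to_numpy(dtype=float)
    cost_block[mask_cost] = np.nan
    out[cost_cols] = cost_block
    for c in outcome_cols:
        vals = out[c].to_numpy(dtype=object if out[c].dtype == object else float)
        if vals.dtype == object:
            vals = vals.copy()
            vals[mask_outcome] = np.nan
        else:
            vals = np.where(mask_outcome, np.nan, vals)
        out[c] = vals
    return out


def write_trial(trial: TrialData, outdir) -> dict[str, str]:
    """Persist a generated trial as CSV plus a JSON design record."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": str(outdir / "participants.csv"),
        "attendance": str(outdir / "attendance.csv"),
        "design": str(outdir / "design.json"),
    }
    trial.participants.to_csv(paths["participants"], index=False)
    trial.attendance.to_csv(paths["attendance"], index=False)
    design_dict = asdict(trial.design)
    design_dict["therapist_params"] = asdict(trial.therapist_params)
    with open(paths["design"], "w") as fh:
        json.dump(design_dict, fh, indent=2, default=float)
    return paths


def read_participants(path) -> pd.DataFrame:
    """Read a participants CSV, keeping EQ-5D profiles as strings."""
    eq5d_cols = [f"eq5d_w{w}" for w in range(4)]
    frame = pd.read_csv(path, dtype={c: "string" for c in eq5d_cols})
    for c in eq5d_cols:
        if c in frame.columns:
            frame[c] = frame[c].astype(object).where(frame[c].notna(), np.nan)
    return frame
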