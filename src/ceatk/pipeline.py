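"""Assemble the participant-level analysis table.

Turns raw trial inputs (participant table with wave-suffixed resource-use
counts and EQ-5D profiles, plus the intervention attendance log) into the
aggregate-level table the statistical analysis consumes: per-interval
other-care costs, micro-costed intervention costs, wave utilities,
depression scores and productivity losses.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .costing import (
    DEFAULT_UNIT_COST_TABLE,
    MedicationRecord,
    TherapistCostParams,
    UnitCostTable,
    cost_attendance_log,
)
from .eq5d import UK_TARIFF, UtilityTariff, score_states

_DAYS_PER_MONTH = 30.4375
DEFAULT_WAVES = (0.0, 7.0, 12.0, 18.0)


def _interval_day_windows(waves) -> list[tuple[float, float]]:
    """Day windows for baseline (6 months pre) and the follow-up intervals."""
    w = [m * _DAYS_PER_MONTH for m in waves]
    windows = [(-6.0 * _DAYS_PER_MONTH, 0.0)]
    windows += [(w[k], w[k + 1]) for k in range(len(w) - 1)]
    return windows


def _interval_service_cost(
    participants: pd.DataFrame, k: int, table: UnitCostTable
) -> pd.Series:
    """Unit-costed service use in interval k.

    A wholly absent block (every count NaN) is genuinely missing and
    yields NaN; individual blank items within an otherwise returned block
    are taken as zero use.
    """
    pattern = re.compile(rf"^(?P<code>.+)_i{k}$")
    cols, codes = [], []
    for c in participants.columns:
        m = pattern.match(c)
        if m and m.group("code") in table.costs:
            cols.append(c)
            codes.append(m.group("code"))
    if not cols:
        return pd.Series(0.0, index=participants.index)
    counts = participants[cols].to_numpy(dtype=float)
    prices = np.array([table.cost_of(code) for code in codes])
    all_missing = np.isnan(counts).all(axis=1)
    filled = np.nan_to_num(counts, nan=0.0)
    cost = filled @ prices
    cost[all_missing] = np.nan
    return pd.Series(cost, index=participants.index)


def _interval_medication_cost(
    participants: pd.DataFrame, window: tuple[float, float]
) -> pd.Series:
    med_cats = sorted(
        {
            m.group(1)
            for c in participants.columns
            if (m := re.match(r"^med_(.+)_active$", c))
        }
    )
    if not med_cats:
        return pd.Series(0.0, index=participants.index)
    total = np.zeros(len(participants))
    missing = np.zeros(len(participants), dtype=bool)
    w0, w1 = window
    for cat in med_cats:
        active = participants[f"med_{cat}_active"].to_numpy(dtype=float)
        start = participants[f"med_{cat}_start"].to_numpy(dtype=float)
        finish = participants[f"med_{cat}_finish"].to_numpy(dtype=float)
        daily = participants[f"med_{cat}_daily_cost"].to_numpy(dtype=float)
        missing |= np.isnan(active)
        on = active == 1
        days = np.clip(np.minimum(finish, w1) - np.maximum(start, w0), 0.0, None)
        contrib = np.where(on, days * np.nan_to_num(daily), 0.0)
        total += np.nan_to_num(contrib)
    total[missing] = np.nan
    return pd.Series(total, index=participants.index)


def build_analysis_table(
    participants: pd.DataFrame,
    attendance: pd.DataFrame,
    tariff: UtilityTariff = UK_TARIFF,
    unit_costs: UnitCostTable = DEFAULT_UNIT_COST_TABLE,
    therapist_params: TherapistCostParams | None = None,
    waves=DEFAULT_WAVES,
) -> pd.DataFrame:
    """Aggregate raw trial data to the analysis table.

    One row per participant with baseline covariates, per-interval
    other-care costs (services plus medications; NaN where the follow-up
    block is missing), productivity losses, wave utilities scored under
    ``tariff``, depression scores, and the micro-costed intervention cost
    from the attendance log (zero for controls, never missing).
    """
    therapist_params = therapist_params or TherapistCostParams()
    windows = _interval_day_windows(waves)
    out = pd.DataFrame(
        {
            "pid": participants["pid"].to_numpy(),
            "arm": participants["arm"].to_numpy(dtype=int),
        },
        index=participants.index,
    )
    for col in ("age", "female", "employed", "hrsd_0"):
        if col in participants.columns:
            out[col] = participants[col].to_numpy(dtype=float)

    # utilities per wave
    for w in range(4):
        col = f"eq5d_w{w}"
        if col in participants.columns:
            out["u_0" if w == 0 else f"u_{w}"] = score_states(
                participants[col].tolist(), tariff
            )

    # costs: baseline window then the three follow-up intervals
    base_cost = _interval_service_cost(participants, 0, unit_costs)
    base_med = _interval_medication_cost(participants, windows[0])
    out["cost_base"] = base_cost + base_med
    for k in (1, 2, 3):
        svc = _interval_service_cost(participants, k, unit_costs)
        med = _interval_medication_cost(participants, windows[k])
        out[f"cost_other_{k}"] = svc + med

    # productivity (human capital approach; zero for those not employed)
    wage = unit_costs.wage_rate
    for k in (1, 2, 3):
        ac = f"absent_hours_i{k}"
        uc = f"unproductive_hours_i{k}"
        out[f"absenteeism_{k}"] = (
            participants[ac].to_numpy(dtype=float) * wage
            if ac in participants.columns
            else 0.0
        )
        out[f"presenteeism_{k}"] = (
            participants[uc].to_numpy(dtype=float) * wage
            if uc in participants.columns
            else 0.0
        )

    # depression scores
    for k in (1, 2, 3):
        col = f"hrsd_w{k}"
        if col in participants.columns:
            out[f"hrsd_{k}"] = participants[col].to_numpy(dtype=float)

    # intervention micro-costs from the attendance log
    int_cols = [
        "cost_intervention_individual",
        "cost_intervention_group",
        "cost_intervention",
        "group_sessions_attended",
        "group_sessions_invited",
    ]
    if len(attendance):
        per_pid = cost_attendance_log(attendance, therapist_params)
        joined = out.join(per_pid, on="pid")
        for c in int_cols:
            out[c] = joined[c].fillna(0.0).to_numpy(dtype=float)
    else:
        for c in int_cols:
            out[c] = 0.0
    return out
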