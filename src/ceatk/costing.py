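"""Resource-use costing: unit-costed services, micro-costed therapy sessions,
medications and productivity losses.

Costs are carried at full floating-point precision throughout; rounding to
pennies happens only when tables are rendered.  The analysis perspective is
the NHS and personal social services (PSS): productivity losses are computed
but reported separately and never enter the NHS/PSS total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# Default unit-cost table (GBP per contact/day, 2014-2015 price year).
# These are illustrative placeholders in the spirit of national reference
# costs; real analyses should supply their own table.
DEFAULT_UNIT_COSTS: Mapping[str, float] = {
    "gp_visit": 38.0,
    "practice_nurse": 11.0,
    "psychiatrist": 150.0,
    "psychologist": 140.0,
    "cmht_contact": 40.0,
    "inpatient_day": 400.0,
    "day_hospital": 120.0,
    "ae_attendance": 140.0,
    "social_worker": 55.0,
    "talking_therapy": 53.0,
    # national per-attendance cost of a generic therapy group session,
    # used when substituting for the micro-costed group programme
    "group_therapy_national": 14.0,
    # pre-aggregated other-care block (unit cost £1), emitted by the
    # synthetic generator's normal cost family
    "other_care": 1.0,
}

DEFAULT_WAGE_RATE = 13.30  # GBP/hour, national gross average


@dataclass(frozen=True)
class UnitCostTable:
    """Service-code to cost-per-unit mapping with price-year metadata."""

    costs: Mapping[str, float]
    wage_rate: float = DEFAULT_WAGE_RATE
    price_year: str = "2014-2015"
    uprating_index: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, cost in self.costs.items():
            if cost < 0:
                raise ValueError(f"negative unit cost for {code!r}")
        if self.wage_rate < 0:
            raise ValueError("wage rate must be non-negative")

    def cost_of(self, code: str) -> float:
        try:
            base = self.costs[code]
        except KeyError:
            raise KeyError(f"no unit cost for service code {code!r}") from None
        return base

    def uprated(self, code: str, price_year: str) -> float:
        """Unit cost uprated to another price year via the index table."""
        mult = self.uprating_index.get(price_year)
        if mult is None:
            raise KeyError(f"no uprating multiplier for price year {price_year!r}")
        return self.cost_of(code) * mult

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "UnitCostTable":
        return cls(costs=dict(zip(frame["service_code"], frame["cost"].astype(float))), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "UnitCostTable":
        return cls.from_frame(pd.read_csv(path), **kwargs)


DEFAULT_UNIT_COST_TABLE = UnitCostTable(costs=DEFAULT_UNIT_COSTS)


@dataclass(frozen=True)
class TherapistCostParams:
    """Micro-costing parameters for therapist-delivered sessions.

    ``hourly_employment_cost`` bundles salary, employer on-costs and
    overheads.  Direct contact time is weighted up by ``nondirect_ratio``
    (a 1:0.91 direct:non-direct split by default) to cover preparation,
    supervision and administration.  Groups above ``small_group_max``
    invitees run with two therapists.
    """

    hourly_employment_cost: float = 65.0
    nondirect_ratio: float = 0.91
    individual_session_minutes: float = 60.0
    group_session_minutes: float = 150.0
    therapists_small_group: int = 1
    therapists_large_group: int = 2
    small_group_max: int = 3

    def __post_init__(self) -> None:
        if self.nondirect_ratio < 0:
            raise ValueError("nondirect_ratio must be >= 0")
        if self.individual_session_minutes <= 0 or self.group_session_minutes <= 0:
            raise ValueError("session durations must be positive")
        if self.hourly_employment_cost < 0:
            raise ValueError("hourly employment cost must be non-negative")

    def therapists_for(self, n_invited: int) -> int:
        if n_invited <= self.small_group_max:
            return self.therapists_small_group
        return self.therapists_large_group


@dataclass(frozen=True)
class MedicationRecord:
    """One prescribed-medication spell, costed at the category's median
    daily dose and assuming full adherence between start and finish."""

    category: str
    daily_cost: float
    start_day: int
    finish_day: int

    CATEGORIES = ("antidepressant", "antipsychotic", "sleeping_tablet", "painkiller")

    def __post_init__(self) -> None:
        if self.finish_day < self.start_day:
            raise ValueError(
                f"medication finish day {self.finish_day} precedes start {self.start_day}"
            )
        if self.daily_cost < 0:
            raise ValueError("daily cost must be non-negative")


@dataclass
class CostSummary:
    """Per-participant cost components over a stated window (GBP)."""

    service_cost: float
    intervention_cost: float
    medication_cost: float
    productivity_cost: float
    window: str = ""

    @property
    def total_nhs_pss(self) -> float:
        """NHS/PSS-perspective total; productivity is deliberately excluded."""
        return self.service_cost + self.intervention_cost + self.medication_cost


def cost_services(
    usage: Mapping[str, float] | pd.Series, table: UnitCostTable
) -> float:
    """Sum of reported use times unit costs.

    Items left blank in a returned questionnaire are treated as zero use,
    so NaN counts contribute nothing.  Codes without a price raise with a
    list of every offending code.
    """
    if isinstance(usage, pd.Series):
        usage = usage.to_dict()
    unpriced = sorted(code for code in usage if code not in table.costs)
    if unpriced:
        raise KeyError(f"no unit cost for service codes: {unpriced}")
    total = 0.0
    for code, count in usage.items():
        if count is None or (isinstance(count, float) and np.isnan(count)):
            continue
        if count < 0:
            raise ValueError(f"negative usage count for {code!r}")
        total += float(count) * table.cost_of(code)
    return total


def cost_individual_session(params: TherapistCostParams) -> float:
    """Cost of one *attended* individual therapy session.

    Non-attended individual sessions are excluded from analysis and cost
    nothing (the therapist is assumed to redeploy the freed time).
    """
    hours = params.individual_session_minutes / 60.0
    return params.hourly_employment_cost * (1.0 + params.nondirect_ratio) * hours


def cost_group_session(
    n_invited: int,
    params: TherapistCostParams,
    n_therapists: int | None = None,
) -> float:
    """Cost of one group session *per invited participant*.

    Group sessions were closed and ran regardless of turnout, so the whole
    session cost is spread across everyone invited, attending or not.  The
    therapist count follows the group-size rule unless given explicitly.
    """
    if n_invited < 1:
        raise ValueError("a closed group session requires at least one invitee")
    if n_therapists is None:
        n_therapists = params.therapists_for(n_invited)
    hours = params.group_session_minutes / 60.0
    total = (
        n_therapists
        * params.hourly_employment_cost
        * (1.0 + params.nondirect_ratio)
        * hours
    )
    return total / n_invited


def cost_medications(
    records: Iterable[MedicationRecord], window: tuple[int, int]
) -> float:
    """Medication cost over a half-open day window ``[start, end)``.

    Each record contributes ``daily_cost`` for every day its half-open
    spell ``[start_day, finish_day)`` overlaps the window; spells in
    different categories simply add.
    """
    w0, w1 = window
    if w1 < w0:
        raise ValueError("window end precedes window start")
    total = 0.0
    for rec in records:
        days = max(0, min(rec.finish_day, w1) - max(rec.start_day, w0))
        total += days * rec.daily_cost
    return total


def cost_productivity(
    absent_hours: float, unproductive_hours: float, wage_rate: float
) -> float:
    """Human-capital valuation of lost work time at the gross wage rate.

    Applies only to participants in paid employment; callers should pass
    zero hours (or skip the call) for those not employed.  Absenteeism and
    presenteeism components are valued identically and simply add.
    """
    if absent_hours < 0 or unproductive_hours < 0:
        raise ValueError("hours cannot be negative")
    if wage_rate < 0:
        raise ValueError("wage rate cannot be negative")
    return (absent_hours + unproductive_hours) * wage_rate


def cost_attendance_log(
    attendance: pd.DataFrame, params: TherapistCostParams
) -> pd.DataFrame:
    """Micro-cost an intervention attendance log.

    ``attendance`` has one row per participant-session with columns
    ``pid, session_type ('individual'|'group'), session_index, group_id,
    invited, attended``.  Individual sessions are costed per attendance;
    group sessions are costed per session (therapist count from the
    per-session invitee count) and allocated across that session's
    invitees.  Returns a per-participant frame with columns
    ``cost_intervention_individual, cost_intervention_group,
    group_sessions_attended, group_sessions_invited``.
    """
    ind = attendance[attendance["session_type"] == "individual"]
    grp = attendance[attendance["session_type"] == "group"]

    per_ind = cost_individual_session(params)
    ind_cost = ind.groupby("pid")["attended"].sum().astype(float) * per_ind

    pieces = []
    invited_grp = grp[grp["invited"] == 1]
    if len(invited_grp):
        sizes = invited_grp.groupby(["group_id", "session_index"])["pid"].transform("size")
        share = np.array(
            [cost_group_session(int(n), params) for n in sizes], dtype=float
        )
        pieces.append(
            pd.DataFrame(
                {
                    "pid": invited_grp["pid"].to_numpy(),
                    "grp_cost": share,
                    "grp_att": invited_grp["attended"].to_numpy(dtype=float),
                }
            )
        )
    if pieces:
        grp_per_pid = (
            pd.concat(pieces)
            .groupby("pid")
            .agg(
                cost_intervention_group=("grp_cost", "sum"),
                group_sessions_attended=("grp_att", "sum"),
                group_sessions_invited=("grp_cost", "size"),
            )
        )
    else:
        grp_per_pid = pd.DataFrame(
            columns=[
                "cost_intervention_group",
                "group_sessions_attended",
                "group_sessions_invited",
            ]
        )

    out = pd.concat([ind_cost.rename("cost_intervention_individual"), grp_per_pid], axis=1)
    out = out.fillna(0.0)
    out["cost_intervention"] = (
        out["cost_intervention_individual"] + out["cost_intervention_group"]
    )
    out.index.name = "pid"
    return out
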