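"""EQ-5D-3L utility scoring and area-under-the-curve QALYs.

The EQ-5D-3L describes health on five dimensions (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each at one of
three levels.  A *tariff* (value set) maps each of the 243 profiles to a
population-preference utility on a scale where 1 is full health and 0 is
dead; states worse than dead take negative values.  QALYs over a follow-up
window are the area under the linearly interpolated utility-versus-time
curve, with time in months converted to years.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

_LEVELS = (1, 2, 3)


@dataclass(frozen=True)
class EQ5DState:
    """One EQ-5D-3L profile; each dimension at level 1 (none) to 3 (extreme)."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in _LEVELS:
                raise ValueError(
                    f"EQ-5D-3L level for {dim!r} must be 1, 2 or 3; got {level!r}"
                )

    @classmethod
    def from_string(cls, digits: str) -> "EQ5DState":
        """Parse a five-digit profile such as ``"21232"``."""
        digits = str(digits).strip()
        if len(digits) != 5 or not digits.isdigit():
            raise ValueError(f"expected a five-digit EQ-5D-3L profile, got {digits!r}")
        return cls(*(int(c) for c in digits))

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, dim) for dim in DIMENSIONS)  # type: ignore[return-value]

    def __str__(self) -> str:
        return "".join(str(l) for l in self.as_tuple())


# UK TTO value set for the EQ-5D-3L (the standard tariff for English
# NHS-perspective analyses), expressed as decrements from full health.
UK_TARIFF_COEFFICIENTS: Mapping[str, object] = {
    "label": "UK TTO value set (EQ-5D-3L)",
    "constant_decrement": 0.081,
    "any_level3_decrement": 0.269,
    "decrements": {
        "mobility": (0.069, 0.314),
        "self_care": (0.104, 0.214),
        "usual_activities": (0.036, 0.094),
        "pain_discomfort": (0.123, 0.386),
        "anxiety_depression": (0.071, 0.236),
    },
}


@dataclass(frozen=True)
class UtilityTariff:
    """Additive-decrement tariff for EQ-5D-3L profiles.

    Utility of a profile is ``1 - constant - sum(level decrements) -
    any_level3`` where the constant applies to any departure from full
    health and the any-level-3 term applies once if any dimension is at
    level 3.  Full health (11111) scores exactly 1.
    """

    constant_decrement: float
    decrements: Mapping[str, tuple[float, float]]
    any_level3_decrement: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.constant_decrement < 0 or self.any_level3_decrement < 0:
            raise ValueError("tariff decrements must be non-negative")
        missing = set(DIMENSIONS) - set(self.decrements)
        if missing:
            raise ValueError(f"tariff missing decrements for {sorted(missing)}")
        for dim in DIMENSIONS:
            d2, d3 = self.decrements[dim]
            if d2 < 0 or d3 < 0:
                raise ValueError(f"negative decrement for {dim!r}")

    @classmethod
    def from_config(cls, config: Mapping[str, object]) -> "UtilityTariff":
        decs = {k: tuple(v) for k, v in dict(config["decrements"]).items()}  # type: ignore[index]
        return cls(
            constant_decrement=float(config["constant_decrement"]),  # type: ignore[arg-type]
            decrements=decs,  # type: ignore[arg-type]
            any_level3_decrement=float(config["any_level3_decrement"]),  # type: ignore[arg-type]
            label=str(config.get("label", "custom")),
        )

    def score(self, state: EQ5DState) -> float:
        levels = state.as_tuple()
        if levels == (1, 1, 1, 1, 1):
            return 1.0
        u = 1.0 - self.constant_decrement
        for dim, level in zip(DIMENSIONS, levels):
            d2, d3 = self.decrements[dim]
            if level == 2:
                u -= d2
            elif level == 3:
                u -= d3
        if 3 in levels:
            u -= self.any_level3_decrement
        return u

    def state_table(self) -> tuple[np.ndarray, list[str]]:
        """All 243 profiles with utilities, sorted by (utility, profile)."""
        items = []
        for levels in itertools.product(_LEVELS, repeat=5):
            s = EQ5DState(*levels)
            items.append((self.score(s), str(s)))
        items.sort()
        utils = np.array([u for u, _ in items])
        labels = [lab for _, lab in items]
        return utils, labels

    def attainable_range(self) -> tuple[float, float]:
        utils, _ = self._cached_table()
        return float(utils[0]), float(utils[-1])

    def _cached_table(self) -> tuple[np.ndarray, list[str]]:
        cache = getattr(self, "_table_cache", None)
        if cache is None:
            cache = self.state_table()
            object.__setattr__(self, "_table_cache", cache)
        return cache

    def nearest_states(self, utilities: np.ndarray) -> list[str]:
        """Snap target utilities to the nearest attainable profile.

        Ties break toward the lower utility; among equal-utility profiles
        the lexicographically smallest five-digit string is used, so the
        mapping is deterministic.
        """
        utils, labels = self._cached_table()
        u = np.asarray(utilities, dtype=float)
        idx = np.searchsorted(utils, u)
        idx = np.clip(idx, 1, len(utils) - 1)
        lower = utils[idx - 1]
        upper = utils[idx]
        pick_upper = (upper - u) < (u - lower)
        chosen = np.where(pick_upper, idx, idx - 1)
        return [labels[i] for i in chosen]


UK_TARIFF = UtilityTariff.from_config(UK_TARIFF_COEFFICIENTS)


def score_state(state: EQ5DState | str, tariff: UtilityTariff = UK_TARIFF) -> float:
    """Utility of a single EQ-5D-3L profile under ``tariff``."""
    if isinstance(state, str):
        state = EQ5DState.from_string(state)
    return tariff.score(state)


def score_states(
    states: Iterable[str | float | None], tariff: UtilityTariff = UK_TARIFF
) -> np.ndarray:
    """Vectorised scoring of five-digit profiles; missing entries give NaN."""
    lookup = {lab: u for u, lab in zip(*tariff._cached_table())}
    out = []
    for s in states:
        if s is None or (isinstance(s, float) and np.isnan(s)):
            out.append(np.nan)
            continue
        key = str(s).strip()
        if key not in lookup:
            # validate and score explicitly to surface a clear error
            out.append(tariff.score(EQ5DState.from_string(key)))
        else:
            out.append(lookup[key])
    return np.array(out, dtype=float)


@dataclass(frozen=True)
class UtilityTrajectory:
    """Utilities observed at months from randomisation, baseline first."""

    times: tuple[float, ...]
    utilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.utilities):
            raise ValueError("times and utilities must have equal length")
        if len(self.times) == 0 or self.times[0] != 0:
            raise ValueError("trajectory must start at time 0 (baseline)")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")


def qaly_auc(traj: UtilityTrajectory, horizon_months: float) -> float:
    """QALYs by the trapezoidal area under the utility curve up to ``horizon_months``.

    The horizon must coincide with one of the measurement times; no
    extrapolation beyond the last observation is performed.  Months are
    converted to years by dividing by 12.
    """
    times = np.asarray(traj.times, dtype=float)
    utils = np.asarray(traj.utilities, dtype=float)
    if horizon_months > times[-1]:
        raise ValueError(
            f"horizon {horizon_months} months exceeds last measurement at {times[-1]}"
        )
    matches = np.nonzero(np.isclose(times, horizon_months))[0]
    if len(matches) == 0:
        raise ValueError(
            f"horizon {horizon_months} does not coincide with a measurement time"
        )
    stop = matches[0]
    widths = np.diff(times[: stop + 1])
    mids = 0.5 * (utils[:stop] + utils[1 : stop + 1])
    return float(np.sum(widths * mids) / 12.0)


def qaly_from_waves(
    utilities: np.ndarray, wave_months: Sequence[float], horizon_months: float
) -> np.ndarray:
    """Vectorised trapezoid QALYs for an (n, waves) utility matrix."""
    times = np.asarray(wave_months, dtype=float)
    matches = np.nonzero(np.isclose(times, horizon_months))[0]
    if len(matches) == 0:
        raise ValueError("horizon must coincide with a wave time")
    stop = matches[0]
    u = np.asarray(utilities, dtype=float)
    widths = np.diff(times[: stop + 1])
    mids = 0.5 * (u[:, :stop] + u[:, 1 : stop + 1])
    return mids @ widths / 12.0
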