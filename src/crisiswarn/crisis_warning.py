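"""Daily affect aggregation and logistic early-warning scoring.

Expressed emotions are collapsed to one record per calendar day: ``pos`` is
the maximum expressed positive intensity over the day's posts and ``neg``
the maximum magnitude of expressed negative intensity (the "more than two
posts a day -> take the daily maximum" rule, applied for any number of
posts).  Two warning inputs are derived per day:

* ``delta_i`` — the negative-minus-positive intensity difference
  ``|I_neg| - I_pos``; with the flip-swing rule enabled, a day whose
  dominant valence flips from positive to negative instead scores the full
  swing ``today.neg + yesterday.pos``.
* ``delta_t`` — the length of the maximal run of consecutive days with
  expressed negative affect ending today, scaled by a reference duration
  (default 3 days) so that persistence saturates the warning score on the
  scale of the "prolonged negative affect" criterion.

The warning value is the logistic ``g = 1 / (1 + exp(-(delta_i +
delta_t_scaled)))`` and is banded into a five-level signal system:

    [0, 0.2]   Security        Green
    (0.2, 0.4) Safer           Blue
    [0.4, 0.6] Criticality     Yellow
    (0.6, 0.8) More dangerous  Orange
    [0.8, 1]   Dangerous       Red
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .affect_dynamics import ActivationVector
from .errors import ConfigurationError, ValidationError
from .model_core import NEGATIVE_INDICES, POSITIVE_INDICES

__all__ = [
    "DailyAffect",
    "WarningInputs",
    "WarningRecord",
    "WarningConfig",
    "aggregate_daily",
    "delta_I",
    "delta_T",
    "warning_value",
    "classify_level",
    "warn_series",
    "warnings_to_dataframe",
]

#: (upper bound, upper bound closed, level, color); lower bounds follow from
#: the previous band.  Encodes the printed closed/open bracket semantics.
_BANDS: tuple[tuple[float, bool, str, str], ...] = (
    (0.2, True, "Security", "Green"),
    (0.4, False, "Safer", "Blue"),
    (0.6, True, "Criticality", "Yellow"),
    (0.8, False, "More dangerous", "Orange"),
    (1.0, True, "Dangerous", "Red"),
)


@dataclass(frozen=True)
class DailyAffect:
    """One day's expressed affect summary."""

    date: dt.date
    pos: float  # max expressed positive intensity, in [0, 1]
    neg: float  # max magnitude of expressed negative intensity, in [0, 1]

    @property
    def dominant(self) -> str:
        if self.pos == 0.0 and self.neg == 0.0:
            return "none"
        return "positive" if self.pos > self.neg else "negative"


@dataclass(frozen=True)
class WarningInputs:
    """Inputs of the logistic warning function for one day."""

    delta_i: float = 0.0
    delta_t_days: int = 0
    delta_t_scaled: float = 0.0


@dataclass(frozen=True)
class WarningRecord:
    """Per-day warning value with its five-level banding."""

    date: dt.date
    pos: float
    neg: float
    delta_i: float
    delta_t_days: int
    warning: float
    level: str
    color: str


@dataclass(frozen=True)
class WarningConfig:
    """Warning-layer constants.

    delta_t_reference : days of sustained negative affect that count as one
        logistic unit (default 3, the "more than 3 days" persistence scale).
    flip_swing : score full valence swings (yesterday positive, today
        negative) as the sum of both magnitudes.
    """

    delta_t_reference: int = 3
    flip_swing: bool = True

    def __post_init__(self) -> None:
        if self.delta_t_reference < 1:
            raise ConfigurationError("delta_t_reference must be >= 1")


def _coerce_date(stamp, context: str) -> dt.date:
    """Accept date/datetime/ISO-8601 string; datetimes are read in UTC."""
    if isinstance(stamp, dt.datetime):
        if stamp.tzinfo is not None:
            stamp = stamp.astimezone(dt.timezone.utc)
        return stamp.date()
    if isinstance(stamp, dt.date):
        return stamp
    if isinstance(stamp, str):
        try:
            parsed = dt.datetime.fromisoformat(stamp.replace("Z", "+00:00"))
        except ValueError:
            raise ValidationError(
                f"unparseable timestamp {stamp!r} in {context}"
            ) from None
        return _coerce_date(parsed, context)
    raise ValidationError(f"unparseable timestamp {stamp!r} in {context}")


def aggregate_daily(
    scored_posts: Iterable[tuple[object, ActivationVector]],
) -> list[DailyAffect]:
    """Collapse per-post activations into one record per calendar day.

    Returns one record for every day from the earliest to the latest post
    (inclusive); days without posts get pos = neg = 0.
    """
    per_day: dict[dt.date, tuple[float, float]] = {}
    for i, (stamp, act) in enumerate(scored_posts):
        day = _coerce_date(stamp, context=f"record {i}")
        values = np.asarray(act.values, dtype=float)
        pos = float(max((values[j] for j in POSITIVE_INDICES), default=0.0))
        neg = float(max((abs(values[j]) for j in NEGATIVE_INDICES), default=0.0))
        old_pos, old_neg = per_day.get(day, (0.0, 0.0))
        per_day[day] = (max(old_pos, pos), max(old_neg, neg))
    if not per_day:
        return []
    first, last = min(per_day), max(per_day)
    out = []
    day = first
    while day <= last:
        pos, neg = per_day.get(day, (0.0, 0.0))
        out.append(DailyAffect(day, pos, neg))
        day += dt.timedelta(days=1)
    return out


def delta_I(
    today: DailyAffect,
    yesterday: DailyAffect | None,
    config: WarningConfig | None = None,
) -> float:
    """Per-day intensity difference |I_neg| - I_pos, with flip-swing option.

    When ``config.flip_swing`` is set and the dominant valence flips from
    positive (yesterday) to negative (today), the drastic change is scored
    as the full swing ``today.neg + yesterday.pos``.
    """
    config = config or WarningConfig()
    if (
        config.flip_swing
        and yesterday is not None
        and yesterday.dominant == "positive"
        and today.dominant == "negative"
    ):
        return today.neg + yesterday.pos
    return today.neg - today.pos


def delta_T(
    series: Sequence[DailyAffect],
    day_index: int,
    config: WarningConfig | None = None,
) -> WarningInputs:
    """Consecutive-negative-day count ending at ``day_index``, and its scaling.

    A day participates in the run when it has any expressed negative affect
    (neg > 0); a day without breaks the run (no imputation).
    """
    config = config or WarningConfig()
    if not 0 <= day_index < len(series):
        raise ValidationError(
            f"day index {day_index} outside series of length {len(series)}"
        )
    days = 0
    for i in range(day_index, -1, -1):
        if series[i].neg > 0.0:
            days += 1
        else:
            break
    return WarningInputs(
        delta_t_days=days, delta_t_scaled=days / config.delta_t_reference
    )


def warning_value(delta_i: float, delta_t_scaled: float) -> float:
    """Logistic early-warning score ``1 / (1 + exp(-(dI + dT)))`` in (0, 1)."""
    return 1.0 / (1.0 + math.exp(-(delta_i + delta_t_scaled)))


def classify_level(g: float) -> tuple[str, str]:
    """Map a warning value in [0, 1] to its (level, color) band."""
    if not 0.0 <= g <= 1.0:
        raise ValidationError(f"warning value {g!r} outside [0, 1]")
    for upper, closed, level, color in _BANDS:
        if g < upper or (closed and g == upper):
            return level, color
    return _BANDS[-1][2], _BANDS[-1][3]  # g == 1.0


def warn_series(
    daily: Sequence[DailyAffect],
    config: WarningConfig | None = None,
) -> list[WarningRecord]:
    """Score every day of a daily-affect series."""
    config = config or WarningConfig()
    if not daily:
        raise ValidationError("daily series must be nonempty")
    records = []
    for i, today in enumerate(daily):
        yesterday = daily[i - 1] if i > 0 else None
        di = delta_I(today, yesterday, config)
        inputs = delta_T(daily, i, config)
        g = warning_value(di, inputs.delta_t_scaled)
        level, color = classify_level(g)
        records.append(
            WarningRecord(
                date=today.date,
                pos=today.pos,
                neg=today.neg,
                delta_i=di,
                delta_t_days=inputs.delta_t_days,
                warning=g,
                level=level,
                color=color,
            )
        )
    return records


def warnings_to_dataframe(records: Sequence[WarningRecord]) -> pd.DataFrame:
    """Tabulate warning records (warning values fixed to 6 decimals)."""
    return pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in records],
            "pos": [r.pos for r in records],
            "neg": [r.neg for r in records],
            "delta_i": [r.delta_i for r in records],
            "delta_t_days": [r.delta_t_days for r in records],
            "warning_value": [f"{r.warning:.6f}" for r in records],
            "level": [r.level for r in records],
            "color": [r.color for r in records],
        }
    )
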