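"""Signed emotion-intensity dynamics, threshold estimation, activation.

The emotion state is a 6-component signed intensity vector on the Ekman
axes ``(dis, ang, sur, fea, joy, sad)``: positive emotions (sur, joy) live
in [0, 1], negative emotions (dis, ang, fea, sad) in [-1, 0].  The state
evolves in daily steps by the recurrence

    I_t = clip( I_{t-1} * exp(-lambda) + Theta_t + Phi(P) )

where ``Theta_t`` is the stimulus of the stress events detected at day t,
``Phi(P)`` is the constant personality bias from
:mod:`crisiswarn.model_core`, and the clip keeps every component inside its
valence range (cross-valence leakage is forbidden: a positive component
never drops below 0, a negative one never rises above 0).

Whether an emotion is *expressed* is decided against a personality-derived
threshold pair.  With ``xi = c + e - n`` the negative threshold is
``omega_neg = (arctan(xi) + pi/2) / pi`` and ``omega_pos = 1 - omega_neg``:
the more positive the personality balance, the harder negative emotions are
to activate and the easier positive ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .model_core import (
    NEGATIVE_INDICES,
    POSITIVE_INDICES,
    PersonalityProfile,
    personality_influence,
)

__all__ = [
    "EmotionState",
    "Thresholds",
    "DynamicsConfig",
    "ActivationVector",
    "clip_to_valence",
    "decay",
    "threshold_estimate",
    "step",
    "activate",
    "run_dynamics",
]

_NEG = list(NEGATIVE_INDICES)
_POS = list(POSITIVE_INDICES)


def clip_to_valence(intensities: np.ndarray) -> np.ndarray:
    """Clip each component into its valence range ([0,1] pos, [-1,0] neg)."""
    out = np.asarray(intensities, dtype=float).copy()
    out[_POS] = np.clip(out[_POS], 0.0, 1.0)
    out[_NEG] = np.clip(out[_NEG], -1.0, 0.0)
    return out


@dataclass(frozen=True)
class EmotionState:
    """Signed emotion intensities at one (1-based) day index."""

    t: int
    intensities: np.ndarray  # shape (6,), order (dis, ang, sur, fea, joy, sad)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.shape != (6,):
            raise ValidationError(
                f"emotion state needs 6 components, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("emotion state contains non-finite intensities")
        if np.any(arr[_POS] < 0) or np.any(arr[_POS] > 1):
            raise ValidationError("positive-emotion intensity outside [0, 1]")
        if np.any(arr[_NEG] > 0) or np.any(arr[_NEG] < -1):
            raise ValidationError("negative-emotion intensity outside [-1, 0]")
        object.__setattr__(self, "intensities", arr)

    @classmethod
    def zero(cls, t: int = 1) -> "EmotionState":
        return cls(t, np.zeros(6))


@dataclass(frozen=True)
class Thresholds:
    """Personality-derived activation thresholds (omega_pos + omega_neg = 1)."""

    xi: float
    omega_pos: float
    omega_neg: float


@dataclass(frozen=True)
class DynamicsConfig:
    """Tunable constants of the intensity recurrence.

    lambda_ : exponential decay factor per day (>= 0).
    gain : scale of the personality bias Phi(P) (>= 0).
    stimulus_mode : "impulse" applies each scheduled stimulus on its day
        only; "sustained" repeats it for ``sustain_steps`` consecutive days.
    """

    lambda_: float = 0.5
    gain: float = 0.1
    stimulus_mode: str = "impulse"
    sustain_steps: int = 3

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ConfigurationError(f"decay factor must be >= 0, got {self.lambda_}")
        if self.gain < 0:
            raise ConfigurationError(f"personality gain must be >= 0, got {self.gain}")
        if self.stimulus_mode not in ("impulse", "sustained"):
            raise ConfigurationError(
                f"stimulus_mode must be 'impulse' or 'sustained', "
                f"got {self.stimulus_mode!r}"
            )
        if self.sustain_steps < 1:
            raise ConfigurationError("sustain_steps must be >= 1")


@dataclass(frozen=True)
class ActivationVector:
    """Which emotions are expressed at one step, with their intensities.

    ``values`` carries the state intensity for expressed emotions and 0
    otherwise.
    """

    expressed: tuple[bool, ...]
    values: np.ndarray = field(default_factory=lambda: np.zeros(6))


def decay(state: EmotionState, lambda_: float) -> EmotionState:
    """Exponential attenuation: every component times ``exp(-lambda)``.

    Sign-preserving; the time index is unchanged (decay is a sub-step of
    :func:`step`).
    """
    if lambda_ < 0:
        raise ConfigurationError(f"decay factor must be >= 0, got {lambda_}")
    return EmotionState(state.t, state.intensities * math.exp(-lambda_))


def threshold_estimate(p: PersonalityProfile) -> Thresholds:
    """Estimate the valence thresholds from the Big-Five balance.

    ``xi = c + e - n``; ``omega_neg = (arctan(xi) + pi/2) / pi`` (an
    S-shaped transfer mapping the signed balance into (0, 1)),
    ``omega_pos = 1 - omega_neg``.
    """
    xi = p.c + p.e - p.n
    omega_neg = (math.atan(xi) + math.pi / 2.0) / math.pi
    return Thresholds(xi=xi, omega_pos=1.0 - omega_neg, omega_neg=omega_neg)


def step(
    prev: EmotionState,
    stimulus: Sequence | np.ndarray,
    phi: Sequence | np.ndarray,
    config: DynamicsConfig,
) -> EmotionState:
    """One day of the recurrence: decay, add stimulus and bias, clip."""
    stim = np.asarray(stimulus, dtype=float)
    bias = np.asarray(phi, dtype=float)
    if stim.shape != (6,) or bias.shape != (6,):
        raise ValidationError(
            f"stimulus and personality bias must have 6 components, got "
            f"{stim.shape} and {bias.shape}"
        )
    decayed = decay(prev, config.lambda_).intensities
    return EmotionState(prev.t + 1, clip_to_valence(decayed + stim + bias))


def activate(state: EmotionState, th: Thresholds) -> ActivationVector:
    """Threshold comparison: which emotions are expressed at this step.

    Positive emotions are expressed when intensity >= omega_pos; negative
    emotions when |intensity| >= omega_neg (negative intensities are stored
    signed, thresholds are magnitudes).
    """
    arr = state.intensities
    expressed = [False] * 6
    for i in _POS:
        expressed[i] = arr[i] >= th.omega_pos
    for i in _NEG:
        expressed[i] = abs(arr[i]) >= th.omega_neg
    values = np.where(expressed, arr, 0.0)
    return ActivationVector(tuple(expressed), values)


def run_dynamics(
    p: PersonalityProfile,
    schedule: Mapping[int, Sequence | np.ndarray],
    config: DynamicsConfig,
    horizon: int,
    k: np.ndarray | None = None,
    f: np.ndarray | None = None,
) -> list[tuple[EmotionState, ActivationVector]]:
    """Iterate the recurrence from an all-zero state over ``horizon`` days.

    ``schedule`` maps 1-based day indices to 6-component stimulus vectors.
    In "sustained" mode each scheduled stimulus is re-applied on the
    following ``sustain_steps - 1`` days as well.  Day t of the returned
    sequence depends only on schedule entries at days <= t.
    """
    if horizon < 1:
        raise ValidationError(f"horizon must be >= 1, got {horizon}")
    for day in schedule:
        if not 1 <= day <= horizon:
            raise ValidationError(
                f"schedule day {day} outside [1, {horizon}]"
            )
    phi = personality_influence(p, k=k, f=f, gain=config.gain)
    thresholds = threshold_estimate(p)
    repeats = config.sustain_steps if config.stimulus_mode == "sustained" else 1
    daily_stimulus = {t: np.zeros(6) for t in range(1, horizon + 1)}
    for day, vec in schedule.items():
        arr = np.asarray(vec, dtype=float)
        if arr.shape != (6,):
            raise ValidationError(
                f"schedule stimulus at day {day} must have 6 components, "
                f"got shape {arr.shape}"
            )
        for t in range(day, min(day + repeats, horizon + 1)):
            daily_stimulus[t] = daily_stimulus[t] + arr
    state = EmotionState.zero(t=0)
    out: list[tuple[EmotionState, ActivationVector]] = []
    for t in range(1, horizon + 1):
        state = step(state, daily_stimulus[t], phi, config)
        out.append((state, activate(state, thresholds)))
    return out
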