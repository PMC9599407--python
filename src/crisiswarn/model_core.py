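"""Personality → mood → emotion mapping chain.

The model projects a Big-Five personality vector ``P = [o, c, e, a, n]``
into PAD mood space (Pleasure, Arousal, Dominance) with a 3x5 regression
matrix ``K``, projects the mood point onto 24 appraisal-theoretic (OCC)
emotion categories with a 3x24 matrix ``F`` whose columns are the PAD
coordinates of those categories, and finally collapses the 24 categories
onto Ekman's six basic emotions (disgust, anger, surprise, fear, joy,
sadness).  The result, scaled by a small gain and signed by valence, is the
constant personality bias that enters the emotion-intensity recurrence at
every time step.

Vector and matrix orders used throughout the package:

* Ekman order: ``(dis, ang, sur, fea, joy, sad)`` — indices 0..5.
* Negative-valence components: dis, ang, fea, sad (stored in [-1, 0]);
  positive-valence: sur, joy (stored in [0, 1]).
* Big-Five column order for ``K``: ``(o, c, e, a, n)``.
* OCC column order for ``F``: :data:`OCC_EMOTIONS`.

The default ``K`` is the Big-Five → PAD linear regression used by the ALMA
affect model (openness, conscientiousness, extraversion, agreeableness,
neuroticism as predictors of each PAD axis).  The default ``F`` columns are
the published PAD coordinates of the OCC categories from the same
literature; Disgust and Surprise, which are not OCC categories, take the
PAD coordinates of the corresponding emotion terms from Mehrabian's
emotion-term scaling.  Both matrices are configuration, not dogma: they can
be replaced wholesale through the run configuration file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "EKMAN_EMOTIONS",
    "OCC_EMOTIONS",
    "NEGATIVE_INDICES",
    "POSITIVE_INDICES",
    "VALENCE_SIGN",
    "BIG_FIVE_TRAITS",
    "PersonalityProfile",
    "DEFAULT_PERSONALITY_MOOD_MAP",
    "DEFAULT_MOOD_EMOTION_MAP",
    "mood_from_personality",
    "occ_from_mood",
    "ekman_from_occ",
    "personality_influence",
]

#: Ekman basic-emotion order used for every 6-component vector in the package.
EKMAN_EMOTIONS: tuple[str, ...] = ("dis", "ang", "sur", "fea", "joy", "sad")

#: Indices of negative-valence emotions (intensities live in [-1, 0]).
NEGATIVE_INDICES: tuple[int, ...] = (0, 1, 3, 5)

#: Indices of positive-valence emotions (intensities live in [0, 1]).
POSITIVE_INDICES: tuple[int, ...] = (2, 4)

#: Valence sign per Ekman component: -1 for negative emotions, +1 for positive.
VALENCE_SIGN = np.array([-1.0, -1.0, 1.0, -1.0, 1.0, -1.0])

BIG_FIVE_TRAITS: tuple[str, ...] = ("o", "c", "e", "a", "n")

#: Fixed order of the 24 OCC emotion categories (columns of F).
OCC_EMOTIONS: tuple[str, ...] = (
    "Disgust",
    "Anger",
    "Reproach",
    "Hate",
    "Surprise",
    "Fear",
    "FearsConfirmed",
    "HappyFor",
    "Gloating",
    "Joy",
    "Pride",
    "Admiration",
    "Liking",
    "Love",
    "Hope",
    "Satisfaction",
    "Relief",
    "Gratification",
    "Gratitude",
    "Resentment",
    "Pity",
    "Distress",
    "Shame",
    "Remorse",
)

# OCC categories feeding each Ekman component.  Joy averages the 12 distinct
# positively valenced categories (the frequently reprinted 14-term listing
# duplicates Relief and Gratification but still divides by 12).
_EKMAN_FROM_OCC_TERMS: dict[str, tuple[str, ...]] = {
    "dis": ("Disgust",),
    "ang": ("Anger", "Reproach", "Hate"),
    "sur": ("Surprise",),
    "fea": ("Fear", "FearsConfirmed"),
    "joy": (
        "HappyFor",
        "Gloating",
        "Joy",
        "Pride",
        "Admiration",
        "Liking",
        "Love",
        "Hope",
        "Satisfaction",
        "Relief",
        "Gratification",
        "Gratitude",
    ),
    "sad": ("Resentment", "Pity", "Distress", "Shame", "Remorse"),
}

# Big-Five -> PAD regression (rows: P, A, D; columns: o, c, e, a, n).
DEFAULT_PERSONALITY_MOOD_MAP = np.array(
    [
        [0.00, 0.00, 0.21, 0.59, 0.19],
        [0.15, 0.00, 0.00, 0.30, -0.57],
        [0.25, 0.17, 0.60, -0.32, 0.00],
    ]
)

# PAD coordinates of the 24 OCC categories (columns follow OCC_EMOTIONS).
_OCC_PAD_COORDINATES: dict[str, tuple[float, float, float]] = {
    "Disgust": (-0.60, 0.35, 0.11),
    "Anger": (-0.51, 0.59, 0.25),
    "Reproach": (-0.30, -0.10, 0.40),
    "Hate": (-0.60, 0.60, 0.30),
    "Surprise": (0.40, 0.67, -0.13),
    "Fear": (-0.64, 0.60, -0.43),
    "FearsConfirmed": (-0.50, -0.30, -0.70),
    "HappyFor": (0.40, 0.20, 0.20),
    "Gloating": (0.30, -0.30, -0.10),
    "Joy": (0.40, 0.20, 0.10),
    "Pride": (0.40, 0.30, 0.30),
    "Admiration": (0.50, 0.30, -0.20),
    "Liking": (0.40, 0.16, -0.24),
    "Love": (0.30, 0.10, 0.20),
    "Hope": (0.20, 0.20, -0.10),
    "Satisfaction": (0.30, -0.20, 0.40),
    "Relief": (0.20, -0.30, 0.40),
    "Gratification": (0.60, 0.50, 0.40),
    "Gratitude": (0.40, 0.20, -0.30),
    "Resentment": (-0.20, -0.30, -0.20),
    "Pity": (-0.40, -0.20, -0.50),
    "Distress": (-0.40, -0.20, -0.50),
    "Shame": (-0.30, 0.10, -0.60),
    "Remorse": (-0.30, 0.10, -0.60),
}

DEFAULT_MOOD_EMOTION_MAP = np.array(
    [_OCC_PAD_COORDINATES[name] for name in OCC_EMOTIONS]
).T


@dataclass(frozen=True)
class PersonalityProfile:
    """Big-Five personality scores, each in [0, 1].

    Attributes follow the OCEAN convention: openness, conscientiousness
    ("cautious"), extraversion, agreeableness, neuroticism.
    """

    o: float
    c: float
    e: float
    a: float
    n: float

    def __post_init__(self) -> None:
        for trait in BIG_FIVE_TRAITS:
            value = getattr(self, trait)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"personality trait {trait!r} must lie in [0, 1], got {value!r}"
                )

    @classmethod
    def from_sequence(cls, values: Iterable[float]) -> "PersonalityProfile":
        vals = [float(v) for v in values]
        if len(vals) != 5:
            raise ValidationError(
                f"personality vector must have exactly 5 components, got {len(vals)}"
            )
        return cls(*vals)

    def as_array(self) -> np.ndarray:
        return np.array([self.o, self.c, self.e, self.a, self.n])


def _as_matrix(m: Sequence | np.ndarray, shape: tuple[int, int], name: str) -> np.ndarray:
    arr = np.asarray(m, dtype=float)
    if arr.shape != shape:
        raise ConfigurationError(
            f"transfer matrix {name} must have shape {shape}, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError(f"transfer matrix {name} contains non-finite entries")
    return arr


def mood_from_personality(
    p: PersonalityProfile, k: np.ndarray | None = None
) -> np.ndarray:
    """Project a personality vector into PAD mood space: ``M = P @ K.T``.

    Returns the (pleasure, arousal, dominance) coordinates as a length-3
    array.
    """
    k = DEFAULT_PERSONALITY_MOOD_MAP if k is None else _as_matrix(k, (3, 5), "K")
    return p.as_array() @ k.T


def occ_from_mood(m: Sequence | np.ndarray, f: np.ndarray | None = None) -> np.ndarray:
    """Project a PAD mood point onto the 24 OCC categories: ``O = M @ F``."""
    mood = np.asarray(m, dtype=float)
    if mood.shape != (3,):
        raise ConfigurationError(
            f"mood vector must have shape (3,), got {mood.shape}"
        )
    f = DEFAULT_MOOD_EMOTION_MAP if f is None else _as_matrix(f, (3, 24), "F")
    return mood @ f


def ekman_from_occ(o: Sequence | np.ndarray) -> np.ndarray:
    """Collapse a 24-component OCC vector onto Ekman's six basic emotions.

    Disgust and surprise pass through; anger, fear, joy and sadness are the
    means of their contributing OCC categories (3, 2, 12 and 5 terms).
    """
    occ = np.asarray(o, dtype=float)
    if occ.shape != (24,):
        raise ConfigurationError(
            f"OCC vector must have shape (24,), got {occ.shape}"
        )
    index = {name: i for i, name in enumerate(OCC_EMOTIONS)}
    return np.array(
        [
            float(np.mean([occ[index[t]] for t in _EKMAN_FROM_OCC_TERMS[name]]))
            for name in EKMAN_EMOTIONS
        ]
    )


def personality_influence(
    p: PersonalityProfile,
    k: np.ndarray | None = None,
    f: np.ndarray | None = None,
    gain: float = 0.1,
) -> np.ndarray:
    """Constant personality bias Phi(P) on the six signed emotion intensities.

    Composes the mapping chain, scales each component by ``gain`` and signs
    it by valence: negative emotions (dis, ang, fea, sad) contribute
    ``-|value|``, positive emotions (sur, joy) ``+|value|``.  The result is
    constant over time for a fixed personality.
    """
    if gain < 0:
        raise ConfigurationError(f"personality gain must be >= 0, got {gain}")
    ekman = ekman_from_occ(occ_from_mood(mood_from_personality(p, k), f))
    return VALENCE_SIGN * np.abs(ekman) * gain
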