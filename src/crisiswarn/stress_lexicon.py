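"""Stress-event lexicon: loading, text matching, stimulus assembly.

A stress-event lexicon maps trigger phrases to life events (dropping out,
failing an exam, bereavement, ...) and assigns each event a 6-component
stimulus vector on the Ekman axes ``(dis, ang, sur, fea, joy, sad)`` plus a
non-negative weight in the spirit of Life-Events-Units checklists.  A post
"expresses" an event when its normalised text contains a trigger phrase;
matching is case-folded substring search so that unsegmented scripts
(e.g. Chinese) work without tokenisation.  A per-offset longest-match rule
resolves nested phrases, and each event counts once per time step no matter
how often it is mentioned.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "LexiconEntry",
    "EventDetection",
    "load_lexicon",
    "parse_lexicon",
    "default_lexicon_path",
    "load_default_lexicon",
    "normalize_text",
    "detect_events",
    "stimulus_from_events",
]

_STIMULUS_COLUMNS = (
    "stim_dis",
    "stim_ang",
    "stim_sur",
    "stim_fea",
    "stim_joy",
    "stim_sad",
)
_HEADER = ("event_id", "phrase", "weight") + _STIMULUS_COLUMNS


@dataclass(frozen=True)
class LexiconEntry:
    """One trigger phrase with its per-emotion stimulus and weight."""

    event_id: str
    phrase: str
    stimulus: tuple[float, ...]  # (dis, ang, sur, fea, joy, sad), each in [-1, 1]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not normalize_text(self.phrase):
            raise ValidationError(
                f"lexicon entry {self.event_id!r} has an empty phrase"
            )
        if len(self.stimulus) != 6:
            raise ValidationError(
                f"lexicon entry {self.event_id!r} needs 6 stimulus components, "
                f"got {len(self.stimulus)}"
            )
        for value in self.stimulus:
            if not -1.0 <= value <= 1.0:
                raise ValidationError(
                    f"lexicon entry {self.event_id!r} stimulus component "
                    f"{value!r} outside [-1, 1]"
                )
        if self.weight < 0:
            raise ValidationError(
                f"lexicon entry {self.event_id!r} weight must be >= 0"
            )


@dataclass(frozen=True)
class EventDetection:
    """One phrase occurrence in one post (0-based half-open span)."""

    event_id: str
    phrase: str
    start: int
    end: int
    post_id: str = ""


def normalize_text(text: str) -> str:
    """NFKC-normalise and case-fold text for matching."""
    return unicodedata.normalize("NFKC", text).casefold()


def parse_lexicon(lines: Iterable[str], source: str = "<memory>") -> list[LexiconEntry]:
    """Parse lexicon rows from an iterable of TSV lines.

    The first non-comment line must be the header ``event_id  phrase  weight
    stim_dis .. stim_sad``.  ``#`` lines are comments.  Duplicate
    (event_id, phrase) pairs are rejected.
    """
    entries: list[LexiconEntry] = []
    seen: set[tuple[str, str]] = set()
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen:
            if tuple(f.strip() for f in fields) != _HEADER:
                raise ValidationError(
                    f"{source}:{lineno}: expected header {' '.join(_HEADER)}"
                )
            header_seen = True
            continue
        if len(fields) != len(_HEADER):
            raise ValidationError(
                f"{source}:{lineno}: expected {len(_HEADER)} tab-separated "
                f"fields, got {len(fields)}"
            )
        event_id, phrase, weight_s, *stim_s = (f.strip() for f in fields)
        try:
            weight = float(weight_s)
            stimulus = tuple(float(s) for s in stim_s)
        except ValueError as exc:
            raise ValidationError(f"{source}:{lineno}: {exc}") from None
        try:
            entry = LexiconEntry(event_id, phrase, stimulus, weight)
        except ValidationError as exc:
            raise ValidationError(f"{source}:{lineno}: {exc}") from None
        key = (entry.event_id, normalize_text(entry.phrase))
        if key in seen:
            raise ValidationError(
                f"{source}:{lineno}: duplicate lexicon entry {key!r}"
            )
        seen.add(key)
        entries.append(entry)
    if not header_seen:
        raise ValidationError(f"{source}: missing lexicon header")
    return entries


def load_lexicon(path: str | Path) -> list[LexiconEntry]:
    """Load a TSV stress-event lexicon from ``path``."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        return parse_lexicon(fh, source=str(path))


def default_lexicon_path() -> Path:
    """Path of the bundled fixture lexicon (synthetic, non-validated)."""
    return Path(resources.files("crisiswarn").joinpath("data/default_lexicon.tsv"))


def load_default_lexicon() -> list[LexiconEntry]:
    return load_lexicon(default_lexicon_path())


def detect_events(
    text: str,
    lexicon: Sequence[LexiconEntry],
    post_id: str = "",
    token_boundaries: bool = False,
) -> list[EventDetection]:
    """Find non-overlapping trigger-phrase occurrences in ``text``.

    Matching is case-folded substring search on the normalised text; with
    ``token_boundaries`` a match must additionally be flanked by
    non-alphanumeric characters (for space-delimited languages).  Candidates
    are resolved left to right, with the longest phrase winning at each
    offset; accepted matches do not overlap.
    """
    hay = normalize_text(text)
    if not hay:
        return []
    candidates: list[tuple[int, int, str, str]] = []  # (start, -len, id, phrase)
    for entry in lexicon:
        needle = normalize_text(entry.phrase)
        start = hay.find(needle)
        while start != -1:
            end = start + len(needle)
            ok = True
            if token_boundaries:
                before = hay[start - 1] if start > 0 else " "
                after = hay[end] if end < len(hay) else " "
                ok = not before.isalnum() and not after.isalnum()
            if ok:
                candidates.append((start, -len(needle), entry.event_id, entry.phrase))
            start = hay.find(needle, start + 1)
    candidates.sort()
    detections: list[EventDetection] = []
    cursor = 0
    for start, neg_len, event_id, phrase in candidates:
        if start < cursor:
            continue
        detections.append(
            EventDetection(event_id, phrase, start, start - neg_len, post_id)
        )
        cursor = start - neg_len
    return detections


def stimulus_from_events(
    detections: Iterable[EventDetection],
    lexicon: Sequence[LexiconEntry],
) -> np.ndarray:
    """Combine detections into one 6-component stimulus vector.

    Each detected event counts once per time step; the weighted stimulus
    vectors of the unique events are summed component-wise and clipped to
    [-1, 1].
    """
    by_id: Mapping[str, LexiconEntry] = {e.event_id: e for e in lexicon}
    total = np.zeros(6)
    seen: set[str] = set()
    for det in detections:
        if det.event_id in seen:
            continue
        entry = by_id.get(det.event_id)
        if entry is None:
            raise ValidationError(
                f"detection references unknown event_id {det.event_id!r}"
            )
        seen.add(det.event_id)
        total += entry.weight * np.asarray(entry.stimulus)
    return np.clip(total, -1.0, 1.0)
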