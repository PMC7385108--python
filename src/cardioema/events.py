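"""Experience-sampling events: change scores and within-person standardization.

An event is one prompt with a 6-dimensional physiological change score —
the feature vector of the 30 s following the prompt minus that of the 30 s
preceding it — plus the self-report attached to the prompt (valence/arousal
on -50..+50, at least one free-text emotion word with a 1-5 intensity, and
posture).  Change scores are standardized within person before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

import numpy as np

from .signals import FEATURE_NAMES, FeatureVector, KubicekParams, extract_features

if TYPE_CHECKING:  # pragma: no cover
    from .synthdata import RawRecording

#: inclusion rule: a participant needs at least this many usable events
MIN_USABLE_EVENTS = 70

#: pre/post window length in seconds
CHANGE_WINDOW_S = 30.0


@dataclass
class Event:
    """One experience-sampling prompt with physiology and self-report."""

    participant_id: str
    event_id: int
    prompt_time: float
    change: Optional[np.ndarray] = None       # post - pre, raw units
    z: Optional[np.ndarray] = None            # within-person standardized
    pre: Optional[FeatureVector] = None
    post: Optional[FeatureVector] = None
    valence: float = np.nan                   # -50..+50
    arousal: float = np.nan
    words: list = field(default_factory=list)  # [(word, intensity 1-5), ...]
    posture: str = "sitting"
    quality: str = "usable"                   # 'usable' | 'artifact'
    true_component: Optional[int] = None      # generator ground truth

    def __post_init__(self) -> None:
        if self.change is not None:
            self.change = np.asarray(self.change, dtype=float)
            if self.change.shape != (len(FEATURE_NAMES),):
                raise ValueError("change must be a 6-vector")
        for v, name in ((self.valence, "valence"), (self.arousal, "arousal")):
            if np.isfinite(v) and abs(v) > 50:
                raise ValueError(f"{name} outside [-50, 50]")


def compute_change_scores(recording: "RawRecording", prompt_time: float,
                          participant_id: str = "p0", event_id: int = 0,
                          params: Optional[KubicekParams] = None,
                          window_s: float = CHANGE_WINDOW_S,
                          anchor_offset_s: float = 0.0) -> Event:
    """Physiological part of an event: post-window minus pre-window features.

    Windows are half-open and anchored at ``prompt_time + anchor_offset_s``
    (a negative offset anchors at the IBI-change onset instead of the
    prompt): pre = [anchor - 30 s, anchor), post = [anchor, anchor + 30 s).
    If any feature is missing on either side the event is flagged
    ``artifact`` (insufficient signal is an artifact event, not an
    exception).
    """
    duration = recording.ecg.size / recording.fs
    ev = Event(participant_id, event_id, prompt_time)
    anchor = prompt_time + anchor_offset_s
    if anchor - window_s < 0 or anchor + window_s > duration:
        ev.quality = "artifact"
        return ev
    ev.pre = extract_features(recording, (anchor - window_s, anchor), params)
    ev.post = extract_features(recording, (anchor, anchor + window_s), params)
    ev.change = ev.post.as_array() - ev.pre.as_array()
    if not (ev.pre.complete and ev.post.complete):
        ev.quality = "artifact"
    return ev


def standardize_within_person(events: list, ddof: int = 1) -> list:
    """Fill ``z`` on usable events: per-feature (change - mean) / SD.

    The SD uses the sample convention (``ddof=1``) over that participant's
    usable events.  A zero-variance feature is an error naming the feature.
    """
    usable = [e for e in events if e.quality == "usable" and e.change is not None]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable events to standardize")
    X = np.vstack([e.change for e in usable])
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    for j, s in enumerate(sd):
        if s <= 0:
            raise ValueError(f"zero variance in feature '{FEATURE_NAMES[j]}'")
    for e in usable:
        e.z = (e.change - mean) / sd
    return events


def change_matrix(events: list, standardized: bool = False) -> np.ndarray:
    """Stack usable events into an n x 6 matrix (raw or z-scored)."""
    usable = [e for e in events if e.quality == "usable" and e.change is not None]
    if standardized:
        return np.vstack([e.z for e in usable])
    return np.vstack([e.change for e in usable])


def filter_participants(events: Iterable[Event],
                        min_events: int = MIN_USABLE_EVENTS) -> set:
    """Participants with at least ``min_events`` artifact-free events."""
    counts: dict = {}
    for e in events:
        if e.quality == "usable":
            counts[e.participant_id] = counts.get(e.participant_id, 0) + 1
    return {pid for pid, c in counts.items() if c >= min_events}
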