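"""Instant-by-instant engagement levels, affect intensity, and body-part organization.

The head leads engagement-related behavior: an instant counts as engaged
only when the head addresses the game or the partner. Given an engaged head
focus f, the level is

    1  head only at f                (passive attention / social acknowledgement)
    2  head + torso at f             (attentional / social readiness)
    3  head + arms/hands at f        (reduced active participation / social engagement)
    4  head + torso + arms at f      (full active participation / social engagement)

with the task variant when f is the game and the social variant when f is
the partner; anything else is level 0 (no engagement). Reduced active
engagement (3) ranks above readiness (2) because manipulation is a
constructive form of engagement while postural attunement only signals a
readiness to act.

Affect intensity at an instant is the signed count, over body parts directed
at the engaged focus, of positive minus negative valence (-3..+3). The
weighted engagement score sums fixed body-part weights (head 0.50, torso
0.10, arms/hands 0.40) over the parts directed at the engaged focus, giving
a 0..1 score monotone in level.

Body-part organization events follow the Laban body category: ``successive``
(head -> torso -> arms, adjacent parts in order), ``sequential`` (head ->
arms skipping the torso), ``simultaneous`` (all onsets within a small
window), and ``space_hold`` (head, and torso when engaged, locked on the
focus while the arms/hands keep gesturing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import CompletenessError
from .scheme import AFFECT_GESTURE, GROUPS, CodingScheme, Focus
from .streams import BehaviorStream, discretize

__all__ = [
    "EngagementWeights",
    "InstantState",
    "EngagementClass",
    "EngagementTimeline",
    "OrganizationConfig",
    "OrganizationEvent",
    "classify_instant",
    "affect_intensity",
    "weighted_engagement",
    "instant_states",
    "build_timeline",
    "detect_patterns",
]


@dataclass(frozen=True)
class EngagementWeights:
    """Per-body-part importance weights; non-negative, summing to one."""

    head: float = 0.50
    torso: float = 0.10
    arms_hands: float = 0.40

    def __post_init__(self) -> None:
        w = (self.head, self.torso, self.arms_hands)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class InstantState:
    """The three body parts' foci and valences at one time bin."""

    t: float
    head_focus: Focus
    torso_focus: Focus
    arms_focus: Focus
    head_val: str = "neutral"
    torso_val: str = "neutral"
    arms_val: str = "neutral"


_VARIANTS = {
    (0, None): "no_engagement",
    (1, Focus.GAME): "passive_attention",
    (1, Focus.PARTNER): "social_acknowledgement",
    (2, Focus.GAME): "attentional_readiness",
    (2, Focus.PARTNER): "social_readiness",
    (3, Focus.GAME): "reduced_active_participation",
    (3, Focus.PARTNER): "reduced_active_social_engagement",
    (4, Focus.GAME): "full_active_participation",
    (4, Focus.PARTNER): "full_active_social_engagement",
}


@dataclass(frozen=True)
class EngagementClass:
    level: int
    focus: Focus | None
    variant: str


def classify_instant(s: InstantState) -> EngagementClass:
    """Head-led classification of one instant into a level 0-4 and its variant."""
    if s.head_focus not in (Focus.GAME, Focus.PARTNER):
        return EngagementClass(level=0, focus=None, variant="no_engagement")
    f = s.head_focus
    torso = s.torso_focus == f
    arms = s.arms_focus == f
    if torso and arms:
        level = 4
    elif arms:
        level = 3
    elif torso:
        level = 2
    else:
        level = 1
    return EngagementClass(level=level, focus=f, variant=_VARIANTS[(level, f)])


def affect_intensity(s: InstantState) -> int:
    """Signed affect count over body parts directed at the engaged focus (-3..+3)."""
    cls = classify_instant(s)
    if cls.level == 0:
        return 0
    f = cls.focus
    score = 0
    for focus, val in (
        (s.head_focus, s.head_val),
        (s.torso_focus, s.torso_val),
        (s.arms_focus, s.arms_val),
    ):
        if focus == f:
            if val == "positive":
                score += 1
            elif val == "negative":
                score -= 1
    return score


def weighted_engagement(s: InstantState, w: EngagementWeights = EngagementWeights()) -> float:
    """Weighted sum over body parts directed at the engaged focus; 0 at level 0."""
    cls = classify_instant(s)
    if cls.level == 0:
        return 0.0
    f = cls.focus
    total = w.head  # the head defines the engaged focus
    if s.torso_focus == f:
        total += w.torso
    if s.arms_focus == f:
        total += w.arms_hands
    return total


@dataclass
class EngagementTimeline:
    """Per-bin engagement classification plus affect and weighted score."""

    resolution_s: float
    classes: list[EngagementClass]
    affect: list[int]
    weighted: list[float]

    def __len__(self) -> int:
        return len(self.classes)

    def level_budget(self) -> dict[int, float]:
        """Fraction of time spent at each engagement level (0-4)."""
        n = len(self.classes)
        budget = {lv: 0.0 for lv in range(5)}
        for c in self.classes:
            budget[c.level] += 1.0 / n
        return budget

    def mean_weighted(self) -> float:
        return sum(self.weighted) / len(self.weighted)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": [i * self.resolution_s for i in range(len(self.classes))],
                "level": [c.level for c in self.classes],
                "variant": [c.variant for c in self.classes],
                "focus": [c.focus.value if c.focus else "none" for c in self.classes],
                "affect": self.affect,
                "weighted_score": self.weighted,
            }
        )


def _streams_by_group(streams: Iterable[BehaviorStream]) -> dict[str, BehaviorStream]:
    by_group = {s.group: s for s in streams}
    missing = [g for g in GROUPS if g not in by_group]
    if missing:
        raise CompletenessError(f"missing group streams: {missing}")
    return by_group


def _focus_and_valence(scheme: CodingScheme, code: str, modifier: str) -> tuple[Focus, str]:
    bdef = scheme.behavior(code)
    if bdef.focus == AFFECT_GESTURE:
        # affect gestures address no focus; their valence is intrinsic
        return Focus.NONE, bdef.intrinsic_valence
    return bdef.focus, modifier


def instant_states(
    streams: Iterable[BehaviorStream],
    scheme: CodingScheme,
    resolution_s: float = 0.5,
) -> list[InstantState]:
    """Discretize the three group streams into a shared sequence of instants."""
    by_group = _streams_by_group(streams)
    seqs = {g: discretize(by_group[g], resolution_s) for g in GROUPS}
    n = min(len(seqs[g]) for g in GROUPS)
    states = []
    for i in range(n):
        hf, hv = _focus_and_valence(scheme, *seqs["head"].labels[i])
        tf, tv = _focus_and_valence(scheme, *seqs["torso"].labels[i])
        af, av = _focus_and_valence(scheme, *seqs["arms_hands"].labels[i])
        states.append(
            InstantState(
                t=i * resolution_s,
                head_focus=hf,
                torso_focus=tf,
                arms_focus=af,
                head_val=hv,
                torso_val=tv,
                arms_val=av,
            )
        )
    return states


def build_timeline(
    streams: Iterable[BehaviorStream],
    scheme: CodingScheme,
    resolution_s: float = 0.5,
    weights: EngagementWeights = EngagementWeights(),
) -> EngagementTimeline:
    """Time-sampled engagement progression over one participant-session."""
    states = instant_states(streams, scheme, resolution_s)
    return EngagementTimeline(
        resolution_s=resolution_s,
        classes=[classify_instant(s) for s in states],
        affect=[affect_intensity(s) for s in states],
        weighted=[weighted_engagement(s, weights) for s in states],
    )


# ---------------------------------------------------------------------------
# body-part organization patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrganizationConfig:
    epsilon_s: float = 0.5  # simultaneity window
    lag_s: float = 3.0  # max inter-part onset lag for successive/sequential
    hold_min_s: float = 5.0  # minimum space-hold duration

    def __post_init__(self) -> None:
        if not self.epsilon_s < self.lag_s:
            raise ValueError("epsilon_s must be smaller than lag_s")


@dataclass(frozen=True)
class OrganizationEvent:
    kind: str  # successive | sequential | simultaneous | space_hold
    focus: Focus
    parts: tuple[str, ...]
    onset_times: tuple[float, ...]
    duration_s: float


def _focus_episodes(
    stream: BehaviorStream, scheme: CodingScheme, focus: Focus
) -> list[tuple[float, float]]:
    """Maximal intervals during which the stream is directed at ``focus``."""
    episodes: list[tuple[float, float]] = []
    for ev in stream.events:
        f, _ = _focus_and_valence(scheme, ev.behavior, ev.modifier)
        if f != focus:
            continue
        if episodes and abs(episodes[-1][1] - ev.start_s) < 1e-9:
            episodes[-1] = (episodes[-1][0], ev.stop_s)
        else:
            episodes.append((ev.start_s, ev.stop_s))
    return episodes


def _onset_in(episodes: Sequence[tuple[float, float]], lo: float, hi: float) -> float | None:
    """First episode onset strictly in (lo, hi], or None."""
    for start, _ in episodes:
        if lo < start <= hi:
            return start
    return None


def detect_patterns(
    streams: Iterable[BehaviorStream],
    scheme: CodingScheme,
    focus: Focus | None = None,
    config: OrganizationConfig = OrganizationConfig(),
) -> list[OrganizationEvent]:
    """Detect body-part organization events around each head turn to a focus.

    For each head episode directed at the focus: ``simultaneous`` when all
    three onsets fall within ``epsilon_s`` of each other; ``successive``
    when the torso onset follows the head within ``lag_s`` and the arms
    follow the torso within ``lag_s``; ``sequential`` when the arms follow
    the head within ``lag_s`` with no intervening torso onset. A
    ``space_hold`` is appended when the engaged parts then keep the focus
    for at least ``hold_min_s`` while the arms/hands stay active (gesturing)
    rather than at rest.
    """
    by_group = _streams_by_group(streams)
    foci = [focus] if focus is not None else [Focus.GAME, Focus.PARTNER]
    events: list[OrganizationEvent] = []
    for f in foci:
        head_eps = _focus_episodes(by_group["head"], scheme, f)
        torso_eps = _focus_episodes(by_group["torso"], scheme, f)
        arms_eps = _focus_episodes(by_group["arms_hands"], scheme, f)
        for h0, h1 in head_eps:
            torso_on = _onset_in(torso_eps, h0, h0 + config.lag_s)
            kind = None
            if torso_on is not None:
                arms_on = _onset_in(arms_eps, torso_on, torso_on + config.lag_s)
                if arms_on is not None:
                    onsets = (h0, torso_on, arms_on)
                    if max(onsets) - min(onsets) <= config.epsilon_s:
                        kind = "simultaneous"
                    else:
                        kind = "successive"
                    events.append(
                        OrganizationEvent(
                            kind=kind,
                            focus=f,
                            parts=("head", "torso", "arms_hands"),
                            onset_times=onsets,
                            duration_s=max(onsets) - h0,
                        )
                    )
            if kind is None:
                arms_on = _onset_in(arms_eps, h0, h0 + config.lag_s)
                if arms_on is not None and torso_on is None:
                    onsets = (h0, arms_on)
                    events.append(
                        OrganizationEvent(
                            kind="sequential",
                            focus=f,
                            parts=("head", "arms_hands"),
                            onset_times=onsets,
                            duration_s=arms_on - h0,
                        )
                    )
                elif arms_on is None and torso_on is None:
                    continue  # head-only turn; no multi-part organization
            # space hold: engaged parts keep f while arms stay active
            chain_end = max(t for t in (h0, torso_on, arms_on) if t is not None)
            hold_parts = ["head"]
            hold_end = h1
            if torso_on is not None:
                t_ep = next((e for e in torso_eps if e[0] == torso_on), None)
                if t_ep is not None:
                    hold_parts.append("torso")
                    hold_end = min(hold_end, t_ep[1])
            arms_active_end = None
            if arms_on is not None:
                a_ep = next((e for e in arms_eps if e[0] == arms_on), None)
                if a_ep is not None:
                    arms_active_end = a_ep[1]
            if arms_active_end is not None:
                hold_dur = min(hold_end, arms_active_end) - chain_end
                if hold_dur >= config.hold_min_s:
                    events.append(
                        OrganizationEvent(
                            kind="space_hold",
                            focus=f,
                            parts=tuple(hold_parts),
                            onset_times=(chain_end,),
                            duration_s=hold_dur,
                        )
                    )
    events.sort(key=lambda e: e.onset_times[0])
    return events
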