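"""Duration percentages and the six body-part engagement scores.

Every behavior's share of the observation is computed as a percentage of the
session duration, so within a body-part group the percentages sum to 100.
The six engagement scores per participant-session each range from -100
(complete disengagement) to 100 (complete engagement):

    GAct          = (GP + GG) - (GFE + NoneH)
    LTAct         = (LIP + NRLTG) - NoneT
    RoAct         = (RoP + MG) - (RoFE + NoneAH)
    GAct_gsup     = (GP_pos + GG_pos) - (GP_neg + GG_neg)
    LTAct_postsup = (LIP_pos + NRLTG_pos) - (LIP_neg + NRLTG_neg)
    RoAct_qogest  = (RoP_pos + MG_pos + SOA_pos) - (RoP_neg + MG_neg + SOA_neg)

Behaviors directed at the game or the partner count as engagement-related;
those directed at the facilitator/experimenter or at no focus count as
disengagement-related. The affect scores subtract negatively modified time
from positively modified time; neutral time contributes to behavior
percentages only. The signs-of-affection gestures (SOApos/SOAneg) enter
RoAct_qogest through their intrinsic valence but not RoAct, while still
counting toward the arms/hands 100% total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import CompletenessError, IntegrityError
from .scheme import AFFECT_GESTURE, GROUPS, CodingScheme
from .streams import BehaviorStream

__all__ = [
    "SCORE_NAMES",
    "DurationTable",
    "ScoreRow",
    "ScoreTable",
    "duration_table",
    "reduce_scores",
    "build_score_table",
]

SCORE_NAMES = (
    "GAct",
    "LTAct",
    "RoAct",
    "GAct_gsup",
    "LTAct_postsup",
    "RoAct_qogest",
)


@dataclass
class DurationTable:
    """Per-behavior and per-(behavior, valence) duration percentages for one participant-session."""

    session_id: str
    participant_id: str
    behavior_pct: dict[str, float]
    modifier_pct: dict[tuple[str, str], float]
    activity: str | None = None

    def pct(self, code: str) -> float:
        return self.behavior_pct.get(code, 0.0)

    def mod(self, code: str, valence: str) -> float:
        return self.modifier_pct.get((code, valence), 0.0)


@dataclass(frozen=True)
class ScoreRow:
    """The six engagement scores for one participant-session.

    Scores derived from a duration table necessarily lie in [-100, 100]
    because each group's percentages sum to 100; ``in_range`` checks this.
    """

    session_id: str
    participant_id: str
    GAct: float
    LTAct: float
    RoAct: float
    GAct_gsup: float
    LTAct_postsup: float
    RoAct_qogest: float
    activity: str | None = None

    def in_range(self) -> bool:
        return all(
            -100.0 - 1e-9 <= getattr(self, name) <= 100.0 + 1e-9
            for name in SCORE_NAMES
        )


@dataclass
class ScoreTable:
    """One ScoreRow per (session, participant); keys are unique."""

    rows: list[ScoreRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.session_id, r.participant_id) for r in self.rows]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise IntegrityError(f"duplicate (session, participant) keys: {dup}")

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "session_id": r.session_id,
                    "participant_id": r.participant_id,
                    "activity": r.activity,
                    **{name: getattr(r, name) for name in SCORE_NAMES},
                }
                for r in self.rows
            ],
            columns=["session_id", "participant_id", "activity", *SCORE_NAMES],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScoreTable":
        rows = [
            ScoreRow(
                session_id=str(row["session_id"]),
                participant_id=str(row["participant_id"]),
                activity=(None if pd.isna(row.get("activity")) else str(row["activity"])),
                **{name: float(row[name]) for name in SCORE_NAMES},
            )
            for _, row in df.iterrows()
        ]
        return cls(rows=rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        return cls.from_frame(pd.read_csv(path))


def duration_table(
    streams: Iterable[BehaviorStream],
    scheme: CodingScheme,
    activity: str | None = None,
) -> DurationTable:
    """Duration percentages for one participant-session's three group streams.

    ``behavior_pct[b]`` is 100 x (total time in b) / duration; the valence
    split ``modifier_pct[(b, valence)]`` accumulates the intervals of b
    carrying a positive or negative modifier. All three body-part groups
    must be present.
    """
    streams = list(streams)
    keys = {(s.session_id, s.participant_id, s.coder_id) for s in streams}
    if len(keys) != 1:
        raise CompletenessError(
            f"streams must belong to a single participant-session/coder, got {sorted(keys)}"
        )
    present = {s.group for s in streams}
    missing = [g for g in GROUPS if g not in present]
    if missing:
        key = next(iter(keys))
        raise CompletenessError(f"participant-session {key} is missing groups {missing}")

    behavior_pct: dict[str, float] = {b.code: 0.0 for b in scheme.behaviors}
    modifier_pct: dict[tuple[str, str], float] = {}
    for stream in streams:
        dur = stream.duration_s
        for ev in stream.events:
            share = 100.0 * ev.duration_s / dur
            behavior_pct[ev.behavior] = behavior_pct.get(ev.behavior, 0.0) + share
            bdef = scheme.behavior(ev.behavior)
            valence = (
                bdef.intrinsic_valence
                if bdef.focus == AFFECT_GESTURE
                else (ev.modifier if ev.modifier in ("positive", "negative") else None)
            )
            if valence is not None:
                k = (ev.behavior, valence)
                modifier_pct[k] = modifier_pct.get(k, 0.0) + share
    s0 = streams[0]
    return DurationTable(
        session_id=s0.session_id,
        participant_id=s0.participant_id,
        behavior_pct=behavior_pct,
        modifier_pct=modifier_pct,
        activity=activity,
    )


def reduce_scores(dt: DurationTable) -> ScoreRow:
    """Apply the six reduction formulas to a duration table."""
    p, m = dt.pct, dt.mod
    return ScoreRow(
        session_id=dt.session_id,
        participant_id=dt.participant_id,
        activity=dt.activity,
        GAct=(p("GP") + p("GG")) - (p("GFE") + p("NoneH")),
        LTAct=(p("LIP") + p("NRLTG")) - p("NoneT"),
        RoAct=(p("RoP") + p("MG")) - (p("RoFE") + p("NoneAH")),
        GAct_gsup=(m("GP", "positive") + m("GG", "positive"))
        - (m("GP", "negative") + m("GG", "negative")),
        LTAct_postsup=(m("LIP", "positive") + m("NRLTG", "positive"))
        - (m("LIP", "negative") + m("NRLTG", "negative")),
        RoAct_qogest=(m("RoP", "positive") + m("MG", "positive") + p("SOApos"))
        - (m("RoP", "negative") + m("MG", "negative") + p("SOAneg")),
    )


def build_score_table(
    streams: Iterable[BehaviorStream],
    scheme: CodingScheme,
    activities: Mapping[str, str] | None = None,
) -> ScoreTable:
    """Score a whole cohort: one ScoreRow per (session, participant).

    ``activities`` optionally maps session_id to its activity type
    (``cognitive_games`` / ``robot_play``). Streams from more than one coder
    are rejected; score one coder's annotations at a time.
    """
    by_ps: dict[tuple[str, str], list[BehaviorStream]] = {}
    coders = set()
    for s in streams:
        coders.add(s.coder_id)
        by_ps.setdefault((s.session_id, s.participant_id), []).append(s)
    if len(coders) > 1:
        raise IntegrityError(
            f"score one coder at a time; got coders {sorted(coders)}"
        )
    rows = []
    for (session, participant), group_streams in sorted(by_ps.items()):
        activity = activities.get(session) if activities else None
        dt = duration_table(group_streams, scheme, activity=activity)
        rows.append(reduce_scores(dt))
    return ScoreTable(rows=rows)
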