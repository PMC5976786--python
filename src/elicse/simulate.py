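"""Synthetic study data: score tables, session streams, coder noise, cohorts.

Two generation layers serve different tests. The score-level generator draws
the six engagement scores directly from the linear recursive structure of
the engagement path model, isolating the estimator from behavioral
dynamics. The stream-level generator emulates 20-25 minute dyadic sessions
of the two activity types with a head-led semi-Markov focus process: the
head dwells on a focus (game, partner, facilitator/experimenter, none) with
gamma-distributed dwell times; on a head turn to the game or the partner,
the torso follows with some probability after a short lag and the arms/hands
after a further lag, producing the successive body-part organization that
dominates real sessions. Affect bouts are superimposed on directional
states at an activity-dependent rate: rare during game-based cognitive
stimulation, frequent during robot-based free play.

Default dwell means are calibrated so the head is at the game about 88% of
the time in cognitive games and about 73% in robot play, matching the
observed duration shares of gaze toward the game in the two activities.

A two-coder noise model perturbs a reference annotation (boundary jitter,
label substitution, dropped short events) to exercise the inter-rater
reliability machinery. All randomness flows from explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .scheme import CodingScheme, Focus, default_elicse_scheme
from .scores import SCORE_NAMES, ScoreRow, ScoreTable, build_score_table
from .sem import emodeb_model
from .streams import AnnotationEvent, BehaviorStream, write_event_log

__all__ = [
    "ScoreSimConfig",
    "StreamSimConfig",
    "CoderNoiseConfig",
    "emodeb_true_coefficients",
    "simulate_scores",
    "simulate_session_streams",
    "corrupt_streams",
    "simulate_cohort",
]


def emodeb_true_coefficients() -> dict[tuple[str, str], float]:
    """Reference unstandardized path coefficients for the 9-edge model."""
    return {
        ("GAct", "LTAct"): 0.372,
        ("LTAct", "RoAct"): 0.122,
        ("GAct", "RoAct"): 0.349,
        ("GAct", "GAct_gsup"): 0.240,
        ("RoAct", "RoAct_qogest"): -0.255,
        ("GAct_gsup", "LTAct_postsup"): 0.390,
        ("LTAct_postsup", "RoAct_qogest"): 0.845,
        ("GAct_gsup", "RoAct_qogest"): 0.112,
        ("LTAct", "LTAct_postsup"): -0.218,
    }


# ---------------------------------------------------------------------------
# score-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoreSimConfig:
    n: int = 84
    path_coefficients: Mapping[tuple[str, str], float] = field(
        default_factory=emodeb_true_coefficients
    )
    intercepts: Mapping[str, float] | None = None
    error_sd: Mapping[str, float] | None = None  # default 10 per endogenous variable
    exo_mean: float = 78.0
    exo_sd: float = 12.0
    activity_mix: float = 0.5
    activity_offsets: Mapping[str, float] | None = None
    clip: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.activity_mix <= 1.0:
            raise ValueError("activity_mix must lie in [0, 1]")


def simulate_scores(c: ScoreSimConfig) -> tuple[ScoreTable, dict]:
    """Draw a score table from the linear recursive structure.

    GAct comes from its Gaussian marginal; each endogenous variable is
    intercept + sum(coefficient x parent) + Gaussian error, generated in
    topological order. Returns the table and a truth record of the
    generating parameters.
    """
    rng = np.random.default_rng(c.seed)
    model = emodeb_model()
    intercepts = dict(c.intercepts or {})
    error_sd = {v: 10.0 for v in model.endogenous}
    error_sd.update(c.error_sd or {})
    for v in model.endogenous:
        if error_sd[v] <= 0:
            raise ValueError(f"error_sd[{v}] must be positive")
    offsets = dict(c.activity_offsets or {})

    activity = np.where(
        rng.random(c.n) < c.activity_mix, "robot_play", "cognitive_games"
    )
    values: dict[str, np.ndarray] = {}
    for v in model.topological_order():
        if v in model.exogenous:
            x = rng.normal(c.exo_mean, c.exo_sd, size=c.n)
        else:
            x = np.full(c.n, intercepts.get(v, 0.0))
            for parent in model.parents(v):
                x = x + c.path_coefficients[(parent, v)] * values[parent]
            x = x + rng.normal(0.0, error_sd[v], size=c.n)
        if v in offsets:
            x = x + np.where(activity == "robot_play", offsets[v], 0.0)
        if c.clip:
            x = np.clip(x, -100.0, 100.0)
        values[v] = x

    rows = [
        ScoreRow(
            session_id=f"sim{i:04d}",
            participant_id="p1",
            activity=str(activity[i]),
            **{name: float(values[name][i]) for name in SCORE_NAMES},
        )
        for i in range(c.n)
    ]
    truth = {
        "path_coefficients": dict(c.path_coefficients),
        "intercepts": intercepts,
        "error_sd": error_sd,
        "exo_mean": c.exo_mean,
        "exo_sd": c.exo_sd,
        "seed": c.seed,
    }
    return ScoreTable(rows=rows), truth


# ---------------------------------------------------------------------------
# stream-level simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StreamSimConfig:
    """Semi-Markov session generator parameters for one participant-session."""

    duration_s: float = 1320.0  # 22 min, within the 20-25 min session range
    activity: str = "cognitive_games"
    session_id: str = "s1"
    participant_id: str = "p1"
    coder_id: str = "c1"
    # mean dwell (s) per head focus; calibrated to observed duration shares
    dwell_means: Mapping[str, float] | None = None
    dwell_shape: float = 2.0  # gamma shape for dwell times
    p_torso: float = 0.75  # per-episode probability the torso follows the head
    p_arms: float = 0.90  # per-episode probability the arms follow
    lag_bounds: tuple[float, float] = (0.5, 2.5)  # uniform inter-part onset lag
    affect_rate_per_min: float | None = None  # default depends on activity
    affect_bout_mean_s: float = 4.0
    p_positive: float = 0.85
    engagement_propensity: float = 0.0  # tilts head-at-game dwell, log-scale
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.p_torso, self.p_arms, self.p_positive):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    def resolved_dwell_means(self) -> dict[str, float]:
        if self.dwell_means is not None:
            means = dict(self.dwell_means)
        elif self.activity == "robot_play":
            # head-at-game share 44/60 ~ 73%
            means = {"game": 44.0, "partner": 4.0, "facilitator_experimenter": 4.0, "none": 8.0}
        else:
            # head-at-game share 66/75 = 88%
            means = {"game": 66.0, "partner": 2.5, "facilitator_experimenter": 3.5, "none": 3.0}
        if any(v <= 0 for v in means.values()):
            raise ValueError("dwell means must be positive")
        tilt = math.exp(self.engagement_propensity)
        return {f: (m * tilt if f == "game" else m / tilt) for f, m in means.items()}

    def resolved_affect_rate(self) -> float:
        if self.affect_rate_per_min is not None:
            return self.affect_rate_per_min
        return 2.0 if self.activity == "robot_play" else 0.2


_HEAD_BEHAVIOR = {
    Focus.GAME: "GG",
    Focus.PARTNER: "GP",
    Focus.FACILITATOR_EXPERIMENTER: "GFE",
    Focus.NONE: "NoneH",
}
_TORSO_BEHAVIOR = {Focus.GAME: "NRLTG", Focus.PARTNER: "LIP"}
_ARMS_BEHAVIOR = {Focus.GAME: "MG", Focus.PARTNER: "RoP"}


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _follow_prob(base: float, propensity: float) -> float:
    if base <= 0.0 or base >= 1.0:
        return base
    return _sigmoid(math.log(base / (1.0 - base)) + propensity)


def _segments_to_events(
    segments: list[tuple[str, str, float, float]],
    key: tuple[str, str, str, str],
) -> BehaviorStream:
    """Merge zero-length-free contiguous segments into a validated stream."""
    events = []
    merged: list[list] = []
    for behavior, modifier, start, stop in segments:
        if stop - start <= 1e-9:
            continue
        if merged and merged[-1][0] == behavior and merged[-1][1] == modifier and abs(
            merged[-1][3] - start
        ) < 1e-9:
            merged[-1][3] = stop
        else:
            merged.append([behavior, modifier, start, stop])
    session, participant, coder, group = key
    for behavior, modifier, start, stop in merged:
        start_r, stop_r = round(start, 3), round(stop, 3)
        if stop_r <= start_r:  # collapsed by rounding; neighbor re-closes the gap
            continue
        events.append(
            AnnotationEvent(
                session_id=session,
                participant_id=participant,
                coder_id=coder,
                group=group,
                behavior=behavior,
                modifier=modifier,
                start_s=start_r,
                stop_s=stop_r,
            )
        )
    # re-close any rounding gaps
    fixed = []
    for i, ev in enumerate(events):
        start = fixed[-1].stop_s if fixed else 0.0
        if ev.stop_s <= start:
            continue
        fixed.append(replace(ev, start_s=start))
    duration = fixed[-1].stop_s if fixed else 0.0
    return BehaviorStream(key=key, events=fixed, duration_s=duration)


def simulate_session_streams(c: StreamSimConfig) -> list[BehaviorStream]:
    """Generate the three group streams of one participant-session.

    Constructive guarantee: the returned streams are mutually exclusive and
    exhaustive (they always pass validation with zero errors).
    """
    rng = np.random.default_rng(c.seed)
    dwell = c.resolved_dwell_means()
    T = c.duration_s

    # head semi-Markov chain over the four foci
    foci = [Focus.GAME, Focus.PARTNER, Focus.FACILITATOR_EXPERIMENTER, Focus.NONE]
    head: list[tuple[Focus, float, float]] = []
    t = 0.0
    current = Focus.GAME if rng.random() < 0.8 else Focus.NONE
    while t < T:
        mean = dwell[current.value]
        length = rng.gamma(c.dwell_shape, mean / c.dwell_shape)
        stop = min(t + max(length, 0.2), T)
        head.append((current, t, stop))
        t = stop
        others = [f for f in foci if f != current]
        current = others[int(rng.integers(len(others)))]

    # torso and arms follow engaged head episodes after a lag
    p_torso = _follow_prob(c.p_torso, c.engagement_propensity)
    p_arms = _follow_prob(c.p_arms, c.engagement_propensity)
    torso: list[tuple[Focus, float, float]] = []
    arms: list[tuple[Focus, float, float]] = []
    for focus, start, stop in head:
        if focus not in (Focus.GAME, Focus.PARTNER):
            continue
        lag1 = rng.uniform(*c.lag_bounds)
        follows_torso = rng.random() < p_torso and start + lag1 < stop
        if follows_torso:
            torso.append((focus, start + lag1, stop))
        if rng.random() < p_arms:
            lag2 = rng.uniform(*c.lag_bounds)
            onset = (start + lag1 + lag2) if follows_torso else (start + lag1)
            if onset < stop:
                arms.append((focus, onset, stop))

    def fill(
        episodes: list[tuple[Focus, float, float]],
        behavior_map: Mapping[Focus, str],
        none_code: str,
        group: str,
    ) -> list[tuple[str, str, float, float]]:
        segs: list[tuple[str, str, float, float]] = []
        t0 = 0.0
        for focus, start, stop in sorted(episodes, key=lambda e: e[1]):
            start = max(start, t0)
            if start >= stop:
                continue
            if start > t0:
                segs.append((none_code, "neutral", t0, start))
            segs.append((behavior_map[focus], "neutral", start, stop))
            t0 = stop
        if t0 < T:
            segs.append((none_code, "neutral", t0, T))
        return segs

    head_segs = [
        (_HEAD_BEHAVIOR[f], "neutral", start, stop) for f, start, stop in head
    ]
    torso_segs = fill(torso, _TORSO_BEHAVIOR, "NoneT", "torso")
    arms_segs = fill(arms, _ARMS_BEHAVIOR, "NoneAH", "arms_hands")

    # affect bouts: modifiers over directional states during the bout window
    rate = c.resolved_affect_rate()
    n_bouts = rng.poisson(rate * T / 60.0)
    bouts = []
    for _ in range(n_bouts):
        b0 = rng.uniform(0.0, T)
        b1 = min(b0 + rng.exponential(c.affect_bout_mean_s), T)
        valence = "positive" if rng.random() < c.p_positive else "negative"
        bouts.append((b0, b1, valence))

    directional = {
        "GG",
        "GP",
        "NRLTG",
        "LIP",
        "MG",
        "RoP",
    }

    def overlay(segs: list[tuple[str, str, float, float]]):
        for b0, b1, valence in bouts:
            out = []
            for behavior, modifier, start, stop in segs:
                if behavior not in directional or stop <= b0 or start >= b1:
                    out.append((behavior, modifier, start, stop))
                    continue
                if start < b0:
                    out.append((behavior, modifier, start, b0))
                out.append((behavior, valence, max(start, b0), min(stop, b1)))
                if stop > b1:
                    out.append((behavior, modifier, b1, stop))
            segs = out
        return segs

    key = (c.session_id, c.participant_id, c.coder_id)
    return [
        _segments_to_events(overlay(head_segs), (*key, "head")),
        _segments_to_events(overlay(torso_segs), (*key, "torso")),
        _segments_to_events(overlay(arms_segs), (*key, "arms_hands")),
    ]


# ---------------------------------------------------------------------------
# two-coder noise model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoderNoiseConfig:
    jitter_sd_s: float = 0.0  # boundary perturbation (truncated Gaussian)
    substitution_prob: float = 0.0  # per-event label swap probability
    miss_below_s: float = 0.0  # events shorter than this are absorbed
    coder_id: str = "c2"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.jitter_sd_s < 0 or self.substitution_prob < 0 or self.miss_below_s < 0:
            raise ValueError("noise parameters must be >= 0")


def corrupt_streams(
    streams: Iterable[BehaviorStream],
    c: CoderNoiseConfig,
    scheme: CodingScheme | None = None,
) -> list[BehaviorStream]:
    """Produce a noisy second-coder version of a reference annotation.

    Interior boundaries are jittered order-preservingly, labels substituted
    within the behavior's group, and sub-threshold events absorbed into the
    preceding event; the output remains a valid exhaustive partition.
    """
    scheme = scheme or default_elicse_scheme()
    rng = np.random.default_rng(c.seed)
    out: list[BehaviorStream] = []
    for stream in streams:
        segs = [
            [e.behavior, e.modifier, e.start_s, e.stop_s] for e in stream.events
        ]
        if c.jitter_sd_s > 0:
            for i in range(len(segs) - 1):
                b = segs[i][3]
                lo = segs[i][2] + 0.05
                hi = segs[i + 1][3] - 0.05
                if hi <= lo:
                    continue
                nb = float(np.clip(b + rng.normal(0.0, c.jitter_sd_s), lo, hi))
                segs[i][3] = nb
                segs[i + 1][2] = nb
        if c.miss_below_s > 0:
            kept: list[list] = []
            for seg in segs:
                if seg[3] - seg[2] < c.miss_below_s and kept:
                    kept[-1][3] = seg[3]  # neighbor extension
                else:
                    kept.append(seg)
            segs = kept
        if c.substitution_prob > 0:
            codes = scheme.group_codes(stream.group)
            for seg in segs:
                if rng.random() < c.substitution_prob:
                    alternatives = [x for x in codes if x != seg[0]]
                    seg[0] = alternatives[rng.integers(len(alternatives))]
        session, participant, _, group = stream.key
        new = _segments_to_events(
            [tuple(s) for s in segs], (session, participant, c.coder_id, group)
        )
        # preserve the declared duration exactly
        if new.events and new.events[-1].stop_s != stream.duration_s:
            last = new.events[-1]
            new.events[-1] = replace(last, stop_s=stream.duration_s)
        new.duration_s = stream.duration_s
        out.append(new)
    return out


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    paper_sized: bool = True,
    seed: int | None = 0,
    duration_s: float = 1320.0,
    n_couples: int | None = None,
    n_sessions: int | None = None,
    propensity_sd: float = 0.6,
) -> tuple[pd.DataFrame, dict]:
    """Generate a full cohort event log plus a truth record.

    The study shape is seven couples (14 participants), each observed in six
    sessions alternating between game-based cognitive stimulation and
    robot-based free play: 42 session recordings, 84 participant-sessions,
    21 sessions of each activity. A per-participant engagement propensity
    (plus session noise) couples the head, torso and arms/hands processes so
    the derived scores carry the positive head-to-torso association the
    model expects.
    """
    if paper_sized:
        n_couples, n_sessions = 7, 6
    else:
        n_couples = n_couples or 2
        n_sessions = n_sessions or 2
    rng = np.random.default_rng(seed)
    streams: list[BehaviorStream] = []
    activities: dict[str, str] = {}
    truth_sessions: dict[str, dict] = {}
    base_prop = {
        f"p{2*i + j + 1:02d}": rng.normal(0.0, propensity_sd)
        for i in range(n_couples)
        for j in range(2)
    }
    for couple in range(1, n_couples + 1):
        participants = (f"p{2*couple - 1:02d}", f"p{2*couple:02d}")
        for sess in range(1, n_sessions + 1):
            session_id = f"c{couple}s{sess}"
            activity = "cognitive_games" if sess % 2 == 1 else "robot_play"
            activities[session_id] = activity
            for pid in participants:
                prop = base_prop[pid] + rng.normal(0.0, 0.3)
                cfg = StreamSimConfig(
                    duration_s=duration_s,
                    activity=activity,
                    session_id=session_id,
                    participant_id=pid,
                    engagement_propensity=prop,
                    seed=int(rng.integers(2**31 - 1)),
                )
                streams.extend(simulate_session_streams(cfg))
                truth_sessions[f"{session_id}/{pid}"] = {
                    "activity": activity,
                    "engagement_propensity": prop,
                }
    log = write_event_log(streams)
    truth = {
        "seed": seed,
        "activities": activities,
        "sessions": truth_sessions,
        "path_coefficients": {
            f"{parent}->{child}": v
            for (parent, child), v in emodeb_true_coefficients().items()
        },
    }
    return log, truth


def score_cohort_log(log: pd.DataFrame, truth: dict, scheme: CodingScheme | None = None) -> ScoreTable:
    """Convenience: parse a simulated cohort log and build its score table."""
    from .streams import parse_event_log

    scheme = scheme or default_elicse_scheme()
    streams = parse_event_log(log, scheme)
    return build_score_table(streams, scheme, activities=truth.get("activities"))
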