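import numpy as np
import pytest

from elicse import (
    AnnotationEvent,
    BehaviorStream,
    default_elicse_scheme,
)


@pytest.fixture(scope="session")
def scheme():
    return default_elicse_scheme()


def make_stream(group, segments, duration=None, session="s1", participant="p1", coder="c1"):
    """Build a stream from (behavior, start, stop[, modifier]) tuples."""
    events = []
    for seg in segments:
        behavior, start, stop = seg[:3]
        modifier = seg[3] if len(seg) > 3 else "neutral"
        events.append(
            AnnotationEvent(
                session_id=session,
                participant_id=participant,
                coder_id=coder,
                group=group,
                behavior=behavior,
                modifier=modifier,
                start_s=float(start),
                stop_s=float(stop),
            )
        )
    if duration is None:
        duration = max(e.stop_s for e in events)
    return BehaviorStream(
        key=(session, participant, coder, group), events=events, duration_s=float(duration)
    )


def full_session(duration=60.0, head="GG", torso="NRLTG", arms="MG", modifier="neutral", **kw):
    """Three single-state streams covering [0, duration]."""
    return [
        make_stream("head", [(head, 0, duration, modifier)], duration, **kw),
        make_stream("torso", [(torso, 0, duration, modifier)], duration, **kw),
        make_stream("arms_hands", [(arms, 0, duration, modifier)], duration, **kw),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
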