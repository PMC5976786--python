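"""Engagement levels, affect intensity, weighted scores, organization patterns."""

import itertools

import pytest

from elicse import (
    EngagementWeights,
    Focus,
    InstantState,
    OrganizationConfig,
    affect_intensity,
    build_timeline,
    classify_instant,
    detect_patterns,
    weighted_engagement,
)

from conftest import full_session, make_stream

FOCI = [Focus.GAME, Focus.PARTNER, Focus.FACILITATOR_EXPERIMENTER, Focus.NONE]
VALS = ["positive", "negative", "neutral"]


def instant(head, torso, arms, hv="neutral", tv="neutral", av="neutral"):
    return InstantState(
        t=0.0, head_focus=head, torso_focus=torso, arms_focus=arms,
        head_val=hv, torso_val=tv, arms_val=av,
    )


def brute_force_level(head, torso, arms):
    """Independent rule table: head-led level and variant."""
    if head not in (Focus.GAME, Focus.PARTNER):
        return 0, "no_engagement"
    names = {
        (1, Focus.GAME): "passive_attention",
        (1, Focus.PARTNER): "social_acknowledgement",
        (2, Focus.GAME): "attentional_readiness",
        (2, Focus.PARTNER): "social_readiness",
        (3, Focus.GAME): "reduced_active_participation",
        (3, Focus.PARTNER): "reduced_active_social_engagement",
        (4, Focus.GAME): "full_active_participation",
        (4, Focus.PARTNER): "full_active_social_engagement",
    }
    level = {
        (False, False): 1,
        (True, False): 2,
        (False, True): 3,
        (True, True): 4,
    }[(torso == head, arms == head)]
    return level, names[(level, head)]


class TestClassifier:
    @pytest.mark.parametrize(
        "head,torso,arms,level,variant",
        [
            ("GG", "NRLTG", "MG", 4, "full_active_participation"),
            ("GP", "NoneT", "NoneAH", 1, "social_acknowledgement"),
            ("GG", "NoneT", "MG", 3, "reduced_active_participation"),
            ("NoneH", "NRLTG", "MG", 0, "no_engagement"),  # head-led rule
        ],
    )
    def test_reference_configurations(self, scheme, head, torso, arms, level, variant):
        foci = {c: scheme.focus_of(c) for c in (head, torso, arms)}
        s = instant(foci[head], foci[torso], foci[arms])
        cls = classify_instant(s)
        assert (cls.level, cls.variant) == (level, variant)

    def test_exhaustive_against_rule_table(self):
        # classifier is pure and total over all 4^3 focus combinations
        for head, torso, arms in itertools.product(FOCI, repeat=3):
            cls = classify_instant(instant(head, torso, arms))
            level, variant = brute_force_level(head, torso, arms)
            assert (cls.level, cls.variant) == (level, variant)

    def test_mixed_foci_follow_the_head(self):
        cls = classify_instant(instant(Focus.PARTNER, Focus.GAME, Focus.GAME))
        assert cls.level == 1 and cls.focus == Focus.PARTNER


class TestAffect:
    def test_all_positive_full_engagement(self):
        s = instant(Focus.GAME, Focus.GAME, Focus.GAME, "positive", "positive", "positive")
        assert affect_intensity(s) == 3

    def test_neutral_gives_zero(self):
        s = instant(Focus.GAME, Focus.GAME, Focus.GAME)
        assert affect_intensity(s) == 0

    def test_signed_count_cancels(self):
        s = instant(Focus.GAME, Focus.GAME, Focus.GAME, "positive", "neutral", "negative")
        assert affect_intensity(s) == 0

    def test_exhaustive_bounds_and_rule(self):
        # over all 4^3 x 3^3 combinations: bounded by engaged parts, matches
        # an independent signed count
        for head, torso, arms in itertools.product(FOCI, repeat=3):
            for hv, tv, av in itertools.product(VALS, repeat=3):
                s = instant(head, torso, arms, hv, tv, av)
                a = affect_intensity(s)
                level, _ = brute_force_level(head, torso, arms)
                if level == 0:
                    assert a == 0
                    continue
                sign = {"positive": 1, "negative": -1, "neutral": 0}
                expected = sum(
                    sign[v]
                    for f, v in [(head, hv), (torso, tv), (arms, av)]
                    if f == head
                )
                assert a == expected
                engaged = 1 + (torso == head) + (arms == head)
                assert abs(a) <= engaged


class TestWeightedScore:
    def test_levels_map_to_expected_weights(self):
        g, n = Focus.GAME, Focus.NONE
        cases = {
            (g, n, n): 0.50,  # level 1
            (g, g, n): 0.60,  # level 2
            (g, n, g): 0.90,  # level 3
            (g, g, g): 1.00,  # level 4
            (n, g, g): 0.00,  # level 0
        }
        for (h, t, a), expected in cases.items():
            assert weighted_engagement(instant(h, t, a)) == pytest.approx(expected)

    def test_monotone_in_level(self):
        g, n = Focus.GAME, Focus.NONE
        scores = [
            weighted_engagement(instant(*cfg))
            for cfg in [(n, n, n), (g, n, n), (g, g, n), (g, n, g), (g, g, g)]
        ]
        assert scores == sorted(scores)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            EngagementWeights(head=0.7, torso=0.2, arms_hands=0.2)


class TestTimeline:
    def test_fully_engaged_session(self, scheme):
        tl = build_timeline(full_session(), scheme, resolution_s=1.0)
        assert tl.level_budget()[4] == pytest.approx(1.0)
        assert tl.mean_weighted() == pytest.approx(1.0)

    def test_alternating_budget(self, scheme):
        # half the session head-only, half fully engaged
        streams = [
            make_stream("head", [("GG", 0, 60)]),
            make_stream("torso", [("NoneT", 0, 30), ("NRLTG", 30, 60)]),
            make_stream("arms_hands", [("NoneAH", 0, 30), ("MG", 30, 60)]),
        ]
        tl = build_timeline(streams, scheme, resolution_s=1.0)
        budget = tl.level_budget()
        assert budget[1] == pytest.approx(0.5)
        assert budget[4] == pytest.approx(0.5)

    def test_budget_stable_under_refinement(self, scheme):
        streams = [
            make_stream("head", [("GG", 0, 25.3), ("NoneH", 25.3, 60)]),
            make_stream("torso", [("NRLTG", 0, 40.1), ("NoneT", 40.1, 60)]),
            make_stream("arms_hands", [("MG", 0, 33.3), ("NoneAH", 33.3, 60)]),
        ]
        coarse = build_timeline(streams, scheme, resolution_s=1.0).level_budget()
        fine = build_timeline(streams, scheme, resolution_s=0.5).level_budget()
        # at most one boundary bin per transition may move per level
        for lv in range(5):
            assert abs(coarse[lv] - fine[lv]) <= 3 * 1.0 / 60.0


class TestPatterns:
    def test_successive_then_space_hold(self, scheme):
        streams = [
            make_stream("head", [("NoneH", 0, 1e-3), ("GG", 1e-3, 32)], duration=32),
            make_stream("torso", [("NoneT", 0, 1), ("NRLTG", 1, 32)], duration=32),
            make_stream("arms_hands", [("NoneAH", 0, 2), ("MG", 2, 32)], duration=32),
        ]
        kinds = [e.kind for e in detect_patterns(streams, scheme, focus=Focus.GAME)]
        assert kinds == ["successive", "space_hold"]

    def test_simultaneous_onsets(self, scheme):
        streams = [
            make_stream("head", [("NoneH", 0, 0.1), ("GG", 0.1, 30)], duration=30),
            make_stream("torso", [("NoneT", 0, 0.3), ("NRLTG", 0.3, 30)], duration=30),
            make_stream("arms_hands", [("NoneAH", 0, 0.4), ("MG", 0.4, 30)], duration=30),
        ]
        events = detect_patterns(
            streams, scheme, focus=Focus.GAME,
            config=OrganizationConfig(epsilon_s=0.5, lag_s=3.0, hold_min_s=50.0),
        )
        assert [e.kind for e in events] == ["simultaneous"]

    def test_sequential_skips_torso(self, scheme):
        streams = [
            make_stream("head", [("NoneH", 0, 1e-3), ("GG", 1e-3, 30)], duration=30),
            make_stream("torso", [("NoneT", 0, 30)], duration=30),
            make_stream("arms_hands", [("NoneAH", 0, 2), ("MG", 2, 30)], duration=30),
        ]
        events = detect_patterns(
            streams, scheme, focus=Focus.GAME,
            config=OrganizationConfig(hold_min_s=50.0),
        )
        assert [e.kind for e in events] == ["sequential"]
        assert events[0].parts == ("head", "arms_hands")

    def test_lag_beyond_threshold_breaks_chain(self, scheme):
        streams = [
            make_stream("head", [("NoneH", 0, 1e-3), ("GG", 1e-3, 40)], duration=40),
            make_stream("torso", [("NoneT", 0, 10), ("NRLTG", 10, 40)], duration=40),
            make_stream("arms_hands", [("NoneAH", 0, 12), ("MG", 12, 40)], duration=40),
        ]
        events = detect_patterns(
            streams, scheme, focus=Focus.GAME,
            config=OrganizationConfig(hold_min_s=500.0),
        )
        assert all(e.kind not in ("successive", "sequential", "simultaneous") for e in events)
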