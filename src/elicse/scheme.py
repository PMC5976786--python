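"""The ELICSE coding scheme: body-part groups, behaviors, foci, and affect modifiers.

ELICSE (Ethographic and Laban-Inspired Coding System of Engagement) annotates
dyadic activity sessions of people with dementia with three mutually exclusive
behavior groups — head, torso, arms/hands — whose behaviors are directional
shapes toward one of four foci (the partner, the facilitator/experimenter, the
game, or none of them), plus positive/negative/neutral affect modifiers.
Facilitator and experimenter are a single operational focus because every
scored behavior merges them (GFE, RoFE).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import yaml

from .errors import SchemaError

__all__ = [
    "Focus",
    "AFFECT_GESTURE",
    "GROUPS",
    "MODIFIERS",
    "BehaviorDef",
    "CodingScheme",
    "default_elicse_scheme",
]


class Focus(str, Enum):
    """Target of a directional behavior.

    ``GAME`` denotes the board games during cognitive stimulation or the
    robot during free play, depending on the activity.
    """

    PARTNER = "partner"
    FACILITATOR_EXPERIMENTER = "facilitator_experimenter"
    GAME = "game"
    NONE = "none"


#: Pseudo-focus for arm/hand affect gestures (applause, dancing hands) that do
#: not address a focus but carry an intrinsic positive or negative valence.
AFFECT_GESTURE = "affect_gesture"

GROUPS = ("head", "torso", "arms_hands")
MODIFIERS = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class BehaviorDef:
    """One scored behavior: its code, body-part group, focus and description."""

    code: str
    group: str
    focus: Focus | str
    intrinsic_valence: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(f"unknown group {self.group!r} for behavior {self.code!r}")
        is_affect = self.focus == AFFECT_GESTURE
        if is_affect != (self.intrinsic_valence is not None):
            raise SchemaError(
                f"behavior {self.code!r}: intrinsic_valence must be set iff "
                f"focus is {AFFECT_GESTURE!r}"
            )
        if self.intrinsic_valence is not None and self.intrinsic_valence not in (
            "positive",
            "negative",
        ):
            raise SchemaError(
                f"behavior {self.code!r}: intrinsic_valence must be positive/negative"
            )
        if not is_affect and not isinstance(self.focus, Focus):
            object.__setattr__(self, "focus", Focus(self.focus))


@dataclass
class CodingScheme:
    """The full behavior inventory: three groups, behaviors, modifiers.

    Invariants (checked at construction): exactly the three body-part groups
    are populated, codes are unique, and each group contains exactly one
    "none" behavior so that streams can be exhaustive.
    """

    behaviors: list[BehaviorDef]
    modifiers: tuple[str, ...] = MODIFIERS

    def __post_init__(self) -> None:
        codes = [b.code for b in self.behaviors]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise SchemaError(f"duplicate behavior codes: {dup}")
        present = {b.group for b in self.behaviors}
        if present != set(GROUPS):
            raise SchemaError(f"scheme must populate exactly the groups {GROUPS}, got {sorted(present)}")
        for g in GROUPS:
            nones = [b for b in self.group_behaviors(g) if b.focus == Focus.NONE]
            if len(nones) != 1:
                raise SchemaError(f"group {g!r} must contain exactly one 'none' behavior")
        self._by_code = {b.code: b for b in self.behaviors}

    # -- lookups ---------------------------------------------------------

    @property
    def groups(self) -> tuple[str, ...]:
        return GROUPS

    def behavior(self, code: str) -> BehaviorDef:
        try:
            return self._by_code[code]
        except KeyError:
            raise SchemaError(f"unknown behavior code {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def group_behaviors(self, group: str) -> list[BehaviorDef]:
        return [b for b in self.behaviors if b.group == group]

    def group_codes(self, group: str) -> list[str]:
        return [b.code for b in self.group_behaviors(group)]

    def none_behavior(self, group: str) -> BehaviorDef:
        return next(b for b in self.group_behaviors(group) if b.focus == Focus.NONE)

    def focus_of(self, code: str) -> Focus | str:
        return self.behavior(code).focus

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "modifiers": list(self.modifiers),
            "behaviors": [
                {
                    "code": b.code,
                    "group": b.group,
                    "focus": b.focus.value if isinstance(b.focus, Focus) else b.focus,
                    "intrinsic_valence": b.intrinsic_valence,
                    "description": b.description,
                }
                for b in self.behaviors
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodingScheme":
        try:
            behaviors = [
                BehaviorDef(
                    code=row["code"],
                    group=row["group"],
                    focus=row["focus"],
                    intrinsic_valence=row.get("intrinsic_valence"),
                    description=row.get("description", ""),
                )
                for row in d["behaviors"]
            ]
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed scheme document: {exc}") from exc
        return cls(behaviors=behaviors, modifiers=tuple(d.get("modifiers", MODIFIERS)))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "CodingScheme":
        """Load a scheme from a YAML or JSON document."""
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        try:
            d = json.loads(text)
        except json.JSONDecodeError:
            d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise SchemaError(f"scheme file {path} does not contain a mapping")
        return cls.from_dict(d)


def default_elicse_scheme() -> CodingScheme:
    """The ELICSE inventory used with dementia dyads in cognitive games and robot play.

    Head: GP (gaze partner), GFE (gaze facilitator/experimenter), GG (gaze
    game), NoneH. Torso: LIP (lean in partner), NRLTG (near reach / lean
    toward game), NoneT — the torso has no facilitator-directed behavior.
    Arms/hands: RoP (reach out partner), RoFE (reach out facilitator/
    experimenter), MG (manipulate game), SOApos/SOAneg (signs of affection,
    gestural and intrinsically valenced), NoneAH.
    """
    P, FE, G, N = (
        Focus.PARTNER,
        Focus.FACILITATOR_EXPERIMENTER,
        Focus.GAME,
        Focus.NONE,
    )
    b = BehaviorDef
    return CodingScheme(
        behaviors=[
            b("GP", "head", P, description="gaze toward the partner"),
            b("GFE", "head", FE, description="gaze toward facilitator/experimenter"),
            b("GG", "head", G, description="gaze toward the game"),
            b("NoneH", "head", N, description="none of the target head movements"),
            b("LIP", "torso", P, description="lean in partner"),
            b("NRLTG", "torso", G, description="near reach/lean toward game"),
            b("NoneT", "torso", N, description="none of the target torso movements"),
            b("RoP", "arms_hands", P, description="reach out partner"),
            b("RoFE", "arms_hands", FE, description="reach out facilitator/experimenter"),
            b("MG", "arms_hands", G, description="manipulate the game"),
            b(
                "SOApos",
                "arms_hands",
                AFFECT_GESTURE,
                intrinsic_valence="positive",
                description="positive signs of affection involving arms/hands",
            ),
            b(
                "SOAneg",
                "arms_hands",
                AFFECT_GESTURE,
                intrinsic_valence="negative",
                description="negative signs of affection involving arms/hands",
            ),
            b("NoneAH", "arms_hands", N, description="none of the target arm/hand movements"),
        ]
    )
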