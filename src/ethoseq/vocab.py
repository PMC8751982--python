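"""Behavior vocabulary for the mantis hunting ethogram.

Twelve mutually exclusive behavior bins label every video frame. Five are
prey-directed ("hunting" regime): the two strike outcomes (successful SS,
missed MS) plus specific translation (ST), rotation (SR) and monitoring
(SM). General monitoring (GM) is a neutral, stationary whole-arena
assessment. The remaining behaviors — general rotation/translation,
grooming, deimatic display, escape — form the nonhunting regime. RESET is
an absorbing marker for experimenter arena resets, not an animal behavior.

Strikes are instantaneous events: a strike occupies a single time step and
carries no dwell duration.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BehaviorCode:
    """One bin of the ethogram vocabulary."""

    code: str
    display_name: str
    regime: str  # 'hunting' | 'neutral' | 'nonhunting' | 'absorbing'
    instantaneous: bool = False


#: Canonical matrix/vector ordering of the 12 behavior bins.
BEHAVIORS: tuple[BehaviorCode, ...] = (
    BehaviorCode("SS", "successful strike", "hunting", instantaneous=True),
    BehaviorCode("MS", "missed strike", "hunting", instantaneous=True),
    BehaviorCode("ST", "specific translation", "hunting"),
    BehaviorCode("SR", "specific rotation", "hunting"),
    BehaviorCode("SM", "specific monitoring", "hunting"),
    BehaviorCode("GM", "general monitoring", "neutral"),
    BehaviorCode("GR", "general rotation", "nonhunting"),
    BehaviorCode("GT", "general translation", "nonhunting"),
    BehaviorCode("GROOM", "grooming", "nonhunting"),
    BehaviorCode("DEIM", "deimatic display", "nonhunting"),
    BehaviorCode("ESC", "escape attempt", "nonhunting"),
    BehaviorCode("RESET", "arena reset", "absorbing"),
)

CODES: tuple[str, ...] = tuple(b.code for b in BEHAVIORS)
BY_CODE: dict[str, BehaviorCode] = {b.code: b for b in BEHAVIORS}
INDEX: dict[str, int] = {b.code: i for i, b in enumerate(BEHAVIORS)}

N_BEHAVIORS = len(BEHAVIORS)  # 12

#: Prey-directed behaviors (both strikes included).
HUNTING: tuple[str, ...] = tuple(b.code for b in BEHAVIORS if b.regime == "hunting")
#: Nonhunting regime proper (excludes neutral GM).
NONHUNTING: tuple[str, ...] = tuple(b.code for b in BEHAVIORS if b.regime == "nonhunting")
#: Instantaneous (strike) codes.
INSTANTANEOUS: tuple[str, ...] = tuple(b.code for b in BEHAVIORS if b.instantaneous)
#: Behaviors that carry dwell time: everything except strikes and RESET.
DURATION_BEHAVIORS: tuple[str, ...] = tuple(
    b.code for b in BEHAVIORS if not b.instantaneous and b.regime != "absorbing"
)
#: All non-absorbing codes, in canonical order.
NONRESET: tuple[str, ...] = tuple(b.code for b in BEHAVIORS if b.regime != "absorbing")

RESET = "RESET"

#: Default video frame rate (frames per second) of the hunting recordings.
DEFAULT_FPS = 29.97

#: Trial length: each hunting bout in the arena runs about seven minutes.
TRIAL_DURATION_S = 420.0

#: Satiety levels: number of prey items consumed before the trial.
FEED_STATES = (0, 1, 2, 3, 4)
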