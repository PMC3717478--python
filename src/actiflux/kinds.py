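"""Activity labels and behavior categories.

Seven activity labels exist: the six reference-protocol activities
(postures and locomotion at three speeds) plus the device-off state
``non_wear``.  Labels are ordered; the integer code is the deterministic
tie-break order used by the classifier.
"""

from __future__ import annotations

from enum import IntEnum


class ActivityKind(IntEnum):
    """The seven epoch-level activity classes."""

    lying = 0
    sitting = 1
    standing = 2
    walk_slow = 3
    walk_fast = 4
    running = 5
    non_wear = 6

    def __str__(self) -> str:  # CSV-friendly
        return self.name


class BehaviorCategory(IntEnum):
    """Aggregated behavior categories used for the daily PA measures."""

    sedentary = 0
    inactive = 1
    mvpa = 2
    very_vigorous = 3
    non_wear = 4

    def __str__(self) -> str:
        return self.name


#: Mapping from activity label to behavior category: lying and sitting are
#: sedentary, standing is inactive, both walking speeds are moderate-to-
#: vigorous physical activity (MVPA), running is very vigorous PA.
CATEGORY_OF: dict[ActivityKind, BehaviorCategory] = {
    ActivityKind.lying: BehaviorCategory.sedentary,
    ActivityKind.sitting: BehaviorCategory.sedentary,
    ActivityKind.standing: BehaviorCategory.inactive,
    ActivityKind.walk_slow: BehaviorCategory.mvpa,
    ActivityKind.walk_fast: BehaviorCategory.mvpa,
    ActivityKind.running: BehaviorCategory.very_vigorous,
    ActivityKind.non_wear: BehaviorCategory.non_wear,
}

ALL_KINDS: tuple[ActivityKind, ...] = tuple(ActivityKind)
REFERENCE_KINDS: tuple[ActivityKind, ...] = tuple(ActivityKind)[:6]

AFFECT_FACTORS: tuple[str, ...] = (
    "pleasantness",
    "unpleasantness",
    "activation",
    "deactivation",
)
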