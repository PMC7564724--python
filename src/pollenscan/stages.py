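"""Developmental stage vocabulary for eggplant microspores and pollen.

Six optical stages span the maturation axis from meiosis to mature pollen:
tetrad -> young microspore -> medium microspore -> vacuolated microspore
-> young pollen -> mature pollen.  A seventh annotation-only code, DOUBTFUL,
flags boxes an annotator could not assign; it is never produced by the
simulator or by a detector.
"""

from __future__ import annotations

import enum


class StageClass(enum.Enum):
    """Pollen developmental stage codes (maturation order)."""

    TETRAD = 1
    YOUNG_MICROSPORE = 2
    MEDIUM_MICROSPORE = 3
    VACUOLATED_MICROSPORE = 4
    YOUNG_POLLEN = 5
    MATURE_POLLEN = 6
    DOUBTFUL = 7

    @property
    def short(self) -> str:
        return _SHORT[self]

    @property
    def maturation_index(self) -> int:
        """Position on the maturation axis, 0 (tetrad) .. 5 (mature pollen)."""
        if self is StageClass.DOUBTFUL:
            raise ValueError("DOUBTFUL has no maturation position")
        return self.value - 1


_SHORT = {
    StageClass.TETRAD: "T",
    StageClass.YOUNG_MICROSPORE: "YM",
    StageClass.MEDIUM_MICROSPORE: "MM",
    StageClass.VACUOLATED_MICROSPORE: "VM",
    StageClass.YOUNG_POLLEN: "YP",
    StageClass.MATURE_POLLEN: "MP",
    StageClass.DOUBTFUL: "DOUBTFUL",
}

#: The six detectable stages, in maturation order (DOUBTFUL excluded).
DETECTABLE_STAGES: tuple[StageClass, ...] = tuple(
    s for s in StageClass if s is not StageClass.DOUBTFUL
)

SHORT_TO_STAGE = {s.short: s for s in StageClass}


def stage_from_any(value) -> StageClass:
    """Coerce a stage given as enum, category id, name or short code."""
    if isinstance(value, StageClass):
        return value
    if isinstance(value, int):
        return StageClass(value)
    key = str(value).strip()
    if key in SHORT_TO_STAGE:
        return SHORT_TO_STAGE[key]
    try:
        return StageClass[key.upper().replace(" ", "_")]
    except KeyError:
        raise ValueError(f"unknown stage {value!r}") from None
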