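"""Five-digit food coding system.

Every single food item carries a short code that fully determines its
component allocation and processing state:

* digit 1 — component type: ``F`` fruit, ``V`` vegetable, ``G`` grain,
  ``P`` protein food, ``D`` dairy, or ``X`` (contributes to no component;
  no further digits).
* digit 2 — group within the type (alphabet below).
* digits 3-4 — item number; a raw food and its processed forms share it.
* digit 5 — processing state, ``0`` raw / ``1`` processed.

Protein and dairy codes stop after the group digit: their equivalents are
computed from protein and calcium content alone, so neither an item number
nor a processing state is needed.

The group alphabet used here covers every distinction the 13-component
scoring requires; users with their own taxonomy can remap it by editing
:data:`GROUP_ALPHABET` and :data:`_GROUP_COMPONENTS`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .components import Component

__all__ = [
    "FoodCode",
    "CodeError",
    "parse_code",
    "format_code",
    "component_of",
    "all_valid_codes",
    "GROUP_ALPHABET",
    "LegumeAllocation",
]

#: Per component-type group letters.
GROUP_ALPHABET: dict[str, str] = {
    "F": "JCO",  # juice, citrus/melons/berries, other whole fruit
    "V": "DRLSO",  # dark green, red/orange, legumes, starchy, other
    "G": "WR",  # whole, refined
    "P": "MUESNYL",  # meat, poultry, eggs, seafood, nuts/seeds, soy, legumes
    "D": "MYCO",  # milk, yogurt, cheese, other dairy
}

RAW = 0
PROCESSED = 1


class CodeError(ValueError):
    """A malformed food code; the message names the offending position."""


class LegumeAllocation(str, Enum):
    """How legume-group vegetable intake is credited across components.

    ``protein_and_vegetables`` is the HEI-2015 convention: legumes count
    toward total vegetables, greens and beans, total protein foods, and
    seafood and plant proteins simultaneously.
    """

    PROTEIN_AND_VEGETABLES = "protein_and_vegetables"
    VEGETABLES_ONLY = "vegetables_only"


@dataclass(frozen=True)
class FoodCode:
    """A parsed, validated food code.

    ``group``, ``item_number`` and ``processing_state`` are ``None`` where the
    grammar omits them (all three for X; the last two for P and D).
    """

    component_type: str
    group: str | None = None
    item_number: int | None = None
    processing_state: int | None = None

    def __post_init__(self) -> None:
        t = self.component_type
        if t == "X":
            if not (self.group is None and self.item_number is None and self.processing_state is None):
                raise CodeError("position 1: 'X' codes carry no further digits")
            return
        if t not in GROUP_ALPHABET:
            raise CodeError(f"position 1: unknown component type {t!r}")
        if self.group is None or self.group not in GROUP_ALPHABET[t]:
            raise CodeError(
                f"position 2: unknown group {self.group!r} for component type {t!r}"
            )
        if t in "PD":
            if self.item_number is not None or self.processing_state is not None:
                raise CodeError(
                    "position 3: protein and dairy codes carry only the first two digits"
                )
            return
        if self.item_number is None or not 0 <= self.item_number <= 99:
            raise CodeError(f"positions 3-4: item number {self.item_number!r} outside 00-99")
        if self.processing_state not in (RAW, PROCESSED):
            raise CodeError(
                f"position 5: processing state {self.processing_state!r} not in {{0, 1}}"
            )

    @property
    def is_raw(self) -> bool:
        return self.processing_state == RAW

    @property
    def item_key(self) -> tuple[str, str, int] | None:
        """(component_type, group, item_number) — shared by raw/processed forms."""
        if self.item_number is None:
            return None
        return (self.component_type, self.group, self.item_number)

    @property
    def is_legume_vegetable(self) -> bool:
        return self.component_type == "V" and self.group == "L"


def parse_code(text: str) -> FoodCode:
    """Parse a 1-5 character food code (case-insensitive).

    Grammar: ``X`` | ``[PD]`` + group | ``[FVG]`` + group + 2-digit item +
    state digit in {0, 1}.
    """
    if not isinstance(text, str) or not text:
        raise CodeError("position 1: empty code")
    s = text.strip().upper()
    t = s[0]
    if t == "X":
        if len(s) != 1:
            raise CodeError("position 2: 'X' codes must be exactly one character")
        return FoodCode("X")
    if t not in GROUP_ALPHABET:
        raise CodeError(f"position 1: unknown component type {t!r}")
    if len(s) < 2:
        raise CodeError("position 2: missing group character")
    group = s[1]
    if group not in GROUP_ALPHABET[t]:
        raise CodeError(f"position 2: unknown group {group!r} for component type {t!r}")
    if t in "PD":
        if len(s) != 2:
            raise CodeError(
                f"position 3: {t!r} codes carry only the first two digits, got {len(s)}"
            )
        return FoodCode(t, group)
    if len(s) != 5:
        raise CodeError(f"position 3: {t!r} codes must be 5 characters, got {len(s)}")
    if not s[2:4].isdigit():
        raise CodeError(f"positions 3-4: item number {s[2:4]!r} is not two digits")
    if s[4] not in "01":
        raise CodeError(f"position 5: processing state {s[4]!r} not in {{0, 1}}")
    return FoodCode(t, group, int(s[2:4]), int(s[4]))


def format_code(code: FoodCode) -> str:
    """Canonical (uppercase) textual form; inverse of :func:`parse_code`."""
    if code.component_type == "X":
        return "X"
    if code.component_type in "PD":
        return f"{code.component_type}{code.group}"
    return f"{code.component_type}{code.group}{code.item_number:02d}{code.processing_state}"


#: Component sets per (type, group); legume vegetables resolved at call time.
_GROUP_COMPONENTS: dict[tuple[str, str], frozenset[Component]] = {
    ("F", "J"): frozenset({Component.TOTAL_FRUITS}),
    ("F", "C"): frozenset({Component.TOTAL_FRUITS, Component.WHOLE_FRUITS}),
    ("F", "O"): frozenset({Component.TOTAL_FRUITS, Component.WHOLE_FRUITS}),
    ("V", "D"): frozenset({Component.TOTAL_VEGETABLES, Component.GREENS_AND_BEANS}),
    ("V", "R"): frozenset({Component.TOTAL_VEGETABLES}),
    ("V", "S"): frozenset({Component.TOTAL_VEGETABLES}),
    ("V", "O"): frozenset({Component.TOTAL_VEGETABLES}),
    ("G", "W"): frozenset({Component.WHOLE_GRAINS}),
    ("G", "R"): frozenset({Component.REFINED_GRAINS}),
    ("P", "M"): frozenset({Component.TOTAL_PROTEIN_FOODS}),
    ("P", "U"): frozenset({Component.TOTAL_PROTEIN_FOODS}),
    ("P", "E"): frozenset({Component.TOTAL_PROTEIN_FOODS}),
    ("P", "S"): frozenset(
        {Component.TOTAL_PROTEIN_FOODS, Component.SEAFOOD_PLANT_PROTEINS}
    ),
    ("P", "N"): frozenset(
        {Component.TOTAL_PROTEIN_FOODS, Component.SEAFOOD_PLANT_PROTEINS}
    ),
    ("P", "Y"): frozenset(
        {Component.TOTAL_PROTEIN_FOODS, Component.SEAFOOD_PLANT_PROTEINS}
    ),
    ("P", "L"): frozenset(
        {Component.TOTAL_PROTEIN_FOODS, Component.SEAFOOD_PLANT_PROTEINS}
    ),
    ("D", "M"): frozenset({Component.DAIRY}),
    ("D", "Y"): frozenset({Component.DAIRY}),
    ("D", "C"): frozenset({Component.DAIRY}),
    ("D", "O"): frozenset({Component.DAIRY}),
}

_LEGUME_VEG: dict[LegumeAllocation, frozenset[Component]] = {
    LegumeAllocation.PROTEIN_AND_VEGETABLES: frozenset(
        {
            Component.TOTAL_VEGETABLES,
            Component.GREENS_AND_BEANS,
            Component.TOTAL_PROTEIN_FOODS,
            Component.SEAFOOD_PLANT_PROTEINS,
        }
    ),
    LegumeAllocation.VEGETABLES_ONLY: frozenset(
        {Component.TOTAL_VEGETABLES, Component.GREENS_AND_BEANS}
    ),
}


def component_of(
    code: FoodCode,
    legume_allocation: LegumeAllocation = LegumeAllocation.PROTEIN_AND_VEGETABLES,
) -> frozenset[Component]:
    """Set of index components the food can contribute to; empty for X."""
    if code.component_type == "X":
        return frozenset()
    if code.is_legume_vegetable:
        return _LEGUME_VEG[legume_allocation]
    return _GROUP_COMPONENTS[(code.component_type, code.group)]


def all_valid_codes(item_numbers: range = range(100)) -> list[FoodCode]:
    """Enumerate the code alphabet (useful for exhaustive round-trip checks)."""
    codes: list[FoodCode] = [FoodCode("X")]
    for t, groups in GROUP_ALPHABET.items():
        for g in groups:
            if t in "PD":
                codes.append(FoodCode(t, g))
            else:
                for i in item_numbers:
                    for state in (RAW, PROCESSED):
                        codes.append(FoodCode(t, g, i, state))
    return codes
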