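"""Scoring standards: per-component thresholds for maximum and minimum score.

Two presets ship with the package:

* ``mhei2015`` — metric standards (gram equivalents, protein grams, calcium
  milligrams per 1000 kcal), calibrated against NHANES 2017-2018 consumption;
* ``hei2015`` — the original imperial standards (cup/ounce equivalents per
  1000 kcal).

The four purely nutrient-based components (fatty-acid ratio, sodium, added
sugars, saturated fats) are identical between the two. Custom standards load
from JSON or YAML in the same schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .components import ALL_COMPONENTS, MAX_POINTS, MODERATION, Component

__all__ = ["ComponentStandard", "ScoringStandards", "MHEI_2015", "HEI_2015", "get_standards"]


@dataclass(frozen=True)
class ComponentStandard:
    """Thresholds for one component.

    ``standard_for_max`` is the density at (or beyond) which full points are
    earned. ``standard_for_min`` applies to moderation components and the
    fatty-acid ratio: the density at (or beyond, in the unfavourable
    direction) which zero points are earned. Adequacy components reach zero
    at density zero, so their ``standard_for_min`` is ``None``.
    """

    max_points: float
    standard_for_max: float
    standard_for_min: float | None
    unit: str

    def __post_init__(self) -> None:
        if self.standard_for_max <= 0:
            raise ValueError("standard_for_max must be positive")


@dataclass(frozen=True)
class ScoringStandards:
    """A complete set of standards for the 13 components."""

    standards_id: str
    components: dict[Component, ComponentStandard]

    def __post_init__(self) -> None:
        missing = [c for c in ALL_COMPONENTS if c not in self.components]
        if missing:
            raise ValueError(f"standards {self.standards_id!r} missing {missing}")
        total = sum(self.components[c].max_points for c in ALL_COMPONENTS)
        if total != 100:
            raise ValueError(f"max points sum to {total}, expected 100")
        for c in MODERATION + (Component.FATTY_ACIDS,):
            cs = self.components[c]
            if cs.standard_for_min is None:
                raise ValueError(f"{c}: moderation/ratio standard_for_min required")
        for c in MODERATION:
            cs = self.components[c]
            if cs.standard_for_min <= cs.standard_for_max:
                raise ValueError(
                    f"{c}: standard_for_min must exceed standard_for_max"
                )

    def __getitem__(self, component: Component) -> ComponentStandard:
        return self.components[component]

    def to_dict(self) -> dict:
        return {
            "standards_id": self.standards_id,
            "components": {
                c.value: {
                    "max_points": cs.max_points,
                    "standard_for_max": cs.standard_for_max,
                    "standard_for_min": cs.standard_for_min,
                    "unit": cs.unit,
                }
                for c, cs in self.components.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringStandards":
        return cls(
            standards_id=d.get("standards_id", "custom"),
            components={
                Component(name): ComponentStandard(
                    max_points=float(v["max_points"]),
                    standard_for_max=float(v["standard_for_max"]),
                    standard_for_min=(
                        float(v["standard_for_min"])
                        if v.get("standard_for_min") is not None
                        else None
                    ),
                    unit=str(v.get("unit", "")),
                )
                for name, v in d["components"].items()
            },
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoringStandards":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)


def _std(
    component: Component, standard_for_max: float, unit: str, standard_for_min: float | None = None
) -> tuple[Component, ComponentStandard]:
    return component, ComponentStandard(
        MAX_POINTS[component], standard_for_max, standard_for_min, unit
    )


#: Metric standards: densities per 1000 kcal in gram equivalents, g protein,
#: mg calcium; moderation thresholds in g equivalents, g sodium, % of energy.
MHEI_2015 = ScoringStandards(
    "mhei2015",
    dict(
        [
            _std(Component.TOTAL_FRUITS, 141, "g eq/1000 kcal"),
            _std(Component.WHOLE_FRUITS, 60, "g eq/1000 kcal"),
            _std(Component.TOTAL_VEGETABLES, 160, "g eq/1000 kcal"),
            _std(Component.GREENS_AND_BEANS, 29, "g eq/1000 kcal"),
            _std(Component.WHOLE_GRAINS, 31, "g eq/1000 kcal"),
            _std(Component.DAIRY, 412, "mg calcium/1000 kcal"),
            _std(Component.TOTAL_PROTEIN_FOODS, 15.6, "g protein/1000 kcal"),
            _std(Component.SEAFOOD_PLANT_PROTEINS, 3.3, "g protein/1000 kcal"),
            _std(Component.FATTY_ACIDS, 2.5, "(PUFA+MUFA)/SFA", 1.2),
            _std(Component.REFINED_GRAINS, 32, "g eq/1000 kcal", 76),
            _std(Component.SODIUM, 1.1, "g/1000 kcal", 2.0),
            _std(Component.ADDED_SUGARS, 6.5, "% of energy", 26),
            _std(Component.SATURATED_FATS, 8, "% of energy", 16),
        ]
    ),
)

#: Imperial HEI-2015 standards (cup/ounce equivalents per 1000 kcal).
HEI_2015 = ScoringStandards(
    "hei2015",
    dict(
        [
            _std(Component.TOTAL_FRUITS, 0.8, "cup eq/1000 kcal"),
            _std(Component.WHOLE_FRUITS, 0.4, "cup eq/1000 kcal"),
            _std(Component.TOTAL_VEGETABLES, 1.1, "cup eq/1000 kcal"),
            _std(Component.GREENS_AND_BEANS, 0.2, "cup eq/1000 kcal"),
            _std(Component.WHOLE_GRAINS, 1.5, "oz eq/1000 kcal"),
            _std(Component.DAIRY, 1.3, "cup eq/1000 kcal"),
            _std(Component.TOTAL_PROTEIN_FOODS, 2.5, "oz eq/1000 kcal"),
            _std(Component.SEAFOOD_PLANT_PROTEINS, 0.8, "oz eq/1000 kcal"),
            _std(Component.FATTY_ACIDS, 2.5, "(PUFA+MUFA)/SFA", 1.2),
            _std(Component.REFINED_GRAINS, 1.8, "oz eq/1000 kcal", 4.3),
            _std(Component.SODIUM, 1.1, "g/1000 kcal", 2.0),
            _std(Component.ADDED_SUGARS, 6.5, "% of energy", 26),
            _std(Component.SATURATED_FATS, 8, "% of energy", 16),
        ]
    ),
)

_PRESETS = {"mhei2015": MHEI_2015, "hei2015": HEI_2015}


def get_standards(preset_or_path: str | Path) -> ScoringStandards:
    """Resolve a preset name ('mhei2015', 'hei2015') or a JSON/YAML file path."""
    if isinstance(preset_or_path, str) and preset_or_path in _PRESETS:
        return _PRESETS[preset_or_path]
    return ScoringStandards.from_file(preset_or_path)
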