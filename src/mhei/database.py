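"""Food database: per-100-g nutrient records keyed by food id.

The canonical exchange format is a CSV with one row per food and columns
``food_id, name, code, energy_kcal, protein_g, calcium_mg, pufa_g, mufa_g,
sfa_g, added_sugars_g, sodium_mg`` — all contents per 100 g of food.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .codes import RAW, CodeError, FoodCode, format_code, parse_code

__all__ = [
    "FoodRecord",
    "FoodDatabase",
    "ValidationIssue",
    "validate_database",
    "read_food_db",
    "write_food_db",
]

DB_COLUMNS = [
    "food_id",
    "name",
    "code",
    "energy_kcal",
    "protein_g",
    "calcium_mg",
    "pufa_g",
    "mufa_g",
    "sfa_g",
    "added_sugars_g",
    "sodium_mg",
]

_NUTRIENT_FIELDS = (
    "energy_kcal_per_100g",
    "protein_g_per_100g",
    "calcium_mg_per_100g",
    "pufa_g_per_100g",
    "mufa_g_per_100g",
    "sfa_g_per_100g",
    "added_sugars_g_per_100g",
    "sodium_mg_per_100g",
)


@dataclass(frozen=True)
class FoodRecord:
    """One food's code and per-100-g nutrient contents."""

    food_id: str
    name: str
    code: FoodCode
    energy_kcal_per_100g: float
    protein_g_per_100g: float = 0.0
    calcium_mg_per_100g: float = 0.0
    pufa_g_per_100g: float = 0.0
    mufa_g_per_100g: float = 0.0
    sfa_g_per_100g: float = 0.0
    added_sugars_g_per_100g: float = 0.0
    sodium_mg_per_100g: float = 0.0
    #: optional explicit gram-equivalent factor for processed foods whose raw
    #: counterpart is absent from the database
    factor_override: float | None = None

    @property
    def fat_g_per_100g(self) -> float:
        return self.pufa_g_per_100g + self.mufa_g_per_100g + self.sfa_g_per_100g


@dataclass
class FoodDatabase:
    """Collection of :class:`FoodRecord`, indexed by id and by code item key."""

    records: dict[str, FoodRecord] = field(default_factory=dict)
    # (component_type, group, item_number) -> {processing_state: record}
    _item_index: dict[tuple[str, str, int], dict[int, FoodRecord]] = field(
        default_factory=dict, repr=False
    )

    def add(self, record: FoodRecord) -> None:
        if record.food_id in self.records:
            raise ValueError(f"duplicate food_id {record.food_id!r}")
        self.records[record.food_id] = record
        key = record.code.item_key
        if key is not None:
            self._item_index.setdefault(key, {})[record.code.processing_state] = record

    def __contains__(self, food_id: str) -> bool:
        return food_id in self.records

    def __getitem__(self, food_id: str) -> FoodRecord:
        return self.records[food_id]

    def __iter__(self) -> Iterator[FoodRecord]:
        return iter(self.records.values())

    def __len__(self) -> int:
        return len(self.records)

    def counterpart(self, record: FoodRecord, state: int) -> FoodRecord | None:
        """The record sharing this food's item key with the given processing state."""
        key = record.code.item_key
        if key is None:
            return None
        return self._item_index.get(key, {}).get(state)

    def raw_counterpart(self, record: FoodRecord) -> FoodRecord | None:
        return self.counterpart(record, RAW)

    @classmethod
    def from_records(cls, records: Iterable[FoodRecord]) -> "FoodDatabase":
        db = cls()
        for r in records:
            db.add(r)
        return db


@dataclass(frozen=True)
class ValidationIssue:
    food_id: str
    rule: str
    detail: str

    def to_json(self) -> str:
        return json.dumps(
            {"food_id": self.food_id, "rule": self.rule, "detail": self.detail}
        )


def validate_database(db: FoodDatabase) -> list[ValidationIssue]:
    """Check record and database invariants; issues are data, not exceptions.

    Deterministic: issues are ordered by food_id, then rule name.
    """
    issues: list[ValidationIssue] = []
    for rec in db:
        for fld in _NUTRIENT_FIELDS:
            v = getattr(rec, fld)
            if not (v >= 0):  # also catches NaN
                issues.append(
                    ValidationIssue(rec.food_id, "negative_value", f"{fld} = {v}")
                )
        mass = rec.protein_g_per_100g + rec.fat_g_per_100g
        if mass > 100:
            issues.append(
                ValidationIssue(
                    rec.food_id,
                    "mass_overflow",
                    f"protein + fat = {mass:.3g} g per 100 g exceeds 100",
                )
            )
        if (
            rec.code.component_type in "FVG"
            and rec.code.processing_state != RAW
            and db.raw_counterpart(rec) is None
            and rec.factor_override is None
        ):
            issues.append(
                ValidationIssue(
                    rec.food_id,
                    "no-raw-reference",
                    f"processed food {format_code(rec.code)} has no raw counterpart "
                    "and no factor override",
                )
            )
    issues.sort(key=lambda i: (i.food_id, i.rule))
    return issues


def _record_from_row(row: pd.Series) -> FoodRecord:
    try:
        code = parse_code(str(row["code"]))
    except CodeError as e:
        raise CodeError(f"food_id {row['food_id']!r}: {e}") from e
    return FoodRecord(
        food_id=str(row["food_id"]),
        name=str(row["name"]),
        code=code,
        energy_kcal_per_100g=float(row["energy_kcal"]),
        protein_g_per_100g=float(row["protein_g"]),
        calcium_mg_per_100g=float(row["calcium_mg"]),
        pufa_g_per_100g=float(row["pufa_g"]),
        mufa_g_per_100g=float(row["mufa_g"]),
        sfa_g_per_100g=float(row["sfa_g"]),
        added_sugars_g_per_100g=float(row["added_sugars_g"]),
        sodium_mg_per_100g=float(row["sodium_mg"]),
        factor_override=(
            float(row["factor_override"])
            if "factor_override" in row and pd.notna(row["factor_override"])
            else None
        ),
    )


def read_food_db(path: str | Path) -> FoodDatabase:
    """Load a food database CSV (UTF-8, header required)."""
    df = pd.read_csv(path, dtype={"food_id": str, "code": str})
    missing = [c for c in DB_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"food database {path}: missing columns {missing}")
    return FoodDatabase.from_records(_record_from_row(row) for _, row in df.iterrows())


def to_frame(db: FoodDatabase) -> pd.DataFrame:
    rows = []
    for r in db:
        rows.append(
            {
                "food_id": r.food_id,
                "name": r.name,
                "code": format_code(r.code),
                "energy_kcal": r.energy_kcal_per_100g,
                "protein_g": r.protein_g_per_100g,
                "calcium_mg": r.calcium_mg_per_100g,
                "pufa_g": r.pufa_g_per_100g,
                "mufa_g": r.mufa_g_per_100g,
                "sfa_g": r.sfa_g_per_100g,
                "added_sugars_g": r.added_sugars_g_per_100g,
                "sodium_mg": r.sodium_mg_per_100g,
                "factor_override": r.factor_override,
            }
        )
    return pd.DataFrame(rows, columns=DB_COLUMNS + ["factor_override"])


def write_food_db(db: FoodDatabase, path: str | Path) -> None:
    to_frame(db).to_csv(path, index=False)


def write_validation_report(issues: list[ValidationIssue], path: str | Path) -> None:
    """JSON lines, one issue per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for issue in issues:
            fh.write(issue.to_json() + "\n")
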