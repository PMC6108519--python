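"""From recall records to analysis matrices.

A *meal table* treats each meal occurrence (a recall day with positive
intake at that eating occasion) as one observation of 39 food-group gram
amounts; occurrences are analysed independently of the participant. The
*habitual table* averages, per participant, the day totals over all 11
eating occasions across the participant's available recall days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import json
import numpy as np
import pandas as pd

from .foods import FOOD_GROUPS, MAIN_MEALS, OCCASIONS
from .synthetic import RECALL_CSV_HEADER, RecallDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FoodGroupMap",
    "MealTable",
    "HabitualTable",
    "load_recalls",
    "build_meal_table",
    "build_habitual_table",
    "summarize_intake",
]


@dataclass(frozen=True)
class FoodGroupMap:
    """Total mapping from raw food item labels to canonical group labels."""

    mapping: Mapping[str, str]
    groups: tuple[str, ...] = FOOD_GROUPS

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - set(self.groups)
        if bad:
            raise ValueError(f"map targets outside declared groups: {sorted(bad)[:5]}")

    @classmethod
    def identity(cls, groups: tuple[str, ...] = FOOD_GROUPS) -> "FoodGroupMap":
        return cls({g: g for g in groups}, groups)

    def apply(self, items: pd.Series) -> pd.Series:
        mapped = items.map(self.mapping)
        if mapped.isna().any():
            unknown = sorted(items[mapped.isna()].unique())
            raise ValueError(f"unmapped food items: {unknown[:10]}")
        return mapped


@dataclass
class MealTable:
    """Meal occurrences x food groups, grams per eating event."""

    meal_label: str
    data: pd.DataFrame  # index: (participant_id, recall_index); columns: groups

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("gram amounts must be nonnegative")
        totals = self.data.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("every meal occurrence must have positive total intake")

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.data.reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class HabitualTable:
    """Participants x food groups, average grams per day."""

    data: pd.DataFrame  # index: participant_id
    n_recalls: pd.Series  # recalls averaged per participant

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("gram amounts must be nonnegative")
        if self.data.index.duplicated().any():
            raise ValueError("one row per participant required")
        if (self.n_recalls < 1).any():
            raise ValueError("participants must have at least one recall")

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "n_recalls", self.n_recalls)
        out.reset_index().to_csv(path, sep="\t", index=False)


def load_recalls(path: str | Path, group_map: FoodGroupMap | None = None) -> RecallDataset:
    """Read a tidy recall CSV (with optional JSON metadata sidecar).

    Duplicate (participant, recall, occasion, group) rows are summed with a
    logged warning; negative gram amounts and unknown occasion labels are
    errors.
    """
    path = Path(path)
    records = pd.read_csv(path)
    missing = [c for c in RECALL_CSV_HEADER if c not in records.columns]
    if missing:
        raise ValueError(f"recall CSV missing columns {missing}")
    records["grams"] = pd.to_numeric(records["grams"], errors="raise")
    neg = records.index[records["grams"] < 0]
    if len(neg):
        # +2: header line plus 1-based numbering, as a user sees the file
        raise ValueError(f"negative gram amount at file row {neg[0] + 2}")

    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        occasions = tuple(meta["occasions"])
        groups = tuple(meta["food_groups"])
        main_meals = tuple(meta["main_meals"])
        provenance, seed = meta.get("provenance", "loaded"), meta.get("seed")
    else:
        occasions, groups, main_meals = OCCASIONS, FOOD_GROUPS, MAIN_MEALS
        provenance, seed = "loaded", None

    bad_occ = set(records["occasion"]) - set(occasions)
    if bad_occ:
        raise ValueError(
            f"unknown occasion labels {sorted(bad_occ)}; valid labels: {list(occasions)}"
        )
    if group_map is None:
        group_map = FoodGroupMap.identity(groups)
    records["food_group"] = group_map.apply(records["food_group"])

    key_cols = ["participant_id", "recall_index", "occasion", "food_group"]
    if records.duplicated(key_cols).any():
        n_dup = int(records.duplicated(key_cols).sum())
        logger.warning("summing %d duplicate recall rows", n_dup)
        records = records.groupby(key_cols, as_index=False, sort=False)["grams"].sum()

    return RecallDataset(
        records=records.reset_index(drop=True),
        food_groups=tuple(group_map.groups),
        occasions=occasions,
        main_meals=main_meals,
        provenance=provenance,
        seed=seed,
    )


def build_meal_table(data: RecallDataset, meal_label: str) -> MealTable:
    """One row per recall day with positive total intake at ``meal_label``."""
    if meal_label not in data.occasions:
        raise ValueError(
            f"{meal_label!r} is not an occasion; valid: {list(data.occasions)}"
        )
    rec = data.records
    at_meal = rec[(rec["occasion"] == meal_label) & (rec["grams"] > 0)]
    wide = at_meal.pivot_table(
        index=["participant_id", "recall_index"],
        columns="food_group", values="grams", aggfunc="sum", fill_value=0.0,
    )
    wide = wide.reindex(columns=list(data.food_groups), fill_value=0.0)
    wide.columns.name = None
    if len(wide) < 2:
        raise ValueError(
            f"fewer than 2 occurrences of {meal_label!r}: no correlation estimable"
        )
    return MealTable(meal_label=meal_label, data=wide.sort_index())


def build_habitual_table(data: RecallDataset) -> HabitualTable:
    """Per participant: occasion-summed day totals averaged over recall days."""
    rec = data.records
    if rec.empty:
        raise ValueError("no recall records")
    day_totals = rec.pivot_table(
        index=["participant_id", "recall_index"],
        columns="food_group", values="grams", aggfunc="sum", fill_value=0.0,
    )
    day_totals = day_totals.reindex(columns=list(data.food_groups), fill_value=0.0)
    day_totals.columns.name = None
    habitual = day_totals.groupby(level="participant_id").mean()
    n_recalls = day_totals.groupby(level="participant_id").size().rename("n_recalls")
    return HabitualTable(data=habitual.sort_index(), n_recalls=n_recalls)


def summarize_intake(table: MealTable | HabitualTable) -> pd.DataFrame:
    """Per-group mean and SD (n-1 denominator), for cohort-style reporting."""
    if table.n_obs == 0:
        raise ValueError("empty table")
    df = table.data
    return pd.DataFrame({"mean": df.mean(axis=0), "sd": df.std(axis=0, ddof=1)})
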