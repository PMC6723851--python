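"""Conversion of raw FFQ item responses into a daily-gram consumption matrix.

A semi-quantitative food frequency questionnaire (FFQ) records, for each of
97 food items, how often a participant eats it (five ordinal frequency
categories), how many times per occasion, and the portion in grams (mL are
treated as grams 1:1).  Monthly/weekly frequencies are deconvoluted to a
per-day occurrence rate using fixed category midpoints, multiplied by the
portion, and the 97 items are aggregated into 14 food groups defined by
nutritional similarity.  The result is the ``ConsumptionMatrix``: participants
x 14 food groups, daily grams, the object every downstream analysis consumes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "FOOD_GROUPS",
    "FREQUENCY_CATEGORIES",
    "DEFAULT_FREQUENCY_MIDPOINTS",
    "FFQItemResponse",
    "FoodGroupMap",
    "load_default_food_group_map",
    "frequency_to_daily_occurrences",
    "item_daily_grams",
    "aggregate_food_groups",
    "read_responses_csv",
    "write_consumption_csv",
    "read_consumption_csv",
]

#: Canonical food-group order; every ConsumptionMatrix uses exactly these
#: 14 columns in this order.
FOOD_GROUPS: tuple[str, ...] = (
    "Sugar and sweets",
    "Sweetened beverages",
    "Typical Brazilian dishes",
    "Fast food",
    "Oils",
    "Milk and dairy",
    "Meat",
    "Processed meat products",
    "Rice and cereals",
    "Roots",
    "Beans and legumes",
    "Vegetables",
    "Fruits",
    "Coffee",
)

N_GROUPS = len(FOOD_GROUPS)
N_ITEMS = 97

FREQUENCY_CATEGORIES: tuple[str, ...] = (
    "never_rare",
    "one_to_three_per_month",
    "once_per_week",
    "two_to_four_per_week",
    "four_plus_per_week",
)

# Occurrences per day for one "time": category midpoints, months standardized
# to 30 days and weeks to 7 days.  The open-ended top category ">=4/week" is
# mapped to 5/week by convention; all midpoints are config-overridable.
DEFAULT_FREQUENCY_MIDPOINTS: dict[str, float] = {
    "never_rare": 0.0,
    "one_to_three_per_month": 2.0 / 30.0,
    "once_per_week": 1.0 / 7.0,
    "two_to_four_per_week": 3.0 / 7.0,
    "four_plus_per_week": 5.0 / 7.0,
}


@dataclass(frozen=True)
class FFQItemResponse:
    """One participant's answer for one FFQ item."""

    participant_id: str
    item_id: int
    frequency_category: str
    times: int = 1
    portion_grams: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.item_id <= N_ITEMS):
            raise ValueError(f"item_id must be in 1..{N_ITEMS}, got {self.item_id}")
        if self.frequency_category not in FREQUENCY_CATEGORIES:
            raise ValueError(
                f"unknown frequency category {self.frequency_category!r}; "
                f"allowed: {', '.join(FREQUENCY_CATEGORIES)}"
            )
        if self.portion_grams < 0:
            raise ValueError("portion_grams must be >= 0")
        if self.frequency_category != "never_rare" and self.times < 1:
            raise ValueError("times must be >= 1 for a non-rare frequency")


@dataclass(frozen=True)
class FoodGroupMap:
    """Mapping of the 97 FFQ item ids onto the 14 canonical food groups."""

    item_to_group: Mapping[int, str]
    item_labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.item_to_group) != N_ITEMS:
            raise ValueError(
                f"map must cover exactly {N_ITEMS} items, got {len(self.item_to_group)}"
            )
        bad = sorted(set(self.item_to_group) - set(range(1, N_ITEMS + 1)))
        if bad:
            raise ValueError(f"item ids outside 1..{N_ITEMS}: {bad}")
        groups = set(self.item_to_group.values())
        missing = set(FOOD_GROUPS) - groups
        if missing:
            raise ValueError(f"groups with no items: {sorted(missing)}")
        unknown = groups - set(FOOD_GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    def group_of(self, item_id: int) -> str:
        try:
            return self.item_to_group[item_id]
        except KeyError:
            raise KeyError(f"item id {item_id} is not covered by the food-group map")

    def items_in_group(self, group: str) -> list[int]:
        return [i for i, g in sorted(self.item_to_group.items()) if g == group]


def load_default_food_group_map() -> FoodGroupMap:
    """Load the canonical 97-item map shipped with the package."""
    ref = importlib.resources.files("dietnet.data").joinpath("food_group_map.csv")
    with importlib.resources.as_file(ref) as path:
        return read_food_group_map(path)


def read_food_group_map(path) -> FoodGroupMap:
    df = pd.read_csv(path)
    required = {"item_id", "item_label", "group_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"map CSV must have columns {sorted(required)}")
    if df["item_id"].duplicated().any():
        dupes = df.loc[df["item_id"].duplicated(), "item_id"].tolist()
        raise ValueError(f"duplicate item ids in map: {dupes}")
    return FoodGroupMap(
        item_to_group=dict(zip(df["item_id"].astype(int), df["group_label"])),
        item_labels=dict(zip(df["item_id"].astype(int), df["item_label"])),
    )


def frequency_to_daily_occurrences(
    category: str,
    times: int = 1,
    midpoints: Mapping[str, float] | None = None,
) -> float:
    """Occurrences per day implied by a frequency category and a times count.

    ``never_rare`` is always 0 regardless of ``times``; every other category's
    midpoint is scaled by ``times`` (times is an occasions multiplier).
    """
    mids = DEFAULT_FREQUENCY_MIDPOINTS if midpoints is None else midpoints
    if category not in mids:
        raise ValueError(
            f"unknown frequency category {category!r}; allowed: {sorted(mids)}"
        )
    if category == "never_rare":
        return 0.0
    if times < 1:
        raise ValueError("times must be >= 1 for a non-rare frequency")
    return float(times) * float(mids[category])


def item_daily_grams(
    response: FFQItemResponse,
    midpoints: Mapping[str, float] | None = None,
) -> float:
    """Daily grams contributed by one item response (occurrences/day x portion)."""
    occ = frequency_to_daily_occurrences(
        response.frequency_category, response.times, midpoints
    )
    return occ * response.portion_grams


def aggregate_food_groups(
    responses: pd.DataFrame,
    group_map: FoodGroupMap | None = None,
    midpoints: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Aggregate item-level responses into the participants x 14 group matrix.

    Parameters
    ----------
    responses
        One row per participant x item with columns ``participant_id``,
        ``item_id``, ``frequency_category``, ``times``, ``portion_grams``.
        Duplicated (participant, item) pairs are an error.  Items a
        participant did not answer contribute 0 (treated as never/rare).
    group_map
        Item -> group mapping; defaults to the canonical shipped map.

    Returns
    -------
    DataFrame indexed by participant id with the 14 canonical group columns,
    values in grams per day.
    """
    gm = group_map if group_map is not None else load_default_food_group_map()
    df = responses.copy()
    required = {"participant_id", "item_id", "frequency_category", "times", "portion_grams"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"responses missing columns: {sorted(missing)}")

    dup = df.duplicated(subset=["participant_id", "item_id"])
    if dup.any():
        pairs = df.loc[dup, ["participant_id", "item_id"]].values.tolist()
        raise ValueError(f"duplicate participant x item rows: {pairs[:5]}")

    unmapped = sorted(set(df["item_id"].astype(int)) - set(gm.item_to_group))
    if unmapped:
        raise ValueError(f"item ids not covered by the food-group map: {unmapped}")

    grams = [
        item_daily_grams(
            FFQItemResponse(
                participant_id=str(r.participant_id),
                item_id=int(r.item_id),
                frequency_category=str(r.frequency_category),
                times=int(r.times),
                portion_grams=float(r.portion_grams),
            ),
            midpoints,
        )
        for r in df.itertuples(index=False)
    ]
    df = df.assign(
        daily_grams=grams,
        group=[gm.group_of(int(i)) for i in df["item_id"]],
    )
    mat = (
        df.pivot_table(
            index="participant_id",
            columns="group",
            values="daily_grams",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(columns=list(FOOD_GROUPS), fill_value=0.0)
    )
    mat.columns.name = None
    mat.index = mat.index.astype(str)
    mat.index.name = "participant_id"
    return mat.astype(float)


def read_responses_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str})


def write_consumption_csv(consumption: pd.DataFrame, path) -> None:
    consumption.to_csv(path, index=True)


def read_consumption_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="participant_id")
    df.index = df.index.astype(str)
    missing = set(FOOD_GROUPS) - set(df.columns)
    if missing:
        raise ValueError(f"consumption CSV missing groups: {sorted(missing)}")
    return df[list(FOOD_GROUPS)].astype(float)
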