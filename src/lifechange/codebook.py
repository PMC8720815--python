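"""Item codebook: metadata for the survey item batteries.

Three batteries are modelled: a 14-item pandemic life-change battery split
into social/interpersonal and economic stress domains, a 10-item circumplex
mood battery, and a 6-item COVID-worries battery.  Every item is an ordinal
Likert response; ``direction == "reversed"`` marks items whose raw response
runs opposite to the battery's severity coding and must be reflected before
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

VALID_DIRECTIONS = ("normal", "reversed")
VALID_DOMAINS = ("social", "economic", "other")
VALID_BATTERIES = ("mood", "worries", "life_change")


@dataclass(frozen=True)
class Item:
    """Metadata for one survey item."""

    name: str
    scale_min: int
    scale_max: int
    direction: str = "normal"
    battery: str = "life_change"
    domain: str = "other"

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError(
                f"item {self.name!r}: scale_min ({self.scale_min}) must be "
                f"< scale_max ({self.scale_max})"
            )
        if self.direction not in VALID_DIRECTIONS:
            raise ValueError(f"item {self.name!r}: bad direction {self.direction!r}")
        if self.battery not in VALID_BATTERIES:
            raise ValueError(f"item {self.name!r}: bad battery {self.battery!r}")
        if self.domain not in VALID_DOMAINS:
            raise ValueError(f"item {self.name!r}: bad domain {self.domain!r}")


class ItemCodebook:
    """Collection of :class:`Item` records, keyed by unique item name."""

    def __init__(self, items: Iterable[Item]):
        self._items: dict[str, Item] = {}
        for item in items:
            if item.name in self._items:
                raise ValueError(f"duplicate item name {item.name!r}")
            self._items[item.name] = item

    def __contains__(self, name: str) -> bool:
        return name in self._items

    def __getitem__(self, name: str) -> Item:
        return self._items[name]

    def __iter__(self) -> Iterator[Item]:
        return iter(self._items.values())

    def __len__(self) -> int:
        return len(self._items)

    @property
    def item_names(self) -> list[str]:
        return list(self._items)

    def battery_items(self, battery: str) -> list[str]:
        """Names of all items in one battery, in codebook order."""
        if battery not in VALID_BATTERIES:
            raise ValueError(f"unknown battery {battery!r}")
        return [it.name for it in self if it.battery == battery]

    def domain_items(self, domain: str) -> list[str]:
        """Names of life-change items in one stress domain."""
        if domain not in VALID_DOMAINS:
            raise ValueError(f"unknown domain {domain!r}")
        return [
            it.name for it in self if it.battery == "life_change" and it.domain == domain
        ]

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (it.name, it.scale_min, it.scale_max, it.direction, it.battery, it.domain)
                for it in self
            ],
            columns=["name", "scale_min", "scale_max", "direction", "battery", "domain"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ItemCodebook":
        return cls(
            Item(
                name=str(row["name"]),
                scale_min=int(row["scale_min"]),
                scale_max=int(row["scale_max"]),
                direction=str(row["direction"]),
                battery=str(row["battery"]),
                domain=str(row["domain"]),
            )
            for _, row in frame.iterrows()
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ItemCodebook":
        return cls.from_frame(pd.read_csv(path))


def default_codebook() -> ItemCodebook:
    """The default 30-item codebook: 14 life-change, 10 mood, 6 worries items.

    All items are 1-5 Likert responses.  Life-change items are coded so that
    higher scores mean more stress / worse change; ``lc_positive_changes`` is
    asked in the positive direction and therefore reversed.  Two mood items
    (calm, happy) and the worries item about hope for the pandemic ending are
    likewise reverse-keyed.
    """
    social = [
        "lc_family_change",
        "lc_friend_change",
        "lc_family_relationship",
        "lc_friend_relationship",
        "lc_inperson_conversation",
        "lc_time_outside",
        "lc_positive_changes",
    ]
    economic = [
        "lc_income_loss",
        "lc_job_insecurity",
        "lc_food_insecurity",
        "lc_housing_instability",
        "lc_bills_stress",
        "lc_work_disruption",
        "lc_healthcare_access",
    ]
    mood = [
        "mood_sad",
        "mood_anxious",
        "mood_irritable",
        "mood_fatigued",
        "mood_lonely",
        "mood_worried",
        "mood_restless",
        "mood_hopeless",
        "mood_calm",
        "mood_happy",
    ]
    worries = [
        "worry_self_infected",
        "worry_others_infected",
        "worry_physical_health",
        "worry_mental_health",
        "worry_reading_talking",
        "worry_hope_end",
    ]
    reversed_items = {"lc_positive_changes", "mood_calm", "mood_happy", "worry_hope_end"}

    items: list[Item] = []
    for name in social:
        items.append(
            Item(name, 1, 5,
                 "reversed" if name in reversed_items else "normal",
                 "life_change", "social")
        )
    for name in economic:
        items.append(Item(name, 1, 5, "normal", "life_change", "economic"))
    for name in mood:
        items.append(
            Item(name, 1, 5,
                 "reversed" if name in reversed_items else "normal",
                 "mood", "other")
        )
    for name in worries:
        items.append(
            Item(name, 1, 5,
                 "reversed" if name in reversed_items else "normal",
                 "worries", "other")
        )
    return ItemCodebook(items)
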