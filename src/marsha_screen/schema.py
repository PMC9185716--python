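"""Instrument schema: item identifiers, subscales, and screener membership.

The reference instrument is a 34-item past-year dating-abuse victimization
scale with five subscales (privacy control, social control, physical, sexual,
intimidation).  The brief screener is a fixed three-item subset.  The schema
ships as a YAML file so item ids are configuration, not code; the default
packaged schema carries the three published screener items plus schematic
placeholder ids for the unpublished items.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

SUBSCALES = ("privacy_control", "social_control", "physical", "sexual", "intimidation")

#: Reporting taxonomy for headline abuse-type prevalences.  Distinct from the
#: five instrument subscales; items may fall outside it (category = None).
REPORT_CATEGORIES = ("physical", "sexual", "emotional", "technology")

#: Response options: "0 times", "1-3 times", "4-10 times", "more than 10 times".
FREQUENCY_CODES = (0, 1, 2, 3)
#: Minimum act count consistent with each frequency code, in code order.
FREQUENCY_MIN_ACTS = (0, 1, 4, 11)


@dataclass(frozen=True)
class Item:
    id: str
    subscale: str
    text: str = ""
    category: str | None = None

    def __post_init__(self) -> None:
        if self.subscale not in SUBSCALES:
            raise ValueError(f"unknown subscale {self.subscale!r} for item {self.id!r}")
        if self.category is not None and self.category not in REPORT_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for item {self.id!r}")


@dataclass(frozen=True)
class InstrumentSchema:
    """The 34-item instrument plus the designated screener subset."""

    items: tuple[Item, ...]
    screener_items: tuple[str, ...]
    excluded_from_screener: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in schema")
        if len(self.items) != 34:
            raise ValueError(f"expected 34 items, got {len(self.items)}")
        for sid in (*self.screener_items, *self.excluded_from_screener):
            if sid not in ids:
                raise ValueError(f"unknown item id {sid!r}")
        if len(self.screener_items) != 3:
            raise ValueError("screener must have exactly 3 items")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.id for it in self.items)

    @property
    def subscale_map(self) -> dict[str, str]:
        return {it.id: it.subscale for it in self.items}

    @property
    def category_map(self) -> dict[str, str]:
        """Item id -> report category, omitting uncategorized items."""
        return {it.id: it.category for it in self.items if it.category is not None}

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)


def _from_mapping(doc: Mapping) -> InstrumentSchema:
    items = tuple(
        Item(
            id=d["id"],
            subscale=d["subscale"],
            text=d.get("text", ""),
            category=d.get("category"),
        )
        for d in doc["items"]
    )
    return InstrumentSchema(
        items=items,
        screener_items=tuple(doc["screener_items"]),
        excluded_from_screener=tuple(doc.get("excluded_from_screener", ())),
    )


def load_schema(path: str | Path | None = None) -> InstrumentSchema:
    """Load an instrument schema from YAML; default is the packaged schema."""
    if path is None:
        ref = resources.files("marsha_screen.data").joinpath("instrument_schema.yaml")
        doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    else:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _from_mapping(doc)


DEFAULT_SCHEMA = load_schema()

#: The three screener item ids, in schema order.
SCREENER_ITEMS = DEFAULT_SCHEMA.screener_items
#: Most-endorsed item deliberately left off the screener (ceasing contact can
#: be a healthy behavior, so endorsement is ambiguous as an abuse signal).
EXCLUDED_ITEM = DEFAULT_SCHEMA.excluded_from_screener[0]
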