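"""Device arithmetic: battery runtime and bill-of-materials totals.

The recording device runs from a 9 V lithium battery rated for 700 mAh when
discharged at 200 mA; runtime is simply capacity over current draw. The
bill of materials is summed over its printed cost column; rows whose cost
disagrees with quantity x unit price are reported as inconsistencies rather
than silently corrected.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, List, Tuple, Union


@dataclass(frozen=True)
class BomItem:
    """One bill-of-materials row; prices in USD."""

    name: str
    quantity: float
    unit_price: float
    cost: float

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError(f"quantity must be >= 0, got {self.quantity}")
        if self.unit_price < 0 or self.cost < 0:
            raise ValueError("prices must be >= 0")


def battery_runtime(capacity_mAh: float, current_mA: float) -> float:
    """Battery runtime in hours: capacity (mAh) / current draw (mA)."""
    if current_mA <= 0:
        raise ValueError(f"current_mA must be > 0, got {current_mA}")
    if capacity_mAh < 0:
        raise ValueError(f"capacity_mAh must be >= 0, got {capacity_mAh}")
    return capacity_mAh / current_mA


def bom_total(items: List[BomItem]) -> Tuple[float, List[BomItem]]:
    """Total cost (sum of the cost column, rounded to cents) and inconsistencies.

    An item is inconsistent when its printed cost differs from
    quantity x unit_price by more than half a cent.
    """
    total = round(sum(item.cost for item in items), 2)
    inconsistencies = [
        item for item in items if abs(item.quantity * item.unit_price - item.cost) > 0.005
    ]
    return total, inconsistencies


def read_bom(source: Union[str, Path, IO[str]]) -> List[BomItem]:
    """Read a BOM from CSV with columns ``name,quantity,unit_price,cost``."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_bom(fh)
    items = []
    for row in csv.DictReader(source):
        items.append(
            BomItem(
                name=row["name"],
                quantity=float(row["quantity"]),
                unit_price=float(row["unit_price"]),
                cost=float(row["cost"]),
            )
        )
    return items


def biosense_bom() -> List[BomItem]:
    """The packaged 12-row device bill of materials."""
    ref = resources.files("ibmkit").joinpath("data/bom_biosense.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return read_bom(fh)
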