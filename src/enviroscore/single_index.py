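"""Aggregation of a 13-category impact vector into a dimensionless single index.

The index of an item with impacts e(c) per kg, under normalization factors
NF(c) and percentage weights w(c), is

    index = sum_c  e(c) / NF(c) * w(c) / 100

i.e. each category is expressed as a fraction of the per-capita yearly
reference impact, weighted, and summed.  With the bundled food-basket tables
this is the EFSI; with the Commission's economy-wide tables it is the EC
Single Score — the formula is identical, only the reference constants differ.

The index is stored in raw dimensionless units (the grade thresholds operate
on the raw scale); a ``display_milli`` rendering (x 10^3) is provided because
score distributions are conventionally reported on the 10^-3 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import CategoryMismatchError
from .impact_model import CATEGORY_CODES, FoodItem, ImpactVector
from .normalization import NormalizationTable, WeightingTable, bundled_efsi_tables


@dataclass(frozen=True)
class SingleIndexResult:
    """A dimensionless single-index value with per-category contributions.

    Per-category contributions are always retained so that impact transfers
    between categories (e.g. a lower carbon footprint bought with higher
    water use) remain inspectable after aggregation.
    """

    item_id: str
    scheme: str
    total: float
    contributions: Mapping[str, float]

    @property
    def display_milli(self) -> float:
        """The index on the 10^-3 reporting scale."""
        return self.total * 1e3


def compute_single_index(
    impacts: ImpactVector,
    nf: NormalizationTable,
    weights: WeightingTable,
    scheme: str = "user",
    item_id: str = "",
) -> SingleIndexResult:
    """Aggregate an impact vector under the given NF and weight tables.

    The impact vector must cover the full 13-category registry (use
    :meth:`ImpactVector.filled` for the explicit treat-missing-as-zero
    opt-in) and every NF must be positive.
    """
    if impacts.missing:
        raise CategoryMismatchError([], impacts.missing)
    nf.require_positive()
    contributions = {
        c: impacts[c] / nf[c] * weights[c] / 100.0 for c in CATEGORY_CODES
    }
    return SingleIndexResult(
        item_id=item_id,
        scheme=scheme,
        total=sum(contributions.values()),
        contributions=contributions,
    )


def compute_efsi(item: FoodItem) -> SingleIndexResult:
    """Score a food item with the bundled EFSI reference tables."""
    nf, weights = bundled_efsi_tables()
    return compute_single_index(
        item.impacts, nf, weights, scheme="EFSI", item_id=item.item_id
    )


def compute_ec_single_score(
    item: FoodItem, ec_nf: NormalizationTable, ec_weights: WeightingTable
) -> SingleIndexResult:
    """Score a food item under externally supplied EC Single Score tables.

    The Commission's economy-wide normalization references are not bundled;
    the caller provides them (e.g. via a tables config file).
    """
    return compute_single_index(
        item.impacts, ec_nf, ec_weights, scheme="EC-SS", item_id=item.item_id
    )
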