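"""Impact-category vocabulary, per-item impact vectors and the reference basket.

The package works at the level of *characterized* life-cycle impacts: every
food item carries a 13-component vector of ILCD midpoint indicators per 1 kg
of final product (the functional unit used throughout).  Category codes (CC,
ODP, ...) are the canonical keys everywhere; long names and units are display
metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import MissingCategoryError, UnknownCategoryError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImpactCategory:
    """One ILCD midpoint impact category.

    Attributes
    ----------
    code : str
        Short canonical identifier, e.g. ``"CC"`` for climate change.
    name : str
        Human-readable label.
    unit : str
        Characterization unit per functional unit (1 kg of product).
    """

    code: str
    name: str
    unit: str


# The 13 ILCD categories retained after dropping the three toxicity-related
# ones (robustness concerns in their characterization models), in the order
# used for all tabular output.
_DEFAULT_REGISTRY: tuple[ImpactCategory, ...] = (
    ImpactCategory("CC", "Climate change", "kg CO2 eq"),
    ImpactCategory("ODP", "Ozone depletion potential", "kg CFC11 eq"),
    ImpactCategory("IR", "Ionizing radiation", "kBq U-235 eq"),
    ImpactCategory("POF", "Photochemical ozone formation", "kg NMVOC eq"),
    ImpactCategory("RI", "Respiratory inorganics", "disease inc."),
    ImpactCategory("ATF", "Acidification terrestrial and freshwater", "mol H+ eq"),
    ImpactCategory("EuF", "Eutrophication freshwater", "kg P eq"),
    ImpactCategory("EuT", "Eutrophication terrestrial", "kg N eq"),
    ImpactCategory("EuM", "Eutrophication marine", "mol N eq"),
    ImpactCategory("LU", "Land use", "Pt"),
    ImpactCategory("WS", "Water scarcity", "m3 depriv."),
    ImpactCategory("RUe", "Resource use, energy carriers", "MJ"),
    ImpactCategory("RUm", "Resource use, mineral and metals", "kg Sb eq"),
)

#: Canonical category order (codes only).
CATEGORY_CODES: tuple[str, ...] = tuple(c.code for c in _DEFAULT_REGISTRY)

#: Codes of the three toxicity-related ILCD categories excluded from scoring:
#: human toxicity (cancer), human toxicity (non-cancer) and ecotoxicity.
TOXICITY_CODES: frozenset[str] = frozenset({"HTc", "HTnc", "EcoTox"})

TRANSPORT_MODES = ("boat", "plane", "train", "lorry", "local")


def load_default_registry() -> list[ImpactCategory]:
    """Return the 13 default impact categories in canonical order.

    The list is freshly built on every call so callers may mutate it freely.
    """
    return list(_DEFAULT_REGISTRY)


def registry_by_code() -> dict[str, ImpactCategory]:
    return {c.code: c for c in _DEFAULT_REGISTRY}


@dataclass(frozen=True)
class ImpactVector:
    """Characterized impacts of 1 kg of a food item, keyed by category code.

    Missing categories are an explicit state: a vector built from a partial
    mapping simply lacks those keys, and downstream scoring refuses to run on
    an incomplete vector unless the caller opts into treating the missing
    categories as zero (a logged decision, never a silent default).
    Negative values are legitimate (end-of-life credits) but logged.
    """

    values: Mapping[str, float]

    def __post_init__(self):
        known = set(CATEGORY_CODES)
        unknown = set(self.values) - known
        if unknown:
            raise UnknownCategoryError(unknown)
        clean = {}
        negatives = []
        for code in CATEGORY_CODES:
            if code not in self.values:
                continue
            v = float(self.values[code])
            if not math.isfinite(v):
                raise ValueError(f"non-finite impact value for category {code}: {v}")
            if v < 0:
                negatives.append(code)
            clean[code] = v
        if negatives:
            logger.warning(
                "negative impact value(s) for %s (end-of-life credit?)", ", ".join(negatives)
            )
        object.__setattr__(self, "values", clean)

    @property
    def missing(self) -> tuple[str, ...]:
        """Codes of the canonical categories this vector does not cover."""
        return tuple(c for c in CATEGORY_CODES if c not in self.values)

    @property
    def complete(self) -> bool:
        return not self.missing

    def require_complete(self, context: str = "") -> None:
        if self.missing:
            raise MissingCategoryError(self.missing, context=context)

    def filled(self, fill_value: float = 0.0) -> "ImpactVector":
        """Return a complete vector, filling missing categories.

        This is the explicit opt-in path for treating missing categories as
        zero; the substitution is logged because it biases scores low.
        """
        if self.complete:
            return self
        logger.warning(
            "filling missing categories %s with %g", ", ".join(self.missing), fill_value
        )
        vals = dict(self.values)
        for c in self.missing:
            vals[c] = fill_value
        return ImpactVector(vals)

    def __getitem__(self, code: str) -> float:
        return self.values[code]

    def __contains__(self, code: str) -> bool:
        return code in self.values

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    def scaled(self, k: float) -> "ImpactVector":
        return ImpactVector({c: k * v for c, v in self.values.items()})

    def __add__(self, other: "ImpactVector") -> "ImpactVector":
        if set(self.values) != set(other.values):
            raise MissingCategoryError(
                set(self.values) ^ set(other.values), context="vector addition"
            )
        return ImpactVector({c: v + other.values[c] for c, v in self.values.items()})


def drop_toxicity_categories(
    vector_with_16: Mapping[str, float], *, allow_missing: bool = False
) -> ImpactVector:
    """Reduce an up-to-16-category ILCD mapping to the 13 scored categories.

    The three toxicity-related categories (human toxicity cancer/non-cancer
    and ecotoxicity) are removed; everything else passes through unchanged.
    Idempotent on an already-13-category mapping.

    Parameters
    ----------
    vector_with_16
        Mapping of ILCD category codes to values; may contain the toxicity
        codes ``HTc``, ``HTnc``, ``EcoTox``.
    allow_missing
        If False (default), the result must cover all 13 scored categories.

    Raises
    ------
    UnknownCategoryError
        For a code that is neither a scored category nor a toxicity code.
    MissingCategoryError
        If ``allow_missing`` is False and a scored category is absent.
    """
    known = set(CATEGORY_CODES) | TOXICITY_CODES
    unknown = set(vector_with_16) - known
    if unknown:
        raise UnknownCategoryError(unknown)
    kept = {c: v for c, v in vector_with_16.items() if c not in TOXICITY_CODES}
    vec = ImpactVector(kept)
    if not allow_missing:
        vec.require_complete(context="drop_toxicity_categories")
    return vec


@dataclass(frozen=True)
class FoodItem:
    """A food product variant with its characterized impacts per kg."""

    item_id: str
    product: str
    origin: str
    transport_mode: str
    production: str
    impacts: ImpactVector

    def __post_init__(self):
        if not self.item_id:
            raise ValueError("item_id must be non-empty")


@dataclass
class BasketEntry:
    item: FoodItem
    annual_consumption_kg: float  # whole-population yearly consumption, kg

    def __post_init__(self):
        if self.annual_consumption_kg < 0:
            raise ValueError(
                f"annual consumption of {self.item.item_id} is negative: "
                f"{self.annual_consumption_kg}"
            )


@dataclass
class FoodBasket:
    """Reference universe of food items with population-level consumption.

    ``entries`` pair each item with the *whole-population* yearly consumption
    FC(i) in kg; ``population`` is the person count the per-capita reference
    is expressed against.
    """

    entries: list[BasketEntry] = field(default_factory=list)
    population: float = 0.0

    def __post_init__(self):
        if self.population <= 0:
            raise ValueError(f"population must be positive, got {self.population}")
        ids = [e.item.item_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate item_id(s) in basket: {sorted(dupes)}")
        if self.entries and not any(e.annual_consumption_kg > 0 for e in self.entries):
            raise ValueError("basket must contain at least one entry with positive consumption")

    @property
    def items(self) -> list[FoodItem]:
        return [e.item for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterable[BasketEntry]:
        return iter(self.entries)
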