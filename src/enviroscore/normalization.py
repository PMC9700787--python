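"""Per-capita normalization factors and the bundled EFSI constant tables.

The normalization factor of category *i* relative to a reference food basket
is

    NF(i) = sum_items FC(item) * e_i(item) / population

with FC the whole-population yearly consumption (kg) and e_i the
characterized impact per kg.  The published EFSI table (13 NF values, EU-28
food basket, population 509,718,000) and the EC-recommended weighting factors
are bundled as printed; the weights total 100.02% and are deliberately *not*
renormalized to 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from .errors import CategoryMismatchError, MissingCategoryError, SchemaError
from .impact_model import CATEGORY_CODES, FoodBasket, registry_by_code

#: Reference population used for the bundled per-capita table (2013 figure).
EFSI_POPULATION = 509_718_000

# Published EFSI normalization factors, per capita per year, in each
# category's characterization unit (3 significant figures as published).
_EFSI_NF: dict[str, float] = {
    "CC": 2.42e03,
    "ODP": 1.29e-04,
    "IR": 1.31e02,
    "POF": 1.08e01,
    "RI": 2.44e-04,
    "ATF": 3.93e01,
    "EuF": 3.81e-01,
    "EuT": 1.42e01,
    "EuM": 1.58e02,
    "LU": 2.43e05,
    "WS": 7.83e02,
    "RUe": 1.96e04,
    "RUm": 4.33e-03,
}

# EC-recommended weighting factors, percent.  They sum to 100.02 as
# published; they are applied as w/100 without renormalization.
_EFSI_WEIGHTS: dict[str, float] = {
    "CC": 22.19,
    "ODP": 6.75,
    "IR": 5.37,
    "POF": 5.10,
    "RI": 9.54,
    "ATF": 6.64,
    "EuF": 2.95,
    "EuT": 3.12,
    "EuM": 3.91,
    "LU": 8.42,
    "WS": 9.03,
    "RUe": 8.92,
    "RUm": 8.08,
}


@dataclass(frozen=True)
class NormalizationTable:
    """Per-capita normalization factors NF(i), keyed by category code.

    ``provenance`` records where the factors came from: the bundled published
    set (``"EFSI-Table1"``), a basket computation (``"computed"``) or a
    user-supplied config (``"user"``).  A computed table and the bundled one
    are distinct objects; the scorer never mixes them implicitly.
    """

    nf: Mapping[str, float]
    provenance: str = "user"

    def __post_init__(self):
        missing = set(CATEGORY_CODES) - set(self.nf)
        if missing:
            raise MissingCategoryError(missing, context="NormalizationTable")
        extra = set(self.nf) - set(CATEGORY_CODES)
        if extra:
            raise CategoryMismatchError(extra, [])
        object.__setattr__(self, "nf", {c: float(self.nf[c]) for c in CATEGORY_CODES})

    def require_positive(self) -> None:
        bad = [c for c, v in self.nf.items() if not v > 0]
        if bad:
            raise ValueError(f"normalization factor(s) must be positive for scoring: {bad}")

    def __getitem__(self, code: str) -> float:
        return self.nf[code]


@dataclass(frozen=True)
class WeightingTable:
    """Weighting factors as percentages, keyed by category code."""

    weights_percent: Mapping[str, float]

    def __post_init__(self):
        missing = set(CATEGORY_CODES) - set(self.weights_percent)
        if missing:
            raise MissingCategoryError(missing, context="WeightingTable")
        extra = set(self.weights_percent) - set(CATEGORY_CODES)
        if extra:
            raise CategoryMismatchError(extra, [])
        clean = {c: float(self.weights_percent[c]) for c in CATEGORY_CODES}
        bad = [c for c, v in clean.items() if v < 0]
        if bad:
            raise ValueError(f"negative weight(s): {bad}")
        object.__setattr__(self, "weights_percent", clean)

    @property
    def total_percent(self) -> float:
        return sum(self.weights_percent.values())

    def __getitem__(self, code: str) -> float:
        return self.weights_percent[code]


def bundled_efsi_tables() -> tuple[NormalizationTable, WeightingTable]:
    """Return the published EFSI normalization and weighting tables.

    Values are the printed constants at full published precision; every call
    returns equal tables.
    """
    return (
        NormalizationTable(dict(_EFSI_NF), provenance="EFSI-Table1"),
        WeightingTable(dict(_EFSI_WEIGHTS)),
    )


def compute_normalization_factors(basket: FoodBasket) -> NormalizationTable:
    """Derive per-capita normalization factors from a reference basket.

    NF(c) = sum over basket items of FC(item) * e_c(item), divided by the
    basket population.  Every item must expose all 13 categories.
    """
    if len(basket) == 0:
        raise ValueError("cannot compute normalization factors from an empty basket")
    incomplete = {
        e.item.item_id: e.item.impacts.missing for e in basket if not e.item.impacts.complete
    }
    if incomplete:
        detail = "; ".join(f"{i}: {', '.join(m)}" for i, m in incomplete.items())
        raise MissingCategoryError(
            {c for m in incomplete.values() for c in m},
            context=f"basket items ({detail})",
        )
    nf = {}
    for code in CATEGORY_CODES:
        total = sum(e.annual_consumption_kg * e.item.impacts[code] for e in basket)
        nf[code] = total / basket.population
    return NormalizationTable(nf, provenance="computed")


# --- config I/O -----------------------------------------------------------

def load_tables_config(path: str | Path) -> tuple[NormalizationTable, WeightingTable]:
    """Load NF and weighting tables from a YAML or JSON config file.

    Schema: a top-level ``categories`` list of ``{code, nf, unit,
    weight_percent}`` records covering the 13-category registry; units are
    validated against it.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "categories" not in data:
        raise SchemaError(f"{path}: expected a mapping with a 'categories' list")
    units = registry_by_code()
    nf, weights = {}, {}
    for rec in data["categories"]:
        try:
            code = rec["code"]
            nf[code] = float(rec["nf"])
            weights[code] = float(rec["weight_percent"])
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"{path}: malformed category record {rec!r}") from exc
        if code not in units:
            raise SchemaError(f"{path}: unknown category code {code!r}")
        unit = rec.get("unit")
        if unit is not None and unit != units[code].unit:
            raise SchemaError(
                f"{path}: unit mismatch for {code}: {unit!r} != {units[code].unit!r}"
            )
    return (
        NormalizationTable(nf, provenance="user"),
        WeightingTable(weights),
    )


def dump_tables_config(
    nf: NormalizationTable, weights: WeightingTable, path: str | Path
) -> None:
    """Write NF and weighting tables to YAML or JSON (by file extension)."""
    units = registry_by_code()
    data = {
        "categories": [
            {
                "code": c,
                "unit": units[c].unit,
                "nf": nf[c],
                "weight_percent": weights[c],
            }
            for c in CATEGORY_CODES
        ]
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
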