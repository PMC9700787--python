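"""Synthetic reference baskets, hypothetical item variants and paired-label
fixtures.

Real inputs to this package are characterized LCA results for food items —
proprietary databases and modelling tools sit upstream.  This module
statistically emulates their output so that every downstream stage
(normalization, scoring, grading, agreement statistics) can be exercised and
tested without external data:

* ``generate_basket`` builds a reference basket of representative products
  whose per-category impact magnitudes are log-normal around the published
  per-capita reference profile, with overall index magnitudes log-spaced so
  the basket spans all five grades (roughly 4e-5 to 2e-2 on the raw index
  scale).
* ``generate_hypothetical_items`` derives product variants by multiplicative
  scenario perturbations (air transport, heated greenhouse, water-stressed
  origin, organic production, ...), mirroring how origin, transport and
  production method drive within-product impact variability.
* ``delphi_fixture`` builds paired A-E labelings with a controlled
  exact-agreement rate for testing agreement statistics.

Scenario multipliers are invented, documented constants chosen for ordinal
realism (air freight can move a product two or more grades; production-method
changes at most one); they do not claim to reproduce any measured dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .categorize import DEFAULT_THRESHOLDS, GRADES
from .impact_model import CATEGORY_CODES, BasketEntry, FoodBasket, FoodItem, ImpactVector
from .normalization import EFSI_POPULATION, bundled_efsi_tables

# 23 representative products of a European food basket, ordered roughly by
# increasing per-kg environmental impact (drives the index-magnitude ladder).
DEFAULT_PRODUCTS: tuple[str, ...] = (
    "Packed water",
    "Sugar",
    "Onion",
    "Potato",
    "Apple",
    "Orange",
    "Banana",
    "Tomato",
    "Wheat bread",
    "Pasta",
    "Rice",
    "Beer",
    "Dry beans",
    "Sunflower oil",
    "Milk",
    "Wine",
    "Coffee",
    "Eggs",
    "Olive oil",
    "Chicken meat",
    "Pig meat",
    "Cod",
    "Beef",
)


@dataclass(frozen=True)
class Scenario:
    """A multiplicative what-if perturbation of an item's impact vector."""

    name: str
    kind: str  # "transport" | "production" | "origin" | "reference"
    multipliers: Mapping[str, float] = field(default_factory=dict)
    default_multiplier: float = 1.0
    transport_mode: str | None = None
    production: str | None = None
    origin: str | None = None

    def factor(self, code: str) -> float:
        f = float(self.multipliers.get(code, self.default_multiplier))
        if f <= 0:
            raise ValueError(f"scenario {self.name!r}: multiplier for {code} must be > 0")
        return f


# Air freight dominates fossil-energy-driven categories; greenhouse heating
# hits climate and energy; water-stressed origins hit water scarcity only;
# production-method tweaks are mild across the board.
SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in (
        Scenario("reference", "reference"),
        Scenario(
            "plane",
            "transport",
            {"CC": 14.0, "POF": 12.0, "RUe": 12.0, "RI": 5.0},
            default_multiplier=1.5,
            transport_mode="plane",
        ),
        Scenario(
            "long_lorry",
            "transport",
            {"CC": 2.2, "POF": 2.0, "RUe": 2.1, "RI": 1.5},
            default_multiplier=1.1,
            transport_mode="lorry",
        ),
        Scenario(
            "boat",
            "transport",
            {"CC": 1.15, "POF": 1.3, "RUe": 1.15},
            default_multiplier=1.02,
            transport_mode="boat",
        ),
        Scenario(
            "water_stressed_origin",
            "origin",
            {"WS": 6.0},
            origin="water-stressed",
        ),
        Scenario(
            "heated_greenhouse",
            "production",
            {"CC": 2.4, "RUe": 2.6},
            production="heated greenhouse",
        ),
        Scenario(
            "organic",
            "production",
            {"CC": 0.97, "ATF": 0.92, "EuF": 0.90, "EuT": 0.90, "EuM": 0.92, "LU": 1.10},
            production="organic",
        ),
        Scenario(
            "intensive",
            "production",
            {"ATF": 1.3, "EuF": 1.4, "EuT": 1.4, "EuM": 1.3},
            default_multiplier=1.05,
            production="intensive",
        ),
    )
}

TRANSPORT_SCENARIOS = tuple(s for s in SCENARIOS if SCENARIOS[s].kind == "transport")
PRODUCTION_SCENARIOS = tuple(s for s in SCENARIOS if SCENARIOS[s].kind == "production")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generators.

    ``index_span`` is the (min, max) raw-scale index magnitude of the basket
    items; the default spans all five grades.  ``category_sigma`` is the
    log-scale spread of per-category composition noise around the reference
    profile; ``consumption_median_kg``/``consumption_sigma`` parameterize the
    log-normal per-capita yearly consumption draw.
    """

    seed: int = 0
    n_products: int = 23
    population: int = EFSI_POPULATION
    index_span: tuple[float, float] = (4.0e-5, 2.0e-2)
    category_sigma: float = 0.4
    consumption_median_kg: float = 25.0
    consumption_sigma: float = 0.8
    variants_per_product: tuple[int, int] = (5, 9)
    variant_sigma: float = 0.15

    def __post_init__(self):
        if self.n_products < 1:
            raise ValueError("n_products must be >= 1")
        lo, hi = self.index_span
        if not (0 < lo < hi):
            raise ValueError(f"invalid index_span {self.index_span}")
        if self.category_sigma < 0 or self.variant_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        vlo, vhi = self.variants_per_product
        if not (1 <= vlo <= vhi):
            raise ValueError(f"invalid variants_per_product {self.variants_per_product}")


def reference_item(
    target_index: float, item_id: str = "ref", product: str = "Reference"
) -> FoodItem:
    """Deterministic item whose EFSI equals ``target_index`` exactly.

    Impacts are proportional to the bundled per-capita reference profile, so
    each category contributes in proportion to its weight.  Useful as a
    calibrated fixture, e.g. ``reference_item(3.79e-4)`` is a "sugar-like"
    grade-A product.
    """
    nf, weights = bundled_efsi_tables()
    scale = target_index / (weights.total_percent / 100.0)
    impacts = ImpactVector({c: scale * nf[c] for c in CATEGORY_CODES})
    return FoodItem(
        item_id=item_id,
        product=product,
        origin="EU-average",
        transport_mode="lorry",
        production="conventional",
        impacts=impacts,
    )


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_")


def generate_basket(config: GeneratorConfig = GeneratorConfig()) -> FoodBasket:
    """Generate a seeded reference basket of representative food items.

    Item index magnitudes are log-spaced across ``config.index_span`` (the
    default 23-product ladder places at least one item in every grade);
    per-category composition is log-normal noise around the reference
    profile, rescaled so each item's EFSI hits its ladder value exactly.
    Consumption is a log-normal per-capita draw scaled to the population.
    """
    rng = np.random.default_rng(config.seed)
    nf, weights = bundled_efsi_tables()
    w = np.array([weights[c] / 100.0 for c in CATEGORY_CODES])
    nf_vec = np.array([nf[c] for c in CATEGORY_CODES])

    n = config.n_products
    lo, hi = config.index_span
    if n == 1:
        targets = np.array([np.sqrt(lo * hi)])
    else:
        targets = np.exp(np.linspace(np.log(lo), np.log(hi), n))

    names = [
        DEFAULT_PRODUCTS[i] if i < len(DEFAULT_PRODUCTS) else f"Product {i + 1}"
        for i in range(n)
    ]
    entries = []
    for i, (name, target) in enumerate(zip(names, targets)):
        noise = np.exp(rng.normal(0.0, config.category_sigma, size=len(CATEGORY_CODES)))
        raw = nf_vec * noise
        raw_index = float((w * raw / nf_vec).sum())
        impacts_arr = raw * (target / raw_index)
        impacts = ImpactVector(dict(zip(CATEGORY_CODES, impacts_arr)))
        item = FoodItem(
            item_id=f"{_slug(name)}_{i:02d}",
            product=name,
            origin="EU-average",
            transport_mode="lorry",
            production="conventional",
            impacts=impacts,
        )
        per_capita = rng.lognormal(
            np.log(config.consumption_median_kg), config.consumption_sigma
        )
        entries.append(BasketEntry(item, per_capita * config.population))
    return FoodBasket(entries=entries, population=config.population)


def generate_hypothetical_items(
    product: FoodItem,
    scenarios: Sequence[str],
    config: GeneratorConfig | None = None,
    jitter_sigma: float = 0.0,
) -> list[FoodItem]:
    """Derive variant items from a base product by scenario multipliers.

    With an empty scenario list the base product is returned unchanged.
    ``jitter_sigma`` adds seeded log-normal per-category noise on top of the
    (deterministic) multipliers; it defaults to 0 so that a variant under an
    all-ones scenario is identical to its base.
    """
    product.impacts.require_complete(context=product.item_id)
    if not scenarios:
        return [product]
    unknown = [s for s in scenarios if s not in SCENARIOS]
    if unknown:
        raise ValueError(f"unknown scenario key(s): {unknown}; known: {sorted(SCENARIOS)}")
    rng = np.random.default_rng(config.seed if config is not None else 0)
    out = []
    for name in scenarios:
        sc = SCENARIOS[name]
        vals = {}
        for code in CATEGORY_CODES:
            v = product.impacts[code] * sc.factor(code)
            if jitter_sigma > 0:
                v *= float(np.exp(rng.normal(0.0, jitter_sigma)))
            vals[code] = v
        out.append(
            replace(
                product,
                item_id=f"{product.item_id}__{name}",
                transport_mode=sc.transport_mode or product.transport_mode,
                production=sc.production or product.production,
                origin=sc.origin or product.origin,
                impacts=ImpactVector(vals),
            )
        )
    return out


def generate_hypothetical_dataset(
    config: GeneratorConfig = GeneratorConfig(),
    n_products: int = 21,
) -> tuple[list[FoodItem], list[FoodItem]]:
    """Generate representative products plus their hypothetical variants.

    Emulates a within-product variability study: the first ``n_products``
    basket items each spawn a seeded number of variants (default 5-9, so 21
    products yield on the order of 150 items) under randomly drawn scenarios
    with mild extra jitter.  Returns ``(representatives, variants)``.
    """
    basket = generate_basket(config)
    reps = basket.items[:n_products]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    scenario_names = [s for s in SCENARIOS if s != "reference"]
    variants: list[FoodItem] = []
    vlo, vhi = config.variants_per_product
    for rep in reps:
        k = int(rng.integers(vlo, vhi + 1))
        chosen = ["reference"] + list(rng.choice(scenario_names, size=k - 1, replace=True))
        sub_cfg = replace(config, seed=int(rng.integers(0, 2**31 - 1)))
        for j, name in enumerate(chosen):
            (variant,) = generate_hypothetical_items(
                rep, [name], config=sub_cfg, jitter_sigma=config.variant_sigma
            )
            variants.append(replace(variant, item_id=f"{rep.item_id}__v{j}_{name}"))
    return reps, variants


def delphi_fixture(
    n_items: int,
    target_agreement: float,
    seed: int = 0,
    disagreement: str = "adjacent",
) -> tuple[list[str], list[str]]:
    """Paired A-E labelings with a controlled exact-agreement rate.

    Emulates an expert-panel categorization compared against an automated
    grading: ``round(target_agreement * n_items)`` pairs agree exactly; the
    rest disagree by one level (``disagreement="adjacent"``, the typical
    structure of near-miss expert panels) or by the mirrored grade
    (``"opposite"``, useful for constructing negative-kappa fixtures).
    """
    if n_items < 2:
        raise ValueError("need at least 2 items")
    if not 0.0 <= target_agreement <= 1.0:
        raise ValueError(f"target_agreement must be in [0, 1], got {target_agreement}")
    if disagreement not in ("adjacent", "opposite"):
        raise ValueError(f"unknown disagreement mode {disagreement!r}")
    rng = np.random.default_rng(seed)
    k = len(GRADES)
    score_idx = rng.integers(0, k, size=n_items)
    expert_idx = score_idx.copy()
    n_disagree = n_items - round(target_agreement * n_items)
    which = rng.choice(n_items, size=n_disagree, replace=False)
    for pos in which:
        i = int(score_idx[pos])
        if disagreement == "adjacent":
            if i == 0:
                j = 1
            elif i == k - 1:
                j = k - 2
            else:
                j = i + int(rng.choice([-1, 1]))
        else:
            j = (k - 1) - i
            if j == i:  # middle grade mirrors onto itself; push to an extreme
                j = int(rng.choice([0, k - 1]))
        expert_idx[pos] = j
    return [GRADES[i] for i in expert_idx], [GRADES[i] for i in score_idx]


def basket_grade_coverage(basket: FoodBasket) -> dict[str, int]:
    """Count basket items per Enviroscore grade under the bundled tables."""
    from .categorize import assign_enviroscore
    from .single_index import compute_efsi

    counts = {g: 0 for g in GRADES}
    for item in basket.items:
        g = assign_enviroscore(compute_efsi(item).total, DEFAULT_THRESHOLDS)
        counts[g.grade] += 1
    return counts
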