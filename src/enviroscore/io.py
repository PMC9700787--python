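"""CSV readers/writers for the package's table schemas, plus run manifests.

CSV is the canonical interchange format.  All I/O is locale-independent
(decimal point, UTF-8) and accepts scientific notation on read; raw index
values are serialized at full double precision so write/read round-trips are
exact to well below 1e-9 relative.

Schemas
-------
impacts
    ``item_id, product, origin, transport_mode, production`` followed by one
    column per category code.  An optional second header row whose item_id
    cell is ``#units`` carries the units and is validated against the
    registry.
basket
    ``item_id, annual_consumption_kg`` followed by the 13 per-kg impact
    columns; the population is supplied separately.
scores
    ``item_id, scheme, efsi_raw, efsi_milli, grade`` followed by 13
    ``contrib_<code>`` columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from .categorize import EnviroscoreGrade
from .errors import SchemaError
from .impact_model import (
    CATEGORY_CODES,
    BasketEntry,
    FoodBasket,
    FoodItem,
    ImpactVector,
    registry_by_code,
)
from .single_index import SingleIndexResult

_META_COLS = ("item_id", "product", "origin", "transport_mode", "production")
_UNITS_SENTINEL = "#units"
# repr-exact doubles; far more than the 10 significant digits the scores
# schema guarantees
_FLOAT_FMT = "%.17g"


def _read_raw(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    return df


def _pop_units_row(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    if len(df) and df.iloc[0]["item_id"] == _UNITS_SENTINEL:
        units = registry_by_code()
        row = df.iloc[0]
        bad = [
            f"{c}: {row[c]!r} != {units[c].unit!r}"
            for c in CATEGORY_CODES
            if c in df.columns and row[c] not in ("", units[c].unit)
        ]
        if bad:
            raise SchemaError(f"{path}: unit header mismatch ({'; '.join(bad)})")
        df = df.iloc[1:].reset_index(drop=True)
    return df


def _numeric(df: pd.DataFrame, cols: Sequence[str], path: Path) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        values = []
        for row, cell in enumerate(df[col]):
            try:
                # float() is correctly rounded, unlike pandas' fast parser
                values.append(float(cell))
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path}: non-numeric value {cell!r} "
                    f"in column {col!r}, data row {row + 1}"
                ) from None
        out[col] = values
    return out


def read_impacts_csv(path: str | Path) -> list[FoodItem]:
    """Read an impacts-schema CSV into validated food items (order kept)."""
    path = Path(path)
    df = _read_raw(path, (*_META_COLS, *CATEGORY_CODES))
    df = _pop_units_row(df, path)
    df = _numeric(df, CATEGORY_CODES, path)
    dupes = df["item_id"][df["item_id"].duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"{path}: duplicate item_id(s): {', '.join(dupes)}")
    items = []
    for _, row in df.iterrows():
        items.append(
            FoodItem(
                item_id=row["item_id"],
                product=row["product"],
                origin=row["origin"],
                transport_mode=row["transport_mode"],
                production=row["production"],
                impacts=ImpactVector({c: row[c] for c in CATEGORY_CODES}),
            )
        )
    return items


def write_impacts_csv(
    items: Sequence[FoodItem], path: str | Path, include_units: bool = False
) -> None:
    """Write food items in the impacts schema (optionally with a unit row)."""
    if not items:
        raise ValueError("refusing to write an empty impacts file")
    rows = []
    if include_units:
        units = registry_by_code()
        rows.append(
            {**{c: "" for c in _META_COLS}, "item_id": _UNITS_SENTINEL}
            | {c: units[c].unit for c in CATEGORY_CODES}
        )
    for it in items:
        it.impacts.require_complete(context=it.item_id)
        rows.append(
            {
                "item_id": it.item_id,
                "product": it.product,
                "origin": it.origin,
                "transport_mode": it.transport_mode,
                "production": it.production,
                **{c: it.impacts[c] for c in CATEGORY_CODES},
            }
        )
    pd.DataFrame(rows, columns=[*_META_COLS, *CATEGORY_CODES]).to_csv(
        path, index=False, float_format=_FLOAT_FMT, encoding="utf-8"
    )


def read_basket_csv(path: str | Path, population: float) -> FoodBasket:
    """Read a basket-schema CSV; the population comes from config/CLI."""
    path = Path(path)
    df = _read_raw(path, ("item_id", "annual_consumption_kg", *CATEGORY_CODES))
    df = _pop_units_row(df, path)
    df = _numeric(df, ("annual_consumption_kg", *CATEGORY_CODES), path)
    entries = []
    for _, row in df.iterrows():
        item = FoodItem(
            item_id=row["item_id"],
            product=row.get("product", row["item_id"]),
            origin=row.get("origin", ""),
            transport_mode=row.get("transport_mode", ""),
            production=row.get("production", ""),
            impacts=ImpactVector({c: row[c] for c in CATEGORY_CODES}),
        )
        entries.append(BasketEntry(item, float(row["annual_consumption_kg"])))
    return FoodBasket(entries=entries, population=population)


def write_basket_csv(basket: FoodBasket, path: str | Path) -> None:
    rows = [
        {
            "item_id": e.item.item_id,
            "product": e.item.product,
            "annual_consumption_kg": e.annual_consumption_kg,
            **{c: e.item.impacts[c] for c in CATEGORY_CODES},
        }
        for e in basket
    ]
    pd.DataFrame(
        rows, columns=["item_id", "product", "annual_consumption_kg", *CATEGORY_CODES]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT, encoding="utf-8")


def write_scores_csv(
    results: Sequence[SingleIndexResult],
    path: str | Path,
    grades: Sequence[EnviroscoreGrade] | None = None,
) -> None:
    """Write single-index results (and optional grades) in the scores schema."""
    if not results:
        raise ValueError("refusing to write an empty scores file")
    if grades is not None and len(grades) != len(results):
        raise ValueError("grades and results length mismatch")
    rows = []
    for i, res in enumerate(results):
        rows.append(
            {
                "item_id": res.item_id,
                "scheme": res.scheme,
                "efsi_raw": res.total,
                "efsi_milli": res.display_milli,
                "grade": grades[i].grade if grades is not None else "",
                **{f"contrib_{c}": res.contributions[c] for c in CATEGORY_CODES},
            }
        )
    cols = ["item_id", "scheme", "efsi_raw", "efsi_milli", "grade"] + [
        f"contrib_{c}" for c in CATEGORY_CODES
    ]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, index=False, float_format=_FLOAT_FMT, encoding="utf-8"
    )


def read_scores_csv(path: str | Path) -> pd.DataFrame:
    """Read a scores CSV back as a typed DataFrame."""
    path = Path(path)
    df = _read_raw(
        path,
        ("item_id", "scheme", "efsi_raw", "efsi_milli", "grade")
        + tuple(f"contrib_{c}" for c in CATEGORY_CODES),
    )
    return _numeric(
        df, ("efsi_raw", "efsi_milli", *(f"contrib_{c}" for c in CATEGORY_CODES)), path
    )


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    config_hash: str
    seed: int | None
    input_files: tuple[str, ...]
    output_files: tuple[str, ...]
    timestamp: str


def build_manifest(
    command: str,
    inputs: Sequence[str | Path] = (),
    outputs: Sequence[str | Path] = (),
    seed: int | None = None,
    config: dict | None = None,
) -> RunManifest:
    blob = json.dumps(config or {}, sort_keys=True).encode()
    return RunManifest(
        command=command,
        config_hash=hashlib.sha256(blob).hexdigest()[:16],
        seed=seed,
        input_files=tuple(str(p) for p in inputs),
        output_files=tuple(str(p) for p in outputs),
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2) + "\n", encoding="utf-8"
    )
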