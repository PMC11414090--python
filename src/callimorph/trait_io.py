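"""Reading, validation, and normalization of individual-level trait tables.

The raw table has one row per animal: metadata columns, the seven
single-measure traits, and left/right columns for the six bilateral traits.
Normalization averages the bilateral sides into a flat 13-trait matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import SchemaError, ValidationError
from .schema import (
    AGE_CLASSES,
    BILATERAL_TRAITS,
    META_COLUMNS,
    SEX_CODES,
    TAXON_CODES,
    TRAIT_NAMES,
    UNILATERAL_TRAITS,
)

MISSING = float("nan")

#: Strings treated as missing cells on read.
NA_VALUES = ("", "NA", "na", "NaN", "nan", "N/A")


def _is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class TraitRecord:
    """One measured animal: metadata plus unilateral and bilateral traits."""

    individual_id: str
    taxon: str
    sex: str = "unknown"
    age_class: str = "unknown"
    site: str = ""
    weight_g: float = MISSING
    unilateral_traits: dict[str, float] = field(default_factory=dict)
    bilateral_traits: dict[str, tuple[float, float]] = field(default_factory=dict)

    def flat_traits(self) -> dict[str, float]:
        """The 13-trait vector: unilateral values merged with bilateral averages."""
        flat = {"WEIGHT": self.weight_g}
        for trait in UNILATERAL_TRAITS:
            if trait == "WEIGHT":
                continue
            flat[trait] = self.unilateral_traits.get(trait, MISSING)
        flat.update(bilateral_average(self))
        return flat


@dataclass
class TraitTable:
    """An ordered collection of trait records with ingest provenance."""

    records: list[TraitRecord]
    trait_names: tuple[str, ...] = TRAIT_NAMES
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.taxon, None)
        return list(seen)

    def to_flat_frame(self) -> pd.DataFrame:
        """Normalized matrix: metadata columns plus one column per trait."""
        rows = []
        for rec in self.records:
            row = {
                "individual_id": rec.individual_id,
                "taxon": rec.taxon,
                "sex": rec.sex,
                "age_class": rec.age_class,
                "site": rec.site,
            }
            row.update(rec.flat_traits())
            rows.append(row)
        frame = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(TRAIT_NAMES))
        return frame


def bilateral_average(record: TraitRecord) -> dict[str, float]:
    """Per bilateral trait, the mean of the available sides.

    A single available side is used as-is; both sides missing yields a
    missing value. Missingness is data here, never an error.
    """
    out: dict[str, float] = {}
    for trait in BILATERAL_TRAITS:
        left, right = record.bilateral_traits.get(trait, (MISSING, MISSING))
        have = [v for v in (left, right) if not _is_missing(v)]
        out[trait] = sum(have) / len(have) if have else MISSING
    return out


def filter_adults(table: TraitTable) -> TraitTable:
    """Retain only records with ``age_class == 'adult'`` (idempotent)."""
    kept = [rec for rec in table.records if rec.age_class == "adult"]
    provenance = dict(table.provenance)
    provenance["excluded_non_adults"] = len(table.records) - len(kept)
    return TraitTable(records=kept, trait_names=table.trait_names, provenance=provenance)


# ---------------------------------------------------------------------------
# CSV dialect


DEFAULT_ALIASES: dict[str, str] = {
    "Individual": "individual_id",
    "Taxon": "taxon",
    "Sex": "sex",
    "Age": "age_class",
    "Place of Collection": "site",
    "Site": "site",
}

_MANDATORY = ("individual_id", "taxon")


def _resolve_columns(columns: list[str], aliases: dict[str, str] | None) -> dict[str, str]:
    """Map raw header names onto canonical names (case-preserving for traits)."""
    mapping = dict(DEFAULT_ALIASES)
    if aliases:
        mapping.update(aliases)
    resolved = {}
    for col in columns:
        key = mapping.get(col, col)
        if key.lower() in META_COLUMNS:
            key = key.lower()
        resolved[col] = key
    return resolved


def _coerce_number(value) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        return MISSING
    return x


def read_trait_table(path: str | Path, aliases: dict[str, str] | None = None) -> TraitTable:
    """Read a delimited trait table into a :class:`TraitTable`.

    Unparseable numeric cells become missing values (counted in the
    validation report attached to provenance), never dropped rows.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty input file: {path}") from exc

    colmap = _resolve_columns(list(raw.columns), aliases)
    raw = raw.rename(columns=colmap)

    missing_cols = [c for c in _MANDATORY if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing_cols)}")

    dupes = raw["individual_id"][raw["individual_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate individual_id values: {sorted(set(dupes))}")

    missing_counts: dict[str, int] = {}
    warnings: list[str] = []

    def get_num(row, col) -> float:
        if col not in raw.columns:
            return MISSING
        cell = row[col]
        if cell in NA_VALUES:
            missing_counts[col] = missing_counts.get(col, 0) + 1
            return MISSING
        x = _coerce_number(cell)
        if math.isnan(x):
            missing_counts[col] = missing_counts.get(col, 0) + 1
            warnings.append(f"unparseable numeric cell {col}={cell!r}")
        return x

    records = []
    for _, row in raw.iterrows():
        taxon = str(row.get("taxon", "")).strip()
        if taxon not in TAXON_CODES:
            warnings.append(f"unknown taxon code {taxon!r} for {row['individual_id']}")
        sex = str(row.get("sex", "unknown")).strip() or "unknown"
        if sex not in SEX_CODES:
            sex = "unknown"
        age = str(row.get("age_class", "unknown")).strip().lower() or "unknown"
        if age not in AGE_CLASSES:
            age = "unknown"
        uni = {t: get_num(row, t) for t in UNILATERAL_TRAITS if t != "WEIGHT"}
        bi = {
            t: (get_num(row, f"{t}_L"), get_num(row, f"{t}_R"))
            for t in BILATERAL_TRAITS
        }
        records.append(
            TraitRecord(
                individual_id=str(row["individual_id"]),
                taxon=taxon,
                sex=sex,
                age_class=age,
                site=str(row.get("site", "")),
                weight_g=get_num(row, "WEIGHT"),
                unilateral_traits=uni,
                bilateral_traits=bi,
            )
        )

    provenance = {
        "source": str(path),
        "row_count": len(records),
        "missing_cells_per_column": missing_counts,
        "warnings": warnings,
        "bilateral_single_side_fallback": True,
    }
    return TraitTable(records=records, provenance=provenance)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write the raw (pre-averaging) table back to CSV."""
    rows = []
    for rec in table.records:
        row = {
            "individual_id": rec.individual_id,
            "taxon": rec.taxon,
            "sex": rec.sex,
            "age_class": rec.age_class,
            "site": rec.site,
            "WEIGHT": rec.weight_g,
        }
        for t in UNILATERAL_TRAITS:
            if t != "WEIGHT":
                row[t] = rec.unilateral_traits.get(t, MISSING)
        for t in BILATERAL_TRAITS:
            left, right = rec.bilateral_traits.get(t, (MISSING, MISSING))
            row[f"{t}_L"] = left
            row[f"{t}_R"] = right
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_flat_table(table: TraitTable, path: str | Path) -> None:
    """Write the normalized 13-trait matrix to CSV."""
    table.to_flat_frame().to_csv(path, index=False)


def write_validation_report(table: TraitTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(table.provenance, fh, indent=2)
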