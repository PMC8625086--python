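"""Readers for the three survey tables and writer for the population CSV.

Files are RFC 4180 comma-separated UTF-8 with a mandatory header row.
Reading goes through a :class:`~rpgen.schema.SchemaMap`; rows violating a
record invariant (e.g. nonpositive sampling weight) are rejected and
counted, not fatal — unless more than half of the file rejects, which
aborts the read, so silent total loss is impossible.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .enums import (
    ETHNICITIES,
    FUELS,
    GENDERS,
    METRO_CLASSES,
    OCCUPANCIES,
    RACES,
    REGION_LABELS,
    TENURES,
)
from .errors import DataQualityError, RecodeError, SchemaError
from .schema import SchemaMap

logger = logging.getLogger("rpgen")

_REGION_NAMES = tuple(REGION_LABELS.values())
_BOOL_STRINGS = {
    "true": True, "false": False, "1": True, "0": False,
    "t": True, "f": False, "yes": True, "no": False,
}

# field name -> (kind, allowed categories or None)
PERSON_FIELDS = {
    "person_id": ("str", None),
    "household_id": ("str", None),
    "age": ("int", None),
    "gender": ("cat", GENDERS),
    "race": ("cat", RACES),
    "ethnicity": ("cat", ETHNICITIES),
    "state_fips": ("str", None),
    "puma_id": ("str", None),
    "puma_density": ("float", None),
    "household_income": ("float", None),
    "n_adults": ("int", None),
    "n_children": ("int", None),
    "raw_house_type": ("str", None),
    "weight": ("float", None),
}

HOUSING_FIELDS = {
    "housing_id": ("str", None),
    "rooms": ("int", None),
    "bedrooms": ("int", None),
    "bathrooms": ("int", None),
    "area_sqft": ("float", None),
    "raw_house_type": ("str", None),
    "metro_class": ("cat", METRO_CLASSES),
    "region": ("cat", _REGION_NAMES),
    "household_income": ("float", None),
    "tenure": ("cat", TENURES),
    "occupancy": ("cat", OCCUPANCIES),
    "n_ceiling_fans": ("int", None),
    "n_windows": ("int", None),
    "has_pool": ("bool", None),
    "has_vehicle": ("bool", None),
    "high_ceilings": ("bool", None),
    "n_adults": ("int", None),
    "n_children": ("int", None),
    "weight": ("float", None),
}

ENERGY_FIELDS = {
    "energy_id": ("str", None),
    "has_washer": ("bool", None),
    "n_cooktops": ("int", None),
    "fuel": ("cat", FUELS),
    "metro_class": ("cat", METRO_CLASSES),
    "region": ("cat", _REGION_NAMES),
    "household_income": ("float", None),
    "raw_house_type": ("str", None),
    "n_adults": ("int", None),
    "n_children": ("int", None),
    "weight": ("float", None),
}


def _apply_schema(raw: pd.DataFrame, schema: SchemaMap, fields: dict) -> pd.DataFrame:
    schema.require(fields)
    missing = [c for c in schema.columns.values() if c not in raw.columns]
    if missing:
        raise SchemaError(
            "input file lacks mapped column(s): " + ", ".join(sorted(missing))
        )
    df = pd.DataFrame(index=raw.index)
    for field in fields:
        df[field] = raw[schema.columns[field]]
    # recodes apply as string lookups
    for field, table in schema.recodes.items():
        if field not in df.columns:
            continue
        col = df[field].astype(str).str.strip()
        mapped = col.map(table)
        unmapped = mapped.isna() & col.notna()
        if unmapped.any():
            kind, allowed = fields[field]
            already_ok = (
                col.isin([str(v) for v in allowed]) if allowed else pd.Series(False, index=col.index)
            )
            unmapped &= ~already_ok
            if unmapped.any():
                row = int(np.flatnonzero(unmapped.to_numpy())[0])
                code = col.iloc[row]
                raise RecodeError(
                    f"unmapped code {code!r} for field {field!r} at input row {row}"
                )
            mapped = mapped.where(~already_ok, col)
        df[field] = mapped
    return df


def _coerce(df: pd.DataFrame, fields: dict):
    """Cast columns; return (df, invalid_mask, reasons)."""
    invalid = pd.Series(False, index=df.index)
    reasons: dict[str, int] = {}

    def flag(mask, why):
        mask = mask.fillna(False) if hasattr(mask, "fillna") else mask
        n = int(mask.sum())
        if n:
            reasons[why] = reasons.get(why, 0) + n
        return mask

    out = {}
    for field, (kind, allowed) in fields.items():
        col = df[field]
        if kind in ("int", "float"):
            num = pd.to_numeric(col, errors="coerce")
            bad = num.isna()
            if kind == "int":
                bad |= (num % 1 != 0).fillna(False)
            invalid |= flag(bad, f"non-numeric {field}")
            out[field] = num
        elif kind == "bool":
            low = col.astype(str).str.strip().str.lower()
            mapped = low.map(_BOOL_STRINGS)
            invalid |= flag(mapped.isna(), f"non-boolean {field}")
            out[field] = mapped
        elif kind == "cat":
            s = col.astype(str).str.strip()
            invalid |= flag(~s.isin(list(allowed)), f"invalid {field} code")
            out[field] = s
        else:
            out[field] = col.astype(str).str.strip()
    return pd.DataFrame(out, index=df.index), invalid, reasons


def _validate(df, invalid, reasons, checks, *, what: str) -> pd.DataFrame:
    for why, mask in checks:
        mask = mask & ~invalid
        n = int(mask.sum())
        if n:
            reasons[why] = reasons.get(why, 0) + n
        invalid |= mask
    n_bad = int(invalid.sum())
    if n_bad:
        logger.warning(
            "%s: rejected %d of %d rows (%s)",
            what, n_bad, len(df),
            "; ".join(f"{k}: {v}" for k, v in reasons.items()),
        )
    if len(df) and n_bad > len(df) / 2:
        raise DataQualityError(
            f"{what}: {n_bad} of {len(df)} rows failed validation (>50%); aborting"
        )
    out = df[~invalid].reset_index(drop=True)
    return out


def _read_raw(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"cannot read {path}: {exc}") from exc


def _cast_ints(df: pd.DataFrame, fields: dict) -> pd.DataFrame:
    for field, (kind, _) in fields.items():
        if kind == "int":
            df[field] = df[field].astype(np.int64)
        elif kind == "bool":
            df[field] = df[field].astype(bool)
    return df


def read_person_survey(path, schema: SchemaMap) -> pd.DataFrame:
    """Read a person (census-microdata-style) survey file.

    Row invariants enforced: positive weight, age in [0, 99], nonnegative
    density/income, nonnegative household member counts, valid gender /
    race / ethnicity codes. Violating rows are rejected with a logged count.
    """
    raw = _read_raw(path)
    df = _apply_schema(raw, schema, PERSON_FIELDS)
    df, invalid, reasons = _coerce(df, PERSON_FIELDS)
    num = lambda f: pd.to_numeric(df[f], errors="coerce")
    checks = [
        ("nonpositive weight", num("weight") <= 0),
        ("age out of [0,99]", (num("age") < 0) | (num("age") > 99)),
        ("negative puma_density", num("puma_density") < 0),
        ("negative income", num("household_income") < 0),
        ("negative member count", (num("n_adults") < 0) | (num("n_children") < 0)),
    ]
    out = _validate(df, invalid, reasons, checks, what="person survey")
    return _cast_ints(out, PERSON_FIELDS)


def read_housing_survey(path, schema: SchemaMap) -> pd.DataFrame:
    """Read a housing (AHS-style) survey file.

    Vacant units are *retained* here — the vacancy exclusion belongs to
    harmonization. Rows with rooms < bedrooms, nonpositive weight or area,
    or negative counts are rejected.
    """
    raw = _read_raw(path)
    df = _apply_schema(raw, schema, HOUSING_FIELDS)
    df, invalid, reasons = _coerce(df, HOUSING_FIELDS)
    num = lambda f: pd.to_numeric(df[f], errors="coerce")
    checks = [
        ("nonpositive weight", num("weight") <= 0),
        ("rooms < 1", num("rooms") < 1),
        ("rooms < bedrooms", num("rooms") < num("bedrooms")),
        ("negative bedrooms/bathrooms", (num("bedrooms") < 0) | (num("bathrooms") < 0)),
        ("nonpositive area", num("area_sqft") <= 0),
        ("negative income", num("household_income") < 0),
        ("negative counts", (num("n_ceiling_fans") < 0) | (num("n_windows") < 0)
         | (num("n_adults") < 0) | (num("n_children") < 0)),
    ]
    out = _validate(df, invalid, reasons, checks, what="housing survey")
    return _cast_ints(out, HOUSING_FIELDS)


def read_energy_survey(path, schema: SchemaMap) -> pd.DataFrame:
    """Read an energy/appliance (RECS-style) survey file."""
    raw = _read_raw(path)
    df = _apply_schema(raw, schema, ENERGY_FIELDS)
    df, invalid, reasons = _coerce(df, ENERGY_FIELDS)
    num = lambda f: pd.to_numeric(df[f], errors="coerce")
    checks = [
        ("nonpositive weight", num("weight") <= 0),
        ("negative n_cooktops", num("n_cooktops") < 0),
        ("negative income", num("household_income") < 0),
        ("negative member count", (num("n_adults") < 0) | (num("n_children") < 0)),
    ]
    out = _validate(df, invalid, reasons, checks, what="energy survey")
    return _cast_ints(out, ENERGY_FIELDS)


def write_population(pop: pd.DataFrame, path) -> None:
    """Write an assembled population, one row per individual, with header.

    Uses full float precision so that a round-trip read reproduces integer
    and categorical columns bit-exactly and reals to printed precision.
    """
    if pop is None or len(pop) == 0:
        raise ValueError("population table is empty; nothing to write")
    pop.to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    """Read a population CSV written by :func:`write_population`."""
    return pd.read_csv(path)
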