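"""Derivation of the five shared pool variables and the 1-288 pool index.

Person and household records from the three survey sources share no common
identifier, so they are linked through a coarse 5-tuple: community setting
(urban/rural), census region, condensed house type, family-composition
category, and a location-stratified income tercile. The ordered tuple is
packed into a single integer in [1, 288] (2 x 4 x 3 x 4 x 3), the ``pool``
variable, which is the join key for population assembly and is carried into
the output.

Exclusion rules applied here:

* group-quarters housing codes (military bases, prisons, shelters) are
  EXCLUDED — the housing surveys do not cover them;
* vacant housing units are EXCLUDED;
* households without at least one adult (age >= 18) are FILTERED;
* persons outside the contiguous US are discarded.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .enums import (
    FamilyCategory,
    HouseType,
    IncomeCategory,
    Region,
    Setting,
    HOUSE_TYPE_LABELS,
    REGION_FROM_LABEL,
    REGION_LABELS,
    SETTING_LABELS,
)
from .errors import DomainError, RecodeError
from .geography import normalize_fips, region_by_state

#: Population-density cutoff (people per km^2) above which a PUMA counts as
#: urban. Strictly greater-than: a density of exactly 130 is rural.
URBAN_DENSITY_THRESHOLD = 130.0

#: Sentinel for records removed because their housing type has no
#: counterpart in the household surveys, or the unit is vacant.
EXCLUDED = "EXCLUDED"

#: Sentinel for households removed by the no-adult filter.
FILTERED = "FILTERED"

#: Default raw house-type vocabulary. Schema maps may override this with the
#: source survey's own codes; values must be one of the labels below or
#: "group_quarters".
DEFAULT_HOUSE_TYPE_RECODES = {
    "house": "standalone",
    "attached house": "standalone",
    "apartment": "multi_structure",
    "condominium": "multi_structure",
    "mobile home": "other",
    "boat": "other",
    "rv": "other",
    "military base": "group_quarters",
    "prison": "group_quarters",
    "homeless shelter": "group_quarters",
    "group quarters": "group_quarters",
}

_N_SETTING, _N_REGION, _N_HOUSE, _N_FAMILY, _N_INCOME = 2, 4, 3, 4, 3
N_POOLS = _N_SETTING * _N_REGION * _N_HOUSE * _N_FAMILY * _N_INCOME


class PoolKey(NamedTuple):
    """The five category values behind one pool index."""

    setting: Setting
    region: Region
    house_type: HouseType
    family_category: FamilyCategory
    income_category: IncomeCategory

    @property
    def index(self) -> int:
        return encode_pool(*self)


# ---------------------------------------------------------------------------
# scalar classifiers
# ---------------------------------------------------------------------------

def classify_setting_density(density: float) -> Setting:
    """Urban/rural from PUMA population density (people per km^2).

    The cutoff is strictly greater than 130/km^2: 131 is urban, 130 rural.
    """
    if density < 0:
        raise DomainError(f"density must be nonnegative, got {density!r}")
    return Setting.URBAN if density > URBAN_DENSITY_THRESHOLD else Setting.RURAL


def classify_setting_metro(metro_class: str) -> Setting:
    """Urban/rural from the OMB statistical-area class.

    Metropolitan areas are urban; micropolitan and all other areas rural.
    """
    if metro_class == "metropolitan":
        return Setting.URBAN
    if metro_class in ("micropolitan", "neither"):
        return Setting.RURAL
    raise RecodeError(f"unknown metro class {metro_class!r}")


def classify_house_type(raw_code: str, recodes: dict | None = None):
    """Condense a raw housing-unit code to the three shared categories.

    Returns a :class:`HouseType`, or :data:`EXCLUDED` for group-quarters
    codes, which have no counterpart in the household surveys.
    """
    table = DEFAULT_HOUSE_TYPE_RECODES if recodes is None else recodes
    try:
        target = table[str(raw_code)]
    except KeyError:
        raise RecodeError(f"unmapped house-type code {raw_code!r}") from None
    if target == "group_quarters":
        return EXCLUDED
    try:
        return {v: k for k, v in HOUSE_TYPE_LABELS.items()}[target]
    except KeyError:
        raise RecodeError(
            f"house-type recode target {target!r} is not a valid category"
        ) from None


def classify_family_category(n_adults: int, n_children: int):
    """Household composition bin; FILTERED when the household has no adult."""
    if n_adults < 0 or n_children < 0:
        raise DomainError("household member counts must be nonnegative")
    if n_adults == 0:
        return FILTERED
    if n_children == 0:
        return (
            FamilyCategory.ONE_ADULT_NO_CHILDREN
            if n_adults == 1
            else FamilyCategory.MULTI_ADULT_NO_CHILDREN
        )
    return (
        FamilyCategory.ONE_ADULT_WITH_CHILDREN
        if n_adults == 1
        else FamilyCategory.MULTI_ADULT_WITH_CHILDREN
    )


def family_category_from_ages(ages) -> object:
    """Family bin from a household's member ages (adult = age >= 18)."""
    ages = np.asarray(list(ages))
    n_adults = int((ages >= 18).sum())
    return classify_family_category(n_adults, len(ages) - n_adults)


# ---------------------------------------------------------------------------
# income terciles
# ---------------------------------------------------------------------------

def assign_income_categories(income, location) -> np.ndarray:
    """Location-stratified income terciles, coded 1 (high) to 3 (low).

    Households are first grouped by location — the (setting, region) pair —
    and ranked by income within each group, so the category reflects local
    purchasing power. Each group is split into three bins of equal size;
    when the group size is not divisible by 3 the extra members go to the
    lower categories (3 first, then 2). Ties are broken by stable input
    order.

    Parameters
    ----------
    income : array-like of nonnegative reals
    location : array-like of hashables (one group key per record)

    Returns
    -------
    numpy.ndarray of int, same length, values in {1, 2, 3}.
    """
    income = np.asarray(income, dtype=float)
    location = np.asarray(location, dtype=object)
    if income.ndim != 1 or income.shape != location.shape:
        raise DomainError("income and location must be parallel 1-d arrays")
    if np.any(~np.isfinite(income)) or np.any(income < 0):
        raise DomainError("income must be finite and nonnegative")

    out = np.empty(len(income), dtype=np.int64)
    for key in pd.unique(location):
        rows = np.flatnonzero(location == key)
        n = len(rows)
        order = rows[np.argsort(income[rows], kind="stable")]
        base, rem = divmod(n, 3)
        n_low = base + (1 if rem >= 1 else 0)
        n_mid = base + (1 if rem == 2 else 0)
        out[order[:n_low]] = int(IncomeCategory.LOW)
        out[order[n_low : n_low + n_mid]] = int(IncomeCategory.MIDDLE)
        out[order[n_low + n_mid :]] = int(IncomeCategory.HIGH)
    return out


# ---------------------------------------------------------------------------
# pool index
# ---------------------------------------------------------------------------

def encode_pool(setting, region, house_type, family_category, income_category):
    """Pack the five category codes into the pool index in [1, 288].

    The ordering is fixed and documented: setting varies slowest, then
    region, house type, family category, and income category fastest::

        index = ((((s-1)*4 + (r-1))*3 + (h-1))*4 + (f-1))*3 + c

    Accepts scalars (enums or ints) or parallel integer arrays.
    """
    s = np.asarray(setting, dtype=np.int64)
    r = np.asarray(region, dtype=np.int64)
    h = np.asarray(house_type, dtype=np.int64)
    f = np.asarray(family_category, dtype=np.int64)
    c = np.asarray(income_category, dtype=np.int64)
    for arr, hi, name in (
        (s, _N_SETTING, "setting"),
        (r, _N_REGION, "region"),
        (h, _N_HOUSE, "house_type"),
        (f, _N_FAMILY, "family_category"),
        (c, _N_INCOME, "income_category"),
    ):
        if np.any((arr < 1) | (arr > hi)):
            raise DomainError(f"{name} code out of range 1..{hi}")
    idx = ((((s - 1) * _N_REGION + (r - 1)) * _N_HOUSE + (h - 1)) * _N_FAMILY
           + (f - 1)) * _N_INCOME + c
    if idx.ndim == 0:
        return int(idx)
    return idx


def decode_pool(index) -> PoolKey:
    """Invert :func:`encode_pool`; scalar indices only."""
    i = int(index)
    if not 1 <= i <= N_POOLS:
        raise DomainError(f"pool index {index!r} outside 1..{N_POOLS}")
    i -= 1
    i, c = divmod(i, _N_INCOME)
    i, f = divmod(i, _N_FAMILY)
    i, h = divmod(i, _N_HOUSE)
    s, r = divmod(i, _N_REGION)
    return PoolKey(
        Setting(s + 1),
        Region(r + 1),
        HouseType(h + 1),
        FamilyCategory(f + 1),
        IncomeCategory(c + 1),
    )


# ---------------------------------------------------------------------------
# table-level harmonizers
# ---------------------------------------------------------------------------

def _finalize(df, setting_codes, region_codes, house_codes, family_codes):
    """Attach label + pool columns given integer category code arrays."""
    loc_keys = np.array(
        [f"{s}-{r}" for s, r in zip(setting_codes, region_codes)], dtype=object
    )
    inccat = assign_income_categories(df["household_income"].to_numpy(), loc_keys)
    df = df.copy()
    df["setting"] = [SETTING_LABELS[Setting(s)] for s in setting_codes]
    df["region"] = [REGION_LABELS[Region(r)] for r in region_codes]
    df["house_type"] = [HOUSE_TYPE_LABELS[HouseType(h)] for h in house_codes]
    df["family_category"] = np.asarray(family_codes, dtype=np.int64)
    df["inccat"] = inccat
    df["pool"] = encode_pool(
        setting_codes, region_codes, house_codes, family_codes, inccat
    )
    return df


def harmonize_persons(persons: pd.DataFrame, house_type_recodes: dict | None = None):
    """Derive pool variables for a validated person table.

    Returns ``(harmonized, summary)`` where *harmonized* has added columns
    ``setting, region, house_type, family_category, inccat, pool`` and
    *summary* counts the rows removed by each rule: group-quarters housing
    (EXCLUDED), zero-adult households (FILTERED), and non-contiguous states
    (discarded).
    """
    df = persons.copy()
    summary = {"input": len(df)}

    regions = df["state_fips"].map(lambda f: region_by_state().get(normalize_fips(f)))
    contiguous = regions.notna()
    summary["discarded_noncontiguous"] = int((~contiguous).sum())
    df, regions = df[contiguous], regions[contiguous]

    ht = df["raw_house_type"].map(
        lambda code: classify_house_type(code, house_type_recodes)
    )
    gq = ht == EXCLUDED
    summary["excluded_group_quarters"] = int(gq.sum())
    df, ht, regions = df[~gq], ht[~gq], regions[~gq]

    fam = [
        classify_family_category(int(a), int(c))
        for a, c in zip(df["n_adults"], df["n_children"])
    ]
    no_adult = np.array([f is FILTERED for f in fam])
    summary["filtered_zero_adult"] = int(no_adult.sum())
    df, regions, ht = df[~no_adult], regions[~no_adult], ht[~no_adult]
    fam = [int(f) for f, drop in zip(fam, no_adult) if not drop]

    setting_codes = [
        int(classify_setting_density(d)) for d in df["puma_density"].to_numpy()
    ]
    region_codes = [int(REGION_FROM_LABEL[r]) for r in regions]
    house_codes = [int(h) for h in ht]

    # Income terciles are a household-level quantity: rank each household
    # once per location and broadcast the category to its members, so large
    # households do not drag the boundaries.
    loc_keys = np.array(
        [f"{s}-{r}" for s, r in zip(setting_codes, region_codes)], dtype=object
    )
    hh = pd.DataFrame(
        {
            "household_id": df["household_id"].to_numpy(),
            "income": df["household_income"].to_numpy(dtype=float),
            "loc": loc_keys,
        }
    ).drop_duplicates("household_id")
    hh_cat = assign_income_categories(hh["income"].to_numpy(), hh["loc"].to_numpy())
    cat_by_hh = dict(zip(hh["household_id"], hh_cat))

    out = df.copy()
    out["setting"] = [SETTING_LABELS[Setting(s)] for s in setting_codes]
    out["region"] = [REGION_LABELS[Region(r)] for r in region_codes]
    out["house_type"] = [HOUSE_TYPE_LABELS[HouseType(h)] for h in house_codes]
    out["family_category"] = np.asarray(fam, dtype=np.int64)
    out["inccat"] = out["household_id"].map(cat_by_hh).astype(np.int64)
    out["pool"] = encode_pool(
        setting_codes, region_codes, house_codes, fam, out["inccat"].to_numpy()
    )
    summary["output"] = len(out)
    return out, summary


def harmonize_housing(housing: pd.DataFrame, house_type_recodes: dict | None = None):
    """Derive pool variables for a validated housing table.

    Vacant units and group-quarters codes are EXCLUDED before income
    terciles are computed, so discarded rows do not shift the boundaries.
    """
    df = housing.copy()
    summary = {"input": len(df)}

    vacant = df["occupancy"] == "vacant"
    summary["excluded_vacant"] = int(vacant.sum())
    df = df[~vacant]

    ht = df["raw_house_type"].map(
        lambda code: classify_house_type(code, house_type_recodes)
    )
    gq = ht == EXCLUDED
    summary["excluded_group_quarters"] = int(gq.sum())
    df, ht = df[~gq], ht[~gq]

    # AHS-style rows describe the unit, not the occupants, so the family
    # category comes from the reported household composition columns when
    # present; otherwise the bins cannot be formed.
    fam = [
        classify_family_category(int(a), int(c))
        for a, c in zip(df["n_adults"], df["n_children"])
    ]
    no_adult = np.array([f is FILTERED for f in fam], dtype=bool)
    summary["filtered_zero_adult"] = int(no_adult.sum())
    df = df[~no_adult]
    ht = ht[~no_adult]
    fam = [int(f) for f, drop in zip(fam, no_adult) if not drop]

    setting_codes = [int(classify_setting_metro(m)) for m in df["metro_class"]]
    region_codes = [int(REGION_FROM_LABEL[r]) for r in df["region"]]
    house_codes = [int(h) for h in ht]

    out = _finalize(df, setting_codes, region_codes, house_codes, fam)
    summary["output"] = len(out)
    return out, summary


def harmonize_energy(energy: pd.DataFrame, house_type_recodes: dict | None = None):
    """Derive pool variables for a validated energy/appliance table."""
    df = energy.copy()
    summary = {"input": len(df)}

    ht = df["raw_house_type"].map(
        lambda code: classify_house_type(code, house_type_recodes)
    )
    gq = ht == EXCLUDED
    summary["excluded_group_quarters"] = int(gq.sum())
    df, ht = df[~gq], ht[~gq]

    fam = [
        classify_family_category(int(a), int(c))
        for a, c in zip(df["n_adults"], df["n_children"])
    ]
    no_adult = np.array([f is FILTERED for f in fam], dtype=bool)
    summary["filtered_zero_adult"] = int(no_adult.sum())
    df = df[~no_adult]
    ht = ht[~no_adult]
    fam = [int(f) for f, drop in zip(fam, no_adult) if not drop]

    setting_codes = [int(classify_setting_metro(m)) for m in df["metro_class"]]
    region_codes = [int(REGION_FROM_LABEL[r]) for r in df["region"]]
    house_codes = [int(h) for h in ht]

    out = _finalize(df, setting_codes, region_codes, house_codes, fam)
    summary["output"] = len(out)
    return out, summary
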