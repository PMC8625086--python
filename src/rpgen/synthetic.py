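"""Synthetic person, housing, and energy survey tables.

Emulates the three survey sources — a person microdata sample, a housing
survey, and an energy/appliance survey — with controllable size, seed,
weight distributions, pool coverage, and correlation structure, so the full
pipeline is testable without any external downloads. Incomes are lognormal
per location (urban medians above rural, reproducing the purchasing-power
stratification); rooms, floor area and income in the housing table follow a
Gaussian copula with a configurable positive correlation.

With ``ensure_full_pool_coverage`` the generators construct, per location,
balanced (house type x family category x income third) cells whose incomes
are drawn inside disjoint tercile quantile bands of the location's income
distribution. The downstream tercile split then coincides exactly with the
intended thirds and every one of the 288 pools is guaranteed nonempty;
row counts are padded up to a multiple of 36 per location as needed.

The tables returned are in the *internal* representation (what the survey
readers produce). :func:`write_survey_fixtures` encodes them back into
raw-coded CSV files with matching schema maps, exercising the full read
path.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .enums import FUELS, REGION_LABELS
from .harmonize import harmonize_energy, harmonize_housing
from .schema import SchemaMap

REGIONS = tuple(REGION_LABELS.values())
SETTINGS = ("urban", "rural")
#: The eight locations: (setting, region) in pool order.
LOCATIONS = tuple((s, r) for s in SETTINGS for r in REGIONS)

#: Two representative contiguous states per region (FIPS codes).
STATES_BY_REGION = {
    "Northeast": ("36", "25"),
    "Midwest": ("17", "39"),
    "South": ("48", "13"),
    "West": ("06", "08"),
}

#: Raw house-type codes used by the synthetic survey dialect.
HOUSE_CODES_BY_TYPE = {1: ("01", "02"), 2: ("03", "04"), 3: ("05", "06")}
GROUP_QUARTERS_CODES = ("07", "08", "09")
SYNTHETIC_HOUSE_TYPE_RECODES = {
    "01": "standalone", "02": "standalone",
    "03": "multi_structure", "04": "multi_structure",
    "05": "other", "06": "other",
    "07": "group_quarters", "08": "group_quarters", "09": "group_quarters",
}

#: (median USD/yr, lognormal sigma) per location; urban above rural.
DEFAULT_INCOME_PARAMS = {
    "urban-Northeast": (75000.0, 0.7),
    "urban-Midwest": (62000.0, 0.7),
    "urban-South": (58000.0, 0.7),
    "urban-West": (72000.0, 0.7),
    "rural-Northeast": (58000.0, 0.7),
    "rural-Midwest": (52000.0, 0.7),
    "rural-South": (45000.0, 0.7),
    "rural-West": (55000.0, 0.7),
}

_HOUSE_TYPE_P = (0.62, 0.28, 0.10)
_FAMILY_P = (0.15, 0.30, 0.15, 0.40)
_RACE_P = dict(zip("WBNAPO", (0.72, 0.13, 0.01, 0.05, 0.005, 0.085)))
_ETH_P = dict(zip("NMO", (0.82, 0.11, 0.07)))


class SyntheticSurveyConfig(BaseModel):
    """Knobs for the three synthetic survey tables."""

    n_persons: int = Field(default=5000, ge=1)
    n_housing: int = Field(default=2000, ge=1)
    n_energy: int = Field(default=1500, ge=1)
    seed: int = 1001
    ensure_full_pool_coverage: bool = False
    leave_pools_empty: list[int] = Field(default_factory=list)
    income_lognormal_params: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_INCOME_PARAMS)
    )
    rooms_area_income_correlation: float = Field(default=0.5, gt=-1.0, lt=1.0)
    inject_zero_adult_households: float = Field(default=0.0, ge=0.0, le=1.0)
    vacant_fraction: float = Field(default=0.05, ge=0.0, le=0.5)
    group_quarters_fraction: float = Field(default=0.0, ge=0.0, le=0.5)
    person_group_quarters_fraction: float = Field(default=0.0, ge=0.0, le=0.5)
    washer_prob: float | None = Field(default=None, ge=0.0, le=1.0)


def _loc_key(setting: str, region: str) -> str:
    return f"{setting}-{region}"


def _income_dist(cfg: SyntheticSurveyConfig, setting: str, region: str):
    median, sigma = cfg.income_lognormal_params[_loc_key(setting, region)]
    return median, sigma


def _banded_uniform(rng, third: int) -> float:
    """Uniform quantile inside tercile band ``third`` (1=low..3=high)."""
    lo = (third - 1) / 3 + 0.02
    hi = third / 3 - 0.02
    return float(rng.uniform(lo, hi))


def _composition(rng, fam: int) -> tuple[int, int]:
    if fam == 1:
        return 1, 0
    if fam == 2:
        return int(rng.integers(2, 4)), 0
    if fam == 3:
        return 1, int(rng.integers(1, 4))
    return int(rng.integers(2, 4)), int(rng.integers(1, 4))


def _household_cells(cfg, rng, n_target: int):
    """Yield (setting, region, htype, fam, u_income) household skeletons.

    With full pool coverage, cells per location are balanced across the 36
    (house type, family, income-third) combinations; otherwise they are
    drawn independently with realistic marginals.
    """
    cells = []
    if cfg.ensure_full_pool_coverage:
        per_loc = max(36, math.ceil(n_target / len(LOCATIONS) / 36) * 36)
        for setting, region in LOCATIONS:
            block = [
                (h, f, t)
                for h in (1, 2, 3)
                for f in (1, 2, 3, 4)
                for t in (1, 2, 3)
            ] * (per_loc // 36)
            for h, f, t in block:
                cells.append((setting, region, h, f, _banded_uniform(rng, t)))
    else:
        for _ in range(n_target):
            setting, region = LOCATIONS[int(rng.integers(len(LOCATIONS)))]
            h = int(rng.choice((1, 2, 3), p=_HOUSE_TYPE_P))
            f = int(rng.choice((1, 2, 3, 4), p=_FAMILY_P))
            cells.append((setting, region, h, f, float(rng.uniform(0.001, 0.999))))
    return cells


def _density_for(rng, setting: str) -> float:
    if setting == "urban":
        return round(130.0 * float(np.exp(rng.uniform(0.2, 2.5))), 1)
    return round(130.0 * float(rng.uniform(0.05, 1.0)), 1)


def generate_person_survey(cfg: SyntheticSurveyConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Person-microdata emulator in the internal representation.

    Households always contain at least one adult unless
    ``inject_zero_adult_households`` asks for a share of adult-free
    households (to exercise the downstream family filter). PUMA densities
    span both sides of the 130/km^2 urban cutoff.
    """
    n_hh = math.ceil(cfg.n_persons / 2.6)
    cells = _household_cells(cfg, rng, n_hh)
    rows = []
    for hh_idx, (setting, region, htype, fam, u_inc) in enumerate(cells):
        median, sigma = _income_dist(cfg, setting, region)
        income = round(float(stats.lognorm.ppf(u_inc, s=sigma, scale=median)), 2)
        n_adults, n_children = _composition(rng, fam)
        if cfg.inject_zero_adult_households > 0 and rng.random() < cfg.inject_zero_adult_households:
            n_adults, n_children = 0, int(rng.integers(1, 3))
        if cfg.person_group_quarters_fraction > 0 and rng.random() < cfg.person_group_quarters_fraction:
            house_code = str(rng.choice(GROUP_QUARTERS_CODES))
        else:
            house_code = str(rng.choice(HOUSE_CODES_BY_TYPE[htype]))
        state = str(rng.choice(STATES_BY_REGION[region]))
        puma = f"{state}{int(rng.integers(100, 120)):05d}"
        density = _density_for(rng, setting)
        ages = [int(rng.integers(18, 100)) for _ in range(n_adults)]
        ages += [int(rng.integers(0, 18)) for _ in range(n_children)]
        for age in ages:
            rows.append({
                "person_id": f"P{len(rows):07d}",
                "household_id": f"H{hh_idx:06d}",
                "age": age,
                "gender": str(rng.choice(list("MF"))),
                "race": str(rng.choice(list(_RACE_P), p=list(_RACE_P.values()))),
                "ethnicity": str(rng.choice(list(_ETH_P), p=list(_ETH_P.values()))),
                "state_fips": state,
                "puma_id": puma,
                "puma_density": density,
                "household_income": income,
                "n_adults": n_adults,
                "n_children": n_children,
                "raw_house_type": house_code,
                "weight": round(100.0 * float(np.exp(rng.normal(0.0, 0.5))), 2),
            })
    df = pd.DataFrame(rows)
    if not cfg.ensure_full_pool_coverage and len(df) > cfg.n_persons:
        df = df.iloc[: cfg.n_persons].reset_index(drop=True)
    return df


def _conditional_copula(rng, z_inc: np.ndarray, rho: float):
    """Draw (z_rooms, z_area) | z_income under equicorrelation ``rho``."""
    n = len(z_inc)
    if abs(rho) < 1e-12:
        return rng.standard_normal(n), rng.standard_normal(n)
    a = math.sqrt(1.0 - rho**2)
    b = (rho - rho**2) / a
    c = math.sqrt(max(1.0 - rho**2 - b**2, 1e-12))
    e1, e2 = rng.standard_normal(n), rng.standard_normal(n)
    z_rooms = rho * z_inc + a * e1
    z_area = rho * z_inc + b * e1 + c * e2
    return z_rooms, z_area


def _drop_pools(df: pd.DataFrame, pools: list[int], harmonizer, id_col: str,
                max_iter: int = 20) -> pd.DataFrame:
    """Remove rows landing in the given pools, to a fixpoint.

    Dropping rows moves the tercile boundaries, which can push other rows
    into the vacated pool, so harmonization is recomputed after each drop
    until no row maps there.
    """
    targets = set(int(p) for p in pools)
    for _ in range(max_iter):
        harm, _ = harmonizer(df, SYNTHETIC_HOUSE_TYPE_RECODES)
        bad_ids = set(harm.loc[harm["pool"].isin(targets), id_col])
        if not bad_ids:
            return df.reset_index(drop=True)
        df = df[~df[id_col].isin(bad_ids)]
    raise RuntimeError(f"could not empty pools {sorted(targets)} after {max_iter} passes")


def generate_housing_survey(cfg: SyntheticSurveyConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Housing-survey emulator with correlated rooms / area / income.

    A configurable share of vacant and group-quarters rows is appended to
    exercise the harmonization exclusions (they are excluded before income
    terciles are computed, so they cannot disturb pool coverage).
    """
    cells = _household_cells(cfg, rng, cfg.n_housing)
    rho = cfg.rooms_area_income_correlation
    n = len(cells)
    u_inc = np.array([c[4] for c in cells])
    z_inc = stats.norm.ppf(u_inc)
    z_rooms, z_area = _conditional_copula(rng, z_inc, rho)

    rows = []
    for i, (setting, region, htype, fam, u) in enumerate(cells):
        median, sigma = _income_dist(cfg, setting, region)
        income = round(float(median * np.exp(sigma * z_inc[i])), 2)
        rooms = int(np.clip(round(5.5 + 2.2 * z_rooms[i]), 1, 14))
        bedrooms = int(np.clip(round(0.45 * rooms + rng.normal(0, 0.5)), 0, rooms))
        n_adults, n_children = _composition(rng, fam)
        rows.append({
            "housing_id": f"A{i:06d}",
            "rooms": rooms,
            "bedrooms": bedrooms,
            "bathrooms": int(np.clip(round(1 + rooms / 5 + rng.normal(0, 0.4)), 1, 4)),
            "area_sqft": round(float(1700.0 * np.exp(0.5 * z_area[i])), 1),
            "raw_house_type": str(rng.choice(HOUSE_CODES_BY_TYPE[htype])),
            "metro_class": "metropolitan" if setting == "urban"
                           else str(rng.choice(("micropolitan", "neither"))),
            "region": region,
            "household_income": income,
            "tenure": str(rng.choice(("own", "rent", "occupy_without_rent"),
                                     p=(0.65, 0.32, 0.03))),
            "occupancy": "occupied",
            "n_ceiling_fans": int(rng.poisson(1.2)),
            "n_windows": int(2 + rng.poisson(8)),
            "has_pool": bool(rng.random() < 0.03 + 0.12 * u),
            "has_vehicle": bool(rng.random() < 0.75 + 0.2 * u),
            "high_ceilings": bool(rng.random() < 0.2),
            "n_adults": n_adults,
            "n_children": n_children,
            "weight": round(50.0 * float(np.exp(rng.normal(0.0, 0.5))), 2),
        })
    df = pd.DataFrame(rows)

    extras = []
    n_vacant = round(cfg.vacant_fraction * n)
    n_gq = round(cfg.group_quarters_fraction * n)
    for j in range(n_vacant + n_gq):
        setting, region = LOCATIONS[int(rng.integers(len(LOCATIONS)))]
        median, sigma = _income_dist(cfg, setting, region)
        vacant = j < n_vacant
        code = (str(rng.choice(HOUSE_CODES_BY_TYPE[int(rng.integers(1, 4))]))
                if vacant else str(rng.choice(GROUP_QUARTERS_CODES)))
        rooms = int(rng.integers(2, 9))
        extras.append({
            "housing_id": f"A{n + j:06d}",
            "rooms": rooms,
            "bedrooms": int(rng.integers(0, rooms + 1)),
            "bathrooms": int(rng.integers(1, 4)),
            "area_sqft": round(float(1400.0 * np.exp(rng.normal(0, 0.4))), 1),
            "raw_house_type": code,
            "metro_class": "metropolitan" if setting == "urban"
                           else str(rng.choice(("micropolitan", "neither"))),
            "region": region,
            "household_income": round(float(stats.lognorm.rvs(
                sigma, scale=median, random_state=rng)), 2),
            "tenure": "own",
            "occupancy": "vacant" if vacant else "occupied",
            "n_ceiling_fans": int(rng.poisson(1.2)),
            "n_windows": int(2 + rng.poisson(8)),
            "has_pool": False,
            "has_vehicle": True,
            "high_ceilings": False,
            "n_adults": int(rng.integers(1, 3)),
            "n_children": int(rng.integers(0, 3)),
            "weight": round(50.0 * float(np.exp(rng.normal(0.0, 0.5))), 2),
        })
    if extras:
        df = pd.concat([df, pd.DataFrame(extras)], ignore_index=True)
    if cfg.leave_pools_empty:
        df = _drop_pools(df, cfg.leave_pools_empty, harmonize_housing, "housing_id")
    return df


def generate_energy_survey(cfg: SyntheticSurveyConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Energy/appliance-survey emulator.

    Appliance indicators are Bernoulli with income-dependent probabilities
    (washer ownership rises with the within-location income quantile unless
    ``washer_prob`` pins it).
    """
    cells = _household_cells(cfg, rng, cfg.n_energy)
    rows = []
    for i, (setting, region, htype, fam, u) in enumerate(cells):
        median, sigma = _income_dist(cfg, setting, region)
        income = round(float(stats.lognorm.ppf(u, s=sigma, scale=median)), 2)
        p_washer = cfg.washer_prob if cfg.washer_prob is not None else 0.45 + 0.5 * u
        n_adults, n_children = _composition(rng, fam)
        rows.append({
            "energy_id": f"E{i:06d}",
            "has_washer": bool(rng.random() < p_washer),
            "n_cooktops": int(1 + (rng.random() < 0.12)),
            "fuel": str(rng.choice(FUELS, p=(0.42, 0.40, 0.06, 0.05, 0.04, 0.03))),
            "metro_class": "metropolitan" if setting == "urban"
                           else str(rng.choice(("micropolitan", "neither"))),
            "region": region,
            "household_income": income,
            "raw_house_type": str(rng.choice(HOUSE_CODES_BY_TYPE[htype])),
            "n_adults": n_adults,
            "n_children": n_children,
            "weight": round(60.0 * float(np.exp(rng.normal(0.0, 0.5))), 2),
        })
    df = pd.DataFrame(rows)
    if cfg.leave_pools_empty:
        df = _drop_pools(df, cfg.leave_pools_empty, harmonize_energy, "energy_id")
    return df


def generate_surveys(cfg: SyntheticSurveyConfig):
    """All three tables from independent sub-streams of ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_p, rng_h, rng_e = (np.random.default_rng(s) for s in ss.spawn(3))
    return (
        generate_person_survey(cfg, rng_p),
        generate_housing_survey(cfg, rng_h),
        generate_energy_survey(cfg, rng_e),
    )


# ---------------------------------------------------------------------------
# raw-coded fixture files + schema maps
# ---------------------------------------------------------------------------

_RACE_TO_RAW = {r: str(i + 1) for i, r in enumerate("WBNAPO")}
_ETH_TO_RAW = {"N": "1", "M": "2", "O": "3"}
_REGION_TO_RAW = {r: str(i + 1) for i, r in enumerate(REGIONS)}
_FUEL_TO_RAW = {f: str(i + 1) for i, f in enumerate(FUELS)}


def person_schema_map() -> SchemaMap:
    return SchemaMap(
        columns={
            "person_id": "PID", "household_id": "HHID", "age": "AGEP",
            "gender": "SEX", "race": "RAC1P", "ethnicity": "HISP",
            "state_fips": "ST", "puma_id": "PUMA", "puma_density": "DENSITY",
            "household_income": "HINCP", "n_adults": "NRA",
            "n_children": "NRC", "raw_house_type": "BLD", "weight": "PWGTP",
        },
        recodes={
            "gender": {"1": "M", "2": "F"},
            "race": {v: k for k, v in _RACE_TO_RAW.items()},
            "ethnicity": {v: k for k, v in _ETH_TO_RAW.items()},
        },
        house_type_recodes=dict(SYNTHETIC_HOUSE_TYPE_RECODES),
    )


def housing_schema_map() -> SchemaMap:
    return SchemaMap(
        columns={
            "housing_id": "CONTROL", "rooms": "ROOMS", "bedrooms": "BEDRMS",
            "bathrooms": "BATHS", "area_sqft": "UNITSF",
            "raw_house_type": "BLD", "metro_class": "METRO",
            "region": "REGION", "household_income": "HINCP",
            "tenure": "TEN", "occupancy": "VAC",
            "n_ceiling_fans": "CEILFAN", "n_windows": "WINDOWS",
            "has_pool": "POOL", "has_vehicle": "VEH",
            "high_ceilings": "HICEIL", "n_adults": "NRA",
            "n_children": "NRC", "weight": "WEIGHT",
        },
        recodes={
            "metro_class": {"1": "metropolitan", "2": "micropolitan", "3": "neither"},
            "region": {v: k for k, v in _REGION_TO_RAW.items()},
            "tenure": {"1": "own", "2": "rent", "3": "occupy_without_rent"},
            "occupancy": {"0": "occupied", "1": "vacant"},
            "has_pool": {"1": "true", "2": "false"},
            "has_vehicle": {"1": "true", "2": "false"},
            "high_ceilings": {"1": "true", "2": "false"},
        },
        house_type_recodes=dict(SYNTHETIC_HOUSE_TYPE_RECODES),
    )


def energy_schema_map() -> SchemaMap:
    return SchemaMap(
        columns={
            "energy_id": "DOEID", "has_washer": "WASHER",
            "n_cooktops": "NUMCOOK", "fuel": "FUEL", "metro_class": "METRO",
            "region": "REGION", "household_income": "MONEYPY",
            "raw_house_type": "TYPEHUQ", "n_adults": "NRA",
            "n_children": "NRC", "weight": "NWEIGHT",
        },
        recodes={
            "fuel": {v: k for k, v in _FUEL_TO_RAW.items()},
            "metro_class": {"METRO": "metropolitan", "MICRO": "micropolitan",
                            "NONE": "neither"},
            "region": {v: k for k, v in _REGION_TO_RAW.items()},
        },
        house_type_recodes=dict(SYNTHETIC_HOUSE_TYPE_RECODES),
    )


def _encode_raw_person(df: pd.DataFrame) -> pd.DataFrame:
    m = person_schema_map().columns
    out = pd.DataFrame()
    for internal, raw in m.items():
        col = df[internal]
        if internal == "gender":
            col = col.map({"M": "1", "F": "2"})
        elif internal == "race":
            col = col.map(_RACE_TO_RAW)
        elif internal == "ethnicity":
            col = col.map(_ETH_TO_RAW)
        out[raw] = col
    return out


def _encode_raw_housing(df: pd.DataFrame) -> pd.DataFrame:
    m = housing_schema_map().columns
    bool_raw = lambda col: col.map({True: "1", False: "2"})
    out = pd.DataFrame()
    for internal, raw in m.items():
        col = df[internal]
        if internal == "metro_class":
            col = col.map({"metropolitan": "1", "micropolitan": "2", "neither": "3"})
        elif internal == "region":
            col = col.map(_REGION_TO_RAW)
        elif internal == "tenure":
            col = col.map({"own": "1", "rent": "2", "occupy_without_rent": "3"})
        elif internal == "occupancy":
            col = col.map({"occupied": "0", "vacant": "1"})
        elif internal in ("has_pool", "has_vehicle", "high_ceilings"):
            col = bool_raw(col)
        out[raw] = col
    return out


def _encode_raw_energy(df: pd.DataFrame) -> pd.DataFrame:
    m = energy_schema_map().columns
    out = pd.DataFrame()
    for internal, raw in m.items():
        col = df[internal]
        if internal == "has_washer":
            col = col.map({True: "1", False: "0"})
        elif internal == "fuel":
            col = col.map(_FUEL_TO_RAW)
        elif internal == "metro_class":
            col = col.map({"metropolitan": "METRO", "micropolitan": "MICRO",
                           "neither": "NONE"})
        elif internal == "region":
            col = col.map(_REGION_TO_RAW)
        out[raw] = col
    return out


def write_survey_fixtures(outdir, cfg: SyntheticSurveyConfig) -> dict:
    """Emit the three raw-coded survey CSVs plus matching schema-map YAMLs.

    Returns a dict of the six paths keyed ``person``, ``person_schema``, ...
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    persons, housing, energy = generate_surveys(cfg)
    paths = {}
    for name, df, encoder, schema in (
        ("person", persons, _encode_raw_person, person_schema_map()),
        ("housing", housing, _encode_raw_housing, housing_schema_map()),
        ("energy", energy, _encode_raw_energy, energy_schema_map()),
    ):
        csv_path = outdir / f"{name}_survey.csv"
        encoder(df).to_csv(csv_path, index=False)
        schema_path = outdir / f"{name}_schema.yaml"
        schema.to_file(schema_path)
        paths[name] = csv_path
        paths[f"{name}_schema"] = schema_path
    return paths
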