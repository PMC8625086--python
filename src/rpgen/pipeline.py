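"""End-to-end population assembly.

Order of operations: harmonize all three validated survey tables (deriving
the pool variables and applying the exclusion filters), apply the run
configuration's person filters, sample ``num_persons`` individuals with
replacement by sampling weight, match one housing and one energy record to
each by pool, generate jittered physiology, and assemble one output row per
individual.

All randomness flows from the single run seed through named sub-streams
(person sampling, housing match, energy match, physiology), so a run is
bit-reproducible and insensitive to module-order changes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .geography import normalize_fips
from .harmonize import harmonize_energy, harmonize_housing, harmonize_persons
from .physiology import DEFAULT_JITTER_SIGMA, generate_population_physiology
from .runconfig import RunConfig
from .sampler import match_households, sample_persons
from .schema import SchemaMap
from .survey_io import (
    read_energy_survey,
    read_housing_survey,
    read_person_survey,
    write_population,
)

_PERSON_COLS = [
    "person_id", "household_id", "age", "gender", "race", "ethnicity",
    "state_fips", "puma_id", "puma_density", "n_adults", "n_children",
    "weight",
]
_HOUSING_COLS = [
    "housing_id", "rooms", "bedrooms", "bathrooms", "area_sqft", "tenure",
    "n_ceiling_fans", "n_windows", "has_pool", "has_vehicle", "high_ceilings",
]
_ENERGY_COLS = ["energy_id", "has_washer", "n_cooktops", "fuel"]


def _filter_persons(harmonized: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Apply the run filters, naming the first one that empties the table."""
    df = harmonized
    steps = [
        ("age range", lambda d: d[(d["age"] >= cfg.min_age) & (d["age"] <= cfg.max_age)]),
        ("gender", lambda d: d[d["gender"].isin(cfg.gender)]),
        ("ethnicity", lambda d: d[d["ethnicity"].isin(cfg.ethnicity)]),
        ("race", lambda d: d[d["race"].isin(cfg.race)]),
        ("regions", lambda d: d[d["region"].isin(cfg.regions)]),
        ("states", lambda d: d[d["state_fips"].map(normalize_fips).isin(cfg.states)]),
    ]
    for name, step in steps:
        df = step(df)
        if len(df) == 0:
            raise ConfigurationError(
                f"person table is empty after applying the {name} filter"
            )
    return df


def generate_population(cfg: RunConfig, persons: pd.DataFrame,
                        housing: pd.DataFrame, energy: pd.DataFrame,
                        house_type_recodes: dict | None = None,
                        jitter_sigma: float = DEFAULT_JITTER_SIGMA):
    """Assemble a synthetic population of ``cfg.num_persons`` individuals.

    Inputs are validated survey tables (as produced by the survey readers
    or the synthetic generators). Returns ``(population, summary)`` where
    *population* has one row per individual — person fields, matched
    housing and energy fields, physiology, and the ``pool``, ``inccat``,
    ``income`` and ``fallback_level`` columns — and *summary* reports
    filter counts, pool coverage and fallback usage.
    """
    persons_h, p_sum = harmonize_persons(persons, house_type_recodes)
    housing_h, h_sum = harmonize_housing(housing, house_type_recodes)
    energy_h, e_sum = harmonize_energy(energy, house_type_recodes)
    summary = {"persons": p_sum, "housing": h_sum, "energy": e_sum}
    if len(housing_h) == 0 or len(energy_h) == 0:
        raise ConfigurationError("no household records survive harmonization")

    eligible = _filter_persons(persons_h, cfg).reset_index(drop=True)
    summary["persons"]["eligible"] = len(eligible)

    ss = np.random.SeedSequence(cfg.seed)
    s_person, s_housing, s_energy, s_phys = ss.spawn(4)
    rng_person = np.random.default_rng(s_person)

    sampled = sample_persons(eligible, cfg.num_persons, rng_person)
    matches = match_households(
        sampled, housing_h, energy_h,
        np.random.default_rng(s_housing), np.random.default_rng(s_energy),
    )
    phys_seed = int(s_phys.generate_state(1)[0] % (2**31))
    phys = generate_population_physiology(
        sampled["age"].to_numpy(), sampled["gender"].to_numpy(),
        sampled["ethnicity"].to_numpy(), seed=phys_seed,
        jitter_sigma=jitter_sigma,
    )

    hrows = housing_h.iloc[matches["housing_row"].to_numpy()].reset_index(drop=True)
    erows = energy_h.iloc[matches["energy_row"].to_numpy()].reset_index(drop=True)

    pop = sampled[_PERSON_COLS + ["setting", "region", "house_type",
                                  "family_category", "inccat", "pool"]].copy()
    pop = pop.rename(columns={"weight": "person_weight"})
    pop["person_household_income"] = sampled["household_income"].to_numpy()
    for col in _HOUSING_COLS:
        pop[f"housing_{col}" if col != "housing_id" else "housing_id"] = (
            hrows[col].to_numpy()
        )
    pop["income"] = hrows["household_income"].to_numpy()  # carried from housing
    pop["housing_pool"] = hrows["pool"].to_numpy()
    for col in _ENERGY_COLS:
        pop[f"energy_{col}" if col != "energy_id" else "energy_id"] = (
            erows[col].to_numpy()
        )
    pop["energy_pool"] = erows["pool"].to_numpy()
    pop = pd.concat([pop.reset_index(drop=True), phys], axis=1)
    pop["fallback_level_housing"] = matches["fallback_level_housing"].to_numpy()
    pop["fallback_level_energy"] = matches["fallback_level_energy"].to_numpy()
    pop["fallback_level"] = matches["fallback_level"].to_numpy()

    fallback_hist = (
        pop["fallback_level"].value_counts().sort_index().to_dict()
    )
    summary["fallback_histogram"] = {int(k): int(v) for k, v in fallback_hist.items()}
    summary["pools_in_output"] = int(pop["pool"].nunique())
    summary["pools_relaxed"] = sorted(
        int(p) for p in pop.loc[pop["fallback_level"] > 0, "pool"].unique()
    )
    summary["rows"] = len(pop)
    return pop, summary


def run_from_files(cfg: RunConfig, person_path, person_schema_path,
                   housing_path, housing_schema_path,
                   energy_path, energy_schema_path, out_dir) -> dict:
    """Read the surveys, assemble the population, write CSV + summary.

    The house-type recode table is taken from the person schema map (the
    three maps ship the same table for the synthetic dialect). Output files:
    ``<run_name>_population.csv`` and ``<run_name>_summary.json``.
    """
    p_schema = SchemaMap.from_file(person_schema_path)
    h_schema = SchemaMap.from_file(housing_schema_path)
    e_schema = SchemaMap.from_file(energy_schema_path)
    persons = read_person_survey(person_path, p_schema)
    housing = read_housing_survey(housing_path, h_schema)
    energy = read_energy_survey(energy_path, e_schema)
    recodes = p_schema.house_type_recodes or h_schema.house_type_recodes

    pop, summary = generate_population(cfg, persons, housing, energy, recodes)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pop_path = out_dir / f"{cfg.run_name}_population.csv"
    write_population(pop, pop_path)
    summary_path = out_dir / f"{cfg.run_name}_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2), encoding="utf-8")
    return {"population": pop_path, "summary": summary_path}
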