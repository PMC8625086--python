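"""Per-individual physiology conditional on age, gender, and ethnicity.

A simplified parametric model generates internally consistent body measures
for toxicokinetic downstream use. Height comes from piecewise-linear
age/gender growth knots with multiplicative normal spread; body weight from
a lognormal BMI conditional on age and gender; everything else is a
documented closed form of height and weight:

* body surface area — Du Bois: ``BSA = 0.007184 * H^0.725 * W^0.425``
  (H in cm, W in kg, BSA in m^2);
* cardiac output — allometric ``CO = a * W^0.75`` (L/h), ``a`` calibrated so
  adult means sit at physiologic norms (~5.6 L/min adult male);
* breathing rate proportional to cardiac output (m^3/day);
* blood volume — Nadler's height/weight formula for adults, a per-kg
  coefficient for under-18s;
* compartment volumes (L, density ~1 kg/L) — adipose from a BMI-dependent
  fat fraction, organs and muscle as fixed fractions of lean mass,
  rest-of-body as the remainder after blood.

Internal consistency is the contract: recomputing every derived quantity
from an individual's stored height and weight reproduces the stored values
exactly. Jittering perturbs height and weight multiplicatively and then
recomputes the derived quantities, so consistency survives; jittered height
and weight are hard-capped at 225 cm and 160 kg.

All parameters live in ``data/physiology_constants.csv`` (columns:
parameter, gender, age, value; knot parameters carry one row per age knot)
so a different calibration — e.g. a survey-regression backend — can be
swapped in without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .enums import ETHNICITIES, GENDERS
from .errors import DomainError

HEIGHT_CAP_CM = 225.0
WEIGHT_CAP_KG = 160.0

#: Default multiplicative lognormal jitter scale for height and weight.
DEFAULT_JITTER_SIGMA = 0.05

#: Multiplicative shift applied to mean height by ethnicity. The default is
#: no shift; users with calibration data can supply their own mapping.
DEFAULT_ETHNICITY_HEIGHT_SHIFT = {e: 0.0 for e in ETHNICITIES}

_ORGANS = ("liver", "kidney", "lung", "brain", "adipose", "muscle", "rest")


@lru_cache(maxsize=1)
def _constants():
    ref = resources.files("rpgen.data").joinpath("physiology_constants.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    knots: dict = {}
    scalars: dict = {}
    for (param, gender), grp in df.groupby(["parameter", "gender"]):
        if grp["age"].notna().all() and len(grp) > 1:
            grp = grp.sort_values("age")
            knots[(param, gender)] = (
                grp["age"].to_numpy(dtype=float),
                grp["value"].to_numpy(dtype=float),
            )
        else:
            scalars[(param, gender)] = float(grp["value"].iloc[0])
    return knots, scalars


def _knot(param: str, gender: str, age: float) -> float:
    ages, values = _constants()[0][(param, gender)]
    return float(np.interp(age, ages, values))


def _scalar(param: str, gender: str) -> float:
    return _constants()[1][(param, gender)]


def mean_height(age: float, gender: str) -> float:
    """Population mean height (cm) at an age for a gender."""
    return _knot("mean_height", gender, age)


def mean_bmi(age: float, gender: str) -> float:
    """Population mean BMI (kg/m^2) at an age for a gender."""
    return _knot("mean_bmi", gender, age)


def body_surface_area(height_cm: float, weight_kg: float) -> float:
    """Du Bois body surface area in m^2 from height (cm) and weight (kg)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DomainError("height and weight must be positive")
    return 0.007184 * height_cm**0.725 * weight_kg**0.425


@dataclass(frozen=True)
class Physiology:
    """Internally consistent body measures for one synthetic individual."""

    age: int
    gender: str
    ethnicity: str
    height: float  # cm
    body_weight: float  # kg
    body_surface_area: float  # m^2
    breathing_rate: float  # m^3/day
    cardiac_output: float  # L/h
    blood_volume: float  # L
    hematocrit: float  # fraction
    compartment_volumes: dict = field(default_factory=dict)  # organ -> L


def _blood_volume(height_cm: float, weight_kg: float, gender: str, age: float) -> float:
    if age < 18:
        return _knot("bv_per_kg", gender, age) * weight_kg
    h_m = height_cm / 100.0
    if gender == "M":
        return 0.3669 * h_m**3 + 0.03219 * weight_kg + 0.6041
    return 0.3561 * h_m**3 + 0.03308 * weight_kg + 0.1833


def derive(height_cm: float, weight_kg: float, gender: str, age: float) -> dict:
    """All derived quantities as a deterministic function of (H, W, gender, age)."""
    bsa = body_surface_area(height_cm, weight_kg)
    co = _scalar("co_coeff", gender) * weight_kg**0.75
    br = _scalar("br_per_co", gender) * co
    bv = _blood_volume(height_cm, weight_kg, gender, age)
    hct = _knot("hematocrit", gender, age)

    bmi = weight_kg / (height_cm / 100.0) ** 2
    fat_frac = _knot("fat_base", gender, age) + _scalar(
        "fat_slope_per_bmi", gender
    ) * (bmi - 22.0)
    fat_frac = float(np.clip(fat_frac, _scalar("fat_min", gender),
                             _scalar("fat_max", gender)))
    adipose = fat_frac * weight_kg
    lean = weight_kg - adipose
    liver = _scalar("liver_lean_frac", gender) * lean
    kidney = _scalar("kidney_lean_frac", gender) * lean
    lung = _scalar("lung_lean_frac", gender) * lean
    brain = min(_scalar("brain_max_l", gender),
                _scalar("brain_per_kg", gender) * weight_kg)
    muscle = _scalar("muscle_lean_frac", gender) * lean
    rest = weight_kg - adipose - liver - kidney - lung - brain - muscle - bv
    rest = max(rest, 0.01 * weight_kg)  # degenerate-extreme guard
    return {
        "body_surface_area": bsa,
        "cardiac_output": co,
        "breathing_rate": br,
        "blood_volume": bv,
        "hematocrit": hct,
        "compartment_volumes": {
            "liver": liver, "kidney": kidney, "lung": lung, "brain": brain,
            "adipose": adipose, "muscle": muscle, "rest": rest,
        },
    }


def _draw_height_weight(age, gender, ethnicity, rng, ethnicity_shift=None):
    shift = (ethnicity_shift or DEFAULT_ETHNICITY_HEIGHT_SHIFT).get(ethnicity, 0.0)
    mu_h = mean_height(age, gender) * (1.0 + shift)
    cv = _scalar("height_cv", gender)
    height = mu_h * float(np.exp(rng.normal(0.0, cv)))
    sigma = _scalar("bmi_sigma", gender)
    bmi = mean_bmi(age, gender) * float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
    weight = bmi * (height / 100.0) ** 2
    return min(height, HEIGHT_CAP_CM), min(weight, WEIGHT_CAP_KG)


def generate_physiology(age: int, gender: str, ethnicity: str,
                        rng: np.random.Generator,
                        ethnicity_shift: dict | None = None) -> Physiology:
    """Generate one pre-jitter physiology conditional on demographics.

    Two calls with identical (age, gender, ethnicity) and identical
    generator state yield identical values; variation between such twins is
    supplied afterwards by :func:`jitter_physiology`.
    """
    if not 0 <= age <= 99:
        raise DomainError(f"age {age!r} outside [0, 99]")
    if gender not in GENDERS:
        raise DomainError(f"unknown gender code {gender!r}")
    if ethnicity not in ETHNICITIES:
        raise DomainError(f"unknown ethnicity code {ethnicity!r}")
    height, weight = _draw_height_weight(age, gender, ethnicity, rng, ethnicity_shift)
    return Physiology(
        age=int(age), gender=gender, ethnicity=ethnicity,
        height=height, body_weight=weight,
        **derive(height, weight, gender, age),
    )


def _with_factors(phys: Physiology, f_height: float, f_weight: float) -> Physiology:
    """Apply multiplicative factors to height/weight, cap, and recompute."""
    height = min(phys.height * f_height, HEIGHT_CAP_CM)
    weight = min(phys.body_weight * f_weight, WEIGHT_CAP_KG)
    return replace(
        phys, height=height, body_weight=weight,
        **derive(height, weight, phys.gender, phys.age),
    )


def jitter_physiology(phys: Physiology, rng: np.random.Generator,
                      sigma: float = DEFAULT_JITTER_SIGMA) -> Physiology:
    """Perturb height and weight multiplicatively (lognormal, scale sigma).

    Post-jitter height is capped at 225 cm and weight at 160 kg; every
    derived quantity is recomputed from the jittered pair, preserving
    internal consistency.
    """
    f_h, f_w = np.exp(rng.normal(0.0, sigma, size=2))
    return _with_factors(phys, float(f_h), float(f_w))


def generate_population_physiology(ages, genders, ethnicities, seed: int,
                                   jitter_sigma: float = DEFAULT_JITTER_SIGMA,
                                   ethnicity_shift: dict | None = None) -> pd.DataFrame:
    """Vectorized physiology for a sampled population.

    Pre-jitter draws use a sub-stream keyed on (age, gender, ethnicity)
    derived from ``seed``, so individuals sharing a demographic profile
    share pre-jitter values; a separate sequential stream supplies the
    per-individual jitter. Returns one row per input element.
    """
    ages = np.asarray(ages, dtype=int)
    genders = np.asarray(genders, dtype=object)
    ethnicities = np.asarray(ethnicities, dtype=object)
    n = len(ages)

    base: dict[tuple, Physiology] = {}
    for key in {(int(a), g, e) for a, g, e in zip(ages, genders, ethnicities)}:
        a, g, e = key
        sub = np.random.default_rng(
            np.random.SeedSequence([int(seed), 101, a, GENDERS.index(g),
                                    ETHNICITIES.index(e)])
        )
        base[key] = generate_physiology(a, g, e, sub, ethnicity_shift)

    jit_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    factors = np.exp(jit_rng.normal(0.0, jitter_sigma, size=(n, 2)))

    rows = []
    for i in range(n):
        phys = _with_factors(
            base[(int(ages[i]), genders[i], ethnicities[i])],
            float(factors[i, 0]), float(factors[i, 1]),
        )
        row = {
            "height_cm": phys.height,
            "body_weight_kg": phys.body_weight,
            "body_surface_area_m2": phys.body_surface_area,
            "breathing_rate_m3_day": phys.breathing_rate,
            "cardiac_output_l_h": phys.cardiac_output,
            "blood_volume_l": phys.blood_volume,
            "hematocrit": phys.hematocrit,
        }
        for organ in _ORGANS:
            row[f"vol_{organ}_l"] = phys.compartment_volumes[organ]
        rows.append(row)
    return pd.DataFrame(rows)
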