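"""Run configuration: which individuals to generate and how many.

Configurations come from a flat ``key = value`` text file (keys are
case-insensitive; dots and underscores are interchangeable, so
``Num.persons`` and ``num_persons`` both work), from YAML, or directly as
keyword arguments. Omitted fields take inclusive defaults: all ages 0-99,
both genders, every race/ethnicity code, all four regions, and all
contiguous-US states within the selected regions.

Region codes on input follow the run-file convention 1=West, 2=Midwest,
3=South, 4=Northeast.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .enums import ETHNICITIES, GENDERS, RACES, REGION_LABELS, Region
from .errors import ConfigurationError
from .geography import normalize_fips, region_by_state, states_in_regions

#: Input region codes -> region label (run-file convention).
TABLE1_REGION_CODES = {1: "West", 2: "Midwest", 3: "South", 4: "Northeast"}

DEFAULT_SEED = 1001


class RunConfig(BaseModel):
    """Validated parameters for one population run."""

    run_name: str
    num_persons: int = Field(ge=1)
    min_age: int = Field(default=0, ge=0, le=99)
    max_age: int = Field(default=99, ge=0, le=99)
    gender: set[str] = Field(default_factory=lambda: set(GENDERS))
    ethnicity: set[str] = Field(default_factory=lambda: set(ETHNICITIES))
    race: set[str] = Field(default_factory=lambda: set(RACES))
    regions: set[str] = Field(
        default_factory=lambda: set(REGION_LABELS.values())
    )
    states: set[str] | None = None
    seed: int = DEFAULT_SEED

    @field_validator("gender")
    @classmethod
    def _check_gender(cls, v):
        bad = v - set(GENDERS)
        if bad or not v:
            raise ValueError(f"invalid gender code(s): {sorted(bad) or 'empty'}")
        return v

    @field_validator("ethnicity")
    @classmethod
    def _check_eth(cls, v):
        bad = v - set(ETHNICITIES)
        if bad or not v:
            raise ValueError(f"invalid ethnicity code(s): {sorted(bad) or 'empty'}")
        return v

    @field_validator("race")
    @classmethod
    def _check_race(cls, v):
        bad = v - set(RACES)
        if bad or not v:
            raise ValueError(f"invalid race code(s): {sorted(bad) or 'empty'}")
        return v

    @field_validator("regions")
    @classmethod
    def _check_regions(cls, v):
        bad = v - set(REGION_LABELS.values())
        if bad or not v:
            raise ValueError(f"invalid region(s): {sorted(bad) or 'empty'}")
        return v

    @model_validator(mode="after")
    def _finish(self):
        if self.min_age > self.max_age:
            raise ValueError(
                f"min_age {self.min_age} exceeds max_age {self.max_age}"
            )
        if self.states is None:
            self.states = states_in_regions(self.regions)
        else:
            normalized = set()
            for f in self.states:
                nf = normalize_fips(f)
                if nf not in region_by_state():
                    raise ValueError(f"unknown or non-contiguous state FIPS code {f!r}")
                normalized.add(nf)
            in_regions = {
                f for f in normalized if region_by_state()[f] in self.regions
            }
            if not in_regions:
                raise ValueError(
                    "no requested state lies within the requested regions"
                )
            self.states = in_regions
        return self


def _parse_letters(value: str, what: str) -> set[str]:
    value = value.replace(",", "").replace(" ", "").upper()
    if not value:
        raise ConfigurationError(f"empty {what} specification")
    return set(value)


def _parse_region_codes(value: str) -> set[str]:
    value = value.replace(",", "").replace(" ", "")
    labels = set()
    for ch in value:
        try:
            labels.add(TABLE1_REGION_CODES[int(ch)])
        except (ValueError, KeyError):
            raise ConfigurationError(f"unknown region code {ch!r}") from None
    return labels


def _normalize_key(key: str) -> str:
    return key.strip().lower().replace(".", "_").replace("-", "_")


def _kv_from_text(text: str) -> dict:
    out = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"line {lineno}: expected key = value, got {line!r}")
        key, value = line.split("=", 1)
        out[_normalize_key(key)] = value.strip()
    return out


def parse_run_config(source, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a file path, text, or dict.

    ``source`` may be a path to a ``key = value`` or YAML file, a string of
    ``key = value`` lines, a dict, or ``None`` (overrides only).
    ``run_name`` and ``num_persons`` are required; everything else is
    defaulted inclusively.
    """
    data: dict = {}
    if source is not None:
        if isinstance(source, dict):
            data = {_normalize_key(k): v for k, v in source.items()}
        else:
            path = Path(source)
            if path.exists():
                text = path.read_text(encoding="utf-8")
                if path.suffix.lower() in (".yaml", ".yml"):
                    loaded = yaml.safe_load(text) or {}
                    data = {_normalize_key(k): v for k, v in loaded.items()}
                else:
                    data = _kv_from_text(text)
            else:
                data = _kv_from_text(str(source))
    data.update({_normalize_key(k): v for k, v in overrides.items()})

    fields: dict = {}
    for key, value in data.items():
        if value is None or (isinstance(value, str) and not value.strip()):
            continue  # blank inputs take defaults
        if key in ("run_name",):
            fields["run_name"] = str(value)
        elif key in ("num_persons", "min_age", "max_age", "seed"):
            try:
                fields[key] = int(value)
            except ValueError:
                raise ConfigurationError(f"{key} must be an integer, got {value!r}")
        elif key == "gender":
            fields["gender"] = _parse_letters(str(value), "gender")
        elif key == "ethnicity":
            fields["ethnicity"] = _parse_letters(str(value), "ethnicity")
        elif key == "race":
            fields["race"] = _parse_letters(str(value), "race")
        elif key == "regions":
            if isinstance(value, (list, set, tuple)):
                value = "".join(str(v) for v in value)
            fields["regions"] = _parse_region_codes(str(value))
        elif key == "states":
            if isinstance(value, (list, set, tuple)):
                items = [str(v) for v in value]
            else:
                items = [s for s in str(value).replace(" ", "").split(",") if s]
            fields["states"] = {normalize_fips(s) for s in items}
        else:
            raise ConfigurationError(f"unknown configuration key {key!r}")

    for required in ("run_name", "num_persons"):
        if required not in fields:
            raise ConfigurationError(f"required field {required!r} is missing")
    try:
        return RunConfig(**fields)
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc
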