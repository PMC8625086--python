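"""Schema maps: how a concrete survey file maps onto the internal tables.

Survey dialects differ by vintage and agency — column names, categorical
codings, even which integer means "male" — so each input file is read
through a :class:`SchemaMap` that names the source column for every
internal field and recodes raw categorical values onto the internal
vocabulary. Maps are stored as YAML (or JSON) files.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .errors import SchemaError


class SchemaMap(BaseModel):
    """Mapping from internal field names to one survey file's dialect.

    Attributes
    ----------
    columns:
        internal field name -> column name in the input file.
    recodes:
        internal field name -> {raw code -> internal value}. Fields absent
        here are taken verbatim. Raw codes are compared as strings.
    house_type_recodes:
        raw house-type code -> one of ``standalone``, ``multi_structure``,
        ``other``, ``group_quarters``. Used during harmonization, not at
        read time; ``None`` falls back to the package default vocabulary.
    """

    columns: dict[str, str]
    recodes: dict[str, dict[str, str]] = Field(default_factory=dict)
    house_type_recodes: dict[str, str] | None = None

    @classmethod
    def from_file(cls, path) -> "SchemaMap":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        try:
            data = (
                json.loads(text)
                if path.suffix.lower() == ".json"
                else yaml.safe_load(text)
            )
        except (json.JSONDecodeError, yaml.YAMLError) as exc:
            raise SchemaError(f"cannot parse schema map {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise SchemaError(f"schema map {path} is not a mapping")
        return cls.model_validate(data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = self.model_dump(exclude_none=True)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    def require(self, fields) -> None:
        """Raise SchemaError unless every required field is mapped."""
        missing = [f for f in fields if f not in self.columns]
        if missing:
            raise SchemaError(
                "schema map does not map required field(s): " + ", ".join(missing)
            )
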