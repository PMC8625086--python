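"""Categorical vocabularies shared across the survey sources.

The five pool dimensions (setting, region, house type, family category,
income category) carry the integer codes used by the pool index; the
remaining vocabularies are plain string codes as they appear in the
internal tables.
"""

from enum import IntEnum


class Setting(IntEnum):
    """Urban/rural community classification."""

    URBAN = 1
    RURAL = 2


class Region(IntEnum):
    """The four US census regions."""

    NORTHEAST = 1
    MIDWEST = 2
    SOUTH = 3
    WEST = 4


class HouseType(IntEnum):
    """Condensed housing-unit structure categories."""

    STANDALONE = 1
    MULTI_STRUCTURE = 2
    OTHER = 3


class FamilyCategory(IntEnum):
    """Household composition bins (adults are persons aged >= 18)."""

    ONE_ADULT_NO_CHILDREN = 1
    MULTI_ADULT_NO_CHILDREN = 2
    ONE_ADULT_WITH_CHILDREN = 3
    MULTI_ADULT_WITH_CHILDREN = 4


class IncomeCategory(IntEnum):
    """Location-stratified income terciles; 1 is the highest."""

    HIGH = 1
    MIDDLE = 2
    LOW = 3


# Label forms used in the internal DataFrames and in written CSVs.
SETTING_LABELS = {Setting.URBAN: "urban", Setting.RURAL: "rural"}
REGION_LABELS = {
    Region.NORTHEAST: "Northeast",
    Region.MIDWEST: "Midwest",
    Region.SOUTH: "South",
    Region.WEST: "West",
}
HOUSE_TYPE_LABELS = {
    HouseType.STANDALONE: "standalone",
    HouseType.MULTI_STRUCTURE: "multi_structure",
    HouseType.OTHER: "other",
}

SETTING_FROM_LABEL = {v: k for k, v in SETTING_LABELS.items()}
REGION_FROM_LABEL = {v: k for k, v in REGION_LABELS.items()}
HOUSE_TYPE_FROM_LABEL = {v: k for k, v in HOUSE_TYPE_LABELS.items()}

GENDERS = ("M", "F")
RACES = ("W", "B", "N", "A", "P", "O")
ETHNICITIES = ("N", "M", "O")
METRO_CLASSES = ("metropolitan", "micropolitan", "neither")
TENURES = ("own", "rent", "occupy_without_rent")
OCCUPANCIES = ("occupied", "vacant")
FUELS = ("electricity", "natural_gas", "fuel_oil", "propane", "wood", "other")
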