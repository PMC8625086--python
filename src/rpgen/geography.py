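"""Contiguous-US state lookup.

Ships the 48 contiguous states plus the District of Columbia with their
census regions. Persons outside this set (Alaska, Hawaii, territories)
cannot be matched to the housing surveys and are discarded during
harmonization.
"""

from functools import lru_cache
from importlib import resources

import pandas as pd

from .enums import Region, REGION_FROM_LABEL


@lru_cache(maxsize=1)
def state_table() -> pd.DataFrame:
    """Contiguous states + DC: columns state_fips, abbr, name, region."""
    ref = resources.files("rpgen.data").joinpath("state_regions.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype={"state_fips": str})
    return df


@lru_cache(maxsize=1)
def region_by_state() -> dict:
    """Map 2-digit state FIPS -> region label (e.g. '36' -> 'Northeast')."""
    df = state_table()
    return dict(zip(df["state_fips"], df["region"]))


def is_contiguous(fips: str) -> bool:
    return normalize_fips(fips) in region_by_state()


def normalize_fips(fips) -> str:
    """Zero-pad a state FIPS code to the canonical 2-digit string."""
    return str(fips).strip().zfill(2)


def states_in_regions(regions) -> set:
    """All contiguous state FIPS codes belonging to the given regions.

    ``regions`` may contain Region enums or region labels.
    """
    labels = set()
    for r in regions:
        if isinstance(r, Region):
            labels.add(r)
        else:
            labels.add(REGION_FROM_LABEL[str(r)])
    wanted = {lab for lab, enum in REGION_FROM_LABEL.items() if enum in labels}
    return {f for f, reg in region_by_state().items() if reg in wanted}
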