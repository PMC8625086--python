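from pathlib import Path

import pytest

from rpgen.synthetic import (
    SYNTHETIC_HOUSE_TYPE_RECODES,
    SyntheticSurveyConfig,
    generate_surveys,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def house_type_recodes() -> dict:
    return dict(SYNTHETIC_HOUSE_TYPE_RECODES)


@pytest.fixture(scope="session")
def covered_surveys():
    """Synthetic survey trio with every pool populated in all three tables."""
    cfg = SyntheticSurveyConfig(
        n_persons=3000, n_housing=1500, n_energy=900,
        seed=907, ensure_full_pool_coverage=True,
    )
    return generate_surveys(cfg)


@pytest.fixture(scope="session")
def small_surveys():
    """Organically sampled (no coverage guarantee) small survey trio."""
    cfg = SyntheticSurveyConfig(
        n_persons=600, n_housing=400, n_energy=300, seed=11,
    )
    return generate_surveys(cfg)
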