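from importlib import resources
from pathlib import Path

import pytest

from lignoferm.composition import BiomassComposition, read_composition_table


def data_path(name: str) -> Path:
    return Path(str(resources.files("lignoferm.data").joinpath(name)))


@pytest.fixture(scope="session")
def compositions() -> dict[str, BiomassComposition]:
    return read_composition_table(data_path("substrates.csv"))


@pytest.fixture(scope="session")
def flask_products_csv() -> Path:
    return data_path("flask_products.csv")


@pytest.fixture(scope="session")
def balance_experiments_csv() -> Path:
    return data_path("balance_experiments.csv")


@pytest.fixture(scope="session")
def scenario_yaml() -> Path:
    return data_path("scenario_coculture.yaml")
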