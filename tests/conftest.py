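import pytest

from pvkit.faers_ingest import default_smq, deduplicate
from pvkit.synth_faers import SimulationConfig, simulate


@pytest.fixture(scope="session")
def smq():
    return default_smq()


@pytest.fixture(scope="session")
def planted_config():
    return SimulationConfig(
        n_cases=8000,
        n_drugs=5,
        n_events=4,
        background_rate=0.02,
        signal_matrix={("DRUG_001", "Pancreatitis acute"): 10.0},
        tto_params={("DRUG_001", "Pancreatitis acute"): (900.0, 1.2)},
        duplicate_rate=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_dataset(planted_config):
    return simulate(planted_config)


@pytest.fixture(scope="session")
def planted_reports(planted_dataset):
    return deduplicate(planted_dataset.tables)
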