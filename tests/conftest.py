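import pytest

from pvsignal.synth import SynthConfig, generate_dataset


QUERY_DRUG = "LEVONORGESTREL"
PLANTED_EVENT = "Menstruation delayed"


def small_config(**overrides) -> SynthConfig:
    """A compact multi-drug, multi-event stream with one planted pair."""
    defaults = dict(
        n_cases_per_quarter=1000,
        quarters=("2012Q2", "2012Q3", "2012Q4", "2013Q1"),
        drug_vocabulary=(
            (QUERY_DRUG, 0.10),
            ("IBUPROFEN", 0.30),
            ("METFORMIN", 0.20),
            ("ATORVASTATIN", 0.15),
        ),
        event_vocabulary=(
            (PLANTED_EVENT, 0.02),
            ("Headache", 0.20),
            ("Nausea", 0.15),
            ("Dizziness", 0.10),
            ("Rash", 0.10),
        ),
        planted_associations=((QUERY_DRUG, PLANTED_EVENT, 6.0),),
        duplicate_fraction=0.10,
        seed=20_260_901,
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """One generated dataset shared by parsing/assembly/pipeline tests."""
    config = small_config()
    out = tmp_path_factory.mktemp("synth_data")
    files = generate_dataset(config, out)
    return config, out, files
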