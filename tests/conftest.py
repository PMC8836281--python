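import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from oleopep import datasets, motifs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: strategy for bare canonical sequences
sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


@pytest.fixture(scope="session")
def library():
    return motifs.default_library()


@pytest.fixture(scope="session")
def db_records():
    return datasets.voo_db_records()


@pytest.fixture(scope="session")
def denovo_records():
    return datasets.voo_denovo_records()
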